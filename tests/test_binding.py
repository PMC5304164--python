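"""Binding-isotherm solvers and fits against closed-form/bisection oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from augerdna.binding import (
    TitrationSeries,
    inner_filter_correct,
    kaminoh_fit,
    kaminoh_model,
    mvh_bound_density,
    mvh_bound_fraction,
    mvh_free_ligand,
    mvh_fit,
)
from augerdna.synthdata import gen_titration

GRID = np.linspace(2e-7, 8e-5, 12)
LTOT = 5e-6


def bisection_isotherm_oracle(K, n, Cf, tol=1e-12):
    """Plain interval-halving solution of the neighbor-exclusion isotherm."""

    def f(r):
        return (
            Cf * K * (1 - n * r) * ((1 - n * r) / (1 - (n - 1) * r)) ** (n - 1)
            - r
        )

    lo, hi = 0.0, (1.0 / n) * (1 - 1e-15)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


class TestInnerFilter:
    def test_transparent_sample_unchanged(self):
        s = TitrationSeries(LTOT, GRID, np.full(12, 100.0),
                            absorb_ex=np.zeros(12), absorb_em=np.zeros(12))
        out = inner_filter_correct(s)
        np.testing.assert_allclose(out.intensity, s.intensity)
        assert out.inner_filter_corrected

    @pytest.mark.parametrize(
        "a_ex, a_em, i_obs, expected",
        [(0.1, 0.1, 100.0, 125.9), (0.04, 0.0, 50.0, 52.3)],
    )
    def test_correction_arithmetic(self, a_ex, a_em, i_obs, expected):
        s = TitrationSeries(LTOT, GRID, np.full(12, i_obs),
                            absorb_ex=np.full(12, a_ex),
                            absorb_em=np.full(12, a_em))
        out = inner_filter_correct(s)
        assert out.intensity[0] == pytest.approx(expected, abs=0.1)

    def test_missing_absorbance_passthrough_flag(self):
        s = TitrationSeries(LTOT, GRID, np.full(12, 100.0))
        out = inner_filter_correct(s)
        assert out is s
        assert not out.inner_filter_corrected


class TestIsothermSolver:
    def test_zero_free_ligand(self):
        assert mvh_bound_density(3.5e5, 1.25, 0.0) == 0.0

    def test_langmuir_reduction_at_n_one(self):
        # K*Cf = 1 -> half occupancy
        assert mvh_bound_density(1e5, 1.0, 1e-5) == pytest.approx(0.5)
        for cf in (1e-7, 1e-6, 1e-5):
            K = 2e5
            assert mvh_bound_density(K, 1.0, cf) == pytest.approx(
                K * cf / (1 + K * cf), rel=1e-12
            )

    @pytest.mark.parametrize("K, n, cf", [
        (3.8e5, 1.3, 1e-6),
        (6.02e5, 2.48, 5e-6),
        (1e4, 4.0, 1e-4),
    ])
    def test_matches_bisection_oracle(self, K, n, cf):
        assert mvh_bound_density(K, n, cf) == pytest.approx(
            bisection_isotherm_oracle(K, n, cf), abs=1e-10
        )

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        K=st.floats(1e3, 1e7),
        n=st.floats(1.0, 6.0),
        cf=st.floats(1e-9, 1e-3),
    )
    def test_bounded_and_monotone(self, K, n, cf):
        r = mvh_bound_density(K, n, cf)
        assert 0.0 <= r < 1.0 / n
        assert mvh_bound_density(K, n, cf * 1.5) >= r
        assert mvh_bound_density(K * 2.0, n, cf) >= r

    def test_mass_balance_self_consistency(self):
        for bp in (1e-6, 1e-5, 1e-4):
            cf = mvh_free_ligand(3.5e5, 1.25, LTOT, bp)
            cb = mvh_bound_density(3.5e5, 1.25, cf) * bp
            assert cb + cf == pytest.approx(LTOT, rel=1e-12)


class TestKaminohFit:
    def test_noiseless_recovery_of_reference_parameters(self):
        # hyperbolic-model parameters of a rhenium conjugate fit
        series = gen_titration(K=1.12e5, n=1.0, I0=5e5, I_sat=4.54e7,
                               dna_bp_M=GRID, ligand_total_M=LTOT,
                               model="kaminoh")
        fit = kaminoh_fit(series)
        assert fit.K == pytest.approx(1.12e5, rel=1e-3)
        assert fit.I_sat == pytest.approx(4.54e7, rel=1e-3)
        assert fit.r2 > 0.9999

    def test_flat_intensity_flagged_non_identifiable(self):
        s = TitrationSeries(LTOT, GRID, np.full(12, 42.0))
        fit = kaminoh_fit(s)
        assert not fit.identifiable
        assert fit.K == 0.0

    def test_noisy_recovery_within_15_percent(self):
        k_true = 9.5e4
        errs = []
        for seed in range(10):
            series = gen_titration(
                K=k_true, n=1.0, I0=5e5, I_sat=6e7, dna_bp_M=GRID[:10],
                ligand_total_M=LTOT, noise_sd=0.02 * 6e7, seed=seed,
                model="kaminoh")
            errs.append(abs(kaminoh_fit(series).K - k_true) / k_true)
        assert np.median(errs) < 0.15

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kaminoh_fit(TitrationSeries(LTOT, GRID[:3],
                                        np.array([1.0, 2.0, 3.0])))


class TestMvhFit:
    def test_noiseless_recovery_of_reference_parameters(self):
        # neighbor-exclusion parameters of an iodinated conjugate fit
        series = gen_titration(K=3.5e5, n=1.25, I0=1e6, I_sat=5e7,
                               dna_bp_M=GRID, ligand_total_M=LTOT)
        fit = mvh_fit(series)
        assert fit.K == pytest.approx(3.5e5, rel=0.01)
        assert fit.n == pytest.approx(1.25, rel=0.01)

    def test_fixed_n_one_agrees_with_langmuir_oracle(self):
        K = 2.2e5
        theta = mvh_bound_fraction(K, 1.0, LTOT, GRID)
        series = TitrationSeries(LTOT, GRID, 1e6 + (5e7 - 1e6) * theta)
        fit = mvh_fit(series, fix_n=1.0)
        assert fit.K == pytest.approx(K, rel=1e-3)

    def test_noisy_recovery_within_10_percent(self):
        """The K-n ridge makes single noisy fits scatter by ~10%, but the
        replicate-averaged estimate recovers K well inside 10%."""
        k_true, n_true = 3.5e5, 1.25
        ks = []
        for seed in range(20):
            series = gen_titration(
                K=k_true, n=n_true, I0=1e6, I_sat=5e7, dna_bp_M=GRID,
                ligand_total_M=LTOT, noise_sd=0.01 * 4.9e7, seed=seed)
            ks.append(mvh_fit(series).K)
        assert abs(np.mean(ks) - k_true) / k_true < 0.10

    def test_kaminoh_K_below_mvh_K_when_sites_overlap(self):
        """With n > 1 the hyperbolic model underestimates K on the same
        data (saturable-enhancement fits of neighbor-exclusion curves)."""
        for K, n in [(3.5e5, 1.25), (6.02e5, 2.48)]:
            series = gen_titration(K=K, n=n, I0=1e6, I_sat=5e7,
                                   dna_bp_M=GRID, ligand_total_M=LTOT)
            assert kaminoh_fit(series).K < mvh_fit(series).K
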