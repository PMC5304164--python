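"""Poisson strand-break inversion and D0 / DSB-yield fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from augerdna.plasmid import (
    GelLane,
    IsoformFractions,
    PlasmidPrep,
    dmso_decomposition,
    dsb_dose_response,
    lane_fractions,
    poisson_breaks,
    yield_from_D0,
)
from augerdna.synthdata import GelSimConfig, gen_gel_series


def bisection_mu_dsb(f_lin, tol=1e-12):
    """Invert f_lin = mu exp(-mu) on [0, 1] by plain interval halving."""
    lo, hi = 0.0, 1.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if mid * math.exp(-mid) < f_lin:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestLaneFractions:
    @pytest.mark.parametrize(
        "bands, factor, expected",
        [
            ((100.0, 0.0, 0.0), 1.0, (1.0, 0.0, 0.0)),
            ((50.0, 30.0, 20.0), 1.0, (0.50, 0.30, 0.20)),
            ((50.0, 30.0, 20.0), 1.4, (0.5833, 0.2500, 0.1667)),
        ],
    )
    def test_staining_corrected_normalization(self, bands, factor, expected):
        lane = GelLane(0.0, *bands)
        fr = lane_fractions(lane, factor)
        assert (fr.f_sc, fr.f_oc, fr.f_lin) == pytest.approx(
            expected, abs=1e-4
        )
        assert fr.f_sc + fr.f_oc + fr.f_lin == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_lane_rejected(self):
        with pytest.raises(ValueError):
            GelLane(0.0, 0.0, 0.0, 0.0)


class TestPoissonBreaks:
    def test_undamaged_plasmid(self):
        fr = IsoformFractions(1.0, 0.0, 0.0, 1.0)
        br = poisson_breaks(fr)
        assert br.mu_dsb == 0.0 and br.mu_ssb == 0.0

    def test_flin_inversion_matches_bisection_oracle(self):
        fr = IsoformFractions(0.85, 0.05, 0.10, 1.0)
        br = poisson_breaks(fr)
        assert br.mu_dsb == pytest.approx(0.1118, abs=2e-4)
        assert br.mu_dsb == pytest.approx(bisection_mu_dsb(0.10), abs=1e-9)

    def test_combined_ssb_dsb_estimate(self):
        fr = IsoformFractions(0.5, 0.4, 0.1, 1.0)
        br = poisson_breaks(fr)
        assert br.mu_dsb == pytest.approx(0.1118, abs=2e-4)
        assert br.mu_ssb == pytest.approx(
            math.log(2.0) - bisection_mu_dsb(0.10), abs=1e-9
        )

    def test_censoring_at_detection_floor(self):
        fr = IsoformFractions(0.0, 0.9, 0.1, 1.0)
        br = poisson_breaks(fr, detection_floor=1e-3)
        assert br.censored
        assert br.mu_dsb + br.mu_ssb == pytest.approx(-math.log(1e-3))

    def test_branch_overflow_falls_back_to_total(self):
        # f_lin beyond e^-1 has no single-DSB solution
        fr = IsoformFractions(0.5, 0.1, 0.4, 1.0)
        br = poisson_breaks(fr)
        assert br.mu_dsb == pytest.approx(math.log(2.0))

    def test_linear_approximation_method(self):
        fr = IsoformFractions(0.9, 0.05, 0.05, 1.0)
        br = poisson_breaks(fr, method="linear")
        assert br.mu_dsb == pytest.approx(0.05)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        mu_dsb=st.floats(0.0, 0.9),
        mu_ssb=st.floats(0.0, 3.0),
    )
    def test_forward_model_round_trip(self, mu_dsb, mu_ssb):
        """Inversion of the exact forward Poisson isoform model."""
        f_sc = math.exp(-(mu_ssb + mu_dsb))
        f_lin = mu_dsb * math.exp(-mu_dsb)
        f_oc = 1.0 - f_sc - f_lin
        if f_oc < 0:  # unreachable corner of the forward model
            return
        fr = IsoformFractions(f_sc, f_oc, f_lin, 1.0)
        br = poisson_breaks(fr)
        assert br.mu_dsb == pytest.approx(mu_dsb, abs=1e-8)
        assert br.mu_ssb == pytest.approx(mu_ssb, abs=1e-8)


class TestDoseResponse:
    def test_perfect_line_recovers_D0(self, prep_tc):
        slope = 2e-14
        lanes = []
        for dose in np.linspace(1e12, 3e13, 6):
            mu = slope * dose
            f_sc = math.exp(-mu)
            f_lin = mu * math.exp(-mu)
            lanes.append(GelLane(dose, f_sc, 1 - f_sc - f_lin, f_lin))
        res = dsb_dose_response(lanes, prep_tc, sc_staining_factor=1.0)
        assert res.D0 == pytest.approx(5e13, rel=1e-9)
        assert res.Y_dsb * res.D0 == pytest.approx(
            res.plasmid_density_per_ml, rel=1e-10
        )

    def test_synthetic_round_trip_within_5_percent(self, tc99m, prep_tc):
        cfg = GelSimConfig(nuclide=tc99m, prep=prep_tc,
                           D0_true_per_ml=1e14, densitometry_cv=0.05, seed=7)
        res = dsb_dose_response(gen_gel_series(cfg), prep_tc, 1.4)
        assert res.D0 == pytest.approx(1e14, rel=0.05)

    def test_noiseless_monotone_mu(self, tc99m, prep_tc):
        cfg = GelSimConfig(nuclide=tc99m, prep=prep_tc,
                           D0_true_per_ml=1e14, densitometry_cv=0.0, seed=0)
        lanes = gen_gel_series(cfg)
        mus = [poisson_breaks(lane_fractions(ln, 1.4)).mu_dsb
               for ln in lanes]
        assert all(b >= a for a, b in zip(mus, mus[1:]))

    def test_flat_series_censored_not_crashing(self, prep_tc):
        lanes = [GelLane(d, 0.9, 0.1, 0.0) for d in (1e12, 2e12, 3e12)]
        res = dsb_dose_response(lanes, prep_tc)
        assert res.censored and res.D0 is None and res.Y_dsb is None

    def test_needs_three_distinct_doses(self, prep_tc):
        lanes = [GelLane(1e12, 0.9, 0.05, 0.05),
                 GelLane(1e12, 0.8, 0.1, 0.1)]
        with pytest.raises(ValueError):
            dsb_dose_response(lanes, prep_tc)


class TestYields:
    def test_reference_yields_from_printed_D0(self, prep_tc, prep_i):
        # graded-activity assay, shortest-linker organometallic compound
        assert yield_from_D0(3.33e13, prep_tc) == pytest.approx(0.0336,
                                                                rel=0.01)
        # aliquot assay, mid-linker iodinated compound
        assert yield_from_D0(6.94e13, prep_i) == pytest.approx(0.048,
                                                               rel=0.01)

    def test_yield_identity(self, prep_i):
        d0 = prep_i.plasmid_density_per_ml
        assert yield_from_D0(d0, prep_i) == pytest.approx(1.0, rel=1e-12)

    def test_non_positive_D0_rejected(self, prep_i):
        with pytest.raises(ValueError):
            yield_from_D0(0.0, prep_i)

    def test_plasmid_density(self, prep_i):
        # 20 ug/mL of 3.6e6 g/mol duplex
        assert prep_i.plasmid_density_per_ml == pytest.approx(3.346e12,
                                                              rel=1e-3)


class TestDmsoDecomposition:
    @staticmethod
    def _dr(y, rho=3.346e12):
        from augerdna.plasmid import DoseResponse
        return DoseResponse(
            slope=y / rho, intercept=0.0, D0=rho / y if y else None,
            Y_dsb=y, plasmid_density_per_ml=rho, se_slope=0.0,
            se_intercept=0.0, se_D0=0.0, se_Y=0.0, n_points=4, r2=1.0)

    def test_direct_indirect_split(self):
        out = dmso_decomposition(self._dr(0.0336), self._dr(0.0224))
        assert out["direct"] == pytest.approx(0.0224)
        assert out["indirect"] == pytest.approx(0.0112)
        assert out["classification"] == "mixed"

    def test_equal_yields_no_indirect(self):
        out = dmso_decomposition(self._dr(0.03), self._dr(0.03))
        assert out["indirect"] == 0.0
        assert out["classification"] == "predominantly direct"

    def test_exclusively_indirect_classification(self):
        out = dmso_decomposition(self._dr(0.033), self._dr(0.001))
        assert out["classification"] == "exclusively indirect"

    def test_negative_indirect_floored_and_flagged(self):
        out = dmso_decomposition(self._dr(0.03), self._dr(0.04))
        assert out["indirect"] == 0.0
        assert out["negative_indirect_flagged"]

    def test_mismatched_preps_rejected(self):
        with pytest.raises(ValueError):
            dmso_decomposition(self._dr(0.03, rho=3.3e12),
                               self._dr(0.02, rho=1.1e12))
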