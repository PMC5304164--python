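"""DNA-binding isotherm fitting from fluorescence titrations.

Intercalators such as acridine orange derivatives light up on binding to
duplex DNA; titrating a fixed ligand concentration with increasing DNA
(in base pairs) gives a saturating intensity curve from which an
intrinsic association constant is extracted.  Two models are provided:

* a saturable hyperbolic enhancement ("Kaminoh-style"),
  ``I([DNA]) = (I0 + I_sat * K * [DNA]) / (1 + K * [DNA])``, reported as
  ``K`` and the saturation intensity ``I_sat``;
* the McGhee-von Hippel neighbor-exclusion lattice isotherm, in which
  the bound-ligand density per base pair ``r`` at free-ligand
  concentration ``Cf`` satisfies

      r / Cf = K (1 - n r) * [(1 - n r) / (1 - (n - 1) r)]^(n - 1)

  with intrinsic constant ``K`` (1/M) and site size ``n`` (bp per bound
  ligand).  The fluorescence signal is modelled as
  ``I = I0 + (I_sat - I0) * Cb / L_tot`` (bound fraction weighting) by
  default.

Observed intensities can first be corrected for inner-filter
attenuation, ``I_corr = I_obs * 10**((A_ex + A_em) / 2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "TitrationSeries",
    "BindingFit",
    "FitError",
    "inner_filter_correct",
    "kaminoh_model",
    "kaminoh_fit",
    "mvh_bound_density",
    "mvh_free_ligand",
    "mvh_bound_fraction",
    "mvh_fit",
]

_R_TOL = 1e-12  # absolute tolerance on the bound density root


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries the last parameter vector."""

    def __init__(self, message: str, last_params=None):
        super().__init__(message)
        self.last_params = last_params


@dataclass(frozen=True)
class TitrationSeries:
    """One fluorescence titration at fixed total ligand concentration.

    dna_bp_M are base-pair concentrations (strictly increasing, >= 0);
    absorbances at the excitation/emission wavelengths are optional and
    enable the inner-filter correction.
    """

    ligand_total_M: float
    dna_bp_M: np.ndarray
    intensity: np.ndarray
    absorb_ex: np.ndarray | None = None
    absorb_em: np.ndarray | None = None
    inner_filter_corrected: bool = False

    def __post_init__(self) -> None:
        d = np.asarray(self.dna_bp_M, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        if d.size == 0:
            raise ValueError("titration has no points")
        if d.shape != i.shape:
            raise ValueError("dna_bp_M and intensity must have equal length")
        if np.any(d < 0):
            raise ValueError("DNA concentrations must be non-negative")
        if np.any(np.diff(d) <= 0):
            raise ValueError("DNA concentrations must be strictly increasing")
        if self.ligand_total_M <= 0:
            raise ValueError("total ligand concentration must be positive")
        object.__setattr__(self, "dna_bp_M", d)
        object.__setattr__(self, "intensity", i)
        for attr in ("absorb_ex", "absorb_em"):
            a = getattr(self, attr)
            if a is not None:
                a = np.asarray(a, dtype=float)
                if a.shape != d.shape:
                    raise ValueError(f"{attr} length mismatch")
                object.__setattr__(self, attr, a)

    def __len__(self) -> int:
        return self.dna_bp_M.size


@dataclass(frozen=True)
class BindingFit:
    """Result of a binding-isotherm fit."""

    model: str
    K: float
    I0: float
    I_sat: float
    r2: float
    se: dict[str, float]
    n: float | None = None
    identifiable: bool = True
    notes: str = ""


def inner_filter_correct(series: TitrationSeries) -> TitrationSeries:
    """Apply the inner-filter correction ``I * 10**((A_ex + A_em)/2)``.

    Returns a new series; when either absorbance list is missing the
    series is passed through unchanged with ``inner_filter_corrected``
    still False, signalling that no correction was possible.
    """
    if series.absorb_ex is None or series.absorb_em is None:
        return series
    factor = 10.0 ** ((series.absorb_ex + series.absorb_em) / 2.0)
    return replace(
        series,
        intensity=series.intensity * factor,
        inner_filter_corrected=True,
    )


# ---------------------------------------------------------------------------
# Kaminoh-style saturable hyperbola
# ---------------------------------------------------------------------------

def kaminoh_model(dna_bp_M, K, I0, I_sat):
    """Saturable enhancement hyperbola; -> I_sat as [DNA] -> infinity."""
    d = np.asarray(dna_bp_M, dtype=float)
    return (I0 + I_sat * K * d) / (1.0 + K * d)


def _r_squared(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


def _param_se(res, names) -> dict[str, float]:
    """First-order standard errors from a least_squares result."""
    m, p = res.jac.shape
    dof = max(m - p, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return dict(zip(names, se.tolist()))


def kaminoh_fit(series: TitrationSeries) -> BindingFit:
    """Least-squares fit of the saturable-enhancement hyperbola.

    Requires >= 4 points.  A flat titration (no intensity change) is
    flagged non-identifiable rather than fitted.
    """
    if len(series) < 4:
        raise ValueError("need at least 4 titration points")
    d = series.dna_bp_M
    y = series.intensity
    span = float(np.ptp(y))
    scale = max(float(np.max(np.abs(y))), 1.0)
    if span <= 1e-9 * scale:
        return BindingFit(
            model="kaminoh", K=0.0, I0=float(y[0]), I_sat=float(y[-1]),
            r2=1.0, se={}, identifiable=False,
            notes="intensity constant over the titration; K not identifiable",
        )

    i0_guess = float(y[0])
    isat_guess = float(y[-1]) + 0.05 * span
    d_pos = d[d > 0]
    k_guesses = [1.0 / float(np.median(d_pos)), 0.2 / float(d_pos.min()),
                 5.0 / float(d_pos.max())]

    def resid(p):
        logK, i0, isat = p
        return kaminoh_model(d, math.exp(logK), i0, isat) - y

    best = None
    for kg in k_guesses:
        try:
            res = least_squares(resid, [math.log(kg), i0_guess, isat_guess],
                                method="lm", xtol=1e-14, ftol=1e-14)
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitError("saturable-hyperbola fit did not converge",
                       last_params=[k_guesses[0], i0_guess, isat_guess])
    logK, i0, isat = best.x
    K = math.exp(logK)
    yhat = kaminoh_model(d, K, i0, isat)
    se = _param_se(best, ["logK", "I0", "I_sat"])
    se["K"] = K * se.pop("logK", float("nan"))
    return BindingFit(model="kaminoh", K=K, I0=float(i0), I_sat=float(isat),
                      r2=_r_squared(y, yhat), se=se)


# ---------------------------------------------------------------------------
# McGhee-von Hippel neighbor-exclusion isotherm
# ---------------------------------------------------------------------------

def mvh_bound_density(K: float, n: float, Cf: float) -> float:
    """Bound-ligand density r per base pair at free concentration Cf.

    Solves the neighbor-exclusion isotherm for the unique root on
    [0, 1/n).  For n = 1 this reduces to the Langmuir closed form
    ``r = K Cf / (1 + K Cf)``.
    """
    if K < 0 or Cf < 0:
        raise ValueError("K and Cf must be non-negative")
    if n < 1:
        raise ValueError("site size n must be >= 1")
    if Cf == 0.0 or K == 0.0:
        return 0.0
    if n == 1.0:
        return K * Cf / (1.0 + K * Cf)

    def h(r: float) -> float:
        one_minus_nr = 1.0 - n * r
        denom = 1.0 - (n - 1.0) * r
        return Cf * K * one_minus_nr * (one_minus_nr / denom) ** (n - 1.0) - r

    hi = (1.0 / n) * (1.0 - 1e-15)
    if h(0.0) <= 0.0:
        return 0.0
    r = brentq(h, 0.0, hi, xtol=_R_TOL, rtol=8.9e-16, maxiter=200)
    if abs(h(r)) > 1e-10:
        raise ArithmeticError("isotherm root did not meet residual tolerance")
    return float(r)


def mvh_free_ligand(K: float, n: float, L_tot: float, bp_M: float) -> float:
    """Free-ligand concentration satisfying mass balance Cf + r*bp = L_tot.

    The isotherm and the mass balance are solved jointly as a single
    root-find in the bound density r on [0, min(1/n, L_tot/bp)):
    G(r) = (L_tot - r*bp) * K * (1-nr) * [(1-nr)/(1-(n-1)r)]^(n-1) - r
    is positive at r = 0 and negative at the upper end, and the physical
    root is unique, so brentq applies directly.
    """
    if L_tot <= 0:
        raise ValueError("total ligand must be positive")
    if bp_M < 0:
        raise ValueError("bp concentration must be non-negative")
    if bp_M == 0.0 or K == 0.0:
        return L_tot

    def big_g(r: float) -> float:
        cf = L_tot - r * bp_M
        one_minus_nr = 1.0 - n * r
        denom = 1.0 - (n - 1.0) * r
        return cf * K * one_minus_nr * (one_minus_nr / denom) ** (n - 1.0) - r

    hi = min(1.0 / n, L_tot / bp_M) * (1.0 - 1e-15)
    if big_g(hi) >= 0.0:  # saturated lattice / all ligand bound
        r = hi
    else:
        r = brentq(big_g, 0.0, hi, xtol=_R_TOL, rtol=8.9e-16, maxiter=200)
    return float(L_tot - r * bp_M)


def mvh_bound_fraction(K: float, n: float, L_tot: float, bp_M) -> np.ndarray:
    """Fraction of total ligand bound at each DNA (bp) concentration."""
    bp = np.atleast_1d(np.asarray(bp_M, dtype=float))
    out = np.empty_like(bp)
    for i, b in enumerate(bp):
        cf = mvh_free_ligand(K, n, L_tot, float(b))
        out[i] = (L_tot - cf) / L_tot
    return out


def _mvh_intensity(K, n, I0, I_sat, L_tot, bp) -> np.ndarray:
    theta = mvh_bound_fraction(K, n, L_tot, bp)
    return I0 + (I_sat - I0) * theta


def mvh_fit(
    series: TitrationSeries,
    fix_n: float | None = None,
    n_starts: int = 3,
    seed: int = 0,
) -> BindingFit:
    """Fit (K, n, I0, I_sat) of the neighbor-exclusion isotherm.

    Bound fraction at each titration point is computed self-consistently
    with ligand mass balance.  Multi-start least squares (``n_starts``
    seeded perturbations around data-derived heuristics) reduces the
    local-minimum risk.  ``fix_n`` pins the site size (e.g. 1 to recover
    a Langmuir hyperbola).
    """
    if len(series) < 4:
        raise ValueError("need at least 4 titration points")
    d = series.dna_bp_M
    y = series.intensity
    L = series.ligand_total_M
    span = float(np.ptp(y))
    scale = max(float(np.max(np.abs(y))), 1.0)
    if span <= 1e-9 * scale:
        return BindingFit(
            model="mcghee_von_hippel", K=0.0, n=fix_n or 1.0,
            I0=float(y[0]), I_sat=float(y[-1]), r2=1.0, se={},
            identifiable=False,
            notes="intensity constant over the titration; K not identifiable",
        )

    d_pos = d[d > 0]
    k0 = 1.0 / float(np.median(d_pos))
    i0_g = float(y[0])
    isat_g = float(y[-1]) + 0.1 * span
    rng = np.random.default_rng(seed)

    fit_n = fix_n is None

    def unpack(p):
        if fit_n:
            logK, n_, i0, isat = p
            return math.exp(logK), n_, i0, isat
        logK, i0, isat = p
        return math.exp(logK), float(fix_n), i0, isat

    def resid(p):
        K, n_, i0, isat = unpack(p)
        return _mvh_intensity(K, n_, i0, isat, L, d) - y

    starts = []
    for j in range(max(n_starts, 1)):
        jit = rng.uniform(-1.0, 1.0) if j else 0.0
        logk = math.log(k0) + jit
        if fit_n:
            starts.append([logk, 1.0 + 0.75 * j, i0_g, isat_g])
        else:
            starts.append([logk, i0_g, isat_g])

    if fit_n:
        lb = [-np.inf, 1.0, -np.inf, -np.inf]
        ub = [np.inf, 50.0, np.inf, np.inf]
    else:
        lb, ub = -np.inf, np.inf

    best = None
    for p0 in starts:
        try:
            res = least_squares(resid, p0, method="trf", bounds=(lb, ub),
                                xtol=1e-14, ftol=1e-14, max_nfev=2000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("neighbor-exclusion fit did not converge",
                       last_params=starts[0])
    K, n_, i0, isat = unpack(best.x)
    yhat = _mvh_intensity(K, n_, i0, isat, L, d)
    names = ["logK", "n", "I0", "I_sat"] if fit_n else ["logK", "I0", "I_sat"]
    se = _param_se(best, names)
    se["K"] = K * se.pop("logK", float("nan"))
    return BindingFit(model="mcghee_von_hippel", K=float(K), n=float(n_),
                      I0=float(i0), I_sat=float(isat),
                      r2=_r_squared(y, yhat), se=se)
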