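"""Plasmid strand-break quantification from gel densitometry.

A supercoiled (SC) plasmid is converted to open-circular (OC) form by a
single-strand break and to linear (Lin) form by a double-strand break.
With breaks accruing independently at random (Poisson statistics), the
isoform fractions after exposure relate to the mean numbers of breaks
per plasmid, ``mu_ssb`` and ``mu_dsb``:

    f_sc  = exp(-(mu_ssb + mu_dsb))
    f_lin = mu_dsb * exp(-mu_dsb)        (exactly one DSB; >1 DSB fragments)

Inverting lane-by-lane gives ``mu_dsb`` per dose point; an ordinary
least-squares line of ``mu_dsb`` against accumulated decays/mL yields
the radiosensitivity parameters

    D0     = 1 / slope        (decays/mL per DSB per plasmid)
    Y(DSB) = plasmid_density / D0   (double-strand breaks per decay)

Running the assay with and without the radical scavenger DMSO
decomposes the yield into direct (scavenger-insensitive) and indirect
(radical-mediated) components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.constants import Avogadro
from scipy.optimize import brentq

__all__ = [
    "PHIX174_MOLAR_MASS",
    "DEFAULT_SC_STAINING_FACTOR",
    "GelLane",
    "IsoformFractions",
    "BreakEstimate",
    "PlasmidPrep",
    "DoseResponse",
    "lane_fractions",
    "poisson_breaks",
    "dsb_dose_response",
    "yield_from_D0",
    "dmso_decomposition",
]

#: Molar mass (g/mol) of the phiX174 replicative-form duplex (5386 bp);
#: the value that makes the D0 and Y(DSB) columns of the damage assays
#: mutually consistent across all compounds.
PHIX174_MOLAR_MASS = 3.6e6

#: Default correction factor for the weaker intercalator staining of the
#: supercoiled form relative to relaxed forms.
DEFAULT_SC_STAINING_FACTOR = 1.4


@dataclass(frozen=True)
class GelLane:
    """One densitometered electrophoresis lane."""

    dose_per_ml: float
    sc: float
    oc: float
    lin: float
    dmso: bool = False
    control: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        for nm in ("sc", "oc", "lin"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} intensity must be non-negative")
        if self.sc + self.oc + self.lin <= 0:
            raise ValueError("lane intensities are all zero")
        if self.dose_per_ml < 0:
            raise ValueError("dose must be non-negative")


@dataclass(frozen=True)
class IsoformFractions:
    """Staining-corrected isoform fractions; sum to 1."""

    f_sc: float
    f_oc: float
    f_lin: float
    staining_factor_applied: float

    def __post_init__(self) -> None:
        total = self.f_sc + self.f_oc + self.f_lin
        if abs(total - 1.0) > 1e-12:
            raise ValueError("fractions must sum to 1")
        for nm in ("f_sc", "f_oc", "f_lin"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm} outside [0, 1]")


@dataclass(frozen=True)
class BreakEstimate:
    """Mean SSB and DSB counts per plasmid inferred from one lane."""

    mu_dsb: float
    mu_ssb: float
    method: str = "poisson"
    censored: bool = False  # f_sc at/below the detection floor


@dataclass(frozen=True)
class PlasmidPrep:
    """Plasmid preparation; fixes the number density in the mixture."""

    mass_per_volume_ug_ml: float
    molar_mass_g_mol: float = PHIX174_MOLAR_MASS

    def __post_init__(self) -> None:
        if self.mass_per_volume_ug_ml <= 0:
            raise ValueError("mass concentration must be positive")
        if self.molar_mass_g_mol <= 0:
            raise ValueError("molar mass must be positive")

    @property
    def plasmid_density_per_ml(self) -> float:
        return (
            self.mass_per_volume_ug_ml * 1e-6 * Avogadro / self.molar_mass_g_mol
        )


@dataclass(frozen=True)
class DoseResponse:
    """Fitted DSB-per-plasmid vs decays/mL line and derived parameters."""

    slope: float
    intercept: float
    D0: float | None
    Y_dsb: float | None
    plasmid_density_per_ml: float
    se_slope: float
    se_intercept: float
    se_D0: float | None
    se_Y: float | None
    n_points: int
    r2: float
    censored: bool = False
    notes: str = ""


def lane_fractions(
    lane: GelLane, sc_staining_factor: float = DEFAULT_SC_STAINING_FACTOR
) -> IsoformFractions:
    """Staining-corrected isoform fractions of one lane.

    The SC band intensity is multiplied by the correction factor before
    normalizing the three bands to unit sum.
    """
    if sc_staining_factor <= 0:
        raise ValueError("staining factor must be positive")
    sc = lane.sc * sc_staining_factor
    total = sc + lane.oc + lane.lin
    f_sc = sc / total
    f_oc = lane.oc / total
    f_lin = lane.lin / total
    # absorb float round-off into the largest fraction
    drift = 1.0 - (f_sc + f_oc + f_lin)
    if abs(drift) > 0:
        if f_sc >= max(f_oc, f_lin):
            f_sc += drift
        elif f_oc >= f_lin:
            f_oc += drift
        else:
            f_lin += drift
    return IsoformFractions(f_sc, f_oc, f_lin, sc_staining_factor)


def _mu_dsb_from_flin(f_lin: float) -> float:
    """Invert f_lin = mu * exp(-mu) on the physical branch mu in [0, 1].

    Above the branch maximum exp(-1) there is no root; callers fall back
    to the total-break estimate.
    """
    if f_lin <= 0.0:
        return 0.0
    if f_lin > math.exp(-1.0):
        raise ValueError("f_lin exceeds the single-DSB branch maximum e^-1")
    return float(brentq(lambda m: m * math.exp(-m) - f_lin, 0.0, 1.0,
                        xtol=1e-15, rtol=8.9e-16))


def poisson_breaks(
    fr: IsoformFractions,
    method: str = "poisson",
    detection_floor: float = 1e-3,
) -> BreakEstimate:
    """Mean SSB/DSB per plasmid from isoform fractions.

    ``method='poisson'`` (default): mu_tot = -ln f_sc and mu_dsb from the
    exact single-DSB branch of f_lin = mu e^-mu; mu_ssb is the remainder,
    floored at 0.  ``method='linear'`` uses the small-dose approximation
    mu_dsb ~ f_lin.  An undetectable SC band (f_sc <= detection floor) is
    reported as a censored lower-bound estimate at the floor.
    """
    if method not in ("poisson", "linear"):
        raise ValueError("method must be 'poisson' or 'linear'")
    censored = False
    f_sc = fr.f_sc
    if f_sc <= detection_floor:
        f_sc = detection_floor
        censored = True
    mu_tot = -math.log(f_sc)
    if method == "linear":
        mu_dsb = fr.f_lin
    else:
        try:
            mu_dsb = _mu_dsb_from_flin(fr.f_lin)
        except ValueError:
            mu_dsb = mu_tot  # heavy fragmentation: all breaks at least double
    mu_dsb = min(mu_dsb, mu_tot)
    mu_ssb = max(mu_tot - mu_dsb, 0.0) + 0.0  # normalize -0.0
    return BreakEstimate(mu_dsb=mu_dsb, mu_ssb=mu_ssb, method=method,
                         censored=censored)


def dsb_dose_response(
    lanes: list[GelLane],
    prep: PlasmidPrep,
    sc_staining_factor: float = DEFAULT_SC_STAINING_FACTOR,
    method: str = "poisson",
    detection_floor: float = 1e-3,
) -> DoseResponse:
    """OLS fit of mu_dsb against accumulated decays/mL.

    Control lanes (zero-dose) define a baseline mu_dsb subtracted from
    treated lanes before fitting.  A non-positive fitted slope leaves D0
    and Y undefined (censored) with a diagnostic note instead of raising.
    """
    treated = [ln for ln in lanes if not ln.control]
    controls = [ln for ln in lanes if ln.control]
    doses = np.array([ln.dose_per_ml for ln in treated])
    if len(treated) < 3 or np.unique(doses).size < 3:
        raise ValueError("need >= 3 non-control lanes at distinct doses")

    def mu(ln: GelLane) -> float:
        fr = lane_fractions(ln, sc_staining_factor)
        return poisson_breaks(fr, method=method,
                              detection_floor=detection_floor).mu_dsb

    baseline = float(np.mean([mu(ln) for ln in controls])) if controls else 0.0
    y = np.array([mu(ln) for ln in treated]) - baseline

    fit = stats.linregress(doses, y)
    slope, intercept = float(fit.slope), float(fit.intercept)
    se_slope, se_int = float(fit.stderr), float(fit.intercept_stderr)
    r2 = float(fit.rvalue**2)
    rho = prep.plasmid_density_per_ml
    if slope <= 0:
        return DoseResponse(
            slope=slope, intercept=intercept, D0=None, Y_dsb=None,
            plasmid_density_per_ml=rho, se_slope=se_slope,
            se_intercept=se_int, se_D0=None, se_Y=None,
            n_points=len(treated), r2=r2, censored=True,
            notes="non-positive slope: no detectable dose response",
        )
    D0 = 1.0 / slope
    se_D0 = se_slope / slope**2  # first-order propagation of 1/slope
    Y = rho / D0
    se_Y = rho * se_slope  # Y = rho * slope
    return DoseResponse(
        slope=slope, intercept=intercept, D0=D0, Y_dsb=Y,
        plasmid_density_per_ml=rho, se_slope=se_slope, se_intercept=se_int,
        se_D0=se_D0, se_Y=se_Y, n_points=len(treated), r2=r2,
    )


def yield_from_D0(D0_per_ml: float, prep: PlasmidPrep) -> float:
    """DSB yield per decay, Y = plasmid_density / D0."""
    if D0_per_ml <= 0:
        raise ValueError("D0 must be positive")
    return prep.plasmid_density_per_ml / D0_per_ml


def dmso_decomposition(minus: DoseResponse, plus: DoseResponse) -> dict:
    """Split the DSB yield into direct and indirect components.

    The scavenger-protected (+DMSO) yield is the direct component; the
    difference to the unprotected (-DMSO) yield is the indirect one,
    floored at 0 with a flag when the difference is negative.  A direct
    yield below 10% of the total is classified "exclusively indirect".
    """
    if not math.isclose(minus.plasmid_density_per_ml,
                        plus.plasmid_density_per_ml, rel_tol=1e-9):
        raise ValueError("DMSO arms must share the same plasmid preparation")
    if minus.Y_dsb is None or plus.Y_dsb is None:
        raise ValueError("both arms need a defined yield")
    direct = plus.Y_dsb
    indirect = minus.Y_dsb - plus.Y_dsb
    flagged = indirect < 0
    indirect = max(indirect, 0.0)
    if minus.Y_dsb > 0 and direct / minus.Y_dsb < 0.1:
        classification = "exclusively indirect"
    elif minus.Y_dsb > 0 and indirect / minus.Y_dsb < 0.1:
        classification = "predominantly direct"
    else:
        classification = "mixed"
    return {
        "direct": direct,
        "indirect": indirect,
        "classification": classification,
        "negative_indirect_flagged": flagged,
    }
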