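"""Comparison of measured DSB yields with simulated energy deposition.

Experimental DSB yields per decay (one per compound, each anchoring the
emitter at a docking-derived distance from the DNA axis) are compared,
per nuclide, with the simulated deposited-energy curve evaluated at the
same distances.  Both series are normalized to their maxima, and the
agreement is summarized by a Kendall-type rank concordance computed by
brute-force pair counting.  Compounds whose measured (normalized) yield
falls well below the simulated prediction are flagged: transport
calculations on a rigid DNA rod tend to overestimate direct damage at
larger distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .nanodose import DepositionResult

__all__ = [
    "CompoundRecord",
    "normalize_to_max",
    "rank_concordance",
    "correlate",
    "load_compounds",
]


@dataclass(frozen=True)
class CompoundRecord:
    """One radioconjugate: emitter-DNA distance and measured yields."""

    name: str
    nuclide: str
    linker: str
    distance_A: float
    y_dsb_minus: float
    y_dsb_plus: float | None = None

    def __post_init__(self) -> None:
        if self.distance_A <= 0:
            raise ValueError("distance must be positive")
        if self.y_dsb_minus < 0:
            raise ValueError("yields must be non-negative")
        if self.y_dsb_plus is not None and self.y_dsb_plus < 0:
            raise ValueError("yields must be non-negative")


def normalize_to_max(values) -> np.ndarray:
    """Divide by the maximum so the largest value maps to 1.

    Idempotent and invariant under positive rescaling.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    m = float(v.max())
    if m <= 0:
        raise ValueError("need at least one positive value")
    return v / m


def rank_concordance(a, b) -> float:
    """Kendall tau-a by explicit pair counting.

    (concordant - discordant) / total pairs over all unordered pairs;
    ties count as neither.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equally sized series of length >= 2")
    n = a.size
    conc = disc = 0
    for i in range(n):
        for j in range(i + 1, n):
            s = (a[i] - a[j]) * (b[i] - b[j])
            if s > 0:
                conc += 1
            elif s < 0:
                disc += 1
    return (conc - disc) / (n * (n - 1) / 2)


def correlate(
    records: list[CompoundRecord],
    sim: list[DepositionResult],
    overestimate_gap: float = 0.5,
) -> dict:
    """Pair normalized yields with normalized simulated deposits.

    ``sim`` must cover every record's distance (linear interpolation on
    the simulated curve; extrapolation is refused).  Returns, per
    nuclide, a table of (distance, normalized yield, normalized
    deposit), the pair-count rank concordance of the two series, and the
    compounds flagged as overestimated by the simulation (normalized
    deposit exceeding the normalized yield by more than
    ``overestimate_gap``).
    """
    if not records:
        raise ValueError("no compound records")
    sd = np.array([r.distance_A for r in sim])
    order = np.argsort(sd)
    sd = sd[order]
    sdep = np.array([sim[i].e_dep_per_decay_eV for i in order])
    out: dict[str, dict] = {}
    for nuclide in sorted({r.nuclide for r in records}):
        recs = [r for r in records if r.nuclide == nuclide]
        if len(recs) < 2:
            raise ValueError(
                f"need >= 2 records for nuclide {nuclide!r}"
            )
        dist = np.array([r.distance_A for r in recs])
        if dist.min() < sd.min() or dist.max() > sd.max():
            raise ValueError(
                f"record distance outside simulated span "
                f"[{sd.min():g}, {sd.max():g}] A; refusing to extrapolate"
            )
        y = normalize_to_max([r.y_dsb_minus for r in recs])
        edep = normalize_to_max(np.interp(dist, sd, sdep))
        table = pd.DataFrame({
            "compound": [r.name for r in recs],
            "distance_A": dist,
            "y_dsb_norm": y,
            "e_dep_norm": edep,
        }).sort_values("distance_A", ignore_index=True)
        flagged = [
            r.name for r, yn, en in zip(recs, y, edep)
            if en - yn > overestimate_gap
        ]
        out[nuclide] = {
            "table": table,
            "concordance": rank_concordance(y, edep),
            "overestimated": flagged,
        }
    return out


def load_compounds(path=None) -> pd.DataFrame:
    """Packaged (or user) compound table: distances, D0 values, yields."""
    if path is None:
        with resources.as_file(
            resources.files("augerdna.data").joinpath("compounds.csv")
        ) as p:
            return pd.read_csv(p)
    return pd.read_csv(path)


def compound_records(df: pd.DataFrame | None = None) -> list[CompoundRecord]:
    """CompoundRecord list from a compound table (packaged by default)."""
    if df is None:
        df = load_compounds()
    return [
        CompoundRecord(
            name=row["name"], nuclide=row["nuclide"], linker=row["linker"],
            distance_A=float(row["distance_docking_A"]),
            y_dsb_minus=float(row["y_minus_per_decay"]),
            y_dsb_plus=float(row["y_plus_per_decay"]),
        )
        for _, row in df.iterrows()
    ]
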