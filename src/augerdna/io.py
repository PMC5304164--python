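"""CSV/JSON/YAML interchange, validation, and the end-to-end pipeline.

Lane tables are CSV with a header row::

    label,a0_uci,time_h,sc,oc,lin,dmso,control

where ``a0_uci``/``time_h`` may be left blank when a precomputed
``dose_per_ml`` column is present instead.  Titration tables are CSV
with ``dna_bp_M,intensity`` and optional ``a_ex,a_em`` columns.
Reports are JSON with input digests and a config echo so every number
is traceable; all isoform quantities are stored as fractions (percent
only at presentation).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binding import TitrationSeries, inner_filter_correct, kaminoh_fit, mvh_fit
from .correlate import CompoundRecord, correlate
from .decay import get_nuclide, uci_to_bq, cumulated_decays
from .nanodose import CylinderTarget, deposition_vs_distance
from .plasmid import (
    DEFAULT_SC_STAINING_FACTOR,
    GelLane,
    PlasmidPrep,
    dmso_decomposition,
    dsb_dose_response,
)

__all__ = [
    "ValidationError",
    "read_lane_csv",
    "write_lane_csv",
    "read_titration_csv",
    "write_report",
    "run_pipeline",
]

_LANE_COLUMNS = ("label", "sc", "oc", "lin", "dmso", "control")


class ValidationError(ValueError):
    """Input file failed schema validation; message names the row."""


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


def read_lane_csv(
    path,
    nuclide_name: str | None = None,
    volume_ml: float | None = None,
) -> list[GelLane]:
    """Read a densitometry lane table into GelLane objects.

    The dose axis is taken from a ``dose_per_ml`` column when present;
    otherwise it is computed from ``a0_uci``/``time_h`` via the decay
    accounting of ``nuclide_name`` in ``volume_ml``.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, _LANE_COLUMNS, path)
    has_dose = "dose_per_ml" in df.columns
    if not has_dose:
        _require_columns(df, ("a0_uci", "time_h"), path)
        if nuclide_name is None or volume_ml is None:
            raise ValidationError(
                f"{path}: no dose_per_ml column; nuclide and volume required"
            )
        nuclide = get_nuclide(nuclide_name)
    seen_labels: set[str] = set()
    lanes = []
    for i, row in df.iterrows():
        rowno = i + 2  # header is line 1
        for col in ("sc", "oc", "lin"):
            v = row[col]
            if pd.isna(v) or v < 0:
                raise ValidationError(
                    f"{path}, row {rowno}: invalid {col!r} value {v!r}"
                )
        label = str(row["label"])
        if label in seen_labels:
            raise ValidationError(
                f"{path}, row {rowno}: duplicated lane label {label!r}"
            )
        seen_labels.add(label)
        control = bool(int(row["control"]))
        if has_dose:
            dose = float(row["dose_per_ml"])
        elif control:
            dose = 0.0
        else:
            a0, t_h = row["a0_uci"], row["time_h"]
            if pd.isna(a0) or pd.isna(t_h):
                raise ValidationError(
                    f"{path}, row {rowno}: blank a0_uci/time_h on a "
                    "non-control lane"
                )
            dose = cumulated_decays(
                nuclide, uci_to_bq(float(a0)), float(t_h) * 3600.0
            ) / volume_ml
        try:
            lanes.append(GelLane(
                dose_per_ml=dose, sc=float(row["sc"]), oc=float(row["oc"]),
                lin=float(row["lin"]), dmso=bool(int(row["dmso"])),
                control=control, label=label,
            ))
        except ValueError as exc:
            raise ValidationError(f"{path}, row {rowno}: {exc}") from exc
    return lanes


def write_lane_csv(lanes: list[GelLane], path) -> None:
    """Write GelLane objects as a dose-resolved lane CSV."""
    pd.DataFrame([{
        "label": ln.label, "dose_per_ml": ln.dose_per_ml,
        "sc": ln.sc, "oc": ln.oc, "lin": ln.lin,
        "dmso": int(ln.dmso), "control": int(ln.control),
    } for ln in lanes]).to_csv(path, index=False, float_format="%.17g")


def read_titration_csv(path, ligand_total_M: float) -> TitrationSeries:
    """Read a titration CSV (``dna_bp_M,intensity[,a_ex,a_em]``)."""
    df = pd.read_csv(path)
    _require_columns(df, ("dna_bp_M", "intensity"), path)
    for i, row in df.iterrows():
        if pd.isna(row["dna_bp_M"]) or pd.isna(row["intensity"]):
            raise ValidationError(f"{path}, row {i + 2}: blank value")
    kwargs = {}
    if "a_ex" in df.columns and "a_em" in df.columns:
        kwargs = {
            "absorb_ex": df["a_ex"].to_numpy(float),
            "absorb_em": df["a_em"].to_numpy(float),
        }
    try:
        return TitrationSeries(
            ligand_total_M=ligand_total_M,
            dna_bp_M=df["dna_bp_M"].to_numpy(float),
            intensity=df["intensity"].to_numpy(float),
            **kwargs,
        )
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_report(report: dict, path) -> None:
    """Write an analysis report as deterministic (sorted-key) JSON."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def _fit_arm(lanes, prep, factor):
    res = dsb_dose_response(lanes, prep, sc_staining_factor=factor)
    return {
        "slope": res.slope, "intercept": res.intercept, "D0": res.D0,
        "Y_dsb": res.Y_dsb, "se_slope": res.se_slope, "se_D0": res.se_D0,
        "se_Y": res.se_Y, "r2": res.r2, "n_points": res.n_points,
        "censored": res.censored, "notes": res.notes,
    }, res


def run_pipeline(config: dict | str | Path) -> dict:
    """Run the full analysis from a YAML/dict configuration.

    Config keys: ``seed``; ``sc_staining_factor``; ``compounds`` (list
    of {name, nuclide, distance_A, prep_ug_per_ml, volume_ml,
    lanes_minus, lanes_plus}); ``nanodose`` ({histories, distances_A}).
    Per-compound failures are isolated and reported, not fatal.
    Deterministic given the seed: rerunning the same config yields an
    identical report body.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    seed = int(config.get("seed", 0))
    factor = float(config.get("sc_staining_factor",
                              DEFAULT_SC_STAINING_FACTOR))
    report: dict = {
        "software": {"name": "augerdna", "version": __version__},
        "config": {"seed": seed, "sc_staining_factor": factor},
        "inputs": {},
        "compounds": {},
        "errors": {},
    }
    records: list[CompoundRecord] = []
    for comp in config.get("compounds", []):
        name = comp["name"]
        try:
            prep = PlasmidPrep(
                mass_per_volume_ug_ml=float(comp["prep_ug_per_ml"]),
                molar_mass_g_mol=float(comp.get("molar_mass_g_mol", 3.6e6)),
            )
            entry: dict = {"nuclide": comp["nuclide"],
                           "distance_A": comp.get("distance_A")}
            arms = {}
            for arm, key in (("minus_dmso", "lanes_minus"),
                             ("plus_dmso", "lanes_plus")):
                if key not in comp:
                    continue
                report["inputs"][str(comp[key])] = _digest(comp[key])
                lanes = read_lane_csv(
                    comp[key], comp.get("nuclide"), comp.get("volume_ml")
                )
                entry[arm], arms[arm] = _fit_arm(lanes, prep, factor)
            if "minus_dmso" in arms and "plus_dmso" in arms:
                m, p = arms["minus_dmso"], arms["plus_dmso"]
                if m.Y_dsb is not None and p.Y_dsb is not None:
                    entry["dmso_decomposition"] = dmso_decomposition(m, p)
            report["compounds"][name] = entry
            if (comp.get("distance_A")
                    and entry.get("minus_dmso", {}).get("Y_dsb")):
                records.append(CompoundRecord(
                    name=name, nuclide=comp["nuclide"],
                    linker=comp.get("linker", ""),
                    distance_A=float(comp["distance_A"]),
                    y_dsb_minus=entry["minus_dmso"]["Y_dsb"],
                ))
        except Exception as exc:  # isolate per-compound failures
            report["errors"][name] = f"{type(exc).__name__}: {exc}"

    nano = config.get("nanodose")
    if nano:
        target = CylinderTarget()
        distances = [float(d) for d in nano["distances_A"]]
        histories = int(nano.get("histories", 20000))
        report["nanodose"] = {}
        for nuclide_name in sorted({r.nuclide for r in records}
                                   or set(nano.get("nuclides", []))):
            nuc = get_nuclide(nuclide_name)
            curve = deposition_vs_distance(
                nuc, target, distances, histories, seed
            )
            report["nanodose"][nuclide_name] = [{
                "distance_A": r.distance_A,
                "e_dep_per_electron_eV": r.e_dep_per_electron_eV,
                "se_per_electron_eV": r.se_per_electron_eV,
                "e_dep_per_decay_eV": r.e_dep_per_decay_eV,
                "se_per_decay_eV": r.se_per_decay_eV,
            } for r in curve]
            nuc_records = [r for r in records if r.nuclide == nuclide_name]
            if len(nuc_records) >= 2:
                try:
                    corr = correlate(nuc_records, curve)[nuclide_name]
                    report.setdefault("correlation", {})[nuclide_name] = {
                        "concordance": corr["concordance"],
                        "overestimated": corr["overestimated"],
                        "table": corr["table"].to_dict(orient="records"),
                    }
                except ValueError as exc:
                    report["errors"][f"correlation:{nuclide_name}"] = str(exc)
    return report
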