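"""Cumulated-decay accounting for radionuclide incubation protocols.

Plasmid-nicking assays with Auger emitters express the dose axis as the
number of radioactive decays accumulated per mL of incubation mixture.
For an initial activity ``A0`` (activity at the start of incubation) the
activity decays as ``A(t) = A0 * exp(-lambda * t)`` with
``lambda = ln2 / T_half``, and the cumulated number of decays over an
incubation of length ``T`` is the time integral

    N(T) = (A0 / lambda) * (1 - exp(-lambda * T))

Two protocol templates are supported: a fixed 24 h exposure at graded
activities (short-lived emitters such as Tc-99m) and a fixed activity
sampled as aliquots at multi-day intervals (long-lived emitters such as
I-125).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

__all__ = [
    "UCI_TO_BQ",
    "AugerSpectrum",
    "Radionuclide",
    "IncubationSchedule",
    "uci_to_bq",
    "bq_to_uci",
    "get_nuclide",
    "available_nuclides",
    "activity_at",
    "cumulated_decays",
    "decays_per_ml",
]

#: 1 uCi expressed in becquerel (exact by definition of the curie).
UCI_TO_BQ = 3.7e4


def uci_to_bq(a_uci: float) -> float:
    """Convert an activity from microcurie to becquerel."""
    return a_uci * UCI_TO_BQ


def bq_to_uci(a_bq: float) -> float:
    """Convert an activity from becquerel to microcurie."""
    return a_bq / UCI_TO_BQ


@dataclass(frozen=True)
class AugerSpectrum:
    """Discrete Auger/Coster-Kronig electron line spectrum of a nuclide.

    Parameters
    ----------
    energies_eV : array of line energies (eV), strictly positive.
    yields_per_decay : electrons emitted per decay on each line; the sum
        must equal ``total_electrons_per_decay`` to 1e-6.
    """

    energies_eV: np.ndarray
    yields_per_decay: np.ndarray
    total_electrons_per_decay: float

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_eV, dtype=float)
        y = np.asarray(self.yields_per_decay, dtype=float)
        if e.size == 0:
            raise ValueError("spectrum has no lines")
        if e.shape != y.shape:
            raise ValueError("energies and yields must have the same length")
        if np.any(e <= 0):
            raise ValueError("line energies must be positive")
        if np.any(y <= 0):
            raise ValueError("line yields must be positive")
        if abs(float(y.sum()) - self.total_electrons_per_decay) > 1e-6:
            raise ValueError(
                "sum of line yields does not match total_electrons_per_decay"
            )
        object.__setattr__(self, "energies_eV", e)
        object.__setattr__(self, "yields_per_decay", y)


@dataclass(frozen=True)
class Radionuclide:
    """An Auger-emitting radionuclide."""

    name: str
    half_life_s: float
    electrons_per_decay: float
    spectrum: AugerSpectrum | None = None

    def __post_init__(self) -> None:
        if self.half_life_s <= 0:
            raise ValueError("half_life_s must be positive")
        if self.electrons_per_decay <= 0:
            raise ValueError("electrons_per_decay must be positive")

    @property
    def decay_constant(self) -> float:
        """Decay constant lambda = ln2 / T_half in 1/s."""
        return math.log(2.0) / self.half_life_s


@dataclass(frozen=True)
class IncubationSchedule:
    """Incubation protocol of a plasmid-damage assay.

    ``sampling_times_s`` is used by the aliquot protocol (long-lived
    emitters) where the same mixture is sampled repeatedly; it must be
    strictly increasing.
    """

    initial_activity_uci: float
    duration_s: float
    sample_volume_ml: float
    sampling_times_s: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.initial_activity_uci < 0:
            raise ValueError("initial activity must be non-negative")
        if self.sample_volume_ml <= 0:
            raise ValueError("sample volume must be positive")
        if self.sampling_times_s is not None:
            ts = tuple(float(t) for t in self.sampling_times_s)
            if any(t < 0 for t in ts):
                raise ValueError("sampling times must be non-negative")
            if any(b <= a for a, b in zip(ts, ts[1:])):
                raise ValueError("sampling times must be strictly increasing")
            object.__setattr__(self, "sampling_times_s", ts)

    @property
    def initial_activity_bq(self) -> float:
        return uci_to_bq(self.initial_activity_uci)


def _load_registry() -> dict:
    text = resources.files("augerdna.data").joinpath("nuclides.json").read_text()
    return json.loads(text)


_REGISTRY_CACHE: dict[str, Radionuclide] = {}


def available_nuclides() -> list[str]:
    """Names of the nuclides packaged with the library."""
    return sorted(_load_registry().keys())


def get_nuclide(name: str, registry_path: str | None = None) -> Radionuclide:
    """Load a nuclide definition from the packaged (or a user) JSON registry.

    The packaged registry holds Tc-99m (T_half = 6.02 h, 5 electrons per
    decay) and I-125 (T_half = 59.4 d, 25 electrons per decay) with
    representative discrete Auger/Coster-Kronig line spectra.
    """
    if registry_path is None and name in _REGISTRY_CACHE:
        return _REGISTRY_CACHE[name]
    if registry_path is None:
        registry = _load_registry()
    else:
        with open(registry_path) as fh:
            registry = json.load(fh)
    if name not in registry:
        raise KeyError(
            f"unknown nuclide {name!r}; available: {sorted(registry)}"
        )
    entry = registry[name]
    spectrum = AugerSpectrum(
        energies_eV=np.array([ln["energy_eV"] for ln in entry["spectrum"]]),
        yields_per_decay=np.array(
            [ln["yield_per_decay"] for ln in entry["spectrum"]]
        ),
        total_electrons_per_decay=float(entry["electrons_per_decay"]),
    )
    nuc = Radionuclide(
        name=entry["name"],
        half_life_s=float(entry["half_life_s"]),
        electrons_per_decay=float(entry["electrons_per_decay"]),
        spectrum=spectrum,
    )
    if registry_path is None:
        _REGISTRY_CACHE[name] = nuc
    return nuc


def activity_at(nuclide: Radionuclide, a0_bq: float, t_s: float) -> float:
    """Activity (Bq) remaining after ``t_s`` seconds of decay."""
    if a0_bq < 0:
        raise ValueError("activity must be non-negative")
    if t_s < 0:
        raise ValueError("time must be non-negative")
    return a0_bq * math.exp(-nuclide.decay_constant * t_s)


def cumulated_decays(nuclide: Radionuclide, a0_bq: float, t_s: float) -> float:
    """Number of decays accumulated over ``[0, t_s]``.

    Closed form ``(A0/lambda) * (1 - exp(-lambda T))``; monotone
    non-decreasing in T and bounded by ``A0/lambda`` (the total number of
    atoms initially present).
    """
    if a0_bq < 0:
        raise ValueError("activity must be non-negative")
    if t_s < 0:
        raise ValueError("time must be non-negative")
    lam = nuclide.decay_constant
    return (a0_bq / lam) * -math.expm1(-lam * t_s)


def decays_per_ml(
    nuclide: Radionuclide,
    schedule: IncubationSchedule,
    t_s: float | None = None,
) -> float:
    """Cumulated decays per mL of incubation mixture after ``t_s`` seconds.

    Defaults to the schedule's full incubation length.
    """
    if t_s is None:
        t_s = schedule.duration_s
    n = cumulated_decays(nuclide, schedule.initial_activity_bq, t_s)
    return n / schedule.sample_volume_ml


def decay_dose_axis(
    nuclide: Radionuclide, schedule: IncubationSchedule
) -> np.ndarray:
    """Decays/mL at each sampling time of an aliquot schedule.

    Falls back to the single end-of-incubation value when the schedule has
    no sampling times.
    """
    times: Sequence[float]
    if schedule.sampling_times_s is not None:
        times = schedule.sampling_times_s
    else:
        times = (schedule.duration_s,)
    return np.array([decays_per_ml(nuclide, schedule, t) for t in times])
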