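"""Synthetic data generators for every analysis stage.

Each generator is the exact forward model of its analysis stage, so
noiseless outputs round-trip exactly (to solver tolerance) and noisy
outputs exercise the estimators under the study's own designs:

* gel series: DSB means proportional to accumulated decays/mL
  (``mu_dsb = dose / D0_true``), Poisson isoform fractions, supercoiled
  band divided by the staining factor, multiplicative lognormal
  densitometry noise (default 5% CV);
* titrations: forward neighbor-exclusion (or hyperbolic) intensity
  curves with additive Gaussian noise;
* decay truth tables: the analytic activity/cumulated-decay curve.

Default dose grids mirror the two assay protocols: 5-500 uCi for 24 h
in 30 uL (Tc-99m) and 40 uCi sampled every 7 days in 100 uL (I-125).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import binding
from .decay import IncubationSchedule, Radionuclide, cumulated_decays
from .plasmid import GelLane, PlasmidPrep

__all__ = [
    "TC99M_ACTIVITY_GRID_UCI",
    "I125_SAMPLING_DAYS",
    "GelSimConfig",
    "gen_gel_series",
    "gen_titration",
    "gen_decay_truth",
]

#: Activity grid (uCi) of the fixed-24 h protocol.
TC99M_ACTIVITY_GRID_UCI = (5.0, 10.0, 50.0, 100.0, 200.0, 500.0)
#: Sampling days of the fixed-activity aliquot protocol.
I125_SAMPLING_DAYS = (7.0, 14.0, 21.0, 28.0)


@dataclass(frozen=True)
class GelSimConfig:
    """Ground truth and noise model for a simulated gel series."""

    nuclide: Radionuclide
    prep: PlasmidPrep
    D0_true_per_ml: float
    ssb_per_dsb_ratio: float = 5.0
    densitometry_cv: float = 0.05
    sc_staining_factor_true: float = 1.4
    seed: int = 0
    # Tc-type protocol: a grid of activities at one duration
    activities_uci: tuple[float, ...] = TC99M_ACTIVITY_GRID_UCI
    duration_s: float = 24 * 3600.0
    sample_volume_ml: float = 0.030
    # I-type protocol: one activity sampled repeatedly (overrides grid)
    sampling_times_s: tuple[float, ...] | None = None
    include_control: bool = True

    def __post_init__(self) -> None:
        if self.D0_true_per_ml <= 0:
            raise ValueError("D0_true must be positive")
        if self.ssb_per_dsb_ratio < 0:
            raise ValueError("SSB/DSB ratio must be non-negative")
        if not 0.0 <= self.densitometry_cv <= 0.5:
            raise ValueError("densitometry CV must be in [0, 0.5]")
        if self.sc_staining_factor_true <= 0:
            raise ValueError("staining factor must be positive")

    def dose_axis(self) -> np.ndarray:
        """Accumulated decays/mL of every lane of the design."""
        if self.sampling_times_s is not None:
            a_bq = self.activities_uci[0] * 3.7e4
            return np.array([
                cumulated_decays(self.nuclide, a_bq, t)
                / self.sample_volume_ml
                for t in self.sampling_times_s
            ])
        return np.array([
            cumulated_decays(self.nuclide, a * 3.7e4, self.duration_s)
            / self.sample_volume_ml
            for a in self.activities_uci
        ])


def _poisson_fractions(mu_dsb: float, mu_ssb: float) -> tuple[float, float, float]:
    f_sc = math.exp(-(mu_ssb + mu_dsb))
    f_lin = mu_dsb * math.exp(-mu_dsb)
    f_oc = max(1.0 - f_sc - f_lin, 0.0)
    return f_sc, f_oc, f_lin


def gen_gel_series(cfg: GelSimConfig) -> list[GelLane]:
    """Simulate one gel series from the forward Poisson isoform model."""
    rng = np.random.default_rng(cfg.seed)
    doses = cfg.dose_axis()
    lanes: list[GelLane] = []
    if cfg.include_control:
        doses = np.concatenate(([0.0], doses))
    sigma = (
        math.sqrt(math.log1p(cfg.densitometry_cv**2))
        if cfg.densitometry_cv > 0 else 0.0
    )
    for i, dose in enumerate(doses):
        mu_dsb = dose / cfg.D0_true_per_ml
        mu_ssb = cfg.ssb_per_dsb_ratio * mu_dsb
        f_sc, f_oc, f_lin = _poisson_fractions(mu_dsb, mu_ssb)
        bands = np.array([f_sc / cfg.sc_staining_factor_true, f_oc, f_lin])
        if sigma > 0:
            # lognormal with unit mean: exp(N(-sigma^2/2, sigma))
            bands = bands * rng.lognormal(-sigma**2 / 2.0, sigma, 3)
        lanes.append(GelLane(
            dose_per_ml=float(dose), sc=float(bands[0]), oc=float(bands[1]),
            lin=float(bands[2]), control=(cfg.include_control and i == 0),
            label=f"lane{i}",
        ))
    return lanes


def gen_titration(
    K: float,
    n: float,
    I0: float,
    I_sat: float,
    dna_bp_M,
    ligand_total_M: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    model: str = "mvh",
) -> binding.TitrationSeries:
    """Simulate a fluorescence titration from a binding isotherm.

    ``noise_sd`` is additive Gaussian noise in intensity units.  The
    forward model matches the corresponding fit exactly (bound-fraction
    intensity weighting for the neighbor-exclusion model).
    """
    grid = np.asarray(dna_bp_M, dtype=float)
    if grid.size == 0:
        raise ValueError("empty DNA concentration grid")
    if model == "mvh":
        theta = binding.mvh_bound_fraction(K, n, ligand_total_M, grid)
        intensity = I0 + (I_sat - I0) * theta
    elif model == "kaminoh":
        intensity = binding.kaminoh_model(grid, K, I0, I_sat)
    else:
        raise ValueError("model must be 'mvh' or 'kaminoh'")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, grid.size)
    return binding.TitrationSeries(
        ligand_total_M=ligand_total_M, dna_bp_M=grid, intensity=intensity
    )


def gen_decay_truth(
    nuclide: Radionuclide,
    schedule: IncubationSchedule,
    n_points: int = 25,
) -> pd.DataFrame:
    """Analytic decay/cumulated-decay table over the incubation window."""
    if schedule.sampling_times_s is not None:
        times = np.asarray(schedule.sampling_times_s, dtype=float)
    else:
        times = np.linspace(0.0, schedule.duration_s, n_points)
    a0 = schedule.initial_activity_bq
    lam = nuclide.decay_constant
    return pd.DataFrame({
        "time_s": times,
        "activity_bq": a0 * np.exp(-lam * times),
        "cumulated_decays": [
            cumulated_decays(nuclide, a0, t) for t in times
        ],
    })
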