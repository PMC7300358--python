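"""Synthetic datasets mimicking the statistical structure of the experiments.

Two generators are provided: Monod-shaped single-strain growth-rate tables
with replicate Gaussian noise, and coculture plate-count tables with
Poisson total-CFU noise and multinomial strain-identity noise.  Both are
pure functions of their inputs and a seed.

Unit conversion (cells/ml, hours) lives here and only here; the inference
modules work in the model's normalized units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .growth import EXPERIMENTAL_CONCENTRATIONS, GrowthDataset
from .simulate import Trajectory

__all__ = ["ExperimentDesign", "generate_growth_dataset", "generate_coculture_counts"]


@dataclass(frozen=True)
class ExperimentDesign:
    """Sampling design of the emulated culturing experiments."""

    carrying_capacity_cells: float = 5e7
    dilution: float = 1.0 / 20.0
    sample_interval_h: float = 24.0
    duration_h: float = 120.0
    replicates: int = 3
    plate_count_depth: int = 100
    hours_per_model_time: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise InvalidParameterError("replicates must be >= 1")
        for name in ("carrying_capacity_cells", "dilution", "sample_interval_h",
                     "duration_h", "hours_per_model_time"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.plate_count_depth <= 0:
            raise InvalidParameterError("plate_count_depth must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def generate_growth_dataset(vmax: float,
                            k_half: float,
                            design: ExperimentDesign,
                            noise_sd_fraction: float = 0.05,
                            strain: str = "LYS",
                            concentrations=EXPERIMENTAL_CONCENTRATIONS) -> GrowthDataset:
    """Replicated growth rates on the supplement ladder, with truncated noise.

    Rates follow ``vmax * s / (s + k_half)`` plus independent Gaussian noise
    of standard deviation ``noise_sd_fraction * vmax``, truncated at zero
    (a plate reader never reports negative growth).
    """
    if noise_sd_fraction < 0:
        raise InvalidParameterError("noise_sd_fraction must be >= 0")
    if vmax <= 0 or k_half <= 0:
        raise InvalidParameterError("vmax and k_half must be positive")
    rng = design.rng()
    s = np.asarray(concentrations, dtype=float)
    truth = vmax * s / (s + k_half)
    conc, rates, reps = [], [], []
    for rep in range(1, design.replicates + 1):
        noise = rng.normal(0.0, noise_sd_fraction * vmax, size=len(s)) \
            if noise_sd_fraction > 0 else np.zeros(len(s))
        conc.append(s)
        rates.append(np.maximum(truth + noise, 0.0))
        reps.append(np.full(len(s), rep))
    return GrowthDataset(strain=strain,
                         concentrations=np.concatenate(conc),
                         rates=np.concatenate(rates),
                         replicates=np.concatenate(reps))


def generate_coculture_counts(traj: Trajectory, design: ExperimentDesign) -> pd.DataFrame:
    """Plate-count table sampled from a model trajectory.

    At each sampling time (every ``sample_interval_h`` hours, mapped onto
    model time by ``hours_per_model_time``) and for each replicate, the
    total CFU count is Poisson around the scaled culture density and strain
    identities of ``plate_count_depth`` colonies are multinomial in the
    trajectory's strain fractions.  Columns: ``time_h, replicate,
    total_cfu, colonies_LYS, colonies_ADE, colonies_O, frac_ADE_est``.
    """
    rng = design.rng()
    sample_hours = np.arange(0.0, design.duration_h + 1e-9, design.sample_interval_h)
    rows = []
    for t_h in sample_hours:
        t_model = t_h / design.hours_per_model_time
        idx = int(np.argmin(np.abs(traj.times - t_model)))
        state = traj.states[idx]
        density = state[:3].sum()
        fractions = state[:3] / density if density > 0 else np.zeros(3)
        expected_cfu = density * design.carrying_capacity_cells * design.dilution
        for rep in range(1, design.replicates + 1):
            total = int(rng.poisson(expected_cfu))
            colonies = rng.multinomial(design.plate_count_depth, fractions) \
                if density > 0 else np.zeros(3, dtype=int)
            counted = colonies.sum()
            rows.append({
                "time_h": float(t_h),
                "replicate": rep,
                "total_cfu": total,
                "colonies_LYS": int(colonies[0]),
                "colonies_ADE": int(colonies[1]),
                "colonies_O": int(colonies[2]),
                "frac_ADE_est": float(colonies[1] / counted) if counted else np.nan,
            })
    return pd.DataFrame(rows)
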