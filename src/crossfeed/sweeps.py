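"""Parameter sweeps over supplementation space.

All sweeps use snapshot semantics — the state at a fixed reporting time,
default 300 — rather than equilibrium detection, because intermittent and
continuous dosing keep the system permanently out of equilibrium and only
a common evaluation time makes regimes comparable.

Every sweep is deterministic: identical inputs produce bit-identical
tables regardless of evaluation order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidParameterError
from .model import ModelParams, SystemState
from .regimes import SupplementationRegime
from .simulate import DEFAULT_T_END, Trajectory, dominant_strain, integrate

__all__ = [
    "PhaseDiagram",
    "DominanceGrid",
    "phase_diagram",
    "coexistence_zone",
    "timing_sweep",
    "overproducer_grid",
    "default_dose_axis",
    "default_ratio_axis",
]

#: Default initial total density of the seeded culture, well below K=1.
DEFAULT_TOTAL_DENSITY = 0.2


def default_dose_axis(n: int = 9) -> np.ndarray:
    """Log-spaced adenine doses bracketing the experimental 0.1/1/10 range."""
    return np.logspace(-2, 1, n)


def default_ratio_axis(n: int = 9) -> np.ndarray:
    """Log-spaced lysine-to-adenine dose ratios."""
    return np.logspace(-1, 1, n)


@dataclass(frozen=True)
class PhaseDiagram:
    """Snapshot ADE fraction over a (adenine dose, lysine ratio) grid."""

    doses_A: np.ndarray
    ratios_L: np.ndarray
    cells: np.ndarray  # shape (len(ratios_L), len(doses_A))
    snapshot_time: float
    regime_mode: str

    def __post_init__(self) -> None:
        if self.cells.shape != (len(self.ratios_L), len(self.doses_A)):
            raise InvalidInputError("cells shape must be (n_ratios, n_doses)")

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table with one row per grid cell."""
        rows = [
            {"dose_A": float(x), "ratio_L": float(y), "dose_L": float(x * y),
             "frac_ADE": float(self.cells[i, j])}
            for i, y in enumerate(self.ratios_L)
            for j, x in enumerate(self.doses_A)
        ]
        return pd.DataFrame(rows)

    def metadata(self) -> dict:
        return {"snapshot_time": self.snapshot_time, "regime_mode": self.regime_mode,
                "doses_A": [float(v) for v in self.doses_A],
                "ratios_L": [float(v) for v in self.ratios_L]}


@dataclass(frozen=True)
class DominanceGrid:
    """Dominant-strain label per (ro, intervention time, lysine dose)."""

    ro_values: np.ndarray
    intervention_times: np.ndarray
    lysine_doses: np.ndarray
    labels: np.ndarray  # shape (n_ro, n_doses, n_times), dtype object/str

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"ro": float(ro), "dose_L": float(d), "intervention_time": float(tau),
             "dominant": str(self.labels[i, j, k])}
            for i, ro in enumerate(self.ro_values)
            for j, d in enumerate(self.lysine_doses)
            for k, tau in enumerate(self.intervention_times)
        ]
        return pd.DataFrame(rows)


def _initial_state(init_fraction: float, total_density: float = DEFAULT_TOTAL_DENSITY,
                   overproducer_fraction: float = 0.0) -> SystemState:
    """Build a starting state from the ADE fraction of the seeded culture."""
    if not 0.0 <= init_fraction <= 1.0:
        raise InvalidParameterError(f"init_fraction must be in [0, 1], got {init_fraction!r}")
    xO = total_density * overproducer_fraction
    rest = total_density - xO
    return SystemState(xL=rest * (1.0 - init_fraction), xA=rest * init_fraction, xO=xO)


def phase_diagram(params: ModelParams,
                  regime_template: SupplementationRegime,
                  doses_A,
                  ratios_L,
                  init_fraction: float = 0.5,
                  snapshot_time: float = DEFAULT_T_END,
                  total_density: float = DEFAULT_TOTAL_DENSITY) -> PhaseDiagram:
    """Snapshot ADE fraction per (adenine dose, lysine ratio) grid cell.

    Each cell runs the template regime with ``doseA = x`` and
    ``doseL = x * y`` and reads the ADE fraction at ``snapshot_time``.
    """
    doses_A = np.asarray(doses_A, dtype=float)
    ratios_L = np.asarray(ratios_L, dtype=float)
    if doses_A.size == 0 or ratios_L.size == 0:
        raise InvalidInputError("dose and ratio axes must be non-empty")
    if np.any(doses_A < 0) or np.any(ratios_L < 0):
        raise InvalidParameterError("doses and ratios must be non-negative")
    init = _initial_state(init_fraction, total_density)
    cells = np.empty((len(ratios_L), len(doses_A)))
    for i, y in enumerate(ratios_L):
        for j, x in enumerate(doses_A):
            regime = regime_template.replace(doseA=float(x), doseL=float(x * y))
            try:
                traj = integrate(params, init, regime, t_end=snapshot_time)
            except Exception as exc:  # attach cell coordinates for diagnosis
                raise InvalidInputError(
                    f"cell (dose_A={x}, ratio_L={y}) failed: {exc}") from exc
            cells[i, j] = traj.ade_fraction[-1]
    return PhaseDiagram(doses_A=doses_A, ratios_L=ratios_L, cells=cells,
                        snapshot_time=snapshot_time, regime_mode=regime_template.mode)


def coexistence_zone(diagram: PhaseDiagram, lo: float = 0.2, hi: float = 0.8) -> float:
    """Fraction of grid cells whose snapshot ADE fraction lies in [lo, hi]."""
    if not (0.0 < lo < hi < 1.0):
        raise InvalidParameterError(f"need 0 < lo < hi < 1, got lo={lo}, hi={hi}")
    cells = diagram.cells
    if cells.size == 0:
        raise InvalidInputError("empty phase diagram")
    return float(np.mean((cells >= lo) & (cells <= hi)))


def timing_sweep(params: ModelParams,
                 periods,
                 doses,
                 init_fractions,
                 start_times=None,
                 snapshot_time: float = DEFAULT_T_END,
                 include_initial_dose: bool = False,
                 dose_ratio_L: float = 0.0,
                 total_density: float = DEFAULT_TOTAL_DENSITY) -> pd.DataFrame:
    """Snapshot ADE fraction across intermittent-supplementation schedules.

    One row per (period, dose, init_fraction, start).  ``start_times=None``
    uses ``start = period`` for each period (a dose at the end of every
    cycle, cycles filling ``[0, snapshot_time]``).  ``dose_ratio_L`` sets
    the lysine dose relative to the adenine dose (0 = adenine only).
    """
    rows = []
    for period in np.asarray(periods, dtype=float):
        if period <= 0:
            raise InvalidParameterError("periods must be positive")
        starts = [period] if start_times is None else list(np.asarray(start_times, dtype=float))
        for dose in np.asarray(doses, dtype=float):
            for f0 in np.asarray(init_fractions, dtype=float):
                init = _initial_state(f0, total_density)
                for start in starts:
                    regime = SupplementationRegime(
                        mode="intermittent", doseA=float(dose),
                        doseL=float(dose * dose_ratio_L),
                        period=float(period), start=float(start),
                        include_initial_dose=include_initial_dose)
                    traj = integrate(params, init, regime, t_end=snapshot_time)
                    rows.append({"period": float(period), "dose": float(dose),
                                 "init_fraction": float(f0), "start": float(start),
                                 "frac_ADE": float(traj.ade_fraction[-1])})
    return pd.DataFrame(rows)


def overproducer_grid(params: ModelParams,
                      ro_values,
                      intervention_times,
                      lysine_doses,
                      snapshot_time: float = DEFAULT_T_END,
                      init_fraction: float = 0.5,
                      overproducer_fraction: float = 1.0 / 3.0,
                      total_density: float = DEFAULT_TOTAL_DENSITY) -> DominanceGrid:
    """Dominant strain under lysine intervention against an overproducer.

    Intervention at time ``tau`` doses lysine at ``tau, 2*tau, 3*tau, ...``.
    A zero dose row reproduces the unsupplemented baseline.
    """
    ro_values = np.asarray(ro_values, dtype=float)
    intervention_times = np.asarray(intervention_times, dtype=float)
    lysine_doses = np.asarray(lysine_doses, dtype=float)
    labels = np.empty((len(ro_values), len(lysine_doses), len(intervention_times)),
                      dtype=object)
    init = _initial_state(init_fraction, total_density, overproducer_fraction)
    for i, ro in enumerate(ro_values):
        p = params.replace(ro=float(ro))
        for j, dose in enumerate(lysine_doses):
            for k, tau in enumerate(intervention_times):
                if dose == 0.0:
                    regime = SupplementationRegime(mode="none")
                else:
                    regime = SupplementationRegime(
                        mode="intermittent", doseA=0.0, doseL=float(dose),
                        period=float(tau), start=float(tau),
                        include_initial_dose=False)
                traj = integrate(p, init, regime, t_end=snapshot_time)
                labels[i, j, k] = dominant_strain(traj.final_state())
    return DominanceGrid(ro_values=ro_values, intervention_times=intervention_times,
                         lysine_doses=lysine_doses, labels=labels)


def save_grid(df: pd.DataFrame, csv_path, meta: dict, json_path=None) -> None:
    """Write a sweep table as long-format CSV plus a JSON metadata record."""
    df.to_csv(csv_path, index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
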