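"""Hybrid-system integration and trajectory analysis.

The flow between doses is smooth, so segments are integrated adaptively
(``scipy.integrate.solve_ivp``, LSODA, rtol = atol = 1e-9) and doses are
applied as exact instantaneous jumps between segments.  States are
reported on the fixed unit grid ``t = 0, 1, ..., t_end`` regardless of the
integrator's internal steps; at a reporting time that coincides with a
dose, the post-dose state is recorded.

A fixed-step explicit Euler integrator is provided as an independent
numerical oracle for the production path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import (
    ExtinctCultureError,
    IntegrationError,
    InvalidInputError,
    InvalidParameterError,
)
from .model import ModelParams, SystemState, rhs_vector
from .regimes import REPORTING_STEP, SupplementationRegime, event_times

__all__ = [
    "Trajectory",
    "EquilibrationReport",
    "integrate",
    "detect_equilibration",
    "dominant_strain",
    "euler_reference",
    "DEFAULT_T_END",
]

#: Snapshot convention used throughout the sweep figures.
DEFAULT_T_END = 300.0

_COLUMNS = ["t", "xL", "xA", "xO", "cA", "cL", "frac_LYS", "frac_ADE", "frac_O"]


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered system states on the unit reporting grid.

    ``states`` has one row per time, columns ordered ``(xL, xA, xO, cA, cL)``.
    """

    times: np.ndarray
    states: np.ndarray

    def __post_init__(self) -> None:
        if self.states.ndim != 2 or self.states.shape[1] != 5:
            raise InvalidInputError("states must be an (n, 5) array")
        if len(self.times) != len(self.states):
            raise InvalidInputError("times and states length mismatch")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def strain_fractions(self) -> np.ndarray:
        """Per-time fractions ``x_i / (xL + xA + xO)``, shape (n, 3)."""
        totals = self.states[:, :3].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            fr = self.states[:, :3] / totals[:, None]
        fr[totals == 0] = np.nan
        return fr

    @property
    def metabolite_fractions(self) -> np.ndarray:
        """Per-time fractions ``cA/(cA+cL)`` and ``cL/(cA+cL)``, shape (n, 2)."""
        totals = self.states[:, 3:].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            fr = self.states[:, 3:] / totals[:, None]
        fr[totals == 0] = np.nan
        return fr

    @property
    def ade_fraction(self) -> np.ndarray:
        return self.strain_fractions[:, 1]

    def state_at(self, t: float) -> SystemState:
        idx = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[idx] - t) > 1e-9:
            raise InvalidInputError(f"time {t} is not on the reporting grid")
        return SystemState.from_vector(self.states[idx], t=float(self.times[idx]))

    def final_state(self) -> SystemState:
        return SystemState.from_vector(self.states[-1], t=float(self.times[-1]))

    def to_dataframe(self) -> pd.DataFrame:
        fr = self.strain_fractions
        df = pd.DataFrame(self.states, columns=["xL", "xA", "xO", "cA", "cL"])
        df.insert(0, "t", self.times)
        df["frac_LYS"], df["frac_ADE"], df["frac_O"] = fr[:, 0], fr[:, 1], fr[:, 2]
        return df

    def to_csv(self, path) -> None:
        # %.17g guarantees float64 round-trips bit-exactly through text
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path, float_precision="round_trip")
        missing = set(_COLUMNS[:6]) - set(df.columns)
        if missing:
            raise InvalidInputError(f"trajectory CSV missing columns: {sorted(missing)}")
        return cls(times=df["t"].to_numpy(float),
                   states=df[["xL", "xA", "xO", "cA", "cL"]].to_numpy(float))


@dataclass(frozen=True)
class EquilibrationReport:
    """Result of the consecutive-step convergence criterion."""

    equilibrated: bool
    first_time: float | None
    max_step_change: float
    tol: float


def _clip_small_negatives(y: np.ndarray, t: float, clip_tol: float) -> np.ndarray:
    worst = y.min()
    if worst < -clip_tol:
        raise IntegrationError(
            f"component went negative beyond tolerance at t={t}: min={worst:.3e}",
            last_state=y, last_time=t)
    return np.maximum(y, 0.0)


def integrate(params: ModelParams,
              init: SystemState,
              regime: SupplementationRegime | None = None,
              t_end: float = DEFAULT_T_END,
              rtol: float = 1e-9,
              atol: float = 1e-9,
              clip_tol: float = 1e-7,
              method: str = "LSODA") -> Trajectory:
    """Integrate the (possibly hybrid) system and report on the unit grid.

    Doses from ``regime`` are applied as exact jumps between smooth
    segments; the comparability dose at ``t = 0`` is folded into the
    initial condition.  Small negative undershoots (``< clip_tol``) at
    reporting points are clipped to zero; larger ones raise
    :class:`IntegrationError`.
    """
    if regime is None:
        regime = SupplementationRegime(mode="none")
    n_steps = t_end / REPORTING_STEP
    if t_end <= 0 or abs(n_steps - round(n_steps)) > 1e-9:
        raise InvalidParameterError(
            f"t_end must be a positive multiple of the reporting step, got {t_end!r}")

    influx = (0.0, 0.0)
    if regime.mode == "continuous" and regime.continuous_influx:
        influx = (regime.doseA / REPORTING_STEP, regime.doseL / REPORTING_STEP)
    f = rhs_vector(params, influx=influx)

    grid = np.arange(int(round(n_steps)) + 1) * REPORTING_STEP
    dA0, dL0 = regime.initial_dose
    y = init.as_vector()
    y[3] += dA0
    y[4] += dL0

    events = event_times(regime, t_end)
    events = events[events > 1e-12]  # t=0 dose already folded in
    breakpoints = np.unique(np.concatenate([events, [t_end]]))

    out = np.empty((len(grid), 5))
    out[0] = y
    t_prev = 0.0
    for b in breakpoints:
        sample = grid[(grid > t_prev + 1e-9) & (grid < b - 1e-9)]
        t_eval = np.concatenate([sample, [b]])
        sol = solve_ivp(f, (t_prev, b), y, method=method,
                        rtol=rtol, atol=atol, t_eval=t_eval, dense_output=False)
        if not sol.success:
            raise IntegrationError(
                f"integrator failed in segment [{t_prev}, {b}]: {sol.message}",
                last_state=y, last_time=t_prev)
        for tk, yk in zip(sol.t[:-1], sol.y[:, :-1].T):
            idx = int(round(tk / REPORTING_STEP))
            out[idx] = _clip_small_negatives(yk, tk, clip_tol)
        y = _clip_small_negatives(sol.y[:, -1], b, clip_tol)
        if np.any(np.abs(events - b) < 1e-12):
            y = y.copy()
            y[3] += regime.doseA
            y[4] += regime.doseL
        on_grid = b / REPORTING_STEP
        if abs(on_grid - round(on_grid)) < 1e-9:
            out[int(round(on_grid))] = y
        t_prev = b

    return Trajectory(times=grid, states=out)


def detect_equilibration(traj: Trajectory,
                         tol: float = 1e-4,
                         all_components: bool = False) -> EquilibrationReport:
    """Check whether consecutive reporting-grid states have stopped moving.

    The criterion compares strain densities only (the published convention);
    ``all_components=True`` additionally includes the metabolites.
    ``first_time`` is the earliest reporting time from which every
    subsequent per-step change stays within ``tol``.
    """
    if len(traj) < 2:
        raise InvalidInputError("trajectory must have at least 2 reporting points")
    cols = slice(0, 5) if all_components else slice(0, 3)
    diffs = np.abs(np.diff(traj.states[:, cols], axis=0)).max(axis=1)
    max_step_change = float(diffs[-1])
    equilibrated = max_step_change <= tol
    first_time = None
    if equilibrated:
        above = np.nonzero(diffs > tol)[0]
        first_idx = (above[-1] + 2) if len(above) else 1
        first_time = float(traj.times[first_idx])
    return EquilibrationReport(equilibrated=equilibrated, first_time=first_time,
                               max_step_change=max_step_change, tol=tol)


def dominant_strain(state: SystemState, tie_tol: float = 1e-12) -> str:
    """Label of the strain with the strictly highest relative fraction.

    Returns one of ``"LYS"``, ``"ADE"``, ``"overproducer"``, or ``"tie"``.
    """
    total = state.total_density
    if total <= 0:
        raise ExtinctCultureError("culture has zero total density")
    fracs = np.array([state.xL, state.xA, state.xO]) / total
    order = np.argsort(fracs)
    if fracs[order[-1]] - fracs[order[-2]] <= tie_tol:
        return "tie"
    return ("LYS", "ADE", "overproducer")[order[-1]]


def euler_reference(params: ModelParams,
                    init: SystemState,
                    t_end: float,
                    dt: float = 1e-4) -> Trajectory:
    """Fixed-step explicit Euler integration (no supplementation).

    Independent oracle for :func:`integrate`; deliberately simple and
    structurally unrelated to the adaptive path.  Reports on the unit grid.
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be > 0")
    r1, r2, K = params.r1, params.r2, params.K
    b1, b2 = params.beta1, params.beta2
    g1, g2 = params.gamma1, params.gamma2
    kA, kL, ro = params.kcA, params.kcL, params.ro

    xL, xA, xO, cA, cL = init.as_vector()
    n_report = int(round(t_end / REPORTING_STEP))
    steps_per_report = int(round(REPORTING_STEP / dt))
    grid = np.arange(n_report + 1) * REPORTING_STEP
    out = np.empty((n_report + 1, 5))
    out[0] = (xL, xA, xO, cA, cL)
    for i in range(1, n_report + 1):
        for _ in range(steps_per_report):
            crowd = 1.0 - (xL + xA + xO) / K
            mA = cA / (cA + kA) if cA > 0 else 0.0
            mL = cL / (cL + kL) if cL > 0 else 0.0
            dxL = xL * r1 * mA * crowd
            dxA = xA * r2 * mL * crowd
            dxO = xO * ro * crowd
            dcA = b1 * (xA + xO) - g1 * mA * xL
            dcL = b2 * (xL + xO) - g2 * mL * xA
            xL += dt * dxL
            xA += dt * dxA
            xO += dt * dxO
            cA = max(cA + dt * dcA, 0.0)
            cL = max(cL + dt * dcL, 0.0)
        out[i] = (xL, xA, xO, cA, cL)
    return Trajectory(times=grid, states=out)
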