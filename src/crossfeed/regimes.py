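"""Environmental supplementation regimes.

Metabolites can be added to the culture in four ways:

``none``
    No external supplementation.
``initial``
    A single dose folded into the initial condition at ``t = 0``.
``intermittent``
    Instantaneous doses on a fixed schedule (``start``, ``start + period``,
    ...), turning the smooth flow into a hybrid dynamical system.
``continuous``
    A dose at every unit reporting step — the limiting case of intermittent
    supplementation with minimal period.

Doses are impulsive jumps in the free metabolite concentrations only;
strain densities are never touched.  The reporting step is fixed at 1.0
model time units, independent of the adaptive integrator's internal steps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidParameterError
from .model import SystemState

__all__ = ["SupplementationRegime", "apply_dose", "event_times", "REPORTING_STEP"]

#: Width of the fixed reporting grid, in model time units.
REPORTING_STEP = 1.0

_MODES = ("none", "initial", "intermittent", "continuous")


@dataclass(frozen=True)
class SupplementationRegime:
    """Disturbance schedule: what is added, how much, and when.

    Parameters
    ----------
    mode :
        One of ``none``, ``initial``, ``intermittent``, ``continuous``.
    doseA, doseL :
        Adenine and lysine added per event (concentration units).
    period :
        Time between events (intermittent only).
    start :
        Time of the first scheduled event (intermittent only).
    include_initial_dose :
        Whether the dose is also applied at ``t = 0`` (intermittent only;
        used to make intermittent runs comparable with the initial regime).
    continuous_influx :
        If true, continuous mode adds a constant source term ``dose/step``
        to the metabolite derivatives instead of per-step impulses.
    """

    mode: str = "none"
    doseA: float = 0.0
    doseL: float = 0.0
    period: float = 25.0
    start: float = 25.0
    include_initial_dose: bool = True
    continuous_influx: bool = False

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise InvalidParameterError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.doseA < 0 or self.doseL < 0:
            raise InvalidParameterError("doses must be non-negative")
        if self.mode == "intermittent":
            if self.period <= 0:
                raise InvalidParameterError("period must be > 0 for intermittent mode")
            if self.start < 0:
                raise InvalidParameterError("start must be >= 0")

    def replace(self, **kwargs) -> "SupplementationRegime":
        return replace(self, **kwargs)

    @property
    def initial_dose(self) -> tuple[float, float]:
        """Dose folded into the state at ``t = 0``, per mode."""
        if self.mode == "initial":
            return (self.doseA, self.doseL)
        if self.mode == "intermittent" and self.include_initial_dose:
            return (self.doseA, self.doseL)
        if self.mode == "continuous" and not self.continuous_influx:
            return (self.doseA, self.doseL)
        return (0.0, 0.0)


def apply_dose(state: SystemState, regime: SupplementationRegime) -> SystemState:
    """Impulsively add one dose of each metabolite to the state.

    Strain densities and time are untouched; doses are additive, so applying
    a dose twice equals applying a doubled dose once.
    """
    if regime.doseA < 0 or regime.doseL < 0:
        raise InvalidParameterError("doses must be non-negative")
    return state.replace(cA=state.cA + regime.doseA, cL=state.cL + regime.doseL)


def event_times(regime: SupplementationRegime, t_end: float) -> np.ndarray:
    """Scheduled dose times in ``[0, t_end]``, in increasing order.

    ``initial`` mode returns ``[0]``; ``intermittent`` returns the arithmetic
    series ``start, start + period, ...`` clipped to ``(0, t_end]``;
    ``continuous`` (impulse variant) returns every reporting step in
    ``(0, t_end]``.  The comparability dose at ``t = 0`` (``initial_dose``)
    is folded into the initial condition and is *not* listed for the
    intermittent and continuous modes.
    """
    if t_end <= 0:
        raise InvalidParameterError(f"t_end must be > 0, got {t_end!r}")
    if regime.mode == "none":
        return np.array([])
    if regime.mode == "initial":
        return np.array([0.0])
    if regime.mode == "continuous":
        if regime.continuous_influx:
            return np.array([])
        n = int(np.floor(t_end / REPORTING_STEP + 1e-9))
        return np.arange(1, n + 1) * REPORTING_STEP
    # intermittent: start, start+period, ... clipped to (0, t_end]
    first = regime.start if regime.start > 0 else regime.period
    n = int(np.floor((t_end - first) / regime.period + 1e-9))
    if n < 0:
        return np.array([])
    return first + np.arange(n + 1) * regime.period
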