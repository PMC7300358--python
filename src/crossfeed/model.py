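"""Core dynamics of the two-strain cross-feeding system and its
three-strain extension with a metabolite-independent overproducer.

Two auxotrophic strains grow logistically, each gated by a Monod factor
on the metabolite its partner secretes: the lysine overproducer (``LYS``)
needs free adenine, the adenine overproducer (``ADE``) needs free lysine.
An optional third strain (the "ultimate overproducer") secretes both
metabolites and grows at a flat, metabolite-independent rate.

All quantities are in normalized, dimensionless units (carrying capacity
``K = 1`` in the shipped presets); conversion to experimental units is
the concern of :mod:`crossfeed.synth`, never of this module.

The state vector is ordered ``(xL, xA, xO, cA, cL)`` everywhere.
"""

from __future__ import annotations

import dataclasses
import pathlib
import tomllib
from dataclasses import dataclass

import numpy as np
import yaml

from .errors import InvalidParameterError, InvalidStateError

__all__ = [
    "ModelParams",
    "SystemState",
    "Derivatives",
    "strain_rhs",
    "metabolite_rhs",
    "overproducer_rhs",
    "full_rhs",
    "rhs_vector",
    "monod",
    "load_params",
    "PRESETS",
]

STATE_ORDER = ("xL", "xA", "xO", "cA", "cL")


@dataclass(frozen=True)
class ModelParams:
    """Rate constants and capacities of the cross-feeding model.

    Attributes
    ----------
    r1, r2 :
        Maximum growth rates of the LYS- and ADE-overproducing strains.
    K :
        Carrying capacity shared by all strains.
    beta1, beta2 :
        Constitutive secretion rates of adenine (by ADE) and lysine (by LYS).
    gamma1, gamma2 :
        Maximum uptake rates of adenine (by LYS) and lysine (by ADE).
    kcA, kcL :
        Half-saturation constants of the Monod factors for adenine and lysine.
    ro :
        Flat growth rate of the ultimate overproducer; 0 disables it.
    """

    r1: float = 1.0
    r2: float = 2.0
    K: float = 1.0
    beta1: float = 0.1
    beta2: float = 0.1
    gamma1: float = 1.0
    gamma2: float = 1.0
    kcA: float = 2.0
    kcL: float = 1.0
    ro: float = 0.0

    def __post_init__(self) -> None:
        for name in ("r1", "r2", "K", "beta1", "beta2", "gamma1", "gamma2", "kcA", "kcL"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                # beta/gamma = 0 are legitimate degenerate cases used in
                # conservation checks; only the saturation constants and
                # capacity must be strictly positive to avoid 0/0.
                if name in ("beta1", "beta2", "gamma1", "gamma2") and v == 0:
                    continue
                raise InvalidParameterError(f"{name} must be strictly positive, got {v!r}")
        if not np.isfinite(self.ro) or self.ro < 0:
            raise InvalidParameterError(f"ro must be >= 0, got {self.ro!r}")

    def replace(self, **kwargs) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


#: Named parameter presets shipped with the package.  "informed" carries the
#: experimentally derived asymmetry (ADE grows twice as fast, with twice the
#: half-saturation constant); "neutral" is the fully symmetric control.
PRESETS: dict[str, ModelParams] = {
    "informed": ModelParams(r1=1.0, r2=2.0, kcA=2.0, kcL=1.0,
                            beta1=0.1, beta2=0.1, gamma1=1.0, gamma2=1.0, K=1.0),
    "neutral": ModelParams(r1=1.0, r2=1.0, kcA=1.0, kcL=1.0,
                           beta1=0.1, beta2=0.1, gamma1=1.0, gamma2=1.0, K=1.0),
}


@dataclass(frozen=True)
class SystemState:
    """Strain densities and free metabolite concentrations at one time."""

    xL: float
    xA: float
    xO: float = 0.0
    cA: float = 0.0
    cL: float = 0.0
    t: float = 0.0

    def __post_init__(self) -> None:
        for name in ("xL", "xA", "xO", "cA", "cL"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidStateError(f"{name} must be non-negative and finite, got {v!r}")

    @property
    def total_density(self) -> float:
        return self.xL + self.xA + self.xO

    def as_vector(self) -> np.ndarray:
        return np.array([self.xL, self.xA, self.xO, self.cA, self.cL], dtype=float)

    @classmethod
    def from_vector(cls, y, t: float = 0.0) -> "SystemState":
        return cls(xL=float(y[0]), xA=float(y[1]), xO=float(y[2]),
                   cA=float(y[3]), cL=float(y[4]), t=t)

    def replace(self, **kwargs) -> "SystemState":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class Derivatives:
    """Time derivatives matching the :class:`SystemState` fields."""

    dxL: float = 0.0
    dxA: float = 0.0
    dxO: float = 0.0
    dcA: float = 0.0
    dcL: float = 0.0

    def as_vector(self) -> np.ndarray:
        return np.array([self.dxL, self.dxA, self.dxO, self.dcA, self.dcL], dtype=float)


def monod(c: float, k: float) -> float:
    """Saturating uptake/growth factor ``c / (c + k)``.

    Defined as 0 at ``c = 0``; ``k <= 0`` is rejected to avoid 0/0.
    """
    if k <= 0:
        raise InvalidParameterError(f"half-saturation constant must be > 0, got {k!r}")
    if c < 0:
        raise InvalidStateError(f"concentration must be >= 0, got {c!r}")
    if c == 0.0:
        return 0.0
    return c / (c + k)


def _crowding(state: SystemState, params: ModelParams) -> float:
    return 1.0 - state.total_density / params.K


def strain_rhs(state: SystemState, params: ModelParams) -> Derivatives:
    """Growth of the two cross-feeding strains.

    Each strain grows at its maximum rate throttled by the Monod factor of
    the partner-supplied metabolite and the shared logistic crowding term.
    """
    crowd = _crowding(state, params)
    dxL = state.xL * params.r1 * monod(state.cA, params.kcA) * crowd
    dxA = state.xA * params.r2 * monod(state.cL, params.kcL) * crowd
    return Derivatives(dxL=dxL, dxA=dxA)


def metabolite_rhs(state: SystemState, params: ModelParams) -> Derivatives:
    """Free metabolite dynamics: constitutive secretion minus saturating uptake.

    Adenine is secreted by the ADE strain (and the overproducer) and taken
    up by LYS; lysine mirrors this.
    """
    dcA = params.beta1 * (state.xA + state.xO) - params.gamma1 * monod(state.cA, params.kcA) * state.xL
    dcL = params.beta2 * (state.xL + state.xO) - params.gamma2 * monod(state.cL, params.kcL) * state.xA
    return Derivatives(dcA=dcA, dcL=dcL)


def overproducer_rhs(state: SystemState, params: ModelParams) -> Derivatives:
    """Logistic growth of the ultimate overproducer at flat rate ``ro``."""
    dxO = state.xO * params.ro * _crowding(state, params)
    return Derivatives(dxO=dxO)


def full_rhs(state: SystemState, params: ModelParams) -> Derivatives:
    """Assembled right-hand side of the complete (three-strain) system."""
    s = strain_rhs(state, params)
    m = metabolite_rhs(state, params)
    o = overproducer_rhs(state, params)
    return Derivatives(dxL=s.dxL, dxA=s.dxA, dxO=o.dxO, dcA=m.dcA, dcL=m.dcL)


def rhs_vector(params: ModelParams, influx: tuple[float, float] = (0.0, 0.0)):
    """Return ``f(t, y) -> dy`` over the vector ``(xL, xA, xO, cA, cL)``.

    A fast closure suitable for :func:`scipy.integrate.solve_ivp`; it avoids
    dataclass construction per call but is algebraically identical to
    :func:`full_rhs`.  ``influx`` adds a constant source term to
    ``(dcA, dcL)`` — used by the influx variant of continuous supplementation.

    Adaptive integrators may probe slightly negative components; the Monod
    and production terms are evaluated with densities clamped at zero so the
    flow never amplifies an undershoot.
    """
    r1, r2, K = params.r1, params.r2, params.K
    b1, b2 = params.beta1, params.beta2
    g1, g2 = params.gamma1, params.gamma2
    kA, kL, ro = params.kcA, params.kcL, params.ro
    qA, qL = float(influx[0]), float(influx[1])

    def f(t: float, y: np.ndarray) -> np.ndarray:
        xL = y[0] if y[0] > 0.0 else 0.0
        xA = y[1] if y[1] > 0.0 else 0.0
        xO = y[2] if y[2] > 0.0 else 0.0
        cA = y[3] if y[3] > 0.0 else 0.0
        cL = y[4] if y[4] > 0.0 else 0.0
        crowd = 1.0 - (xL + xA + xO) / K
        mA = cA / (cA + kA)
        mL = cL / (cL + kL)
        return np.array([
            xL * r1 * mA * crowd,
            xA * r2 * mL * crowd,
            xO * ro * crowd,
            qA + b1 * (xA + xO) - g1 * mA * xL,
            qL + b2 * (xL + xO) - g2 * mL * xA,
        ])

    return f


def load_params(source: str | pathlib.Path | dict | ModelParams) -> ModelParams:
    """Resolve a parameter set from a preset name, config file, or mapping.

    Config files may be YAML (``.yaml``/``.yml``) or TOML (``.toml``) with
    keys named exactly as the :class:`ModelParams` fields; a ``preset`` key
    selects a base preset that the remaining keys override.
    """
    if isinstance(source, ModelParams):
        return source
    if isinstance(source, str) and source in PRESETS:
        return PRESETS[source]
    if isinstance(source, (str, pathlib.Path)):
        path = pathlib.Path(source)
        if not path.exists():
            raise InvalidParameterError(
                f"unknown preset or missing config file: {source!r} "
                f"(presets: {sorted(PRESETS)})")
        if path.suffix == ".toml":
            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        else:
            with open(path) as fh:
                data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise InvalidParameterError(f"config file {path} must contain a mapping")
        source = data
    base = ModelParams()
    data = dict(source)
    preset = data.pop("preset", None)
    if preset is not None:
        if preset not in PRESETS:
            raise InvalidParameterError(f"unknown preset {preset!r}")
        base = PRESETS[preset]
    valid = {f.name for f in dataclasses.fields(ModelParams)}
    unknown = set(data) - valid
    if unknown:
        raise InvalidParameterError(f"unknown parameter keys: {sorted(unknown)}")
    return base.replace(**{k: float(v) for k, v in data.items()})
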