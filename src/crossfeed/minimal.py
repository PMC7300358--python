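"""Minimal density–fraction reduction of the mutualism with explicit death.

The full metabolite-explicit system is collapsed to two variables: total
population density ``z`` and the ADE-strain fraction ``f``.  Each strain's
growth is proportional to its partner's density (the cross-feeding benefit
scales with partner abundance), with logistic crowding and a uniform
death rate ``d``:

    dz/dt = g(f) * z**2 * (1 - z) - d * z,      g(f) = (r1 + r2) * f * (1 - f)
    df/dt = z * (1 - z) * f * (1 - f) * (r2 - f * (r1 + r2))

The fraction dynamics are independent of ``d`` and pin the interior
fixed point at ``f* = r2 / (r1 + r2)``.  At ``f*`` the nontrivial density
equilibria solve ``g(f*) * z * (1 - z) = d`` — a quadratic whose two roots
(stable upper, unstable lower branch) collide in a saddle-node at
``z* = 1/2`` when ``d* = g(f*) / 4 = r1 * r2 / (4 * (r1 + r2))``; past
``d*`` extinction is the only stable state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CrossfeedError, InvalidParameterError, InvalidStateError

__all__ = [
    "MinimalParams",
    "BranchDiagram",
    "minimal_rhs",
    "interior_fraction",
    "equilibrium_branches",
    "find_bifurcation",
    "find_bifurcation_numeric",
]


@dataclass(frozen=True)
class MinimalParams:
    """Growth rates of the two strains and the shared death rate."""

    r1: float = 1.0
    r2: float = 2.0
    d: float = 0.0

    def __post_init__(self) -> None:
        if self.r1 <= 0 or self.r2 <= 0:
            raise InvalidParameterError("r1 and r2 must be strictly positive")
        if self.d < 0:
            raise InvalidParameterError("d must be >= 0")


@dataclass(frozen=True)
class BranchDiagram:
    """Stable/unstable density branches vs. death rate, with the saddle-node."""

    d_values: np.ndarray
    stable_z: np.ndarray    # NaN past the bifurcation
    unstable_z: np.ndarray  # NaN past the bifurcation
    d_star: float
    z_star: float

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"d": self.d_values, "stable_z": self.stable_z,
                             "unstable_z": self.unstable_z})


def _coupling(f: float, p: MinimalParams) -> float:
    return (p.r1 + p.r2) * f * (1.0 - f)


def minimal_rhs(z: float, f: float, p: MinimalParams) -> tuple[float, float]:
    """Time derivatives ``(dz, df)`` of density and ADE fraction."""
    if not 0.0 <= z <= 1.0:
        raise InvalidStateError(f"z must be in [0, 1], got {z!r}")
    if not 0.0 <= f <= 1.0:
        raise InvalidStateError(f"f must be in [0, 1], got {f!r}")
    dz = _coupling(f, p) * z * z * (1.0 - z) - p.d * z
    df = z * (1.0 - z) * f * (1.0 - f) * (p.r2 - f * (p.r1 + p.r2))
    return dz, df


def interior_fraction(p: MinimalParams) -> float:
    """Interior fixed point of the fraction dynamics, ``r2 / (r1 + r2)``."""
    return p.r2 / (p.r1 + p.r2)


def _branch_roots(d: float, g_star: float) -> tuple[float, float] | None:
    """Roots of ``g* z (1-z) = d`` in (0, 1]; None past the saddle-node."""
    disc = 1.0 - 4.0 * d / g_star
    if disc < 0:
        return None
    sq = np.sqrt(disc)
    return (1.0 + sq) / 2.0, (1.0 - sq) / 2.0


def equilibrium_branches(d_values, r1: float = 1.0, r2: float = 2.0) -> BranchDiagram:
    """Nontrivial density equilibria at the interior fraction, per death rate.

    The upper root is the stable branch, the lower the unstable one; both
    are NaN for ``d`` beyond the saddle-node.
    """
    p = MinimalParams(r1=r1, r2=r2)
    d_values = np.asarray(d_values, dtype=float)
    if d_values.size == 0:
        raise CrossfeedError("empty death-rate range")
    g_star = _coupling(interior_fraction(p), p)
    stable = np.full(d_values.shape, np.nan)
    unstable = np.full(d_values.shape, np.nan)
    for i, d in enumerate(d_values):
        roots = _branch_roots(float(d), g_star)
        if roots is not None:
            stable[i], unstable[i] = roots
    d_star, z_star = find_bifurcation(r1, r2)
    return BranchDiagram(d_values=d_values, stable_z=stable, unstable_z=unstable,
                         d_star=d_star, z_star=z_star)


def find_bifurcation(r1: float, r2: float) -> tuple[float, float]:
    """Closed-form saddle-node of the density quadratic.

    The branches coalesce at ``z* = 1/2`` (structural for this family) when
    ``d* = r1 * r2 / (4 * (r1 + r2))``.
    """
    p = MinimalParams(r1=r1, r2=r2)
    g_star = _coupling(interior_fraction(p), p)
    return g_star / 4.0, 0.5


def find_bifurcation_numeric(r1: float, r2: float, tol: float = 1e-12,
                             d_hi: float | None = None) -> tuple[float, float]:
    """Locate the saddle-node by bisection on branch existence.

    Independent continuation-style cross-check for :func:`find_bifurcation`:
    it only queries whether the two density equilibria exist at a given
    ``d`` (via a sign scan of ``dz/z`` over ``z``), never the closed form.
    """
    p = MinimalParams(r1=r1, r2=r2)
    f_star = interior_fraction(p)

    def branches_exist(d: float) -> bool:
        # growth-minus-death per capita rate on a fine z grid; two interior
        # equilibria exist iff the rate becomes positive somewhere in (0, 1)
        z = np.linspace(1e-6, 1.0 - 1e-6, 20001)
        rate = _coupling(f_star, p) * z * (1.0 - z) - d
        return bool(np.any(rate > 0))

    lo = 0.0
    hi = d_hi if d_hi is not None else (r1 + r2)  # generous upper bound
    if branches_exist(hi):
        raise CrossfeedError("upper bisection bound too small")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if branches_exist(mid):
            lo = mid
        else:
            hi = mid
    d_star = 0.5 * (lo + hi)
    # density at coalescence: maximizer of the per-capita growth term,
    # located by bounded scalar search (no closed form used)
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(lambda z: -z * (1.0 - z), bounds=(0.0, 1.0),
                          method="bounded", options={"xatol": 1e-12})
    return d_star, float(res.x)
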