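"""Michaelis–Menten parameterization of single-strain growth-rate data.

Growth rates measured at a ladder of supplement concentrations are fitted
with ``rate(s) = vmax * s / (s + k_half)`` by unweighted nonlinear least
squares, and the two strain fits are normalized against the LYS strain to
produce the model's growth-rate and half-saturation parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitFailureError, InvalidInputError

__all__ = [
    "GrowthDataset",
    "MonodFit",
    "fit_monod",
    "normalize_params",
    "read_growth_csv",
    "EXPERIMENTAL_CONCENTRATIONS",
]

#: Supplement ladder used by the single-strain growth assays (μg/ml).
EXPERIMENTAL_CONCENTRATIONS = (0.0, 0.1, 1.0, 10.0, 25.0, 50.0, 100.0, 200.0)

#: Which supplement each strain's growth assay varies.
_STRAIN_METABOLITE = {"ADE": "lysine", "LYS": "adenine"}


@dataclass(frozen=True)
class GrowthDataset:
    """Replicated (concentration, growth-rate) records for one strain."""

    strain: str
    concentrations: np.ndarray
    rates: np.ndarray
    replicates: np.ndarray
    metabolite: str | None = None

    def __post_init__(self) -> None:
        if self.strain not in _STRAIN_METABOLITE:
            raise InvalidInputError(f"strain must be 'ADE' or 'LYS', got {self.strain!r}")
        c = np.asarray(self.concentrations, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        if len(c) != len(r) or len(c) != len(self.replicates):
            raise InvalidInputError("concentrations, rates, replicates must align")
        if np.any(c < 0):
            raise InvalidInputError("concentrations must be non-negative")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "rates", r)
        object.__setattr__(self, "replicates", np.asarray(self.replicates))
        if self.metabolite is None:
            object.__setattr__(self, "metabolite", _STRAIN_METABOLITE[self.strain])

    @property
    def n_distinct_concentrations(self) -> int:
        return len(np.unique(self.concentrations))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "strain": self.strain,
            "concentration_ug_ml": self.concentrations,
            "growth_rate": self.rates,
            "replicate": self.replicates,
        })


@dataclass(frozen=True)
class MonodFit:
    """Fitted saturation curve with residual and uncertainty summaries."""

    vmax: float
    k_half: float
    vmax_se: float
    k_half_se: float
    rss: float
    n_points: int
    k_at_boundary: bool = False

    def predict(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return monod_curve(s, self.vmax, self.k_half)

    def to_dict(self) -> dict:
        return {"vmax": self.vmax, "k_half": self.k_half,
                "vmax_se": self.vmax_se, "k_half_se": self.k_half_se,
                "rss": self.rss, "n_points": self.n_points,
                "k_at_boundary": self.k_at_boundary}


def monod_curve(s, vmax, k_half):
    s = np.asarray(s, dtype=float)
    return vmax * s / (s + k_half)


def fit_monod(data: GrowthDataset, use_means: bool = False,
              k_boundary: float = 1e-8) -> MonodFit:
    """Least-squares fit of the saturation curve to a growth dataset.

    Replicates are fitted jointly by default so the reported uncertainty
    reflects biological spread; ``use_means=True`` fits replicate means
    instead.  No basal-growth offset is fitted: auxotrophs cannot grow
    unsupplemented, so the curve is pinned to ``rate(0) = 0``.
    """
    if data.n_distinct_concentrations < 3:
        raise InvalidInputError(
            f"need >= 3 distinct concentrations, got {data.n_distinct_concentrations}")
    s = data.concentrations
    r = data.rates
    if use_means:
        df = pd.DataFrame({"s": s, "r": r}).groupby("s", as_index=False).mean()
        s, r = df["s"].to_numpy(), df["r"].to_numpy()

    vmax0 = float(np.max(r))
    if vmax0 <= 0:
        raise FitFailureError("all growth rates are <= 0; nothing to fit",
                              diagnostics={"max_rate": vmax0})
    # initial k: concentration whose observed rate is nearest vmax0 / 2
    pos = s > 0
    k0 = float(s[pos][np.argmin(np.abs(r[pos] - vmax0 / 2.0))]) if np.any(pos) else 1.0
    k0 = max(k0, k_boundary)
    try:
        popt, pcov = curve_fit(monod_curve, s, r, p0=(vmax0, k0),
                               bounds=([0.0, k_boundary], [np.inf, np.inf]),
                               maxfev=10000)
    except RuntimeError as exc:
        raise FitFailureError(f"Monod fit failed to converge: {exc}",
                              diagnostics={"p0": (vmax0, k0)}) from exc
    vmax, k_half = float(popt[0]), float(popt[1])
    resid = r - monod_curve(s, vmax, k_half)
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    # k far below the smallest measured concentration means the data carry
    # no information about the saturation knee (flat-line degeneracy)
    s_min_pos = float(np.min(s[s > 0])) if np.any(s > 0) else np.inf
    at_boundary = k_half <= max(k_boundary * 10, 1e-3 * s_min_pos)
    return MonodFit(vmax=vmax, k_half=k_half,
                    vmax_se=float(se[0]), k_half_se=float(se[1]),
                    rss=float(np.sum(resid ** 2)), n_points=len(s),
                    k_at_boundary=bool(at_boundary))


def normalize_params(fit_ADE: MonodFit, fit_LYS: MonodFit,
                     round_to_presets: bool = False) -> dict:
    """Model parameters normalized against the LYS-strain fit.

    Returns the fragment ``{r1, r2, kcA, kcL}`` with ``r1 = kcL = 1`` by
    construction; ``round_to_presets=True`` snaps the ratios to the nearest
    half-integer (the convention behind the shipped "informed" preset).
    """
    r2 = fit_ADE.vmax / fit_LYS.vmax
    kcA = fit_ADE.k_half / fit_LYS.k_half
    if round_to_presets:
        r2 = round(r2 * 2) / 2
        kcA = round(kcA * 2) / 2
    return {"r1": 1.0, "r2": float(r2), "kcA": float(kcA), "kcL": 1.0}


def read_growth_csv(path, strain: str | None = None, sep: str = ",") -> list[GrowthDataset]:
    """Load growth datasets from delimited text.

    Expects columns ``strain, concentration_ug_ml, growth_rate, replicate``;
    returns one dataset per strain (or just ``strain`` if given).
    """
    df = pd.read_csv(path, sep=sep)
    required = {"strain", "concentration_ug_ml", "growth_rate", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"growth CSV missing columns: {sorted(missing)}")
    out = []
    for name, grp in df.groupby("strain"):
        if strain is not None and name != strain:
            continue
        out.append(GrowthDataset(
            strain=str(name),
            concentrations=grp["concentration_ug_ml"].to_numpy(float),
            rates=grp["growth_rate"].to_numpy(float),
            replicates=grp["replicate"].to_numpy()))
    if not out:
        raise InvalidInputError(f"no records for strain {strain!r} in {path}")
    return out


def write_fit_report(fits: dict[str, MonodFit], path, params_fragment: dict | None = None) -> None:
    """JSON report of per-strain fits plus the normalized parameter fragment."""
    payload = {name: fit.to_dict() for name, fit in fits.items()}
    if params_fragment is not None:
        payload["normalized_params"] = params_fragment
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
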