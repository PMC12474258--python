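"""Vehicle-referenced Box-Cox normalization of behavioral endpoints.

Raw endpoint distributions are strongly right-skewed (activity data are
non-negative with heavy upper tails), so each endpoint is power-transformed
before concentration-response modeling.  The transform is fit once, per
endpoint, on a pool of vehicle-control larvae:

1. a data-driven shift makes all control values positive (several endpoints,
   e.g. the startle differences and habituation slopes, can be <= 0);
2. the Box-Cox exponent ``lambda`` is chosen by profile log-likelihood over a
   grid [-3, 3] in steps of 0.01, ties broken toward lambda = 1;
3. transformed controls are centered at their mean and scaled by their SD, so
   every standardized endpoint is unit-variance noise under the null and one
   cutoff definition applies across endpoints.

Treated larvae are then mapped through the frozen control transform; their
standardized response is the signed displacement from the control mean in
control-SD units.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EPS_POS",
    "EndpointReference",
    "VehicleReference",
    "apply_reference",
    "boxcox_transform",
    "estimate_cutoff",
    "fit_boxcox",
    "fit_reference",
]

#: Positivity floor used both in the shift and when a treated value
#: undershoots the shifted support.
EPS_POS = 1e-6

MIN_CONTROLS = 20

LAMBDA_GRID = np.round(np.arange(-3.0, 3.0 + 1e-9, 0.01), 10)


def boxcox_transform(x: np.ndarray | float, lam: float, shift: float = 0.0) -> np.ndarray:
    """Two-parameter Box-Cox: ``((x+shift)^lam - 1)/lam`` (log at lam=0)."""
    z = np.asarray(x, dtype=float) + shift
    z = np.maximum(z, EPS_POS)
    if lam == 0.0:
        return np.log(z)
    return (np.power(z, lam) - 1.0) / lam


def _grid_llf(z: np.ndarray, lams: np.ndarray) -> np.ndarray:
    """Box-Cox profile log-likelihood at each lambda (vectorized).

    llf(lam) = (lam - 1) * sum(log z) - n/2 * log(var_mle(y_lam)); agrees
    with ``scipy.stats.boxcox_llf`` (asserted in the test suite).
    """
    n = z.size
    logz = np.log(z)
    sum_logz = logz.sum()
    lams = np.asarray(lams, dtype=float)
    y = np.empty((lams.size, n))
    nz = lams != 0.0
    y[nz] = np.expm1(np.outer(lams[nz], logz)) / lams[nz, None]
    y[~nz] = logz
    var = y.var(axis=1)
    return (lams - 1.0) * sum_logz - 0.5 * n * np.log(var)


def fit_boxcox(values: np.ndarray) -> tuple[float, float]:
    """Pick (lambda, shift) for one endpoint's control sample.

    shift = max(0, EPS_POS - min(values)) guarantees positive support;
    lambda maximizes the Box-Cox profile log-likelihood on the grid.
    Ties (within 1e-9 log-likelihood) are broken toward lambda closest to 1.
    """
    x = np.asarray(values, dtype=float)
    if x.size < MIN_CONTROLS:
        raise ValueError(f"insufficient controls: n={x.size} < {MIN_CONTROLS}")
    if np.any(~np.isfinite(x)):
        raise ValueError("non-finite control value")
    if np.var(x) == 0.0:
        raise ValueError("zero variance in controls")
    shift = max(0.0, EPS_POS - float(np.min(x)))
    z = x + shift
    llf = _grid_llf(z, LAMBDA_GRID)
    best = np.max(llf)
    ties = np.flatnonzero(llf >= best - 1e-9)
    lam = float(LAMBDA_GRID[ties[np.argmin(np.abs(LAMBDA_GRID[ties] - 1.0))]])
    return lam, shift


@dataclass(frozen=True)
class EndpointReference:
    """Frozen control transform for one endpoint."""

    lam: float
    shift: float
    center: float
    scale: float
    cutoff: float
    n_controls: int

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")


@dataclass
class VehicleReference:
    """Per-endpoint control transforms plus provenance."""

    endpoints: dict[str, EndpointReference]
    cutoff_multiplier: float = 1.0

    def __getitem__(self, endpoint: str) -> EndpointReference:
        return self.endpoints[endpoint]

    def to_json(self, path) -> None:
        doc = {
            "cutoff_multiplier": self.cutoff_multiplier,
            "endpoints": {k: asdict(v) for k, v in self.endpoints.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "VehicleReference":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        eps = {k: EndpointReference(**v) for k, v in doc["endpoints"].items()}
        return cls(endpoints=eps, cutoff_multiplier=float(doc["cutoff_multiplier"]))


def estimate_cutoff(multiplier: float = 1.0) -> float:
    """Response cutoff in standardized units.

    Controls are scale-standardized, so the cutoff is simply ``multiplier``
    control SDs.  Kept as an explicit operation so the definition has one
    home and one validation point.
    """
    if multiplier <= 0:
        raise ValueError("cutoff multiplier must be > 0")
    return float(multiplier)


def fit_endpoint_reference(
    control_values: np.ndarray, cutoff_multiplier: float = 1.0
) -> EndpointReference:
    lam, shift = fit_boxcox(control_values)
    t = boxcox_transform(np.asarray(control_values, float), lam, shift)
    center = float(np.mean(t))
    scale = float(np.std(t, ddof=1))
    if scale <= 0:
        raise ValueError("zero variance in transformed controls")
    return EndpointReference(
        lam=lam, shift=shift, center=center, scale=scale,
        cutoff=estimate_cutoff(cutoff_multiplier), n_controls=int(len(control_values)),
    )


def fit_reference(
    control_table: pd.DataFrame,
    endpoint_names: list[str] | tuple[str, ...],
    cutoff_multiplier: float = 1.0,
) -> VehicleReference:
    """Fit the per-endpoint control transforms on a vehicle-control pool."""
    refs = {
        name: fit_endpoint_reference(
            control_table[name].to_numpy(dtype=float), cutoff_multiplier
        )
        for name in endpoint_names
    }
    return VehicleReference(endpoints=refs, cutoff_multiplier=cutoff_multiplier)


def apply_reference(
    values: np.ndarray, ref: EndpointReference
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize endpoint values through a frozen control transform.

    Returns ``(responses, floored)``: responses are
    ``(boxcox(x + shift) - center)/scale``; ``floored`` flags values whose
    shifted argument fell at/below zero and was floored at ``EPS_POS``
    (possible for treated larvae outside the control support).
    """
    x = np.asarray(values, dtype=float)
    floored = (x + ref.shift) <= 0.0
    t = boxcox_transform(x, ref.lam, ref.shift)
    return (t - ref.center) / ref.scale, floored


def standardize_table(
    endpoint_table: pd.DataFrame,
    reference: VehicleReference,
    endpoint_names: list[str] | tuple[str, ...],
) -> pd.DataFrame:
    """Standardize every endpoint column of a per-larva endpoint table."""
    out = endpoint_table.copy()
    for name in endpoint_names:
        resp, floored = apply_reference(out[name].to_numpy(dtype=float), reference[name])
        out[name] = resp
        if floored.any():
            out[f"{name}_floored"] = floored
    return out
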