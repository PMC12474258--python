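"""Continuous hitcall and benchmark-concentration estimation per endpoint.

For each behavioral endpoint the standardized responses are fit with the full
model suite (:mod:`zfscreen.models`); activity is then scored by a continuous
hitcall in [0, 1], the product of three probability weights:

* ``w1`` — evidence of any concentration dependence: one minus the Akaike
  weight of the constant model among all converged fits;
* ``w2`` — probability that at least one concentration group's true median
  response exceeds the cutoff, from the median's sampling distribution under
  the fitted t(4) error model (SE_median = sigma / (2 f(0) sqrt(n)));
* ``w3`` — probability that the winning model's |top| exceeds the cutoff,
  from the top estimate and its delta-method standard error.

An endpoint is called active when hitcall >= 0.9 (configurable).  For active
endpoints the benchmark concentration (BMC) is the lowest concentration in
the tested range where the winning curve's |response| reaches the benchmark
response BMR (default 1.349 control SDs); BMDL/BMDU are the 5th/95th
percentiles of the BMC over seeded nonparametric bootstrap refits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .endpoints import ENDPOINT_NAMES
from .models import MODEL_NAMES, ModelFit, fit_suite_arrays, pseudo_conc
from .normalization import VehicleReference, apply_reference

__all__ = [
    "ConcRespInput",
    "ConcRespResult",
    "bmc",
    "fit_suite",
    "hitcall",
    "screen_chemical",
]

log = logging.getLogger(__name__)

DEFAULT_BMR_MULTIPLIER = 1.349
DEFAULT_HIT_THRESHOLD = 0.9

# median of n iid t(4, scale=sigma) draws: asymptotic SE = 1/(2 f(0) sqrt(n)),
# and the central t(4) density at 0 is 0.375/sigma.
_T4_F0 = 0.375


@dataclass(frozen=True)
class ConcRespInput:
    """Standardized responses for one endpoint of one chemical."""

    endpoint: str
    conc: np.ndarray      # µM, 0 for vehicle
    resp: np.ndarray      # standardized responses
    cutoff: float

    def __post_init__(self) -> None:
        conc = np.asarray(self.conc, dtype=float)
        resp = np.asarray(self.resp, dtype=float)
        object.__setattr__(self, "conc", conc)
        object.__setattr__(self, "resp", resp)
        if conc.shape != resp.shape:
            raise ValueError("conc and resp must align")
        if np.any(conc < 0):
            raise ValueError("negative concentration")
        if len(np.unique(conc[conc > 0])) < 2:
            raise ValueError("need >= 2 distinct nonzero concentrations")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")


@dataclass
class ConcRespResult:
    """Everything the screen reports for one endpoint."""

    endpoint: str
    fits: list[ModelFit]
    winner: ModelFit
    hitcall: float
    active: bool
    bmr: float
    bmc: float | None
    bmdl: float | None
    bmdu: float | None
    bmc_reason: str = ""
    w1: float = np.nan
    w2: float = np.nan
    w3: float = np.nan


def fit_suite(inp: ConcRespInput, models: tuple[str, ...] = MODEL_NAMES) -> list[ModelFit]:
    """Fit the whole model suite to one endpoint's responses."""
    return fit_suite_arrays(inp.conc, inp.resp, models=models)


def _akaike_weights(fits: list[ModelFit]) -> np.ndarray:
    aic = np.array([f.aic for f in fits])
    d = aic - aic.min()
    w = np.exp(-0.5 * d)
    return w / w.sum()


def pick_winner(fits: list[ModelFit]) -> ModelFit:
    """Lowest-AIC non-constant model (constant wins only if it is alone)."""
    non_cnst = [f for f in fits if f.name != "cnst"]
    pool = non_cnst if non_cnst else fits
    return min(pool, key=lambda f: f.aic)


def hitcall(fits: list[ModelFit], inp: ConcRespInput) -> tuple[float, float, float, float]:
    """Continuous activity score; returns (hitcall, w1, w2, w3)."""
    non_cnst = [f for f in fits if f.name != "cnst"]
    if not non_cnst:
        return 0.0, 0.0, np.nan, np.nan

    # w1: total Akaike weight of the non-constant models
    w = _akaike_weights(fits)
    cnst_w = sum(wi for f, wi in zip(fits, w) if f.name == "cnst")
    w1 = float(1.0 - cnst_w)

    # w2: P(at least one group median beyond the cutoff), treating groups as
    # independent and each observed median as normal about the truth
    winner = pick_winner(fits)
    sigma = winner.sigma
    p_none = 1.0
    for c in np.unique(inp.conc):
        grp = inp.resp[inp.conc == c]
        med = float(np.median(grp))
        se = sigma / (2.0 * _T4_F0 * np.sqrt(len(grp)))
        p_g = float(stats.norm.sf(inp.cutoff, loc=abs(med), scale=se))
        p_none *= 1.0 - min(max(p_g, 0.0), 1.0)
    w2 = float(1.0 - p_none)

    # w3: P(|top| of the winning model > cutoff)
    se_top = winner.top_se if np.isfinite(winner.top_se) and winner.top_se > 0 else sigma
    w3 = float(stats.norm.sf(inp.cutoff, loc=winner.top, scale=se_top))

    hc = float(np.clip(w1 * w2 * w3, 0.0, 1.0))
    return hc, w1, w2, w3


def _first_crossing(fit: ModelFit, bmr: float, c_lo: float, c_hi: float) -> float | None:
    """Smallest concentration in [c_lo, c_hi] with |f(c)| = bmr.

    Grid scan for the first bracketing interval, then bisection: robust to
    the non-monotone members of the suite (poly2, gnls).
    """
    grid = np.logspace(np.log10(c_lo), np.log10(c_hi), 513)
    g = np.abs(fit.predict(grid)) - bmr
    if g[0] >= 0:
        return float(grid[0])
    idx = np.flatnonzero((g[:-1] < 0) & (g[1:] >= 0))
    if idx.size == 0:
        return None
    lo, hi = grid[idx[0]], grid[idx[0] + 1]
    f = lambda c: abs(float(fit.predict(np.array([c]))[0])) - bmr
    for _ in range(80):
        mid = np.sqrt(lo * hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def bmc(
    winner: ModelFit,
    inp: ConcRespInput,
    bmr_multiplier: float = DEFAULT_BMR_MULTIPLIER,
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[float | None, float | None, float | None, float, str]:
    """Benchmark concentration of the winning model, with bootstrap CI.

    Returns ``(bmc, bmdl, bmdu, bmr, reason)``; the point estimate is None
    (reason set) when the curve never reaches the BMR in the tested range.
    BMDL/BMDU come from refitting the winning model to within-group
    nonparametric resamples.
    """
    if winner.name == "cnst":
        raise ValueError("BMC undefined for the constant model")
    bmr = float(bmr_multiplier)  # responses are in control-SD units
    conc_nz = inp.conc[inp.conc > 0]
    c_lo, c_hi = float(np.min(conc_nz)), float(np.max(conc_nz))
    est = _first_crossing(winner, bmr, c_lo, c_hi)
    if est is None:
        return None, None, None, bmr, "no crossing in tested range"
    if n_boot <= 0:
        return est, None, None, bmr, ""

    rng = np.random.default_rng(seed)
    conc_p = pseudo_conc(inp.conc)
    c0 = float(np.min(conc_p))
    groups = [np.flatnonzero(inp.conc == c) for c in np.unique(inp.conc)]
    boots = []
    from .models import fit_model

    for _ in range(n_boot):
        idx = np.concatenate([rng.choice(g, size=len(g), replace=True) for g in groups])
        refit = fit_model(winner.name, conc_p[idx], inp.resp[idx], c0)
        if refit is None:
            continue
        b = _first_crossing(refit, bmr, c_lo, c_hi)
        if b is not None:
            boots.append(b)
    if len(boots) >= 20:
        bmdl, bmdu = np.percentile(boots, [5.0, 95.0])
        bmdl = float(min(bmdl, est))
        bmdu = float(max(bmdu, est))
    else:  # pragma: no cover - needs pathological resamples
        bmdl = bmdu = None
    return est, bmdl, bmdu, bmr, ""


def analyze_endpoint(
    inp: ConcRespInput,
    bmr_multiplier: float = DEFAULT_BMR_MULTIPLIER,
    hit_threshold: float = DEFAULT_HIT_THRESHOLD,
    n_boot: int = 1000,
    seed: int | None = None,
    models: tuple[str, ...] = MODEL_NAMES,
) -> ConcRespResult:
    """Full per-endpoint analysis: suite fit, hitcall, BMC."""
    fits = fit_suite(inp, models=models)
    hc, w1, w2, w3 = hitcall(fits, inp)
    winner = pick_winner(fits)
    active = hc >= hit_threshold
    b = bl = bu = None
    reason = ""
    bmr = float(bmr_multiplier)
    if active and winner.name != "cnst":
        b, bl, bu, bmr, reason = bmc(
            winner, inp, bmr_multiplier=bmr_multiplier, n_boot=n_boot, seed=seed)
    return ConcRespResult(
        endpoint=inp.endpoint, fits=fits, winner=winner, hitcall=hc,
        active=bool(active), bmr=bmr, bmc=b, bmdl=bl, bmdu=bu,
        bmc_reason=reason, w1=w1, w2=w2, w3=w3,
    )


def screen_chemical(
    endpoint_table: pd.DataFrame,
    reference: VehicleReference,
    endpoint_names: tuple[str, ...] = ENDPOINT_NAMES,
    bmr_multiplier: float = DEFAULT_BMR_MULTIPLIER,
    hit_threshold: float = DEFAULT_HIT_THRESHOLD,
    n_boot: int = 1000,
    seed: int | None = None,
    models: tuple[str, ...] = MODEL_NAMES,
) -> tuple[list[ConcRespResult], pd.DataFrame]:
    """Run the 13-endpoint concentration-response screen for one chemical.

    ``endpoint_table`` holds one chemical's per-larva raw endpoint values
    (vehicle rows at conc 0 included).  Returns the per-endpoint results and
    a one-row-per-endpoint summary table (the heatmap row for this chemical).
    """
    conc = endpoint_table["conc_uM"].to_numpy(dtype=float)
    results: list[ConcRespResult] = []
    rows = []
    chemical = ""
    treated = endpoint_table.loc[endpoint_table["conc_uM"] > 0, "chemical"]
    if len(treated):
        chemical = str(treated.iloc[0])
    for k, name in enumerate(endpoint_names):
        if len(np.unique(conc[conc > 0])) < 2:
            log.warning("endpoint %s skipped: < 2 nonzero concentration groups", name)
            continue
        resp, _ = apply_reference(
            endpoint_table[name].to_numpy(dtype=float), reference[name])
        inp = ConcRespInput(
            endpoint=name, conc=conc, resp=resp, cutoff=reference[name].cutoff)
        sub_seed = None if seed is None else (seed * 131 + k) % (2**31 - 1)
        res = analyze_endpoint(
            inp, bmr_multiplier=bmr_multiplier, hit_threshold=hit_threshold,
            n_boot=n_boot, seed=sub_seed, models=models)
        results.append(res)
        rows.append({
            "chemical": chemical, "endpoint": name, "winning_model": res.winner.name,
            "hitcall": res.hitcall, "active": res.active, "bmc_uM": res.bmc,
            "bmdl_uM": res.bmdl, "bmdu_uM": res.bmdu, "bmr": res.bmr,
        })
    return results, pd.DataFrame(rows)
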