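"""Concentration-response model suite with robust Student-t likelihood.

Ten curve shapes are fit to (concentration, standardized response) pairs by
maximum likelihood with t-distributed residuals (df = 4, scale estimated),
which down-weights the occasional wild larva without explicit outlier
removal.  Responses are signed; every model can move in either direction.

Concentrations are in µM.  Vehicle controls (conc = 0) are mapped to a
pseudo-concentration half a log10 step below the lowest tested level so the
log-concentration models are defined everywhere; models expressed directly in
concentration treat the pseudo-concentration as "essentially zero dose".

Suite (free parameters beyond the residual scale in parentheses):

==========  ==================================================================
``cnst``    f(c) = 0                                              (0)
``poly1``   f(c) = b1 * z,            z = log10(c) - log10(c0)    (1)
``poly2``   f(c) = b1 * z + b2 * z^2                              (2)
``power``   f(c) = a * c^p                                        (2)
``hill``    f(c) = tp / (1 + (ga/c)^p)                            (3)
``gnls``    gain-loss: hill gain times loss term 1/(1+(c/la)^q)   (5)
``exp2``    f(c) = a * (exp(c/b) - 1)                             (2)
``exp3``    f(c) = a * (exp((c/b)^p) - 1)                         (3)
``exp4``    f(c) = tp * (1 - 2^(-c/ga))                           (2)
``exp5``    f(c) = tp * (1 - 2^(-(c/ga)^p))                       (3)
==========  ==================================================================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = ["MODEL_NAMES", "ModelFit", "fit_model", "fit_suite_arrays", "pseudo_conc"]

log = logging.getLogger(__name__)

MODEL_NAMES = (
    "cnst", "poly1", "poly2", "power", "hill",
    "gnls", "exp2", "exp3", "exp4", "exp5",
)

_T4_NORM = np.log(0.375)  # t(df=4) density at 0: gamma(5/2)/(sqrt(4*pi)*gamma(2))
_EXP_CAP = 50.0  # caps exponents so exp-family models cannot overflow


def t4_loglik(resid: np.ndarray, sigma: float) -> float:
    """Sum of log t(df=4, scale=sigma) densities."""
    z = resid / sigma
    return float(np.sum(_T4_NORM - 2.5 * np.log1p(z * z / 4.0) - np.log(sigma)))


def pseudo_conc(conc: np.ndarray) -> np.ndarray:
    """Replace vehicle (0) concentrations by half a log10 step below the
    lowest tested level."""
    conc = np.asarray(conc, dtype=float)
    nonzero = conc[conc > 0]
    if nonzero.size == 0:
        raise ValueError("no nonzero concentrations")
    c0 = float(np.min(nonzero)) / 10.0**0.25
    out = conc.copy()
    out[out == 0] = c0
    return out


def _curve(name: str, params: np.ndarray, conc: np.ndarray, c0: float) -> np.ndarray:
    c = np.asarray(conc, dtype=float)
    if name == "cnst":
        return np.zeros_like(c)
    if name == "poly1":
        (b1,) = params
        return b1 * (np.log10(c) - np.log10(c0))
    if name == "poly2":
        b1, b2 = params
        z = np.log10(c) - np.log10(c0)
        return b1 * z + b2 * z * z
    if name == "power":
        a, p = params
        return a * np.power(c, p)
    if name == "hill":
        tp, ga, p = params
        return tp / (1.0 + np.power(ga / c, p))
    if name == "gnls":
        tp, ga, p, la, q = params
        gain = 1.0 / (1.0 + np.power(ga / c, p))
        loss = 1.0 / (1.0 + np.power(c / la, q))
        return tp * gain * loss
    if name == "exp2":
        a, b = params
        return a * np.expm1(np.minimum(c / b, _EXP_CAP))
    if name == "exp3":
        a, b, p = params
        return a * np.expm1(np.minimum(np.power(c / b, p), _EXP_CAP))
    if name == "exp4":
        tp, ga = params
        return tp * (1.0 - np.exp2(-np.minimum(c / ga, _EXP_CAP)))
    if name == "exp5":
        tp, ga, p = params
        return tp * (1.0 - np.exp2(-np.minimum(np.power(c / ga, p), _EXP_CAP)))
    raise ValueError(f"unknown model {name!r}")


def _bounds_and_starts(
    name: str, conc: np.ndarray, resp: np.ndarray, c0: float
) -> tuple[list[tuple[float, float]], list[np.ndarray]]:
    """Parameter boxes and a small set of data-driven starting points."""
    cmax = float(np.max(conc))
    cmin = float(np.min(conc[conc > c0])) if np.any(conc > c0) else cmax
    rmax = max(float(np.max(np.abs(resp))), 0.1)
    # response at the top tested concentration, a cheap effect-direction probe
    top_med = float(np.median(resp[conc >= cmax * 0.999]))
    if top_med == 0.0:
        top_med = 0.1
    span = np.log10(cmax) - np.log10(c0)
    B_RESP = 1.2 * rmax * 5.0
    ga_lo, ga_hi = c0 / 10.0, cmax * 10.0
    ga_starts = [np.sqrt(cmin * cmax), cmax / 3.0]
    if name == "poly1":
        b = [(-B_RESP, B_RESP)]
        starts = [[top_med / span], [-top_med / span]]
    elif name == "poly2":
        b = [(-B_RESP, B_RESP)] * 2
        starts = [[top_med / span, 0.0], [0.0, top_med / span**2]]
    elif name == "power":
        b = [(-B_RESP, B_RESP), (0.3, 8.0)]
        starts = [[top_med / cmax**0.5, 0.5], [top_med / cmax**1.5, 1.5]]
    elif name == "hill":
        b = [(-B_RESP, B_RESP), (ga_lo, ga_hi), (0.3, 8.0)]
        starts = [[top_med, g, p] for g in ga_starts for p in (1.2, 3.0)]
    elif name == "gnls":
        b = [(-B_RESP, B_RESP), (ga_lo, ga_hi), (0.3, 8.0), (c0 / 10.0, cmax * 100.0), (0.3, 8.0)]
        starts = [[top_med, ga_starts[0], 1.2, cmax * 10.0, 1.2],
                  [2.0 * top_med, ga_starts[0], 1.2, cmax, 2.0]]
    elif name == "exp2":
        b = [(-B_RESP, B_RESP), (cmax / 100.0, cmax * 10.0)]
        starts = [[top_med / np.expm1(1.0), cmax], [top_med / np.expm1(2.0), cmax / 2.0]]
    elif name == "exp3":
        b = [(-B_RESP, B_RESP), (cmax / 100.0, cmax * 10.0), (0.3, 8.0)]
        starts = [[top_med / np.expm1(1.0), cmax, 1.0], [top_med, cmax, 0.5]]
    elif name == "exp4":
        b = [(-B_RESP, B_RESP), (ga_lo, ga_hi)]
        starts = [[top_med, g] for g in ga_starts]
    elif name == "exp5":
        b = [(-B_RESP, B_RESP), (ga_lo, ga_hi), (0.3, 8.0)]
        starts = [[top_med, g, p] for g in ga_starts for p in (1.2, 3.0)]
    else:  # cnst
        b, starts = [], [[]]
    clipped = []
    for s in starts:
        clipped.append(np.array([np.clip(v, lo, hi) for v, (lo, hi) in zip(s, b)]))
    return b, clipped if clipped else [np.array([])]


@dataclass
class ModelFit:
    """One converged model fit."""

    name: str
    params: np.ndarray
    sigma: float
    loglik: float
    aic: float
    top: float            # max |f| over the tested concentration range
    top_se: float         # delta-method SE of top (nan if unavailable)
    conc_at_top: float
    c0: float             # vehicle pseudo-concentration used in the fit
    cov: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_params(self) -> int:
        return len(self.params) + 1  # + residual scale

    def predict(self, conc: np.ndarray) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        c = np.where(c <= 0, self.c0, c)
        return _curve(self.name, self.params, c, self.c0)


def _nll(name, theta, conc, resp, c0):
    params, log_sigma = theta[:-1], theta[-1]
    sigma = np.exp(log_sigma)
    pred = _curve(name, params, conc, c0)
    if not np.all(np.isfinite(pred)):
        return 1e10
    return -t4_loglik(resp - pred, sigma)


def _numeric_hessian(f, x, eps=1e-4):
    n = len(x)
    h = np.empty((n, n))
    step = eps * np.maximum(np.abs(x), 1.0)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = step[i]
            ej = np.zeros(n); ej[j] = step[j]
            fpp = f(x + ei + ej); fpm = f(x + ei - ej)
            fmp = f(x - ei + ej); fmm = f(x - ei - ej)
            h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4 * step[i] * step[j])
    return h


def fit_model(
    name: str, conc: np.ndarray, resp: np.ndarray, c0: float
) -> ModelFit | None:
    """ML fit of one model; returns None when the optimizer fails."""
    conc = np.asarray(conc, dtype=float)
    resp = np.asarray(resp, dtype=float)
    sigma0 = max(float(np.std(resp)), 1e-3)
    bounds, starts = _bounds_and_starts(name, conc, resp, c0)
    full_bounds = bounds + [(np.log(1e-4), np.log(1e3))]

    best = None
    for s in starts:
        theta0 = np.concatenate([s, [np.log(sigma0)]])
        try:
            res = optimize.minimize(
                lambda th: _nll(name, th, conc, resp, c0),
                theta0, method="L-BFGS-B", bounds=full_bounds,
                options={"maxiter": 200},
            )
        except (ValueError, FloatingPointError):  # pragma: no cover
            continue
        if not np.all(np.isfinite(res.x)) or not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        log.warning("model %s failed to converge; excluded", name)
        return None

    params = best.x[:-1]
    sigma = float(np.exp(best.x[-1]))
    loglik = -float(best.fun)
    k = len(params) + 1
    aic = 2 * k - 2 * loglik

    # top = max |f| over the tested range, on a log-spaced grid + tested concs
    cmax = float(np.max(conc))
    grid = np.unique(np.concatenate([
        np.logspace(np.log10(c0), np.log10(cmax), 257), np.unique(conc)]))
    pred = _curve(name, params, grid, c0)
    i_top = int(np.argmax(np.abs(pred)))
    top = float(np.abs(pred[i_top]))
    conc_at_top = float(grid[i_top])

    cov = None
    top_se = np.nan
    if name != "cnst":
        try:
            hess = _numeric_hessian(
                lambda th: _nll(name, th, conc, resp, c0), best.x)
            cov_full = np.linalg.pinv(hess)
            cov = cov_full[:-1, :-1]
            # delta method on top via finite-difference gradient
            gr = np.zeros(len(params))
            for i in range(len(params)):
                dp = 1e-4 * max(abs(params[i]), 1.0)
                pp = params.copy(); pp[i] += dp
                pm = params.copy(); pm[i] -= dp
                fp = _curve(name, pp, np.array([conc_at_top]), c0)[0]
                fm = _curve(name, pm, np.array([conc_at_top]), c0)[0]
                gr[i] = (abs(fp) - abs(fm)) / (2 * dp)
            var = float(gr @ cov @ gr)
            if np.isfinite(var) and var > 0:
                top_se = float(np.sqrt(var))
        except (np.linalg.LinAlgError, ValueError):  # pragma: no cover
            pass
        if not np.isfinite(top_se) or top_se <= 0:
            # conservative fallback: SE of a group mean under the error model
            n_per = max(1, int(np.sum(conc >= cmax * 0.999)))
            top_se = float(np.sqrt(2.0) * sigma / np.sqrt(n_per))
    return ModelFit(
        name=name, params=params, sigma=sigma, loglik=loglik, aic=aic,
        top=top, top_se=top_se, conc_at_top=conc_at_top, c0=c0, cov=cov,
    )


def fit_suite_arrays(
    conc: np.ndarray, resp: np.ndarray, models: tuple[str, ...] = MODEL_NAMES
) -> list[ModelFit]:
    """Fit every model in the suite; failed models are dropped (logged)."""
    conc = pseudo_conc(conc)
    c0 = float(np.min(conc))
    fits = []
    for name in models:
        fit = fit_model(name, conc, resp, c0)
        if fit is not None:
            fits.append(fit)
    if not fits:
        raise RuntimeError("all concentration-response models failed")
    return fits
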