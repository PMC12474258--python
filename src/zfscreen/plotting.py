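"""Diagnostic plots: per-endpoint concentration-response and activity heatmap."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .concresp import ConcRespInput, ConcRespResult

__all__ = ["plot_concresp", "plot_heatmap"]


def plot_concresp(inp: ConcRespInput, result: ConcRespResult, ax=None):
    """Points, group means, cutoff band, BMR line, fitted curve and BMC."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    conc = np.asarray(inp.conc, float)
    nz = conc[conc > 0]
    c0 = nz.min() / 10**0.25
    x = np.where(conc == 0, c0, conc)
    ax.semilogx(x, inp.resp, "k.", ms=4, alpha=0.5, label="larvae")
    for c in np.unique(x):
        ax.plot(c, inp.resp[x == c].mean(), "o", color="tab:blue", ms=8)
    ax.axhspan(-inp.cutoff, inp.cutoff, color="tab:blue", alpha=0.15, label="cutoff")
    ax.axhline(result.bmr, color="k", ls="--", lw=1, label="BMR")
    ax.axhline(-result.bmr, color="k", ls="--", lw=1)
    grid = np.logspace(np.log10(c0), np.log10(nz.max()), 200)
    ax.plot(grid, result.winner.predict(grid), "k-", lw=1.5,
            label=f"{result.winner.name} fit")
    if result.bmc is not None:
        ax.axvline(result.bmc, color="tab:red", ls="--", lw=1.5, label="BMC")
        if result.bmdl is not None and result.bmdu is not None:
            ax.axvspan(result.bmdl, result.bmdu, color="tab:red", alpha=0.15)
    ax.set_xlabel("concentration (µM)")
    ax.set_ylabel("standardized response")
    ax.set_title(f"{inp.endpoint}  hitcall={result.hitcall:.2f}")
    ax.legend(fontsize=7)
    return ax


def plot_heatmap(heatmap: pd.DataFrame, ax=None):
    """Chemical x endpoint activity matrix (dark cells = active)."""
    import matplotlib.pyplot as plt

    mat = heatmap.pivot(index="endpoint", columns="chemical", values="hitcall")
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + mat.shape[1], 5))
    im = ax.imshow(mat.to_numpy(float), cmap="Blues", vmin=0, vmax=1, aspect="auto")
    ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=45, ha="right")
    ax.set_yticks(range(mat.shape[0]), mat.index)
    ax.figure.colorbar(im, ax=ax, label="hitcall")
    return ax
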