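"""Traditional analysis: mixed-design ANOVA with Fisher's LSD post hoc.

Each larva contributes its mean distance moved per bin in the light phase and
in the dark phase; phase is the within-subject factor (two levels, so no
sphericity correction is needed) and chemical concentration the
between-subject factor.  The decomposition is the classic split-plot
sums-of-squares:

* between-subject stratum: concentration vs subjects-within-groups error;
* within-subject stratum: phase and phase x concentration vs the
  phase x subject residual.

If the omnibus concentration effect or the interaction reaches p <= 0.05,
Fisher's LSD compares each treatment with the vehicle on each larva's total
average activity (the mean of its light and dark means), using the pooled
subjects-within-groups error term — i.e. unadjusted pairwise t tests with
the ANOVA's error df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RMAnovaResult", "fishers_lsd", "phase_means_table", "rm_anova"]

ALPHA = 0.05


@dataclass
class RMAnovaResult:
    """F tests for the two main effects and their interaction."""

    f_conc: float
    p_conc: float
    f_phase: float
    p_phase: float
    f_inter: float
    p_inter: float
    df_between: tuple[int, int]   # (g-1, N-g)
    df_within: tuple[int, int]    # (1 or g-1, N-g)
    ms_subj_error: float          # subjects-within-groups mean square
    n_subjects: int
    n_groups: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "effect": ["concentration", "phase", "concentration x phase"],
                "F": [self.f_conc, self.f_phase, self.f_inter],
                "p": [self.p_conc, self.p_phase, self.p_inter],
                "df1": [self.df_between[0], 1, self.df_within[0]],
                "df2": [self.df_between[1], self.df_within[1], self.df_within[1]],
            }
        )


def phase_means_table(endpoint_or_profile_table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a long-format bin table to per-larva light/dark phase means.

    Acclimation bins are dropped; output has one light and one dark row per
    larva with columns ``larva_id, conc_uM, phase, mean_distance``.
    """
    t = endpoint_or_profile_table
    t = t[t["phase"].isin(["light", "dark"])]
    out = (
        t.groupby(["plate_id", "larva_id", "conc_uM", "phase"], sort=True)["distance_cm"]
        .mean()
        .rename("mean_distance")
        .reset_index()
    )
    out["larva_id"] = out["plate_id"].astype(str) + ":" + out["larva_id"].astype(str)
    return out[["larva_id", "conc_uM", "phase", "mean_distance"]]


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    req = {"larva_id", "conc_uM", "phase", "mean_distance"}
    if not req <= set(table.columns):
        raise ValueError(f"phase-means table needs columns {sorted(req)}")
    counts = table.groupby("larva_id")["phase"].nunique()
    if not (counts == 2).all():
        raise ValueError("each larva needs exactly one light and one dark row")
    return table


def rm_anova(table: pd.DataFrame) -> RMAnovaResult:
    """Split-plot ANOVA of mean distance ~ concentration * phase.

    Concentration is between-subject, phase within-subject.  Balanced (or
    near-balanced) groups are assumed; empty concentration x phase cells are
    an error.
    """
    table = _validate(table)
    wide = table.pivot_table(
        index=["larva_id", "conc_uM"], columns="phase", values="mean_distance"
    ).reset_index()
    if wide[["light", "dark"]].isna().any().any():
        raise ValueError("empty cells: every larva needs both phases")

    y = np.stack([wide["light"].to_numpy(float), wide["dark"].to_numpy(float)], axis=1)
    groups = wide["conc_uM"].to_numpy(float)
    levels = np.unique(groups)
    g = len(levels)
    N = len(wide)
    if g < 2:
        raise ValueError("need >= 2 concentration groups")
    if min(np.sum(groups == lv) for lv in levels) < 3:
        raise ValueError("need >= 3 larvae per group")

    gm = y.mean()
    subj_means = y.mean(axis=1)
    grp_means = np.array([subj_means[groups == lv].mean() for lv in levels])
    n_g = np.array([np.sum(groups == lv) for lv in levels])

    ss_total = float(((y - gm) ** 2).sum())
    ss_between_subj = float(2.0 * ((subj_means - gm) ** 2).sum())
    ss_conc = float(2.0 * (n_g * (grp_means - gm) ** 2).sum())
    ss_subj_err = ss_between_subj - ss_conc

    phase_means = y.mean(axis=0)  # [light, dark]
    ss_phase = float(N * ((phase_means - gm) ** 2).sum())
    cell_means = np.array([y[groups == lv].mean(axis=0) for lv in levels])  # g x 2
    ss_inter = float(
        (n_g[:, None] * (cell_means - grp_means[:, None] - phase_means[None, :] + gm) ** 2).sum()
    )
    ss_within_subj = ss_total - ss_between_subj
    ss_phase_err = ss_within_subj - ss_phase - ss_inter

    df_conc, df_serr = g - 1, N - g
    df_phase, df_perr = 1, N - g
    df_inter = g - 1
    if ss_subj_err < 1e-12 or ss_phase_err < 1e-12:
        raise ValueError("degenerate data: zero residual variance")

    ms_conc = ss_conc / df_conc
    ms_serr = ss_subj_err / df_serr
    ms_phase = ss_phase / df_phase
    ms_inter = ss_inter / df_inter
    ms_perr = ss_phase_err / df_perr

    f_conc = ms_conc / ms_serr
    f_phase = ms_phase / ms_perr
    f_inter = ms_inter / ms_perr
    return RMAnovaResult(
        f_conc=float(f_conc), p_conc=float(stats.f.sf(f_conc, df_conc, df_serr)),
        f_phase=float(f_phase), p_phase=float(stats.f.sf(f_phase, df_phase, df_perr)),
        f_inter=float(f_inter), p_inter=float(stats.f.sf(f_inter, df_inter, df_perr)),
        df_between=(df_conc, df_serr), df_within=(df_inter, df_perr),
        ms_subj_error=float(ms_serr), n_subjects=N, n_groups=g,
    )


def fishers_lsd(table: pd.DataFrame, anova: RMAnovaResult, alpha: float = ALPHA) -> pd.DataFrame:
    """Each treatment vs vehicle on total average activity, LSD style.

    Gated: raises unless the omnibus concentration effect or the
    concentration x phase interaction is significant at ``alpha``.  The test
    statistic uses the pooled subjects-within-groups error; because each
    subject's total average is the mean of two phase values, its variance is
    estimated by ``ms_subj_error / 2`` with the ANOVA's error df.
    """
    if not (anova.p_conc <= alpha or anova.p_inter <= alpha):
        raise ValueError("LSD gated by omnibus test")
    table = _validate(table)
    totals = (
        table.groupby(["larva_id", "conc_uM"])["mean_distance"].mean().reset_index()
    )
    if 0.0 not in totals["conc_uM"].to_numpy():
        raise ValueError("no vehicle (conc 0) group")
    veh = totals.loc[totals["conc_uM"] == 0.0, "mean_distance"]
    var_tot = anova.ms_subj_error / 2.0
    df = anova.df_between[1]
    rows = []
    for lv in sorted(set(totals["conc_uM"]) - {0.0}):
        trt = totals.loc[totals["conc_uM"] == lv, "mean_distance"]
        se = np.sqrt(var_tot * (1.0 / len(trt) + 1.0 / len(veh)))
        t_stat = (trt.mean() - veh.mean()) / se
        p = 2.0 * stats.t.sf(abs(t_stat), df)
        rows.append({
            "conc_uM": lv, "mean_treated": trt.mean(), "mean_vehicle": veh.mean(),
            "diff": trt.mean() - veh.mean(), "t": float(t_stat), "df": df,
            "p": float(p), "significant": bool(p <= alpha),
        })
    return pd.DataFrame(rows)
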