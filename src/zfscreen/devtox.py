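"""Well-level developmental-toxicity scoring, plate QC and dosing arithmetic.

At 6 dpf every well is scored by a (blinded) observer for survival, hatching
and a fixed vocabulary of malformations; each well then receives exactly one
observed status with precedence dead > not-hatched > severely-abnormal >
abnormal > normal.  Plates whose vehicle controls are >15% non-normal are
discarded, and only live, hatched, malformation-free larvae (swim bladder
inflated) enter the behavior analysis.

Also houses the dilution-series arithmetic for the semi-log dosing design
(stock plate -> 250x diluted exposure plate) and the rinse-out residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "MALFORMATION_TYPES",
    "DoseDesign",
    "ObservedStatus",
    "WellObservation",
    "behavior_inclusion",
    "build_series",
    "classify_status",
    "plate_qc",
    "rinse_residual",
    "tally_plate",
]

MALFORMATION_TYPES = frozenset({
    "craniofacial", "spinal", "abdominal", "thoracic",
    "swim-bladder-not-inflated", "abnormal-water-column-position",
    "pigmentation-change",
})

QC_MAX_ABNORMAL_FRACTION = 0.15


class ObservedStatus(str, Enum):
    NORMAL = "normal"
    NOT_HATCHED = "not-hatched"
    ABNORMAL = "abnormal"
    SEVERELY_ABNORMAL = "severely-abnormal"
    DEAD = "dead"


STATUS_ORDER = (
    ObservedStatus.NORMAL, ObservedStatus.NOT_HATCHED, ObservedStatus.ABNORMAL,
    ObservedStatus.SEVERELY_ABNORMAL, ObservedStatus.DEAD,
)


@dataclass(frozen=True)
class WellObservation:
    """Raw observer calls for one well (one embryo/larva)."""

    well: str
    alive: bool
    hatched: bool
    malformations: frozenset = field(default_factory=frozenset)
    severity: str = "none"  # none | mild | severe

    def __post_init__(self) -> None:
        object.__setattr__(self, "malformations", frozenset(self.malformations))
        unknown = self.malformations - MALFORMATION_TYPES
        if unknown:
            raise ValueError(f"unknown malformation(s): {sorted(unknown)}")
        if self.severity not in ("none", "mild", "severe"):
            raise ValueError("severity must be none|mild|severe")
        if not self.malformations and self.severity != "none":
            raise ValueError("severity without malformations")


def classify_status(obs: WellObservation) -> ObservedStatus:
    """Collapse raw observations to one mutually-exclusive status.

    Precedence dead > not-hatched > severely-abnormal > abnormal > normal:
    morphology cannot be fully scored inside the chorion, so non-hatching
    outranks malformation calls.
    """
    if not obs.alive:
        return ObservedStatus.DEAD
    if not obs.hatched:
        return ObservedStatus.NOT_HATCHED
    if obs.severity == "severe":
        return ObservedStatus.SEVERELY_ABNORMAL
    if obs.malformations:
        return ObservedStatus.ABNORMAL
    return ObservedStatus.NORMAL


def tally_plate(observations_by_conc: dict[float, list[WellObservation]]) -> pd.DataFrame:
    """Percent of wells in each status per concentration group.

    Percentages are exact (they sum to 100 per group); a ``*_pct_display``
    rounding to one decimal is what the stacked-bar figures print.
    """
    rows = []
    for conc, obs_list in sorted(observations_by_conc.items()):
        if len(obs_list) == 0:
            raise ValueError(f"empty group at {conc}")
        statuses = [classify_status(o) for o in obs_list]
        n = len(statuses)
        row: dict[str, float] = {"conc_uM": conc, "n": n}
        for status in STATUS_ORDER:
            pct = 100.0 * sum(s == status for s in statuses) / n
            row[f"{status.value}_pct"] = pct
        rows.append(row)
    df = pd.DataFrame(rows)
    for status in STATUS_ORDER:
        df[f"{status.value}_pct_display"] = df[f"{status.value}_pct"].round(1)
    return df


def plate_qc(control_observations: list[WellObservation]) -> bool:
    """True (pass) unless strictly more than 15% of controls are non-normal."""
    if len(control_observations) == 0:
        raise ValueError("no control wells")
    non_normal = sum(
        classify_status(o) is not ObservedStatus.NORMAL for o in control_observations
    )
    return non_normal / len(control_observations) <= QC_MAX_ABNORMAL_FRACTION


def behavior_inclusion(obs: WellObservation) -> bool:
    """Only live, hatched, fully normal larvae enter the behavior assay."""
    return obs.alive and obs.hatched and not obs.malformations


@dataclass(frozen=True)
class DoseDesign:
    """Semi-log dilution design from stock plate to exposure plate."""

    top_stock_mM: float
    n_points: int
    dilution_factor: float = 250.0
    log10_step: float = 0.5
    rinses: int = 5
    rinse_retained: float = 0.5

    def __post_init__(self) -> None:
        if self.top_stock_mM <= 0:
            raise ValueError("top stock concentration must be > 0")
        if self.n_points < 1:
            raise ValueError("need >= 1 dose point")
        if not (0.0 <= self.rinse_retained <= 1.0):
            raise ValueError("retained fraction must be in [0, 1]")


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return float(np.round(x, -int(np.floor(np.log10(abs(x)))) + (sig - 1)))


def build_series(design: DoseDesign, display_sig_figs: int = 1) -> pd.DataFrame:
    """Stock and final well concentrations of the dilution series.

    Exact values follow ``top * 10^(-step*k)``; display values round to
    ``display_sig_figs`` significant figures (1 by default — the usual
    half-log {1, 3} x 10^k labelling, e.g. 100, 30, 10 ... 0.03 µM).
    """
    k = np.arange(design.n_points)
    stock_mM = design.top_stock_mM * 10.0 ** (-design.log10_step * k)
    final_uM = stock_mM * 1000.0 / design.dilution_factor
    return pd.DataFrame({
        "point": k + 1,
        "stock_mM": stock_mM,
        "final_uM": final_uM,
        "final_uM_display": [_round_sig(v, display_sig_figs) for v in final_uM],
    })


def rinse_residual(rinses: int, retained_per_rinse: float) -> float:
    """Percent of the original concentration left after serial rinses."""
    if rinses < 0:
        raise ValueError("rinse count must be >= 0")
    if not (0.0 <= retained_per_rinse <= 1.0):
        raise ValueError("retained fraction must be in [0, 1]")
    return 100.0 * retained_per_rinse**rinses
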