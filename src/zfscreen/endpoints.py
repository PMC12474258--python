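"""Behavioral endpoints of the larval light-dark transition test.

A larva's locomotor profile is the series of distances moved (cm) in
consecutive 2-min bins across a dark acclimation period, a light phase and a
dark phase.  From the light and dark bins (acclimation is never used) thirteen
endpoints summarise average activity, within-phase habituation, activity
range, the dark-transition startle and the dark:light balance:

====================  =========================================================
``avgSL``             mean light-bin distance (cm/bin)
``avgSD``             mean dark-bin distance (cm/bin)
``avgST``             mean over light and dark bins combined
``hbt1L``/``hbt1D``   slope first -> last bin, per phase (cm per bin index)
``hbt2L``/``hbt2D``   slope(2nd -> last) minus slope(1st -> 2nd-to-last)
``RoAL``/``RoAD``     max / (min + 1) distance within the phase
``strtlA``            first dark bin minus last light bin (cm/bin)
``strtlAavg``         first dark bin minus light-phase mean (cm/bin)
``strtlF``            first dark bin / last light bin (ratio)
``AUC_r``             trapezoidal AUC(dark) / AUC(light) over bin index
====================  =========================================================

Ratio denominators that could vanish are floored at ``EPS_DEN`` (0.02 cm, the
video-tracking noise floor), except ``RoA*`` whose "+1" guard is part of the
definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ENDPOINT_NAMES",
    "EPS_DEN",
    "LocomotorProfile",
    "bin_track",
    "compute_endpoints",
    "endpoints_table",
    "profiles_from_table",
]

#: Denominator floor (cm): the minimum distance the tracker can resolve.
EPS_DEN = 0.02

#: Canonical order of the 13 endpoints.
ENDPOINT_NAMES = (
    "avgSL", "avgSD", "avgST",
    "hbt1L", "hbt1D", "hbt2L", "hbt2D",
    "RoAL", "RoAD",
    "strtlA", "strtlAavg", "strtlF",
    "AUC_r",
)

PHASES = ("acclimation", "light", "dark")

#: Long-format column schema shared with the simulator and the CLI.
TABLE_COLUMNS = (
    "plate_id", "well", "larva_id", "chemical", "conc_uM",
    "bin_start_min", "phase", "distance_cm",
)


@dataclass(frozen=True)
class LocomotorProfile:
    """One larva's phase-labelled binned locomotor record.

    Parameters
    ----------
    larva_id, plate_id, chemical
        Opaque identifiers carried through to output tables.
    concentration
        Nominal exposure concentration in µM; 0 for vehicle controls.
    bin_starts
        Bin start times, minutes from recording start, strictly increasing
        with constant width.
    phases
        Phase label per bin; phases must appear in the order
        acclimation -> light -> dark, each contiguous (acclimation optional).
    distances
        Distance moved per bin (cm), finite and >= 0.
    """

    larva_id: str
    plate_id: str
    chemical: str
    concentration: float
    bin_starts: np.ndarray
    phases: np.ndarray
    distances: np.ndarray
    bin_width: float = 2.0

    def __post_init__(self) -> None:
        starts = np.asarray(self.bin_starts, dtype=float)
        phases = np.asarray(self.phases, dtype=object)
        dist = np.asarray(self.distances, dtype=float)
        object.__setattr__(self, "bin_starts", starts)
        object.__setattr__(self, "phases", phases)
        object.__setattr__(self, "distances", dist)
        if not (len(starts) == len(phases) == len(dist)):
            raise ValueError("bin arrays must have equal length")
        if len(starts) == 0:
            raise ValueError("profile has no bins")
        steps = np.diff(starts)
        if len(steps) and not np.allclose(steps, self.bin_width):
            raise ValueError("bins must be contiguous with constant width")
        if np.any(~np.isfinite(dist)):
            raise ValueError("non-finite bin distance")
        if np.any(dist < 0):
            raise ValueError("negative bin distance")
        seen = [p for i, p in enumerate(phases) if i == 0 or phases[i - 1] != p]
        if len(seen) != len(set(seen)) or [p for p in PHASES if p in seen] != seen:
            raise ValueError(
                "phases must be contiguous in acclimation -> light -> dark order"
            )
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")

    def phase_distances(self, phase: str) -> np.ndarray:
        return self.distances[self.phases == phase]

    @property
    def n_light(self) -> int:
        return int(np.sum(self.phases == "light"))

    @property
    def n_dark(self) -> int:
        return int(np.sum(self.phases == "dark"))


def bin_track(
    timestamps_min: Sequence[float],
    displacements_cm: Sequence[float],
    *,
    bin_width: float = 2.0,
    min_move: float = 0.02,
    acclimation_min: float = 20.0,
    light_min: float = 40.0,
    dark_min: float = 40.0,
    larva_id: str = "",
    plate_id: str = "",
    chemical: str = "",
    concentration: float = 0.0,
) -> LocomotorProfile:
    """Sum per-sample displacements into half-open 2-min bins.

    Displacements below ``min_move`` are zeroed before summation — the
    tracker's minimum-distance filter that suppresses background jitter.
    Bins are half-open ``[start, start + bin_width)``; phase labels follow
    the protocol durations (acclimation, then light, then dark).
    """
    t = np.asarray(timestamps_min, dtype=float)
    d = np.asarray(displacements_cm, dtype=float)
    if t.size == 0:
        raise ValueError("no samples")
    if t.size != d.size:
        raise ValueError("timestamps and displacements differ in length")
    if np.any(np.diff(t) < 0):
        raise ValueError("timestamps must be monotone non-decreasing")
    if min_move < 0:
        raise ValueError("min_move must be >= 0")
    d = np.where(d < min_move, 0.0, d)

    total = acclimation_min + light_min + dark_min
    n_bins = int(round(total / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.digitize(t, edges[1:], right=False)  # [start, start+width)
    keep = (t >= 0) & (t < total)
    sums = np.bincount(idx[keep], weights=d[keep], minlength=n_bins)[:n_bins]

    starts = edges[:-1]
    phases = np.empty(n_bins, dtype=object)
    phases[starts < acclimation_min] = "acclimation"
    phases[(starts >= acclimation_min) & (starts < acclimation_min + light_min)] = "light"
    phases[starts >= acclimation_min + light_min] = "dark"
    return LocomotorProfile(
        larva_id=larva_id, plate_id=plate_id, chemical=chemical,
        concentration=concentration, bin_starts=starts, phases=phases,
        distances=sums, bin_width=bin_width,
    )


def compute_endpoints(profile: LocomotorProfile) -> dict[str, float]:
    """Evaluate the 13 endpoints on one profile.

    Requires at least 3 light and 3 dark bins; acclimation bins are ignored.
    Returns a dict keyed by :data:`ENDPOINT_NAMES`.
    """
    l = profile.phase_distances("light")
    d = profile.phase_distances("dark")
    for name, arr in (("light", l), ("dark", d)):
        if arr.size < 3:
            raise ValueError(f"need >= 3 {name} bins, got {arr.size}")
        if np.any(np.isnan(arr)):
            raise ValueError(f"NaN distance in {name} phase")
    m, n = l.size, d.size

    avgSL = float(np.mean(l))
    avgSD = float(np.mean(d))
    avgST = float(np.mean(np.concatenate([l, d])))
    hbt1L = float((l[-1] - l[0]) / (m - 1))
    hbt1D = float((d[-1] - d[0]) / (n - 1))
    hbt2L = float((l[-1] - l[1]) / (m - 2) - (l[-2] - l[0]) / (m - 2))
    hbt2D = float((d[-1] - d[1]) / (n - 2) - (d[-2] - d[0]) / (n - 2))
    RoAL = float(np.max(l) / (np.min(l) + 1.0))
    RoAD = float(np.max(d) / (np.min(d) + 1.0))
    strtlA = float(d[0] - l[-1])
    strtlAavg = float(d[0] - avgSL)
    strtlF = float(d[0] / max(l[-1], EPS_DEN))
    auc_l = float(np.trapezoid(l))
    auc_d = float(np.trapezoid(d))
    AUC_r = auc_d / max(auc_l, EPS_DEN)
    return {
        "avgSL": avgSL, "avgSD": avgSD, "avgST": avgST,
        "hbt1L": hbt1L, "hbt1D": hbt1D, "hbt2L": hbt2L, "hbt2D": hbt2D,
        "RoAL": RoAL, "RoAD": RoAD,
        "strtlA": strtlA, "strtlAavg": strtlAavg, "strtlF": strtlF,
        "AUC_r": AUC_r,
    }


def profiles_from_table(table: pd.DataFrame) -> list[LocomotorProfile]:
    """Build profiles from the long-format table (one row per larva-bin).

    Expected columns: ``plate_id, well, larva_id, chemical, conc_uM,
    bin_start_min, phase, distance_cm``.
    """
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    profiles = []
    for (plate, larva), grp in table.groupby(["plate_id", "larva_id"], sort=True):
        grp = grp.sort_values("bin_start_min")
        starts = grp["bin_start_min"].to_numpy(dtype=float)
        width = float(np.median(np.diff(starts))) if len(starts) > 1 else 2.0
        profiles.append(
            LocomotorProfile(
                larva_id=str(larva),
                plate_id=str(plate),
                chemical=str(grp["chemical"].iloc[0]),
                concentration=float(grp["conc_uM"].iloc[0]),
                bin_starts=starts,
                phases=grp["phase"].to_numpy(dtype=object),
                distances=grp["distance_cm"].to_numpy(dtype=float),
                bin_width=width,
            )
        )
    return profiles


def endpoints_table(profiles: Iterable[LocomotorProfile]) -> pd.DataFrame:
    """One row per larva: identifiers plus the 13 endpoint columns."""
    rows = []
    for p in profiles:
        row = {
            "plate_id": p.plate_id,
            "larva_id": p.larva_id,
            "chemical": p.chemical,
            "conc_uM": p.concentration,
        }
        row.update(compute_endpoints(p))
        rows.append(row)
    return pd.DataFrame(rows, columns=["plate_id", "larva_id", "chemical", "conc_uM", *ENDPOINT_NAMES])
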