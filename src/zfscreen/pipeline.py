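"""End-to-end orchestration of the two parallel analyses.

``run_screen`` takes the long-format bin table plus the per-well observation
table, applies plate QC and behavior-inclusion filtering, computes the
13-endpoint table, fits (or loads) the vehicle Box-Cox reference, and runs

* the concentration-response screen (hitcall + BMC per endpoint, heatmap), and
* the traditional repeated-measures ANOVA with Fisher's LSD,

per chemical.  Every output table carries the config hash and seed so a run
can be reproduced from its bundle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classic_stats, concresp, devtox
from .config import PipelineConfig
from .endpoints import ENDPOINT_NAMES, endpoints_table, profiles_from_table
from .normalization import VehicleReference, fit_reference

__all__ = ["ScreenBundle", "run_screen"]

log = logging.getLogger(__name__)


@dataclass
class ScreenBundle:
    """All outputs of one screening run."""

    config: PipelineConfig
    qc_report: pd.DataFrame
    endpoint_table: pd.DataFrame
    reference: VehicleReference
    heatmap: pd.DataFrame
    concresp_results: dict[str, list[concresp.ConcRespResult]]
    anova_tables: dict[str, pd.DataFrame]
    lsd_tables: dict[str, pd.DataFrame]
    log_lines: list[str] = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = {"config_hash": self.config.config_hash(), "seed": self.config.seed}

        def _save(df: pd.DataFrame, name: str) -> None:
            out = df.copy()
            for k, v in meta.items():
                out[k] = v
            out.to_csv(outdir / name, index=False)

        _save(self.qc_report, "qc_report.csv")
        _save(self.endpoint_table, "endpoints.csv")
        _save(self.heatmap, "heatmap.csv")
        self.reference.to_json(outdir / "vehicle_reference.json")
        anova = [t.assign(chemical=c) for c, t in self.anova_tables.items()]
        if anova:
            _save(pd.concat(anova, ignore_index=True), "anova.csv")
        lsd = [t.assign(chemical=c) for c, t in self.lsd_tables.items()]
        if lsd:
            _save(pd.concat(lsd, ignore_index=True), "lsd.csv")
        (outdir / "run.log").write_text("\n".join(self.log_lines) + "\n", encoding="utf-8")


def _observation_from_row(row: pd.Series) -> devtox.WellObservation:
    malformations = frozenset(
        m for m in devtox.MALFORMATION_TYPES if bool(row.get(m, False))
    )
    return devtox.WellObservation(
        well=str(row["well"]), alive=bool(row["alive"]), hatched=bool(row["hatched"]),
        malformations=malformations, severity=str(row.get("severity", "none")),
    )


def run_screen(
    config: PipelineConfig,
    bin_table: pd.DataFrame,
    plate_map: pd.DataFrame,
    observation_table: pd.DataFrame | None = None,
) -> ScreenBundle:
    """Run both analyses on a study's plates.

    ``bin_table`` is the long-format per-larva bin table; ``plate_map`` maps
    (plate_id, well) to chemical and conc_uM; ``observation_table`` (optional,
    one row per plate/well with alive/hatched/malformation columns) drives QC
    and behavior inclusion.  Plates failing QC are dropped with a logged
    reason; if every plate fails, that is an error.
    """
    lines: list[str] = [f"config_hash={config.config_hash()} seed={config.seed}"]

    plates = sorted(bin_table["plate_id"].astype(str).unique())
    qc_rows = []
    keep_plates = []
    excluded_wells: set[tuple[str, str]] = set()
    if observation_table is not None:
        for plate in plates:
            pm = plate_map[plate_map["plate_id"].astype(str) == plate]
            obs_plate = observation_table[
                observation_table["plate_id"].astype(str) == plate
            ] if "plate_id" in observation_table.columns else observation_table
            obs = {str(r["well"]): _observation_from_row(r) for _, r in obs_plate.iterrows()}
            ctrl_wells = pm.loc[pm["conc_uM"] == 0.0, "well"].astype(str)
            controls = [obs[w] for w in ctrl_wells if w in obs]
            ok = devtox.plate_qc(controls) if controls else True
            frac = (
                np.mean([devtox.classify_status(o).value != "normal" for o in controls])
                if controls else np.nan
            )
            qc_rows.append({"plate_id": plate, "n_controls": len(controls),
                            "frac_non_normal": frac, "qc_pass": ok})
            if ok:
                keep_plates.append(plate)
                for w, o in obs.items():
                    if not devtox.behavior_inclusion(o):
                        excluded_wells.add((plate, w))
                        lines.append(f"plate={plate} well={w} excluded: inclusion rule")
            else:
                lines.append(f"plate={plate} removed: QC fail ({frac:.1%} controls non-normal)")
    else:
        keep_plates = plates
        qc_rows = [{"plate_id": p, "n_controls": 0, "frac_non_normal": np.nan,
                    "qc_pass": True} for p in plates]
    qc_report = pd.DataFrame(qc_rows)
    if not keep_plates:
        raise RuntimeError("all plates failed QC")

    bt = bin_table[bin_table["plate_id"].astype(str).isin(keep_plates)].copy()
    if excluded_wells:
        mask = ~bt.apply(
            lambda r: (str(r["plate_id"]), str(r["well"])) in excluded_wells, axis=1
        )
        bt = bt[mask]

    profiles = profiles_from_table(bt)
    ep_table = endpoints_table(profiles)

    if config.reference_path:
        reference = VehicleReference.from_json(config.reference_path)
        lines.append(f"vehicle reference loaded from {config.reference_path}")
    else:
        controls = ep_table[ep_table["conc_uM"] == 0.0]
        reference = fit_reference(controls, list(ENDPOINT_NAMES), config.cutoff_multiplier)
        lines.append(f"vehicle reference fit on {len(controls)} pooled control larvae")

    heat_rows = []
    cr_results: dict[str, list[concresp.ConcRespResult]] = {}
    anova_tables: dict[str, pd.DataFrame] = {}
    lsd_tables: dict[str, pd.DataFrame] = {}
    chemicals = sorted(
        c for c in ep_table.loc[ep_table["conc_uM"] > 0, "chemical"].astype(str).unique()
    )
    for chem in chemicals:
        sub = ep_table[(ep_table["chemical"] == chem) | (ep_table["conc_uM"] == 0.0)]
        results, heat = concresp.screen_chemical(
            sub, reference,
            bmr_multiplier=config.bmr_multiplier,
            hit_threshold=config.hit_threshold,
            n_boot=config.n_boot, seed=config.seed,
        )
        cr_results[chem] = results
        heat_rows.append(heat)
        for r in results:
            if r.bmc is None and r.active:
                lines.append(f"chemical={chem} endpoint={r.endpoint} BMC absent: {r.bmc_reason}")

        pm_table = classic_stats.phase_means_table(
            bt[(bt["chemical"].astype(str) == chem) | (bt["conc_uM"] == 0.0)]
        )
        res = classic_stats.rm_anova(pm_table)
        anova_tables[chem] = res.to_frame()
        if res.p_conc <= config.alpha or res.p_inter <= config.alpha:
            lsd_tables[chem] = classic_stats.fishers_lsd(pm_table, res, config.alpha)
        else:
            lines.append(f"chemical={chem} LSD gated: omnibus p > {config.alpha}")
    heatmap = pd.concat(heat_rows, ignore_index=True) if heat_rows else pd.DataFrame()
    return ScreenBundle(
        config=config, qc_report=qc_report, endpoint_table=ep_table,
        reference=reference, heatmap=heatmap, concresp_results=cr_results,
        anova_tables=anova_tables, lsd_tables=lsd_tables, log_lines=lines,
    )
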