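"""End-to-end orchestration: simulate → QC → behavior → screening → DEG.

Every stage writes plain-text intermediates (CSV/TSV/JSON) plus a manifest
entry recording its parameters and the SHA-256 of each output, so a run is
diffable and re-executable from the manifest alone. One master seed governs
all stochastic stages; conditions gated out for 100% mortality are skipped
downstream with an explicit log line.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import abnormality_stats, behavior_qc, behavior_stats, chem_units, deg_analysis
from . import synthetic_data as synth
from .behavior_qc import PhotoperiodSchedule, QCThresholds
from .exceptions import LarvatoxError, StageError
from .synthetic_data import SimulationConfig

log = logging.getLogger("larvatox")


@dataclass
class RunConfig:
    """Everything a full synthetic run needs; serialized into the manifest."""

    outdir: Path
    seed: int = 0
    simulation: SimulationConfig | None = None
    schedule: PhotoperiodSchedule = field(default_factory=PhotoperiodSchedule)
    qc_thresholds: QCThresholds = field(default_factory=QCThresholds)
    alpha: float = 0.05
    lfc_cut: float = deg_analysis.LFC_CUT
    padj_cut: float = deg_analysis.PADJ_CUT
    dedup_policy: str = "sum"
    control_group: str | None = None  # default: first group label

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)
        elif self.simulation.seed != self.seed:
            self.simulation = dataclasses.replace(self.simulation, seed=self.seed)
        if self.control_group is None:
            self.control_group = self.simulation.groups[0].label


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_dict(config: RunConfig) -> dict:
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, frozenset):
            return sorted(obj)
        if isinstance(obj, dict):
            return {
                ("+".join(sorted(k)) if isinstance(k, frozenset) else str(k)): encode(v)
                for k, v in obj.items()
            }
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        return obj

    return encode(config)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages on synthetic inputs; returns the run manifest."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _config_dict(config), "stages": []}
    sim = config.simulation
    assert sim is not None

    def record(stage: str, outputs: dict[str, Path], **info) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "outputs": {name: {"path": str(p), "sha256": _sha256(p)} for name, p in outputs.items()},
                **info,
            }
        )

    # --- simulate -----------------------------------------------------------
    try:
        traces, trace_truth = synth.simulate_traces(sim, config.schedule)
        screening = synth.simulate_screening(sim)
        deg_table, deg_truth = synth.simulate_deg_table(sim)
        traces_path = outdir / "traces.csv"
        behavior_qc.write_traces_csv(traces, traces_path)
        screening_path = outdir / "screening.csv"
        screening.to_csv(screening_path, index=False)
        deg_path = outdir / "deg_table.tsv"
        deg_analysis.write_deg_table(deg_table, deg_path)
        truth_path = outdir / "truth.json"
        synth.write_truth_json(truth_path, trace_truth, deg_truth)
        record(
            "simulate",
            {
                "traces": traces_path,
                "screening": screening_path,
                "deg_table": deg_path,
                "truth": truth_path,
            },
            seed=sim.seed,
            n_traces=len(traces),
        )
    except LarvatoxError as exc:
        raise StageError("simulate", str(exc)) from exc

    # --- mortality gate (before behavior/abnormalities) ---------------------
    gate = abnormality_stats.mortality_gate(screening)
    non_evaluable = {
        f"{r['chemical']}:{r['concentration_nM']:g}nM:{r['duration']}"
        for _, r in gate.iterrows()
        if not r["evaluable"]
    }
    for label in sorted(non_evaluable):
        log.warning("condition %s non-evaluable (100%% mortality); skipped downstream", label)

    # --- qc -----------------------------------------------------------------
    try:
        usable = [t for t in traces if t.group not in non_evaluable]
        retained, qc_report = behavior_qc.apply_qc(usable, config.qc_thresholds)
        qc_json = outdir / "qc_report.json"
        qc_csv = outdir / "qc_report.csv"
        qc_report.to_json(qc_json)
        qc_report.to_csv(qc_csv)
        record(
            "qc",
            {"report_json": qc_json, "report_csv": qc_csv},
            n_in=len(usable),
            n_retained=len(retained),
            skipped_groups=sorted(non_evaluable),
        )
        log.info("qc: %d/%d traces retained", len(retained), len(usable))
    except LarvatoxError as exc:
        raise StageError("qc", str(exc)) from exc

    # --- behavior stats -----------------------------------------------------
    try:
        summary = behavior_stats.summarize_movement(retained)
        summary_path = outdir / "behavior_summary.csv"
        summary.to_csv(summary_path, index=False)
        behavior_results = {}
        for phase in (behavior_qc.LIGHT, behavior_qc.DARK):
            res = behavior_stats.compare_groups(
                summary, config.control_group, phase, alpha=config.alpha
            )
            behavior_results[phase] = {
                "anova_F": res.anova_F,
                "anova_p": res.anova_p,
                "pairwise": res.pairwise.to_dict(orient="records"),
            }
        behavior_path = outdir / "behavior_tests.json"
        behavior_path.write_text(json.dumps(behavior_results, indent=2, default=float))
        record("behavior", {"summary": summary_path, "tests": behavior_path})
    except LarvatoxError as exc:
        raise StageError("behavior", str(exc)) from exc

    # --- abnormality stats --------------------------------------------------
    try:
        endpoint_results = abnormality_stats.analyze_endpoints(
            screening, alpha=config.alpha
        )
        abn = {
            f"{endpoint}|{chem}|{dur}": {
                "global_chi2": r.global_chi2,
                "df": r.df,
                "global_p": r.global_p,
                "m": r.m,
                "pairwise": r.pairwise.to_dict(orient="records"),
            }
            for (endpoint, chem, dur), r in endpoint_results.items()
        }
        abn_path = outdir / "abnormality_tests.json"
        abn_path.write_text(
            json.dumps(
                {"non_evaluable": sorted(non_evaluable), "tests": abn},
                indent=2,
                default=float,
            )
        )
        gate_path = outdir / "mortality_gate.csv"
        gate.to_csv(gate_path, index=False)
        record("abnormalities", {"tests": abn_path, "gate": gate_path})
    except LarvatoxError as exc:
        raise StageError("abnormalities", str(exc)) from exc

    # --- deg ----------------------------------------------------------------
    try:
        significant = deg_analysis.filter_degs(deg_table, config.lfc_cut, config.padj_cut)
        counts = deg_analysis.count_by_condition(significant, config.dedup_policy)
        counts_path = outdir / "deg_counts.csv"
        counts.per_duration.to_csv(counts_path, index=False)
        per_conc_path = outdir / "deg_counts_per_concentration.csv"
        counts.per_concentration.to_csv(per_conc_path, index=False)
        sets = deg_analysis.combined_chemical_sets(significant)
        venn_path = outdir / "deg_venn.json"
        if len(sets) >= 2:
            venn = deg_analysis.overlap_sets(sets)
            venn_path.write_text(json.dumps(venn.to_json_dict(), indent=2))
        else:
            venn_path.write_text(json.dumps({"sets": sorted(sets), "regions": []}))
        record(
            "deg",
            {"counts": counts_path, "per_concentration": per_conc_path, "venn": venn_path},
            n_records=len(deg_table),
            n_significant=len(significant),
        )
        log.info("deg: %d/%d records pass the filter", len(significant), len(deg_table))
    except LarvatoxError as exc:
        raise StageError("deg", str(exc)) from exc

    # --- unit conversions ---------------------------------------------------
    try:
        rows = []
        for group in sim.groups:
            if group.is_control:
                continue
            try:
                chem = chem_units.get_chemical(group.chemical)
            except LarvatoxError:
                continue
            rows.append(
                {
                    "chemical": chem.name,
                    "concentration_nM": group.concentration_nM,
                    "concentration_ugL": chem_units.nM_to_ugL(chem, group.concentration_nM),
                }
            )
        conv_path = outdir / "concentration_conversions.csv"
        pd.DataFrame(rows).to_csv(conv_path, index=False)
        record("convert", {"conversions": conv_path})
    except LarvatoxError as exc:
        raise StageError("convert", str(exc)) from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
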