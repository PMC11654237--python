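"""End-to-end orchestration: data in, Table-style report and power
comparison out.

``run_reproduction`` drives the whole analysis from one config object:
generate (or load) a control-result stream, evaluate every run under the
phase rule plans, compute the per-analyte/per-phase CV/bias/sigma matrix
with its cross-analyte mean rows and improvement counts, and run the
Monte-Carlo Ped/Pfr comparison of the phase rule sets.  A ``reference``
mode replays the bundled published summary matrix through the identical
report-building code (no raw data exist for it, so per-run decisions are
skipped in that mode).
"""
from __future__ import annotations

import csv
import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import __version__
from .datasets import load_study_config, reference_summaries
from .errors import ConfigError, QCDataError
from .io import (
    StudyConfig,
    read_qc_results,
    write_qc_results,
    write_study_config,
    write_summary_json,
    write_summary_table,
    round_cv,
)
from .metrics import METRICS, StudyReport, build_report, summaries_from_config
from .model import ErrorCondition, QCResult
from .power import compare_phase_rulesets
from .rules import RunDecision, apply_plan
from .simulate import SyntheticStudyConfig, default_config, generate_study

__all__ = ["PipelineConfig", "run_reproduction", "format_report"]

log = logging.getLogger("westgardqc")

MODES = ("synthetic", "file", "reference")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one reproduction run needs.

    Exactly one input mode is active: ``synthetic`` (seeded generator),
    ``file`` (CSV of control results + YAML study config) or ``reference``
    (bundled published summary matrix).
    """

    mode: str = "synthetic"
    outdir: Path = Path("westgardqc-out")
    seed: int = 0
    input_csv: Optional[Path] = None
    config_path: Optional[Path] = None
    synthetic: Optional[SyntheticStudyConfig] = None
    shift_grid: Tuple[float, ...] = (1.0, 2.0, 3.0)
    replicates: int = 500
    horizon_runs: int = 10
    run_power: bool = True

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode == "file" and self.input_csv is None:
            raise ConfigError("file mode requires input_csv")
        if self.mode != "file" and self.input_csv is not None:
            raise ConfigError("input_csv is only valid in file mode")


def _config_hash(config: PipelineConfig) -> str:
    payload = repr(config).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _decisions_rows(decisions: Dict[str, List[RunDecision]]) -> List[dict]:
    rows = []
    for analyte in sorted(decisions):
        for d in decisions[analyte]:
            rows.append(
                {
                    "run_index": d.run_index,
                    "analyte": analyte,
                    "phase": d.phase_label or "",
                    "status": d.status,
                    "violated_rules": ";".join(v.rule.value for v in d.violations),
                }
            )
    return rows


def _log_violation_counts(decisions: Dict[str, List[RunDecision]]) -> None:
    for analyte in sorted(decisions):
        per_phase: Dict[str, Counter] = {}
        for d in decisions[analyte]:
            c = per_phase.setdefault(d.phase_label or "?", Counter())
            for v in d.violations:
                c[v.rule.value] += 1
        for phase in sorted(per_phase):
            counts = per_phase[phase]
            text = (
                ", ".join(f"{r}={n}" for r, n in sorted(counts.items()))
                if counts
                else "none"
            )
            log.info("%s phase %s: violations %s", analyte, phase, text)


def format_report(report: StudyReport) -> str:
    """Plain-text metrics matrix with mean rows and improvement counts."""
    phases = report.phases
    columns = []
    for p in phases:
        columns += [f"CV_{p}", f"Bias_{p}", f"Sigma_{p}"]
    cells = {(s.analyte_id, s.phase_label): s for s in report.summaries}
    data = []
    for analyte in report.analytes:
        row = []
        for p in phases:
            s = cells[(analyte, p)]
            row += [round_cv(s.cv_pct), round(s.bias_pct, 2), round(s.sigma, 2)]
        data.append(row)
    mean_row = []
    for p in phases:
        m = report.phase_means[p]
        mean_row += [m["cv"], m["bias"], m["sigma"]]
    frame = pd.DataFrame(
        data + [mean_row], index=report.analytes + ["Mean"], columns=columns
    )
    lines = [frame.to_string(), ""]
    lines.append(
        "Improved {}->{}: ".format(report.first_phase, report.last_phase)
        + ", ".join(f"{m}={report.improvements[m]}/{len(report.analytes)}" for m in METRICS)
    )
    return "\n".join(lines) + "\n"


def run_reproduction(config: PipelineConfig) -> Dict[str, object]:
    """Run the full analysis and write all outputs under ``config.outdir``.

    Writes the metrics matrix (CSV + JSON + plain text), the improvement
    counts (JSON), per-run decisions with violations (CSV + JSON; not in
    reference mode), the Ped/Pfr phase comparison (CSV) and a manifest
    recording seed, version and config hash.  On any stage failure the
    partially written outputs of this invocation are removed and the error
    re-raised with the stage name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    def target(name: str) -> Path:
        p = outdir / name
        written.append(p)
        return p

    stage = "setup"
    try:
        # --- input stage -------------------------------------------------
        stage = "input"
        dataset: Optional[List[QCResult]] = None
        if config.mode == "file":
            study_cfg = (
                load_study_config()
                if config.config_path is None
                else _read_config(config.config_path)
            )
            dataset = read_qc_results(config.input_csv)
        elif config.mode == "synthetic":
            syn = config.synthetic or default_config(config.seed)
            study_cfg = _study_config_for(syn)
            dataset, _peer, _truth = generate_study(syn)
            write_qc_results(dataset, target("qc_results.csv"))
            write_study_config(study_cfg, target("study_config.yaml"))
        else:  # reference
            study_cfg = load_study_config()

        # --- metrics stage -----------------------------------------------
        stage = "metrics"
        if config.mode == "reference":
            summaries = reference_summaries()
        else:
            summaries = summaries_from_config(dataset, study_cfg)
        report = build_report(summaries)
        write_summary_table(summaries, target("metrics_summary.csv"))
        write_summary_json(summaries, target("metrics_summary.json"))
        target("report.txt").write_text(format_report(report), encoding="utf-8")
        with target("improvements.json").open("w", encoding="utf-8") as fh:
            json.dump(
                {
                    "from_phase": report.first_phase,
                    "to_phase": report.last_phase,
                    "improved": report.improvements,
                    "phase_means": report.phase_means,
                },
                fh,
                indent=2,
            )
            fh.write("\n")

        # --- rule-evaluation stage ---------------------------------------
        if dataset is not None:
            stage = "rules"
            decisions = apply_plan(dataset, study_cfg.phases, study_cfg.controls)
            _log_violation_counts(decisions)
            rows = _decisions_rows(decisions)
            with target("decisions.csv").open("w", newline="", encoding="utf-8") as fh:
                writer = csv.DictWriter(
                    fh,
                    fieldnames=["run_index", "analyte", "phase", "status", "violated_rules"],
                )
                writer.writeheader()
                writer.writerows(rows)
            with target("decisions.json").open("w", encoding="utf-8") as fh:
                json.dump(rows, fh, indent=2)
                fh.write("\n")

        # --- power stage --------------------------------------------------
        if config.run_power:
            stage = "power"
            conditions = [ErrorCondition(shift_sd=s) for s in config.shift_grid]
            comparison = compare_phase_rulesets(
                study_cfg.phases,
                conditions,
                replicates=config.replicates,
                horizon_runs=config.horizon_runs,
                seed=config.seed,
            )
            comparison.to_csv(target("power_comparison.csv"), index=False)

        # --- manifest -----------------------------------------------------
        stage = "manifest"
        with target("manifest.json").open("w", encoding="utf-8") as fh:
            json.dump(
                {
                    "package": "westgard-qc",
                    "version": __version__,
                    "mode": config.mode,
                    "seed": config.seed,
                    "config_hash": _config_hash(config),
                    "outputs": sorted(p.name for p in written if p.exists()),
                },
                fh,
                indent=2,
            )
            fh.write("\n")
    except QCDataError as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    return {"outdir": outdir, "report": report, "files": [p for p in written if p.exists()]}


def _read_config(path) -> StudyConfig:
    from .io import read_study_config

    return read_study_config(path)


def _study_config_for(syn: SyntheticStudyConfig) -> StudyConfig:
    from .simulate import ANALYTES, default_study_config

    if syn.analytes != ANALYTES:
        raise ConfigError(
            "synthetic pipeline mode supports the default analyte panel; "
            "for custom panels drive the modules directly"
        )
    return default_study_config(syn.runs_per_phase)
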