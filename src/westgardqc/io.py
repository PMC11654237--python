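"""Readers and writers for QC result streams, study configuration and
summary tables.

File formats
------------
QC results
    Comma-delimited UTF-8 text with a mandatory header and columns
    ``run_date, analyte, level, value``.  ``run_date`` may be either an
    integer run ordinal or an ISO calendar date; dates are mapped to dense
    0-based run ordinals at read time (rule windows are defined over
    consecutive runs, not wall time).
Study configuration
    A YAML document with sections ``controls``, ``peer``, ``tea``,
    ``phases`` and optionally ``reporting_levels``.
Summary tables
    CSV with one row per analyte and grouped CV/bias/sigma columns per
    phase (plus a JSON variant for machines).
"""
from __future__ import annotations

import csv
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import yaml

from .errors import ConfigError, FormatError, IntegrityError, RecordError
from .model import (
    ControlSpec,
    MetricsSummary,
    PeerStats,
    PhasePlan,
    QCResult,
    RuleSet,
    TEaSpec,
    check_phase_partition,
    level_sort_key,
)

__all__ = [
    "QCResult",
    "ControlSpec",
    "PeerStats",
    "TEaSpec",
    "PhasePlan",
    "StudyConfig",
    "read_qc_results",
    "write_qc_results",
    "read_study_config",
    "write_study_config",
    "write_summary_table",
    "read_summary_table",
    "write_summary_json",
    "round_cv",
]

QC_COLUMNS = ("run_date", "analyte", "level", "value")


def _parse_run_key(token: str, line_no: int):
    """An integer ordinal, or an ISO date to be ranked into ordinals later."""
    token = token.strip()
    try:
        return int(token)
    except ValueError:
        pass
    try:
        return _dt.date.fromisoformat(token)
    except ValueError:
        raise RecordError(
            f"line {line_no}: run_date {token!r} is neither an integer run "
            "ordinal nor an ISO date"
        ) from None


def read_qc_results(path) -> List[QCResult]:
    """Read a QC-results CSV into a sorted list of :class:`QCResult`.

    Records are returned sorted by (analyte, level, run_index).  Calendar
    dates are converted to dense 0-based run ordinals (rank among the
    distinct dates in the file).  Raises :class:`FormatError` for a missing
    column, :class:`RecordError` for a malformed or non-positive value
    (with its line number) and :class:`IntegrityError` for a duplicate
    (analyte, level, run) triple.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in QC_COLUMNS:
            if col not in header:
                raise FormatError(f"{path.name}: missing required column {col!r}")
        rows = []
        for line_no, row in enumerate(reader, start=2):
            run_key = _parse_run_key(row["run_date"] or "", line_no)
            raw = (row["value"] or "").strip()
            try:
                value = float(raw)
            except ValueError:
                raise RecordError(
                    f"line {line_no}: value {raw!r} is not numeric"
                ) from None
            if not value > 0:
                raise RecordError(
                    f"line {line_no}: control value must be strictly positive, "
                    f"got {value}"
                )
            rows.append(
                (row["analyte"].strip(), row["level"].strip(), run_key, value, line_no)
            )

    dates = sorted({r[2] for r in rows if isinstance(r[2], _dt.date)})
    date_rank = {d: i for i, d in enumerate(dates)}

    seen = {}
    results = []
    for analyte, level, run_key, value, line_no in rows:
        run_index = date_rank[run_key] if isinstance(run_key, _dt.date) else run_key
        key = (analyte, level, run_index)
        if key in seen:
            raise IntegrityError(
                f"line {line_no}: duplicate record for {analyte}/{level} "
                f"run {run_index} (first seen at line {seen[key]})"
            )
        seen[key] = line_no
        results.append(QCResult(analyte, level, run_index, value))
    results.sort(key=lambda r: (r.analyte_id, level_sort_key(r.level_id), r.run_index))
    return results


def write_qc_results(results: Iterable[QCResult], path) -> None:
    """Write QC results as the standard four-column CSV (run ordinals)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(QC_COLUMNS)
        for r in results:
            writer.writerow([r.run_index, r.analyte_id, r.level_id, repr(float(r.value))])


# ---------------------------------------------------------------------------
# Study configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyConfig:
    """Fully cross-referenced study configuration.

    ``reporting_levels`` maps each analyte to the control level at which
    CV/bias/sigma are reported (the level that triggered the rule change);
    both levels are always evaluated by the rule engine.
    """

    controls: Tuple[ControlSpec, ...]
    peer: Tuple[PeerStats, ...]
    tea: Tuple[TEaSpec, ...]
    phases: Tuple[PhasePlan, ...]
    reporting_levels: Dict[str, str] = field(default_factory=dict)

    def control(self, analyte_id: str, level_id: str) -> ControlSpec:
        for c in self.controls:
            if c.analyte_id == analyte_id and c.level_id == level_id:
                return c
        raise ConfigError(f"no ControlSpec for {analyte_id}/{level_id}")

    def controls_by_key(self) -> Dict[Tuple[str, str], ControlSpec]:
        return {(c.analyte_id, c.level_id): c for c in self.controls}

    def peer_by_key(self) -> Dict[Tuple[str, str], PeerStats]:
        return {(p.analyte_id, p.level_id): p for p in self.peer}

    def tea_by_analyte(self) -> Dict[str, TEaSpec]:
        return {t.analyte_id: t for t in self.tea}

    @property
    def analytes(self) -> List[str]:
        seen = []
        for plan in self.phases:
            for a in plan.assignments:
                if a not in seen:
                    seen.append(a)
        return seen

    @property
    def levels(self) -> List[str]:
        out = sorted({c.level_id for c in self.controls}, key=level_sort_key)
        return out


def _as_ruleset(value, defaults: dict) -> RuleSet:
    if isinstance(value, str):
        return RuleSet.from_string(value, **defaults)
    if isinstance(value, (list, tuple)):
        return RuleSet.of(*value, **defaults)
    raise ConfigError(f"cannot parse rule set from {value!r}")


def read_study_config(path) -> StudyConfig:
    """Parse and cross-validate a YAML study configuration file.

    Raises :class:`ConfigError` for overlapping phase run ranges and for
    dangling analyte references (an analyte assigned rules in some phase
    but lacking a ControlSpec at any level used in the study).
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path.name}: top level must be a mapping")
    for section in ("controls", "peer", "tea", "phases"):
        if section not in doc:
            raise ConfigError(f"{path.name}: missing section {section!r}")

    controls = tuple(
        ControlSpec(
            str(row["analyte"]), str(row["level"]),
            float(row["target_mean"]), float(row["target_sd"]),
        )
        for row in doc["controls"]
    )
    peer = tuple(
        PeerStats(str(row["analyte"]), str(row["level"]), float(row["group_mean"]))
        for row in doc["peer"]
    )
    tea = tuple(
        TEaSpec(
            str(row["analyte"]), float(row.get("z_score", 1.65)),
            float(row["imprecision_goal_pct"]), float(row["bias_goal_pct"]),
        )
        for row in doc["tea"]
    )

    flag_defaults = {
        k: bool(doc.get(k, default))
        for k, default in (
            ("cross_level", True), ("cross_run", True), ("r4s_pure_range", False),
        )
    }
    phases = []
    for row in doc["phases"]:
        assignments = {
            str(analyte): _as_ruleset(rules, flag_defaults)
            for analyte, rules in row["rules"].items()
        }
        phases.append(
            PhasePlan(str(row["label"]), assignments, (int(row["start"]), int(row["stop"])))
        )
    phases = tuple(check_phase_partition(phases))

    reporting = {str(k): str(v) for k, v in doc.get("reporting_levels", {}).items()}

    cfg = StudyConfig(controls, peer, tea, phases, reporting)

    # cross-reference checks
    levels = set(cfg.levels)
    have = {(c.analyte_id, c.level_id) for c in controls}
    tea_analytes = {t.analyte_id for t in tea}
    for plan in phases:
        for analyte in plan.assignments:
            for level in levels:
                if (analyte, level) not in have:
                    raise ConfigError(
                        f"phase {plan.phase_label} references analyte "
                        f"{analyte!r} but no ControlSpec exists for level {level}"
                    )
            if analyte not in tea_analytes:
                raise ConfigError(
                    f"phase {plan.phase_label} references analyte {analyte!r} "
                    "with no TEa specification"
                )
    peer_keys = {(p.analyte_id, p.level_id) for p in peer}
    for analyte, level in cfg.reporting_levels.items():
        if (analyte, level) not in peer_keys:
            raise ConfigError(
                f"reporting level {analyte}/{level} has no peer-group mean"
            )
    return cfg


def write_study_config(cfg: StudyConfig, path) -> None:
    """Serialize a StudyConfig back to the YAML layout read_study_config accepts."""
    doc = {
        "controls": [
            {
                "analyte": c.analyte_id, "level": c.level_id,
                "target_mean": c.target_mean, "target_sd": c.target_sd,
            }
            for c in cfg.controls
        ],
        "peer": [
            {"analyte": p.analyte_id, "level": p.level_id, "group_mean": p.group_mean}
            for p in cfg.peer
        ],
        "tea": [
            {
                "analyte": t.analyte_id, "z_score": t.z_score,
                "imprecision_goal_pct": t.imprecision_goal_pct,
                "bias_goal_pct": t.bias_goal_pct,
            }
            for t in cfg.tea
        ],
        "reporting_levels": dict(cfg.reporting_levels),
        "phases": [
            {
                "label": p.phase_label,
                "start": p.run_range[0],
                "stop": p.run_range[1],
                "rules": {a: str(rs) for a, rs in p.assignments.items()},
            }
            for p in cfg.phases
        ],
    }
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Summary tables
# ---------------------------------------------------------------------------


def round_cv(cv_pct: float) -> float:
    """Reporting convention for CV%: 1 decimal when >= 1%, else 2."""
    return round(cv_pct, 1) if cv_pct >= 1.0 else round(cv_pct, 2)


def _phase_order(summaries: Sequence[MetricsSummary]) -> List[str]:
    order = []
    for s in summaries:
        if s.phase_label not in order:
            order.append(s.phase_label)
    return sorted(order)


def write_summary_table(summaries: Sequence[MetricsSummary], path) -> None:
    """Write the per-analyte/per-phase metrics matrix as CSV.

    One row per analyte; per phase three columns ``cv_<P>, bias_<P>,
    sigma_<P>``.  Values are rounded per the reporting convention (CV to 1
    decimal when >= 1% else 2; bias and sigma to 2 decimals).  Raises
    :class:`IntegrityError` on a duplicate (analyte, phase) cell.
    """
    cells: Dict[Tuple[str, str], MetricsSummary] = {}
    analytes: List[str] = []
    for s in summaries:
        key = (s.analyte_id, s.phase_label)
        if key in cells:
            raise IntegrityError(f"duplicate summary for analyte/phase {key}")
        cells[key] = s
        if s.analyte_id not in analytes:
            analytes.append(s.analyte_id)
    phases = _phase_order(summaries)

    header = ["analyte"]
    for p in phases:
        header += [f"cv_{p}", f"bias_{p}", f"sigma_{p}"]
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for analyte in analytes:
            row: List[object] = [analyte]
            for p in phases:
                s = cells.get((analyte, p))
                if s is None:
                    row += ["", "", ""]
                else:
                    row += [round_cv(s.cv_pct), round(s.bias_pct, 2), round(s.sigma, 2)]
            writer.writerow(row)


def read_summary_table(path, level_ids: Dict[str, str] | None = None) -> List[MetricsSummary]:
    """Read a summary CSV written by :func:`write_summary_table`."""
    level_ids = level_ids or {}
    out: List[MetricsSummary] = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        phases = sorted({c.split("_", 1)[1] for c in header if c.startswith("cv_")})
        for row in reader:
            analyte = row["analyte"]
            for p in phases:
                if row[f"cv_{p}"] == "":
                    continue
                out.append(
                    MetricsSummary(
                        analyte_id=analyte,
                        level_id=level_ids.get(analyte, "?"),
                        phase_label=p,
                        cv_pct=float(row[f"cv_{p}"]),
                        bias_pct=float(row[f"bias_{p}"]),
                        sigma=float(row[f"sigma_{p}"]),
                    )
                )
    return out


def write_summary_json(summaries: Sequence[MetricsSummary], path) -> None:
    """Machine-readable variant of the summary table (unrounded values)."""
    doc = [
        {
            "analyte": s.analyte_id,
            "level": s.level_id,
            "phase": s.phase_label,
            "n": s.n,
            "cv_pct": s.cv_pct,
            "bias_pct": s.bias_pct,
            "sigma": s.sigma,
        }
        for s in summaries
    ]
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")
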