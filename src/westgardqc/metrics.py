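"""Analytical-performance statistics: CV%, bias%, TEa and the sigma metric.

Definitions (all on the percent scale):

* ``CV% = 100 * SD / mean`` with the sample SD (n-1 denominator);
* ``bias% = 100 * (lab_mean - group_mean) / group_mean``, signed, against
  the peer-group mean of laboratories running the same method;
* ``TEa% = z * imprecision_goal% + bias_goal%`` (total allowable error);
* ``sigma = (TEa% - |bias%|) / CV%`` — error budget per unit imprecision.

The sigma metric uses the magnitude of bias by default so that bias of
either sign consumes error budget; the signed variant is available via
``signed_bias=True``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

from .errors import (
    ContractError,
    CoverageError,
    DomainError,
    InsufficientDataError,
)
from .io import StudyConfig
from .model import MetricsSummary, PeerStats, PhasePlan, QCResult, TEaSpec

__all__ = [
    "MetricsSummary",
    "StudyReport",
    "compute_cv",
    "compute_bias",
    "compute_tea",
    "compute_sigma",
    "phase_summary",
    "mean_across_analytes",
    "count_improved",
    "build_report",
    "METRICS",
]

METRICS = ("cv", "bias", "sigma")

_ROUND = {"cv": 1, "bias": 2, "sigma": 2}


def compute_cv(values: Sequence[float]) -> float:
    """Coefficient of variation in percent, sample SD over mean."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise InsufficientDataError(f"CV needs >= 2 values, got {arr.size}")
    mean = arr.mean()
    if mean <= 0:
        raise DomainError(f"CV undefined for non-positive mean {mean}")
    return float(100.0 * arr.std(ddof=1) / mean)


def compute_bias(lab_mean: float, group_mean: float) -> float:
    """Signed percent deviation of the laboratory mean from the peer mean."""
    if group_mean <= 0:
        raise DomainError(f"group_mean must be > 0, got {group_mean}")
    return float(100.0 * (lab_mean - group_mean) / group_mean)


def compute_tea(spec: TEaSpec) -> float:
    """Total allowable error in percent from its imprecision and bias goals."""
    return spec.z_score * spec.imprecision_goal_pct + spec.bias_goal_pct


def compute_sigma(
    tea_pct: float, bias_pct: float, cv_pct: float, *, signed_bias: bool = False
) -> float:
    """Sigma metric on the percent scale: (TEa - |bias|) / CV."""
    if cv_pct <= 0:
        raise DomainError(f"sigma undefined for CV {cv_pct}")
    bias = bias_pct if signed_bias else abs(bias_pct)
    return float((tea_pct - bias) / cv_pct)


def _phase_values(
    results: Sequence[QCResult],
    plan: PhasePlan,
    analyte: str,
    level: str,
    *,
    cumulative: bool,
) -> List[float]:
    lo = 0 if cumulative else plan.run_range[0]
    hi = plan.run_range[1]
    return [
        r.value
        for r in results
        if r.analyte_id == analyte and r.level_id == level and lo <= r.run_index < hi
    ]


def phase_summary(
    dataset: Iterable[QCResult],
    plans: Sequence[PhasePlan],
    peer: Iterable[PeerStats] | Mapping[Tuple[str, str], PeerStats],
    tea: Iterable[TEaSpec] | Mapping[str, TEaSpec],
    reporting_levels: Mapping[str, str],
    *,
    cumulative: bool = False,
    signed_bias: bool = False,
) -> List[MetricsSummary]:
    """One CV/bias/sigma summary per analyte per phase at the reporting level.

    ``reporting_levels`` selects, per analyte, the control level the
    summary is computed at.  With ``cumulative=True`` each phase summarises
    all results from the study start to the phase end instead of the
    phase's own window.
    """
    results = list(dataset)
    peer_map = (
        dict(peer)
        if isinstance(peer, Mapping)
        else {(p.analyte_id, p.level_id): p for p in peer}
    )
    tea_map = dict(tea) if isinstance(tea, Mapping) else {t.analyte_id: t for t in tea}

    out: List[MetricsSummary] = []
    for plan in sorted(plans, key=lambda p: p.run_range[0]):
        for analyte, level in reporting_levels.items():
            values = _phase_values(results, plan, analyte, level, cumulative=cumulative)
            if len(values) < 2:
                raise InsufficientDataError(
                    f"phase {plan.phase_label}: {analyte}/{level} has "
                    f"{len(values)} results (>= 2 required)"
                )
            cv = compute_cv(values)
            try:
                group_mean = peer_map[(analyte, level)].group_mean
            except KeyError:
                raise CoverageError(f"no peer-group mean for {analyte}/{level}") from None
            bias = compute_bias(float(np.mean(values)), group_mean)
            try:
                tea_pct = compute_tea(tea_map[analyte])
            except KeyError:
                raise CoverageError(f"no TEa specification for {analyte}") from None
            sigma = compute_sigma(tea_pct, bias, cv, signed_bias=signed_bias)
            out.append(
                MetricsSummary(analyte, level, plan.phase_label, cv, bias, sigma, len(values))
            )
    return out


def _metric_value(s: MetricsSummary, metric: str) -> float:
    if metric == "cv":
        return s.cv_pct
    if metric == "bias":
        return s.bias_pct
    if metric == "sigma":
        return s.sigma
    raise ContractError(f"unknown metric {metric!r}; expected one of {METRICS}")


def mean_across_analytes(
    summaries: Sequence[MetricsSummary],
    phase_label: str,
    metric: str,
    *,
    rounded: bool = True,
) -> float:
    """Arithmetic mean of one metric over all analytes in a phase.

    The mean is taken over unrounded per-analyte values and then rounded
    to the reporting precision (CV to 1 decimal, bias and sigma to 2);
    pass ``rounded=False`` for the raw mean.  Raises
    :class:`CoverageError` when an analyte present elsewhere in the report
    is missing from the phase.
    """
    expected = {s.analyte_id for s in summaries}
    got = {s.analyte_id: _metric_value(s, metric) for s in summaries if s.phase_label == phase_label}
    missing = expected - set(got)
    if missing:
        raise CoverageError(
            f"phase {phase_label}: no summary for analyte(s) {sorted(missing)}"
        )
    if not got:
        raise CoverageError(f"no summaries for phase {phase_label!r}")
    value = float(np.mean(list(got.values())))
    return round(value, _ROUND[metric]) if rounded else value


def count_improved(
    summaries: Sequence[MetricsSummary],
    metric: str,
    from_phase: str,
    to_phase: str,
) -> int:
    """Number of analytes whose metric strictly improved between phases.

    Improvement means lower CV, lower |bias|, or higher sigma; ties do not
    count.
    """
    if metric not in METRICS:
        raise ContractError(f"unknown metric {metric!r}; expected one of {METRICS}")
    a = {s.analyte_id: s for s in summaries if s.phase_label == from_phase}
    b = {s.analyte_id: s for s in summaries if s.phase_label == to_phase}
    if set(a) != set(b) or not a:
        raise CoverageError(
            f"phases {from_phase!r} and {to_phase!r} do not cover the same analytes"
        )
    count = 0
    for analyte, before in a.items():
        after = b[analyte]
        if metric == "cv":
            count += bool(after.cv_pct < before.cv_pct)
        elif metric == "bias":
            count += bool(abs(after.bias_pct) < abs(before.bias_pct))
        else:
            count += bool(after.sigma > before.sigma)
    return count


@dataclass(frozen=True)
class StudyReport:
    """Per-analyte/per-phase metrics plus the cross-analyte roll-ups."""

    summaries: Tuple[MetricsSummary, ...]
    phase_means: Dict[str, Dict[str, float]]  # phase -> metric -> rounded mean
    improvements: Dict[str, int]  # metric -> analytes improved first->last phase
    first_phase: str
    last_phase: str

    @property
    def phases(self) -> List[str]:
        seen: List[str] = []
        for s in self.summaries:
            if s.phase_label not in seen:
                seen.append(s.phase_label)
        return sorted(seen)

    @property
    def analytes(self) -> List[str]:
        seen: List[str] = []
        for s in self.summaries:
            if s.analyte_id not in seen:
                seen.append(s.analyte_id)
        return seen


def build_report(summaries: Sequence[MetricsSummary]) -> StudyReport:
    """Roll a summary matrix up into phase means and improvement counts.

    Improvement counts compare the first phase (alphabetically, i.e. the
    pre-intervention baseline) with the last.
    """
    phases = sorted({s.phase_label for s in summaries})
    if not phases:
        raise InsufficientDataError("no summaries to report")
    first, last = phases[0], phases[-1]
    means = {
        p: {m: mean_across_analytes(summaries, p, m) for m in METRICS} for p in phases
    }
    improvements = {m: count_improved(summaries, m, first, last) for m in METRICS}
    return StudyReport(tuple(summaries), means, improvements, first, last)


def summaries_from_config(
    dataset: Iterable[QCResult], config: StudyConfig, **kwargs
) -> List[MetricsSummary]:
    """Convenience wrapper: phase_summary driven by a StudyConfig."""
    return phase_summary(
        dataset,
        config.phases,
        config.peer_by_key(),
        config.tea_by_analyte(),
        config.reporting_levels,
        **kwargs,
    )
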