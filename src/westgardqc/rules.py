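"""Westgard multirule evaluation over streams of control results.

Control results are normalised to z-scores, ``z = (value - target_mean) /
target_sd``, and rules are predicates over the trailing window of z-scores:

* ``1_3s`` — any single result beyond +-3 SD (rejection, not warning);
* ``1_2s`` — any single result beyond +-2 SD (warning only);
* ``R_4s`` — within one run, the two levels straddle the mean with a spread
  of at least 4 SD (one beyond +2 SD, the other beyond -2 SD) — sensitive
  to random error;
* counting rules (``2_2s``, ``2/3_2s``, ``3_1s``, ``4_1s``, ``8_x``,
  ``10_x``, ``12_x``) — k consecutive results beyond a threshold on the
  same side of the mean (threshold 2 SD, 1 SD or the mean itself) —
  sensitive to systematic error.  ``2/3_2s`` requires at least 2 of the
  last 3 beyond 2 SD on the same side.

Thresholds are strict inequalities (a result exactly on a limit does not
trigger), matching conventional Levey-Jennings practice.

Counting windows by default pool both control levels (interleaved by run,
then level) and span consecutive runs; both behaviours are flags on
:class:`~westgardqc.model.RuleSet`.  After a rejected run all counting
windows restart empty, modelling corrective action; windows likewise reset
at phase boundaries, where the rule set in force changes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigError, ContractError, CoverageError
from .model import (
    ControlSpec,
    PhasePlan,
    QCResult,
    RuleId,
    RuleSet,
    check_phase_partition,
    level_sort_key,
)

__all__ = [
    "ZScoredResult",
    "Violation",
    "RunDecision",
    "zscore",
    "check_1_3s",
    "check_R_4s",
    "check_counting_rule",
    "evaluate_run",
    "apply_plan",
    "reject_stream",
    "COUNTING_RULES",
    "counting_side",
]

# rule -> (window length k, z threshold, minimum same-side exceedances)
COUNTING_RULES: Dict[RuleId, Tuple[int, float, int]] = {
    RuleId.R2_2S: (2, 2.0, 2),
    RuleId.R2OF3_2S: (3, 2.0, 2),
    RuleId.R3_1S: (3, 1.0, 3),
    RuleId.R4_1S: (4, 1.0, 4),
    RuleId.R8X: (8, 0.0, 8),
    RuleId.R10X: (10, 0.0, 10),
    RuleId.R12X: (12, 0.0, 12),
}

_MAX_WINDOW = max(k for k, _, _ in COUNTING_RULES.values())


@dataclass(frozen=True)
class ZScoredResult:
    """A control result together with its z-score in SD multiples."""

    analyte_id: str
    level_id: str
    run_index: int
    value: float
    z: float


@dataclass(frozen=True)
class Violation:
    """One rule violation attributed to the results that produced it."""

    rule: RuleId
    run_index: int
    analyte_id: str
    contributing: Tuple[Tuple[str, int, float], ...]  # (level, run, z)
    side: str  # "above" | "below" | "range"


@dataclass(frozen=True)
class RunDecision:
    """Accept/reject verdict for one analytical run."""

    run_index: int
    status: str  # "accept" | "reject"
    violations: Tuple[Violation, ...] = ()
    warnings: Tuple[Violation, ...] = ()
    phase_label: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.status == "reject") != bool(self.violations):
            raise ContractError("status must be 'reject' iff violations is non-empty")


def zscore(result: QCResult, spec: ControlSpec) -> ZScoredResult:
    """Normalise one control result against its target mean and SD."""
    if (result.analyte_id, result.level_id) != (spec.analyte_id, spec.level_id):
        raise ContractError(
            f"spec {spec.analyte_id}/{spec.level_id} does not match result "
            f"{result.analyte_id}/{result.level_id}"
        )
    z = (result.value - spec.target_mean) / spec.target_sd
    return ZScoredResult(result.analyte_id, result.level_id, result.run_index, result.value, z)


def _contrib(results: Sequence[ZScoredResult]) -> Tuple[Tuple[str, int, float], ...]:
    return tuple((r.level_id, r.run_index, r.z) for r in results)


def check_1_3s(current: Sequence[ZScoredResult]) -> Optional[Violation]:
    """Reject if any result in the run lies beyond +-3 SD (strict)."""
    for r in current:
        if abs(r.z) > 3.0:
            return Violation(
                RuleId.R1_3S, r.run_index, r.analyte_id, _contrib([r]),
                "above" if r.z > 0 else "below",
            )
    return None


def _check_1_2s(current: Sequence[ZScoredResult]) -> Optional[Violation]:
    for r in current:
        if abs(r.z) > 2.0:
            return Violation(
                RuleId.W1_2S, r.run_index, r.analyte_id, _contrib([r]),
                "above" if r.z > 0 else "below",
            )
    return None


def check_R_4s(current: Sequence[ZScoredResult], *, pure_range: bool = False) -> Optional[Violation]:
    """Within-run range rule across control levels.

    Classic form: the spread between levels is at least 4 SD *and* the
    extremes reach the 2 SD limits on opposite sides (one at or beyond
    +2 SD, the other at or beyond -2 SD; "at least 4 SD" reads the limits
    inclusively, so {+2.1, -2.0} triggers).  With ``pure_range=True`` any
    spread >= 4 SD triggers.  A single-level run is not evaluable and
    yields ``None``.
    """
    if len(current) < 2:
        return None
    hi = max(current, key=lambda r: r.z)
    lo = min(current, key=lambda r: r.z)
    spread = hi.z - lo.z
    if pure_range:
        triggered = spread >= 4.0
    else:
        triggered = spread >= 4.0 and hi.z >= 2.0 and lo.z <= -2.0
    if triggered:
        return Violation(
            RuleId.RR_4S, hi.run_index, hi.analyte_id, _contrib([hi, lo]), "range"
        )
    return None


def counting_side(zs: Sequence[float], threshold: float, min_hits: int) -> int:
    """Side on which a counting-rule window triggers: +1, -1 or 0 (none).

    A window triggers on side s when at least ``min_hits`` of its values
    satisfy ``s * z > threshold`` (strict).
    """
    above = sum(1 for z in zs if z > threshold)
    if above >= min_hits:
        return 1
    below = sum(1 for z in zs if -z > threshold)
    if below >= min_hits:
        return -1
    return 0


def check_counting_rule(rule: RuleId, window: Sequence[ZScoredResult]) -> Optional[Violation]:
    """Evaluate a counting rule on the trailing window of an ordered sequence.

    Returns ``None`` when the sequence is shorter than the rule's window
    length (rule not evaluable).
    """
    try:
        k, threshold, min_hits = COUNTING_RULES[rule]
    except KeyError:
        raise ContractError(f"{rule} is not a counting rule") from None
    if len(window) < k:
        return None
    tail = window[-k:]
    side = counting_side([r.z for r in tail], threshold, min_hits)
    if side == 0:
        return None
    last = tail[-1]
    return Violation(
        rule, last.run_index, last.analyte_id, _contrib(tail),
        "above" if side > 0 else "below",
    )


def _ordered(results: Iterable[ZScoredResult]) -> List[ZScoredResult]:
    return sorted(results, key=lambda r: (r.run_index, level_sort_key(r.level_id)))


def evaluate_run(
    history: Sequence[ZScoredResult],
    current: Sequence[ZScoredResult],
    ruleset: RuleSet,
    *,
    phase_label: Optional[str] = None,
) -> RunDecision:
    """Apply a rule set to one run given its (post-reset) history.

    ``history`` holds the z-scored results of prior runs since the last
    counting-window reset, ``current`` the results of the run under
    decision (one per control level).  Rules are evaluated independently;
    at most one violation per rule is reported, attributed to the earliest
    triggering window within the run.
    """
    current = _ordered(current)
    if not current:
        raise ContractError("current run is empty")
    run_index = current[0].run_index
    if any(r.run_index != run_index for r in current):
        raise ContractError("current must contain results of a single run")
    if any(r.run_index >= run_index for r in history):
        raise ContractError("history must end strictly before the current run")

    violations: List[Violation] = []
    warnings: List[Violation] = []

    if RuleId.R1_3S in ruleset:
        v = check_1_3s(current)
        if v:
            violations.append(v)
    if RuleId.W1_2S in ruleset:
        w = _check_1_2s(current)
        if w:
            warnings.append(w)
    if RuleId.RR_4S in ruleset:
        v = check_R_4s(current, pure_range=ruleset.r4s_pure_range)
        if v:
            violations.append(v)

    counting = [r for r in ruleset.rules if r in COUNTING_RULES]
    if counting:
        history = _ordered(history)
        # build the sequences counting windows run over
        if ruleset.cross_level:
            seqs = [(history if ruleset.cross_run else []) + current]
            n_new = [len(current)]
        else:
            seqs, n_new = [], []
            for cur in current:
                prior = [h for h in history if h.level_id == cur.level_id]
                seqs.append((prior if ruleset.cross_run else []) + [cur])
                n_new.append(1)
        for rule in counting:
            k = COUNTING_RULES[rule][0]
            found = None
            for seq, fresh in zip(seqs, n_new):
                # windows ending at each result of the current run, in order
                for end in range(len(seq) - fresh + 1, len(seq) + 1):
                    if end < k:
                        continue
                    found = check_counting_rule(rule, seq[:end])
                    if found:
                        break
                if found:
                    break
            if found:
                violations.append(found)

    status = "reject" if violations else "accept"
    return RunDecision(run_index, status, tuple(violations), tuple(warnings), phase_label)


def apply_plan(
    dataset: Iterable[QCResult],
    plans: Sequence[PhasePlan],
    specs: Iterable[ControlSpec] | Mapping[Tuple[str, str], ControlSpec],
    *,
    reset_on_reject: bool = True,
) -> Dict[str, List[RunDecision]]:
    """Evaluate a whole study: each run under the rule set of its phase.

    Returns per-analyte run decisions in run order, each annotated with its
    phase label.  Counting windows reset at phase boundaries (the rule
    semantics change there) and, by default, after every rejected run.
    Raises :class:`CoverageError` for a run outside every phase and
    :class:`ContractError` for a result without a matching ControlSpec.
    """
    plans = check_phase_partition(list(plans))
    if isinstance(specs, Mapping):
        spec_map = dict(specs)
    else:
        spec_map = {(s.analyte_id, s.level_id): s for s in specs}

    by_analyte: Dict[str, List[QCResult]] = {}
    for r in dataset:
        by_analyte.setdefault(r.analyte_id, []).append(r)

    def phase_of(run_index: int) -> PhasePlan:
        for p in plans:
            if p.covers(run_index):
                return p
        raise CoverageError(f"run {run_index} is outside every phase")

    out: Dict[str, List[RunDecision]] = {}
    for analyte, results in by_analyte.items():
        scored: Dict[int, List[ZScoredResult]] = {}
        for r in results:
            spec = spec_map.get((r.analyte_id, r.level_id))
            if spec is None:
                raise ContractError(f"no ControlSpec for {r.analyte_id}/{r.level_id}")
            scored.setdefault(r.run_index, []).append(zscore(r, spec))

        decisions: List[RunDecision] = []
        history: List[ZScoredResult] = []
        last_phase: Optional[str] = None
        for run_index in sorted(scored):
            plan = phase_of(run_index)
            if analyte not in plan.assignments:
                raise ConfigError(
                    f"phase {plan.phase_label} has no rule assignment for {analyte!r}"
                )
            if plan.phase_label != last_phase:
                history = []
                last_phase = plan.phase_label
            current = _ordered(scored[run_index])
            decision = evaluate_run(
                history, current, plan.assignments[analyte], phase_label=plan.phase_label
            )
            decisions.append(decision)
            if decision.status == "reject" and reset_on_reject:
                history = []
            else:
                history.extend(current)
                history = history[-(4 * _MAX_WINDOW):]
        out[analyte] = decisions
    return out


# ---------------------------------------------------------------------------
# Fast path over raw z arrays (used by the Monte-Carlo power module)
# ---------------------------------------------------------------------------


def reject_stream(
    z: np.ndarray,
    ruleset: RuleSet,
    *,
    reset_on_reject: bool = True,
    stop_at_first: bool = False,
) -> np.ndarray:
    """Accept/reject mask for a stream of z-scores, shape (n_runs, n_levels).

    Semantically identical to feeding the stream through
    :func:`evaluate_run` run by run (same window pooling, same resets) but
    operating on bare floats; this is the hot loop of the power simulator.
    With ``stop_at_first`` the scan stops after the first rejected run
    (later entries of the mask stay False).
    """
    zs = np.atleast_2d(np.asarray(z, dtype=float))
    n_runs, n_levels = zs.shape
    rows = zs.tolist()

    has_13s = RuleId.R1_3S in ruleset
    has_r4s = RuleId.RR_4S in ruleset and n_levels >= 2
    pure_range = ruleset.r4s_pure_range
    counting = [COUNTING_RULES[r] for r in ruleset.rules if r in COUNTING_RULES]
    n_buffers = 1 if ruleset.cross_level else n_levels
    buffers: List[List[float]] = [[] for _ in range(n_buffers)]

    rejected = np.zeros(n_runs, dtype=bool)
    for i in range(n_runs):
        row = rows[i]
        reject = False
        if has_13s:
            for v in row:
                if v > 3.0 or v < -3.0:
                    reject = True
                    break
        if not reject and has_r4s:
            hi, lo = max(row), min(row)
            if pure_range:
                reject = hi - lo >= 4.0
            else:
                reject = hi - lo >= 4.0 and hi >= 2.0 and lo <= -2.0

        if counting:
            if not ruleset.cross_run:
                for b in buffers:
                    b.clear()
            if ruleset.cross_level:
                buffers[0].extend(row)
                fresh = [n_levels]
            else:
                for j, v in enumerate(row):
                    buffers[j].append(v)
                fresh = [1] * n_levels
            if not reject:
                for k, thr, min_hits in counting:
                    for buf, n_new in zip(buffers, fresh):
                        m = len(buf)
                        for end in range(max(k, m - n_new + 1), m + 1):
                            if counting_side(buf[end - k:end], thr, min_hits):
                                reject = True
                                break
                        if reject:
                            break
                    if reject:
                        break
            if reject and reset_on_reject:
                for b in buffers:
                    b.clear()
            else:
                for j, b in enumerate(buffers):
                    if len(b) > 4 * _MAX_WINDOW:
                        buffers[j] = b[-(2 * _MAX_WINDOW):]

        if reject:
            rejected[i] = True
            if stop_at_first:
                break
    return rejected
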