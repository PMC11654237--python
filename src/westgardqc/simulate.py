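"""Seeded synthetic IQC studies with the structure of a two-month,
five-analyte nephelometric monitoring study.

The generator emulates five serum-protein analytes (IgA, alpha-1
antitrypsin, prealbumin, lipoprotein(a), ceruloplasmin) measured once
daily at two control levels under a Gaussian in-control model, split into
four study phases (A-D) each governed by its own Westgard rule set.
Optional injected effects: a systematic shift of the true mean (in SD
multiples), multiplicative imprecision inflation, and a reagent-lot change
modelled as a step change in the true mean only.

The peer group is modelled as a scalar: ``group_mean = target_mean *
(1 + peer_offset_frac)``; no individual peer laboratories are simulated.

All control-material targets, TEa goals and peer offsets bundled here are
synthetic (chosen to be plausible for adult serum proteins in g/L); no
real control-lot values are shipped.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigError, ContractError
from .io import StudyConfig
from .model import (
    ControlSpec,
    ErrorCondition,
    PeerStats,
    PhasePlan,
    QCResult,
    RuleSet,
    TEaSpec,
    level_sort_key,
)

__all__ = [
    "SyntheticAnalyte",
    "SyntheticStudyConfig",
    "TruthRecord",
    "ANALYTES",
    "PHASE_LABELS",
    "default_config",
    "default_study_config",
    "generate_study",
    "inject_condition",
    "table1_fixture",
]

PHASE_LABELS = ("A", "B", "C", "D")


@dataclass(frozen=True)
class SyntheticAnalyte:
    """True control-material parameters for one analyte.

    ``levels`` maps a control level to its (true mean, true SD) in g/L;
    ``peer_offset_frac`` places the peer-group mean at
    ``mean * (1 + peer_offset_frac)``.
    """

    analyte_id: str
    levels: Mapping[str, Tuple[float, float]]
    peer_offset_frac: float = 0.0
    tea: Optional[TEaSpec] = None

    def control_specs(self) -> List[ControlSpec]:
        return [
            ControlSpec(self.analyte_id, lvl, mean, sd)
            for lvl, (mean, sd) in sorted(self.levels.items(), key=lambda kv: level_sort_key(kv[0]))
        ]

    def peer_stats(self) -> List[PeerStats]:
        return [
            PeerStats(self.analyte_id, lvl, mean * (1.0 + self.peer_offset_frac))
            for lvl, (mean, _sd) in sorted(self.levels.items(), key=lambda kv: level_sort_key(kv[0]))
        ]


# Synthetic defaults: plausible adult-range serum concentrations (g/L);
# SDs give phase-baseline CVs in the few-percent range with Lp(a) the most
# imprecise, peer offsets give sub-3% baseline biases.  TEa goals use a
# z-score of 1.65 on imprecision plus a fixed bias budget.
ANALYTES: Tuple[SyntheticAnalyte, ...] = (
    SyntheticAnalyte(
        "IgA", {"L1": (1.10, 0.033), "L3": (4.10, 0.119)}, -0.0007,
        TEaSpec("IgA", 1.65, 7.07, 3.0),
    ),
    SyntheticAnalyte(
        "AAT", {"L1": (0.85, 0.041), "L3": (2.40, 0.122)}, -0.0063,
        TEaSpec("AAT", 1.65, 8.11, 3.0),
    ),
    SyntheticAnalyte(
        "Prealbumin", {"L1": (0.18, 0.0077), "L3": (0.45, 0.019)}, -0.0168,
        TEaSpec("Prealbumin", 1.65, 8.65, 3.0),
    ),
    SyntheticAnalyte(
        "Lp(a)", {"L1": (0.30, 0.015), "L3": (0.90, 0.046)}, -0.0224,
        TEaSpec("Lp(a)", 1.65, 11.27, 3.0),
    ),
    SyntheticAnalyte(
        "Cp", {"L1": (0.20, 0.0076), "L3": (0.55, 0.0198)}, -0.0169,
        TEaSpec("Cp", 1.65, 6.10, 3.0),
    ),
)

# Control level whose performance triggered the rule change, per analyte;
# metrics are reported at this level.
REPORTING_LEVELS: Dict[str, str] = {
    "IgA": "L3",
    "AAT": "L3",
    "Prealbumin": "L1",
    "Lp(a)": "L1",
    "Cp": "L3",
}

# Rule sets in force per phase: A is the long-standing default multirule
# configuration; B-D are the advisor-suggested replacements adopted at the
# two intervention points and at study end.
_PHASE_RULES: Dict[str, Dict[str, str]] = {
    "A": {a.analyte_id: "1_3s/R_4s/2_2s" for a in ANALYTES},
    "B": {
        "IgA": "1_3s/2_2s",
        "AAT": "1_3s/2_2s/R_4s/4_1s/10_x",
        "Prealbumin": "1_3s/2_2s/R_4s/4_1s/10_x",
        "Lp(a)": "1_3s/2_2s/R_4s/4_1s/10_x",
        "Cp": "1_3s/2_2s/R_4s/4_1s/10_x",
    },
    "C": {
        "IgA": "1_3s/2_2s/R_4s/4_1s",
        "AAT": "1_3s/2_2s/R_4s/4_1s/10_x",
        "Prealbumin": "1_3s/2_2s/R_4s/4_1s/8_x",
        "Lp(a)": "1_3s/2_2s/R_4s/4_1s",
        "Cp": "1_3s/2_2s/R_4s/4_1s/8_x",
    },
    "D": {
        "IgA": "1_3s",
        "AAT": "1_3s/2/3_2s/R_4s/3_1s/12_x",
        "Prealbumin": "1_3s/2_2s/R_4s/4_1s/8_x",
        "Lp(a)": "1_3s/2_2s/R_4s/4_1s/10_x",
        "Cp": "1_3s/2/3_2s/R_4s/3_1s/12_x",
    },
}


def table1_fixture(runs_per_phase: int = 22, **ruleset_flags: bool) -> List[PhasePlan]:
    """The four-phase rule-assignment matrix of the monitored study.

    Phases A-D cover equal consecutive blocks of ``runs_per_phase`` daily
    runs (default 22, roughly one month of working days each).
    """
    plans = []
    for i, label in enumerate(PHASE_LABELS):
        assignments = {
            analyte: RuleSet.from_string(text, **ruleset_flags)
            for analyte, text in _PHASE_RULES[label].items()
        }
        start = i * runs_per_phase
        plans.append(PhasePlan(label, assignments, (start, start + runs_per_phase)))
    return plans


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one (analyte, level, phase) cell of a synthetic study.

    ``true_mean``/``true_sd`` are run-weighted in case an injected effect
    or lot change starts mid-phase; ``true_bias_pct`` is the bias of the
    true phase mean against the simulated peer-group mean.
    """

    analyte_id: str
    level_id: str
    phase_label: str
    true_mean: float
    true_sd: float
    true_bias_pct: float
    condition: Optional[ErrorCondition] = None


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Parameters of one synthetic study realisation.

    ``conditions`` maps a phase label to an :class:`ErrorCondition`
    injected during that phase (effective from ``max(phase start,
    onset_run)``); ``lot_change`` is an optional ``(run_index,
    offset_in_sd)`` step change of every true mean from that run on.
    """

    analytes: Tuple[SyntheticAnalyte, ...] = ANALYTES
    runs_per_phase: int = 22
    conditions: Mapping[str, ErrorCondition] = field(default_factory=dict)
    lot_change: Optional[Tuple[int, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.runs_per_phase < 2:
            raise ConfigError("runs_per_phase must be >= 2")
        for label in self.conditions:
            if label not in PHASE_LABELS:
                raise ConfigError(f"unknown phase label {label!r} in conditions")

    @property
    def n_runs(self) -> int:
        return self.runs_per_phase * len(PHASE_LABELS)

    def phase_of(self, run_index: int) -> str:
        return PHASE_LABELS[run_index // self.runs_per_phase]


def default_config(seed: int = 0, **overrides) -> SyntheticStudyConfig:
    """The default study conditions: 5 analytes, 2 levels, 4 x 22 daily runs."""
    return SyntheticStudyConfig(seed=seed, **overrides)


def default_study_config(runs_per_phase: int = 22) -> StudyConfig:
    """StudyConfig (controls/peer/TEa/phases) matching the synthetic defaults."""
    controls: List[ControlSpec] = []
    peer: List[PeerStats] = []
    tea: List[TEaSpec] = []
    for a in ANALYTES:
        controls.extend(a.control_specs())
        peer.extend(a.peer_stats())
        assert a.tea is not None
        tea.append(a.tea)
    return StudyConfig(
        tuple(controls),
        tuple(peer),
        tuple(tea),
        tuple(table1_fixture(runs_per_phase)),
        dict(REPORTING_LEVELS),
    )


def _effects_for_run(
    config: SyntheticStudyConfig, run_index: int
) -> Tuple[float, float, Optional[ErrorCondition]]:
    """(shift in SD, re_factor, active condition) for one run."""
    shift = 0.0
    re = 1.0
    label = config.phase_of(run_index)
    cond = config.conditions.get(label)
    active = None
    if cond is not None and run_index >= cond.onset_run:
        shift += cond.shift_sd
        re *= cond.re_factor
        active = cond
    if config.lot_change is not None and run_index >= config.lot_change[0]:
        shift += config.lot_change[1]
    return shift, re, active


def generate_study(
    config: SyntheticStudyConfig,
) -> Tuple[List[QCResult], List[PeerStats], List[TruthRecord]]:
    """Draw one synthetic study: results, peer means and ground truth.

    Values are drawn per (analyte, level, run) as
    ``N(mean + shift_sd * sd, (sd * re_factor)^2)`` with the shift and
    inflation of whichever condition (and lot change) is active at that
    run.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n_runs = config.n_runs
    effects = [_effects_for_run(config, run) for run in range(n_runs)]

    results: List[QCResult] = []
    truths: List[TruthRecord] = []
    peer: List[PeerStats] = []
    for analyte in config.analytes:
        peer.extend(analyte.peer_stats())
        group = {p.level_id: p.group_mean for p in analyte.peer_stats()}
        for level, (mean, sd) in sorted(
            analyte.levels.items(), key=lambda kv: level_sort_key(kv[0])
        ):
            noise = rng.standard_normal(n_runs)
            for run in range(n_runs):
                shift, re, _cond = effects[run]
                value = float(mean + shift * sd + sd * re * noise[run])
                results.append(QCResult(analyte.analyte_id, level, run, value))
            # ground truth per phase, run-weighted
            for i, label in enumerate(PHASE_LABELS):
                runs = range(
                    i * config.runs_per_phase, (i + 1) * config.runs_per_phase
                )
                means = [mean + effects[r][0] * sd for r in runs]
                sds = [sd * effects[r][1] for r in runs]
                true_mean = float(np.mean(means))
                true_sd = float(np.sqrt(np.mean(np.square(sds))))
                truths.append(
                    TruthRecord(
                        analyte.analyte_id,
                        level,
                        label,
                        true_mean,
                        true_sd,
                        100.0 * (true_mean - group[level]) / group[level],
                        config.conditions.get(label),
                    )
                )
    results.sort(key=lambda r: (r.analyte_id, level_sort_key(r.level_id), r.run_index))
    return results, peer, truths


def inject_condition(
    stream: Iterable[QCResult],
    analyte_id: str,
    level_ids: Sequence[str],
    condition: ErrorCondition,
    specs: Iterable[ControlSpec] | Mapping[Tuple[str, str], ControlSpec],
) -> List[QCResult]:
    """Apply an error condition to part of an existing stream.

    From ``condition.onset_run`` on, matching records get
    ``value -> mean + (value - mean) * re_factor + shift_sd * sd`` (i.e.
    deviations scaled, then the mean shifted); all other records are
    returned unchanged (identical objects).
    """
    if isinstance(specs, Mapping):
        spec_map = dict(specs)
    else:
        spec_map = {(s.analyte_id, s.level_id): s for s in specs}
    targets = set(level_ids)
    known = {lvl for a, lvl in spec_map if a == analyte_id}
    if not known:
        raise ContractError(f"no ControlSpec for analyte {analyte_id!r}")
    missing = targets - known
    if missing:
        raise ContractError(
            f"no ControlSpec for {analyte_id!r} level(s) {sorted(missing)}"
        )

    out: List[QCResult] = []
    for r in stream:
        if (
            r.analyte_id == analyte_id
            and r.level_id in targets
            and r.run_index >= condition.onset_run
            and not condition.is_null
        ):
            spec = spec_map[(r.analyte_id, r.level_id)]
            value = (
                spec.target_mean
                + (r.value - spec.target_mean) * condition.re_factor
                + condition.shift_sd * spec.target_sd
            )
            out.append(replace(r, value=value))
        else:
            out.append(r)
    return out
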