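"""Core domain types shared across the package.

The vocabulary is that of internal quality control (IQC) in clinical
chemistry: a *control material* with a known target mean and SD is measured
once per analytical run (here, one run per day at two concentration levels),
results are expressed as z-scores in SD multiples, and Westgard multirules
decide whether each run is accepted or rejected.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Tuple

from .errors import ConfigError, ContractError


class RuleId(enum.Enum):
    """Westgard multirule identifiers.

    The value of each member is the conventional rule name as printed on
    Levey-Jennings software (``1_3s``, ``2_2s``, ``R_4s``, ...).  ``W1_2S``
    is the classic warning rule; it never rejects a run on its own.
    """

    R1_3S = "1_3s"
    W1_2S = "1_2s"
    R2_2S = "2_2s"
    R2OF3_2S = "2/3_2s"
    RR_4S = "R_4s"
    R3_1S = "3_1s"
    R4_1S = "4_1s"
    R8X = "8_x"
    R10X = "10_x"
    R12X = "12_x"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_RULE_BY_NAME = {r.value: r for r in RuleId}
# alias usable inside slash-separated rule lists, where "2/3_2s" is ambiguous
_RULE_BY_NAME["2of3_2s"] = RuleId.R2OF3_2S


def parse_rule(name: str) -> RuleId:
    """Map a conventional rule name (e.g. ``"4_1s"``) to a :class:`RuleId`."""
    try:
        return _RULE_BY_NAME[name.strip()]
    except KeyError:
        raise ConfigError(f"unknown Westgard rule name: {name!r}") from None


@dataclass(frozen=True)
class RuleSet:
    """An ordered set of rules applied jointly to a control stream.

    Parameters
    ----------
    rules
        The rule identifiers, duplicate-free.
    cross_level
        If True (default), counting rules pool both control levels into one
        window, interleaved by run then level.  If False each level keeps
        its own window.
    cross_run
        If True (default), counting windows span consecutive runs; if False
        a window never crosses a run boundary.
    r4s_pure_range
        If True the range rule triggers on any within-run spread >= 4 SD;
        the default (False) is the classic definition which additionally
        requires excursions beyond +2 SD and -2 SD on opposite sides.
    """

    rules: Tuple[RuleId, ...]
    cross_level: bool = True
    cross_run: bool = True
    r4s_pure_range: bool = False

    def __post_init__(self) -> None:
        if not self.rules:
            raise ContractError("RuleSet must contain at least one rule")
        if len(set(self.rules)) != len(self.rules):
            raise ContractError("RuleSet contains duplicate rules")
        object.__setattr__(self, "rules", tuple(self.rules))

    @classmethod
    def of(cls, *names: str, **flags: bool) -> "RuleSet":
        """Build a rule set from rule names, e.g. ``RuleSet.of("1_3s", "2_2s")``."""
        return cls(tuple(parse_rule(n) for n in names), **flags)

    @classmethod
    def from_string(cls, text: str, **flags: bool) -> "RuleSet":
        """Parse a slash- or comma-separated rule list, e.g. ``"1_3s/2_2s/R_4s"``.

        The compound name ``2/3_2s`` is recognised despite containing the
        separator (``2of3_2s`` is an accepted unambiguous spelling).
        """
        text = text.replace("2/3_2s", "2of3_2s").replace(",", "/")
        parts = [p for p in text.split("/") if p.strip()]
        return cls.of(*parts, **flags)

    def __contains__(self, rule: RuleId) -> bool:
        return rule in self.rules

    def __str__(self) -> str:
        return "/".join(r.value for r in self.rules)


@dataclass(frozen=True, order=True)
class QCResult:
    """One control measurement: an analyte at one control level in one run."""

    analyte_id: str
    level_id: str
    run_index: int
    value: float

    def __post_init__(self) -> None:
        if self.run_index < 0:
            raise ContractError(f"run_index must be >= 0, got {self.run_index}")
        if not math.isfinite(self.value) or self.value <= 0:
            raise ContractError(
                f"control value must be finite and > 0, got {self.value!r} "
                f"({self.analyte_id}/{self.level_id} run {self.run_index})"
            )


@dataclass(frozen=True)
class ControlSpec:
    """Target mean and SD (g/L) anchoring z-scores for one analyte/level."""

    analyte_id: str
    level_id: str
    target_mean: float
    target_sd: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.target_mean) and self.target_mean > 0):
            raise ContractError(f"target_mean must be > 0, got {self.target_mean}")
        if not (math.isfinite(self.target_sd) and self.target_sd > 0):
            raise ContractError(f"target_sd must be > 0, got {self.target_sd}")


@dataclass(frozen=True)
class PeerStats:
    """Peer-group (inter-laboratory) mean for bias computation."""

    analyte_id: str
    level_id: str
    group_mean: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.group_mean) and self.group_mean > 0):
            raise ContractError(f"group_mean must be > 0, got {self.group_mean}")


@dataclass(frozen=True)
class TEaSpec:
    """Total allowable error budget: TEa% = z * imprecision_goal% + bias_goal%."""

    analyte_id: str
    z_score: float
    imprecision_goal_pct: float
    bias_goal_pct: float

    def __post_init__(self) -> None:
        for name in ("z_score", "imprecision_goal_pct", "bias_goal_pct"):
            if not math.isfinite(getattr(self, name)):
                raise ContractError(f"{name} must be finite")
        if self.z_score <= 0:
            raise ContractError("z_score must be > 0")
        if self.imprecision_goal_pct <= 0:
            raise ContractError("imprecision_goal_pct must be > 0")
        if self.bias_goal_pct < 0:
            raise ContractError("bias_goal_pct must be >= 0")


@dataclass(frozen=True)
class PhasePlan:
    """Rule assignments in force during one study phase.

    ``run_range`` is a half-open ``[start, stop)`` interval of run indices;
    ``assignments`` maps each analyte to the rule set applied to it.
    """

    phase_label: str
    assignments: Mapping[str, RuleSet]
    run_range: Tuple[int, int]

    def __post_init__(self) -> None:
        start, stop = self.run_range
        if stop <= start:
            raise ConfigError(
                f"phase {self.phase_label}: empty run range [{start}, {stop})"
            )
        object.__setattr__(self, "assignments", dict(self.assignments))

    def covers(self, run_index: int) -> bool:
        return self.run_range[0] <= run_index < self.run_range[1]


def check_phase_partition(plans: "list[PhasePlan]") -> "list[PhasePlan]":
    """Verify phase run ranges are pairwise disjoint; return plans sorted by start."""
    plans = sorted(plans, key=lambda p: p.run_range[0])
    for a, b in zip(plans, plans[1:]):
        if b.run_range[0] < a.run_range[1]:
            raise ConfigError(
                f"phases {a.phase_label} and {b.phase_label} overlap: "
                f"{a.run_range} vs {b.run_range}"
            )
    return plans


@dataclass(frozen=True)
class MetricsSummary:
    """CV%, bias% and sigma for one analyte/level in one phase.

    ``n`` is the number of control results the statistics were computed
    from; ``None`` marks summaries transcribed from an external report
    where the underlying count is unknown.
    """

    analyte_id: str
    level_id: str
    phase_label: str
    cv_pct: float
    bias_pct: float
    sigma: float
    n: int | None = None

    def __post_init__(self) -> None:
        if self.cv_pct < 0:
            raise ContractError("cv_pct must be >= 0")
        if self.n is not None and self.n < 2:
            raise ContractError("n must be >= 2 when known")


@dataclass(frozen=True)
class ErrorCondition:
    """An out-of-control condition injected into a control stream.

    ``shift_sd`` is a systematic shift of the true mean in SD multiples
    (signed); ``re_factor`` multiplies the true SD (random-error inflation,
    >= 1); both take effect from ``onset_run`` onward.
    """

    shift_sd: float = 0.0
    re_factor: float = 1.0
    onset_run: int = 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.shift_sd):
            raise ContractError("shift_sd must be finite")
        if not (math.isfinite(self.re_factor) and self.re_factor >= 1):
            raise ContractError("re_factor must be >= 1")
        if self.onset_run < 0:
            raise ContractError("onset_run must be >= 0")

    @property
    def is_null(self) -> bool:
        return self.shift_sd == 0.0 and self.re_factor == 1.0


LEVEL_ORDER = ("L1", "L2", "L3")


def level_sort_key(level_id: str) -> tuple:
    """Stable ordering of control levels: known levels first, then lexical."""
    try:
        return (0, LEVEL_ORDER.index(level_id))
    except ValueError:
        return (1, level_id)
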