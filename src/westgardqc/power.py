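"""Monte-Carlo power characteristics of Westgard rule sets.

Two quantities describe a rule set's operating characteristic under the
standard Gaussian error model (in-control z ~ N(0,1) per level per run;
systematic error adds ``shift_sd``; random error multiplies the SD by
``re_factor``):

* **Pfr** — probability of false rejection: the per-run probability that
  an in-control run is rejected;
* **Ped** — probability of error detection: the probability that at least
  one run is rejected within a fixed horizon after an error condition
  sets in.

Both are estimated by simulating the same sequential process the rule
engine applies to real data (counting windows pooled across levels,
reset after each rejected run, by default).  Common random numbers — the
same standard-normal draws reused for every rule set compared — make
paired differences exact in the nesting sense: a superset of rules can
never reject fewer runs on the same draws.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ContractError
from .model import ErrorCondition, PhasePlan, RuleSet
from .rules import reject_stream

__all__ = [
    "ErrorCondition",
    "PowerEstimate",
    "simulate_in_control",
    "simulate_error_detection",
    "compare_phase_rulesets",
]


@dataclass(frozen=True)
class PowerEstimate:
    """Monte-Carlo estimate of a rule set's Pfr and/or Ped.

    Standard errors are binomial: sqrt(p * (1-p) / n) with n the number of
    simulated runs (Pfr) or replicates (Ped).
    """

    ruleset: RuleSet
    condition: Optional[ErrorCondition]
    n_levels: int
    runs_per_replicate: int
    replicates: int
    pfr: Optional[float] = None
    pfr_se: Optional[float] = None
    ped: Optional[float] = None
    ped_se: Optional[float] = None


def _binom_se(p: float, n: int) -> float:
    return math.sqrt(p * (1.0 - p) / n)


def simulate_in_control(
    ruleset: RuleSet,
    n_levels: int = 2,
    n_runs: int = 100,
    replicates: int = 1000,
    seed: int = 0,
    *,
    reset_on_reject: bool = True,
) -> PowerEstimate:
    """Estimate the per-run false-rejection probability of a rule set.

    Draws ``replicates`` independent in-control streams of ``n_runs`` runs
    (z ~ N(0,1) per level) and evaluates the rule set sequentially on
    each; Pfr is the rejected fraction of all simulated runs.
    Deterministic for a fixed seed.
    """
    if replicates < 1 or n_runs < 1:
        raise ContractError("replicates and n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    rejected = 0
    total = n_runs * replicates
    for _ in range(replicates):
        z = rng.standard_normal((n_runs, n_levels))
        rejected += int(reject_stream(z, ruleset, reset_on_reject=reset_on_reject).sum())
    pfr = rejected / total
    return PowerEstimate(
        ruleset, None, n_levels, n_runs, replicates,
        pfr=pfr, pfr_se=_binom_se(pfr, total),
    )


def _condition_stream(base: np.ndarray, condition: ErrorCondition) -> np.ndarray:
    """Apply shift/inflation to a base N(0,1) stream from the onset run."""
    z = base.copy()
    z[condition.onset_run:] = (
        base[condition.onset_run:] * condition.re_factor + condition.shift_sd
    )
    return z


def simulate_error_detection(
    ruleset: RuleSet,
    condition: ErrorCondition,
    n_levels: int = 2,
    horizon_runs: int = 10,
    replicates: int = 1000,
    seed: int = 0,
    *,
    reset_on_reject: bool = True,
) -> PowerEstimate:
    """Estimate the probability of detecting an error within a horizon.

    Each replicate simulates ``condition.onset_run`` in-control runs
    followed by ``horizon_runs`` runs under the error condition; Ped is
    the fraction of replicates with at least one rejection at or after the
    onset.  The base standard-normal draws depend only on (seed,
    replicates, horizon, levels), so different rule sets evaluated with
    the same seed share common random numbers and compare pairwise
    exactly.
    """
    if horizon_runs < 1 or replicates < 1:
        raise ContractError("horizon_runs and replicates must be >= 1")
    rng = np.random.default_rng(seed)
    n_total = condition.onset_run + horizon_runs
    hits = 0
    for _ in range(replicates):
        base = rng.standard_normal((n_total, n_levels))
        z = _condition_stream(base, condition)
        mask = reject_stream(z, ruleset, reset_on_reject=reset_on_reject)
        if mask[condition.onset_run:].any():
            hits += 1
    ped = hits / replicates
    return PowerEstimate(
        ruleset, condition, n_levels, n_total, replicates,
        ped=ped, ped_se=_binom_se(ped, replicates),
    )


def compare_phase_rulesets(
    plans: Sequence[PhasePlan],
    conditions: Sequence[ErrorCondition],
    *,
    n_levels: int = 2,
    horizon_runs: int = 10,
    replicates: int = 1000,
    in_control_runs: int = 100,
    seed: int = 0,
    reset_on_reject: bool = True,
) -> pd.DataFrame:
    """Ped/Pfr for every (analyte, phase rule set, condition) combination.

    Returns a tidy DataFrame with one row per (analyte, phase, condition)
    carrying the Monte-Carlo estimates, their binomial standard errors and
    the paired difference in Ped against the first (baseline) phase of the
    same analyte and condition.  All rule sets see identical random draws
    (common random numbers), so paired differences are free of simulation
    noise from independent streams.
    """
    plans = sorted(plans, key=lambda p: p.run_range[0])
    baseline = plans[0].phase_label

    # deduplicate rule sets so each distinct set is simulated once
    pfr_cache: Dict[RuleSet, PowerEstimate] = {}
    ped_cache: Dict[Tuple[RuleSet, ErrorCondition], PowerEstimate] = {}

    rows = []
    for plan in plans:
        for analyte, ruleset in plan.assignments.items():
            if ruleset not in pfr_cache:
                pfr_cache[ruleset] = simulate_in_control(
                    ruleset, n_levels, in_control_runs, replicates, seed,
                    reset_on_reject=reset_on_reject,
                )
            fr = pfr_cache[ruleset]
            for cond in conditions:
                key = (ruleset, cond)
                if key not in ped_cache:
                    ped_cache[key] = simulate_error_detection(
                        ruleset, cond, n_levels, horizon_runs, replicates, seed,
                        reset_on_reject=reset_on_reject,
                    )
                ed = ped_cache[key]
                rows.append(
                    {
                        "analyte": analyte,
                        "phase": plan.phase_label,
                        "ruleset": str(ruleset),
                        "shift_sd": cond.shift_sd,
                        "re_factor": cond.re_factor,
                        "ped": ed.ped,
                        "ped_se": ed.ped_se,
                        "pfr": fr.pfr,
                        "pfr_se": fr.pfr_se,
                    }
                )
    df = pd.DataFrame(rows)
    base = (
        df[df["phase"] == baseline]
        .set_index(["analyte", "shift_sd", "re_factor"])[["ped", "pfr"]]
        .rename(columns={"ped": "ped_baseline", "pfr": "pfr_baseline"})
    )
    df = df.join(base, on=["analyte", "shift_sd", "re_factor"])
    df["ped_vs_baseline"] = df["ped"] - df["ped_baseline"]
    df["pfr_vs_baseline"] = df["pfr"] - df["pfr_baseline"]
    return df.drop(columns=["ped_baseline", "pfr_baseline"])
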