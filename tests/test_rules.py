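"""Rule engine: predicate examples, brute-force oracle equivalence,
monotonicity/symmetry properties and phase-plan application."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from westgardqc.errors import ContractError, CoverageError
from westgardqc.model import ControlSpec, PhasePlan, QCResult, RuleId, RuleSet
from westgardqc.rules import (
    COUNTING_RULES,
    ZScoredResult,
    apply_plan,
    check_1_3s,
    check_R_4s,
    check_counting_rule,
    evaluate_run,
    reject_stream,
    zscore,
)
from westgardqc.simulate import table1_fixture

SPEC = ControlSpec("IgA", "L3", 2.00, 0.05)


def zs(*values, analyte="IgA", level="L3", start_run=0, per_run_levels=None):
    """Build ZScoredResults from raw z values, one run per value."""
    out = []
    for i, z in enumerate(values):
        out.append(ZScoredResult(analyte, level, start_run + i, 2.0 + 0.05 * z, z))
    return out


def run_of(*level_z, run_index=0, analyte="IgA"):
    """One run with given (level, z) pairs."""
    return [
        ZScoredResult(analyte, lvl, run_index, 2.0 + 0.05 * z, z) for lvl, z in level_z
    ]


class TestZScore:
    def test_at_mean_is_zero(self):
        assert zscore(QCResult("IgA", "L3", 0, 2.00), SPEC).z == 0.0

    def test_three_sd_above(self):
        assert zscore(QCResult("IgA", "L3", 0, 2.15), SPEC).z == pytest.approx(3.0)

    def test_hand_arithmetic(self):
        assert zscore(QCResult("IgA", "L3", 0, 2.12), SPEC).z == pytest.approx(2.4)

    def test_mismatched_spec_is_contract_error(self):
        with pytest.raises(ContractError):
            zscore(QCResult("AAT", "L3", 0, 2.0), SPEC)


class TestSingleValueRules:
    def test_1_3s_above(self):
        v = check_1_3s(zs(3.2))
        assert v is not None and v.side == "above" and len(v.contributing) == 1

    def test_1_3s_inside_limit(self):
        assert check_1_3s(zs(2.9)) is None

    def test_1_3s_boundary_is_strict(self):
        assert check_1_3s(zs(-3.0)) is None


class TestRangeRule:
    def test_opposite_excursions_trigger(self):
        v = check_R_4s(run_of(("L1", 2.1), ("L3", -2.0)))
        assert v is not None and v.side == "range"

    def test_below_four_sd_spread(self):
        assert check_R_4s(run_of(("L1", 1.9), ("L3", -1.9))) is None

    def test_same_side_spread_does_not_trigger_classic(self):
        assert check_R_4s(run_of(("L1", 4.5), ("L3", 0.4))) is None

    def test_pure_range_variant_triggers_on_same_side(self):
        assert check_R_4s(run_of(("L1", 4.5), ("L3", 0.4)), pure_range=True) is not None

    def test_single_level_not_evaluable(self):
        assert check_R_4s(run_of(("L1", 5.0))) is None


class TestCountingRules:
    def test_2_2s_same_side(self):
        assert check_counting_rule(RuleId.R2_2S, zs(2.3, 2.1)) is not None

    def test_2_2s_opposite_sides(self):
        assert check_counting_rule(RuleId.R2_2S, zs(2.3, -2.1)) is None

    def test_10_x_ten_same_side(self):
        v = check_counting_rule(RuleId.R10X, zs(*([0.3] * 10)))
        assert v is not None and len(v.contributing) == 10

    def test_10_x_broken_by_one_sign_flip(self):
        assert check_counting_rule(RuleId.R10X, zs(*([0.3] * 9), -0.1)) is None

    def test_2of3_2s_two_of_three(self):
        assert check_counting_rule(RuleId.R2OF3_2S, zs(2.4, 0.5, 2.2)) is not None

    def test_short_window_not_evaluable(self):
        assert check_counting_rule(RuleId.R4_1S, zs(1.5, 1.5, 1.5)) is None

    def test_threshold_is_strict(self):
        assert check_counting_rule(RuleId.R4_1S, zs(1.0, 1.0, 1.0, 1.0)) is None


def oracle_counting_mask(z, rule):
    """Independent sliding-window scan: does any window of the rule's
    length ending at index i trigger on one side of the mean?"""
    k, thr, min_hits = COUNTING_RULES[rule]
    z = np.asarray(z)
    n = len(z)
    mask = np.zeros(n, dtype=bool)
    for i in range(k - 1, n):
        w = z[i - k + 1 : i + 1]
        mask[i] = (w > thr).sum() >= min_hits or (w < -thr).sum() >= min_hits
    return mask


class TestOracleEquivalence:
    @pytest.mark.parametrize("rule", sorted(COUNTING_RULES, key=lambda r: r.value))
    def test_counting_rules_match_brute_force(self, rule, rng):
        for _ in range(200):
            n = rng.integers(1, 31)
            z = rng.normal(0, 1.6, n)
            engine = reject_stream(
                z[:, None], RuleSet((rule,)), reset_on_reject=False
            )
            assert np.array_equal(engine, oracle_counting_mask(z, rule))

    def test_1_3s_matches_brute_force(self, rng):
        for _ in range(200):
            z = rng.normal(0, 1.6, (rng.integers(1, 31), 2))
            engine = reject_stream(z, RuleSet((RuleId.R1_3S,)), reset_on_reject=False)
            assert np.array_equal(engine, (np.abs(z) > 3).any(axis=1))

    def test_R_4s_matches_brute_force(self, rng):
        for _ in range(200):
            z = rng.normal(0, 1.6, (rng.integers(1, 31), 2))
            engine = reject_stream(z, RuleSet((RuleId.RR_4S,)), reset_on_reject=False)
            hi, lo = z.max(axis=1), z.min(axis=1)
            expected = (hi - lo >= 4) & (hi >= 2) & (lo <= -2)
            assert np.array_equal(engine, expected)


class TestProperties:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_negation_symmetry(self, seed):
        """All rules are two-sided: negating every z leaves decisions unchanged."""
        rng = np.random.default_rng(seed)
        z = rng.normal(0, 1.5, (40, 2))
        rs = RuleSet.of("1_3s", "2_2s", "R_4s", "4_1s", "10_x")
        assert np.array_equal(reject_stream(z, rs), reject_stream(-z, rs))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_superset_monotonicity(self, seed):
        """A superset rule set never rejects fewer runs on the same stream."""
        rng = np.random.default_rng(seed)
        z = rng.normal(0, 1.3, (60, 2))
        small = RuleSet.of("1_3s")
        big = RuleSet.of("1_3s", "2_2s", "R_4s", "4_1s", "10_x")
        assert reject_stream(z, small).sum() <= reject_stream(z, big).sum()

    def test_determinism(self, rng):
        z = rng.normal(0, 1.5, (50, 2))
        rs = RuleSet.of("1_3s", "2_2s", "R_4s", "4_1s", "8_x")
        assert np.array_equal(reject_stream(z, rs), reject_stream(z, rs))


class TestEvaluateRun:
    PHASE_A = RuleSet.of("1_3s", "2_2s", "R_4s")

    def test_in_control_run_accepted(self):
        d = evaluate_run([], run_of(("L1", 0.1), ("L3", -0.4)), RuleSet.of("1_3s"))
        assert d.status == "accept" and not d.violations

    def test_phase_a_range_violation(self):
        d = evaluate_run([], run_of(("L1", 2.2), ("L3", -2.2)), self.PHASE_A)
        assert d.status == "reject"
        assert [v.rule for v in d.violations] == [RuleId.RR_4S]

    def test_cross_run_2_2s(self):
        # the pooled window spans runs: last result of run 0, only result of run 1
        history = run_of(("L1", 2.3), run_index=0)
        d = evaluate_run(history, run_of(("L1", 2.4), run_index=1), self.PHASE_A)
        assert d.status == "reject"
        assert d.violations[0].rule == RuleId.R2_2S
        assert len(d.violations[0].contributing) == 2

    def test_per_level_windows_do_not_pool(self):
        rs = RuleSet.of("2_2s", cross_level=False)
        d = evaluate_run([], run_of(("L1", 2.3), ("L3", 2.4)), rs)
        assert d.status == "accept"
        d2 = evaluate_run(
            run_of(("L1", 2.3), run_index=0),
            run_of(("L1", 2.4), run_index=1),
            rs,
        )
        assert d2.status == "reject"

    def test_warning_rule_never_rejects(self):
        d = evaluate_run([], run_of(("L1", 2.5)), RuleSet.of("1_3s", "1_2s"))
        assert d.status == "accept"
        assert [w.rule for w in d.warnings] == [RuleId.W1_2S]

    def test_history_after_current_is_contract_error(self):
        with pytest.raises(ContractError):
            evaluate_run(run_of(("L1", 0.0), run_index=5), run_of(("L1", 0.0), run_index=3), self.PHASE_A)


def _stream_from_z(z, analyte="IgA"):
    """QCResults for a (n_runs, 2) z array under unit-mean specs."""
    specs = [ControlSpec(analyte, "L1", 1.0, 0.1), ControlSpec(analyte, "L3", 4.0, 0.1)]
    results = []
    for run in range(z.shape[0]):
        for j, spec in enumerate(specs):
            results.append(
                QCResult(analyte, spec.level_id, run, spec.target_mean + 0.1 * z[run, j])
            )
    return results, specs


class TestApplyPlan:
    def test_partition_conservation(self, rng):
        z = rng.normal(0, 1.0, (88, 2))
        results, specs = _stream_from_z(z)
        plans = table1_fixture(22)
        decisions = apply_plan(results, plans, specs)["IgA"]
        assert len(decisions) == 88
        labels = [d.phase_label for d in decisions]
        assert all(lbl is not None for lbl in labels)
        assert [labels.count(p) for p in "ABCD"] == [22, 22, 22, 22]

    def test_single_phase_equals_sequential_evaluation(self, rng):
        z = rng.normal(0, 1.4, (40, 2))
        results, specs = _stream_from_z(z)
        rs = RuleSet.of("1_3s", "2_2s", "R_4s")
        plan = PhasePlan("A", {"IgA": rs}, (0, 40))
        decisions = apply_plan(results, [plan], specs)["IgA"]
        mask = reject_stream(z, rs)
        assert [d.status == "reject" for d in decisions] == list(mask)

    def test_spike_rejected_in_phase_c_under_every_assignment(self, rng):
        plans = table1_fixture(22)
        for analyte in ["IgA", "AAT", "Prealbumin", "Lp(a)", "Cp"]:
            z = np.zeros((88, 2))
            z[50, 0] = 3.5  # mid phase C
            results, specs = _stream_from_z(z, analyte=analyte)
            decisions = apply_plan(results, plans, specs)[analyte]
            d = decisions[50]
            assert d.phase_label == "C" and d.status == "reject"
            assert any(v.rule == RuleId.R1_3S for v in d.violations)

    def test_run_outside_phases_is_coverage_error(self):
        results, specs = _stream_from_z(np.zeros((100, 2)))
        with pytest.raises(CoverageError):
            apply_plan(results, table1_fixture(22), specs)

    def test_reset_on_reject_breaks_counting_window(self):
        # per-level windows: L1 breaches 2SD in runs 0-1 -> 2_2s rejects run 1;
        # after the reset run 2 alone cannot re-trigger
        z = np.array([[2.5, 0.0], [2.5, 0.0], [2.5, 0.0]])
        results, specs = _stream_from_z(z)
        plan = PhasePlan("A", {"IgA": RuleSet.of("2_2s", cross_level=False)}, (0, 3))
        decisions = apply_plan(results, [plan], specs)["IgA"]
        assert [d.status for d in decisions] == ["accept", "reject", "accept"]
        without_reset = apply_plan(results, [plan], specs, reset_on_reject=False)["IgA"]
        assert [d.status for d in without_reset] == ["accept", "reject", "reject"]

    def test_windows_reset_at_phase_boundary(self):
        # 2SD excursions straddling the A|B boundary must not pool
        z = np.zeros((4, 2))
        z[1] = [0.0, 2.5]
        z[2] = [2.5, 0.0]
        results, specs = _stream_from_z(z)
        rs = RuleSet.of("2_2s")
        split = [
            PhasePlan("A", {"IgA": rs}, (0, 2)),
            PhasePlan("B", {"IgA": rs}, (2, 4)),
        ]
        merged = [PhasePlan("A", {"IgA": rs}, (0, 4))]
        split_status = [d.status for d in apply_plan(results, split, specs)["IgA"]]
        merged_status = [d.status for d in apply_plan(results, merged, specs)["IgA"]]
        assert split_status == ["accept", "accept", "accept", "accept"]
        assert merged_status == ["accept", "accept", "reject", "accept"]
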