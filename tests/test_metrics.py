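"""CV/bias/TEa/sigma formulas, cross-analyte roll-ups and parameter recovery."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from westgardqc.errors import (
    ContractError,
    CoverageError,
    DomainError,
    InsufficientDataError,
)
from westgardqc.metrics import (
    build_report,
    compute_bias,
    compute_cv,
    compute_sigma,
    compute_tea,
    count_improved,
    mean_across_analytes,
    phase_summary,
    summaries_from_config,
)
from westgardqc.model import ErrorCondition, MetricsSummary, TEaSpec
from westgardqc.simulate import default_config, default_study_config, generate_study


class TestCV:
    def test_zero_dispersion(self):
        assert compute_cv([5.0, 5.0, 5.0]) == 0.0

    def test_hand_arithmetic(self):
        assert compute_cv([9, 10, 11]) == pytest.approx(10.0)

    @given(st.floats(0.1, 50.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, factor):
        base = [9.0, 10.0, 11.0, 10.5]
        assert compute_cv([factor * v for v in base]) == pytest.approx(compute_cv(base))

    def test_noise_increases_cv(self, rng):
        base = 10.0 + rng.normal(0, 0.1, 200)
        noisier = 10.0 + rng.normal(0, 0.3, 200)
        assert compute_cv(noisier) > compute_cv(base)

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            compute_cv([1.0])
        with pytest.raises(DomainError):
            compute_cv([-1.0, -2.0])


class TestBias:
    @pytest.mark.parametrize(
        "lab,group,expected", [(10.0, 10.0, 0.0), (9.8, 10.0, -2.0), (10.5, 10.0, 5.0)]
    )
    def test_hand_arithmetic(self, lab, group, expected):
        assert compute_bias(lab, group) == pytest.approx(expected)

    def test_nonpositive_group_mean(self):
        with pytest.raises(DomainError):
            compute_bias(10.0, 0.0)


class TestTEa:
    def test_hand_arithmetic(self):
        assert compute_tea(TEaSpec("x", 1.65, 4.0, 3.0)) == pytest.approx(9.6)

    def test_identity_like(self):
        assert compute_tea(TEaSpec("x", 1.0, 5.0, 0.0)) == pytest.approx(5.0)

    def test_zero_imprecision_goal_rejected(self):
        with pytest.raises(ContractError):
            TEaSpec("x", 1.65, 0.0, 3.0)


class TestSigma:
    def test_zero_bias(self):
        assert compute_sigma(12.0, 0.0, 2.0) == pytest.approx(6.0)

    def test_negative_bias_uses_magnitude(self):
        assert compute_sigma(10.0, -2.0, 4.0) == pytest.approx(2.0)

    def test_backsolved_tea_forward_computation(self):
        # TEa back-solved from the baseline-phase IgA row (sigma*cv + |bias|
        # = 5.03 * 2.9 + 0.07 ~= 14.7) forward-applied to the final-phase
        # unrounded CV/bias reproduces the reported final sigma
        assert round(compute_sigma(14.7, -1.09, 2.55), 2) == pytest.approx(5.34, abs=0.01)

    def test_signed_variant(self):
        assert compute_sigma(10.0, -2.0, 4.0, signed_bias=True) == pytest.approx(3.0)

    @given(
        st.floats(10.0, 30.0), st.floats(-5.0, 5.0), st.floats(0.5, 10.0)
    )
    @settings(max_examples=50, deadline=None)
    def test_backsolve_consistency_and_monotonicity(self, tea, bias, cv):
        sigma = compute_sigma(tea, bias, cv)
        assert sigma * cv + abs(bias) == pytest.approx(tea, rel=1e-12)
        assert compute_sigma(tea + 1.0, bias, cv) > sigma
        assert compute_sigma(tea, bias, cv + 0.5) < sigma
        assert compute_sigma(tea, abs(bias) + 0.5, cv) < sigma

    def test_zero_cv_is_domain_error(self):
        with pytest.raises(DomainError):
            compute_sigma(10.0, 0.0, 0.0)


class TestMeanAcrossAnalytes:
    def test_final_phase_cv(self, reference):
        assert mean_across_analytes(reference, "D", "cv") == 4.2

    def test_baseline_sigma(self, reference):
        assert mean_across_analytes(reference, "A", "sigma") == 3.75

    def test_all_equal_inputs(self):
        summaries = [
            MetricsSummary(a, "L1", "A", 3.0, 1.0, 4.0) for a in "vwxyz"
        ]
        assert mean_across_analytes(summaries, "A", "cv") == 3.0

    def test_missing_analyte_is_coverage_error(self, reference):
        partial = [s for s in reference if not (s.analyte_id == "Cp" and s.phase_label == "D")]
        with pytest.raises(CoverageError, match="Cp"):
            mean_across_analytes(partial, "D", "cv")


class TestCountImproved:
    def test_reference_counts(self, reference):
        assert count_improved(reference, "cv", "A", "D") == 4
        assert count_improved(reference, "bias", "A", "D") == 2
        assert count_improved(reference, "sigma", "A", "D") == 3

    def test_identical_phases_count_zero(self, reference):
        doubled = [s for s in reference if s.phase_label == "A"]
        doubled += [
            MetricsSummary(s.analyte_id, s.level_id, "Z", s.cv_pct, s.bias_pct, s.sigma)
            for s in doubled
        ]
        for metric in ("cv", "bias", "sigma"):
            assert count_improved(doubled, metric, "A", "Z") == 0

    def test_unknown_metric_is_contract_error(self, reference):
        with pytest.raises(ContractError):
            count_improved(reference, "accuracy", "A", "D")


class TestPhaseSummary:
    def test_report_shape(self, synthetic_study, study_config):
        _cfg, results, _peer, _truth = synthetic_study
        summaries = summaries_from_config(results, study_config)
        assert len(summaries) == 20  # 5 analytes x 4 phases
        assert {s.phase_label for s in summaries} == set("ABCD")

    def test_in_control_bias_recovery(self):
        """With 30 runs/phase and known truth, estimated bias lands within
        3 standard errors of the configured true bias."""
        cfg = default_config(seed=7, runs_per_phase=30)
        results, peer, truths = generate_study(cfg)
        study = default_study_config(runs_per_phase=30)
        summaries = summaries_from_config(results, study)
        truth_map = {(t.analyte_id, t.level_id, t.phase_label): t for t in truths}
        spec_map = study.controls_by_key()
        for s in summaries:
            t = truth_map[(s.analyte_id, s.level_id, s.phase_label)]
            spec = spec_map[(s.analyte_id, s.level_id)]
            group = t.true_mean / (1 + t.true_bias_pct / 100)
            se_bias = 100 * (t.true_sd / np.sqrt(s.n)) / group
            assert abs(s.bias_pct - t.true_bias_pct) < 3 * se_bias

    def test_in_control_cv_recovery(self):
        cfg = default_config(seed=11, runs_per_phase=30)
        results, _peer, truths = generate_study(cfg)
        study = default_study_config(runs_per_phase=30)
        summaries = summaries_from_config(results, study)
        truth_map = {(t.analyte_id, t.level_id, t.phase_label): t for t in truths}
        for s in summaries:
            t = truth_map[(s.analyte_id, s.level_id, s.phase_label)]
            true_cv = 100 * t.true_sd / t.true_mean
            se_cv = true_cv / np.sqrt(2 * (s.n - 1))
            assert abs(s.cv_pct - true_cv) < 3 * se_cv

    def test_imprecision_inflation_doubles_phase_cv(self):
        cfg = default_config(
            seed=3,
            runs_per_phase=30,
            conditions={"B": ErrorCondition(re_factor=2.0, onset_run=30)},
        )
        results, _peer, _truth = generate_study(cfg)
        study = default_study_config(runs_per_phase=30)
        summaries = summaries_from_config(results, study)
        for analyte in study.reporting_levels:
            by_phase = {s.phase_label: s for s in summaries if s.analyte_id == analyte}
            others = np.mean([by_phase[p].cv_pct for p in "ACD"])
            ratio = by_phase["B"].cv_pct / others
            assert 1.5 < ratio < 2.5

    def test_empty_phase_is_insufficient_data(self, study_config):
        from westgardqc.model import QCResult

        tiny = [QCResult("IgA", "L3", 0, 4.1), QCResult("IgA", "L3", 1, 4.0)]
        with pytest.raises(InsufficientDataError):
            phase_summary(
                tiny,
                study_config.phases,
                study_config.peer_by_key(),
                study_config.tea_by_analyte(),
                {"IgA": "L3"},
            )


class TestBuildReport:
    def test_reference_roll_up(self, reference):
        report = build_report(reference)
        assert report.phase_means["D"]["cv"] == 4.2
        assert report.phase_means["A"]["bias"] == 1.28
        assert report.phase_means["D"]["bias"] == -1.49
        assert report.phase_means["A"]["sigma"] == 3.75
        assert report.phase_means["D"]["sigma"] == 3.77
        assert report.improvements == {"cv": 4, "bias": 2, "sigma": 3}

    def test_mean_rows_are_unrounded_means_before_rounding(self, reference):
        raw = mean_across_analytes(reference, "D", "sigma", rounded=False)
        assert raw == pytest.approx((5.33 + 3.25 + 2.95 + 3.81 + 3.49) / 5)
        assert round(raw, 2) == 3.77
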