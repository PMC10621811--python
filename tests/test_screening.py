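"""The any-of-six-thresholds rule, its estimator wrapper, and the Phase-two
questionnaire/checklist helpers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from cviscreen import (
    AgeGroup,
    CellThresholds,
    ChecklistClass,
    NormativeScreener,
    SimulationConfig,
    ThresholdSet,
    Variable,
    Version,
    checklist_classify,
    evaluate_run,
    hvfqi_flag,
    screen_child,
    simulate_cohort,
)

from conftest import make_paired


def fixed_thresholds(overall=40.0, dwell=2.0, accuracy_cutoff=4):
    cells = {
        (group, version): CellThresholds(
            overall_time_threshold_s=overall, dwell_threshold_s=dwell,
            percentile_level=95.0, n=50,
        )
        for group in AgeGroup
        for version in Version
    }
    return ThresholdSet(cells=cells, accuracy_cutoff=accuracy_cutoff)


class TestEvaluateRun:
    def test_low_accuracy_alone_triggers(self):
        paired = make_paired(level_times=(5.0,) * 5, dwells=(1.0,) * 5,
                             correct=(1, 2, 3, 3, 4))  # 2 accurate rounds
        triggered = evaluate_run(paired.run_single, fixed_thresholds())
        assert triggered == {Variable.accuracy}

    def test_values_exactly_at_threshold_do_not_trigger(self):
        paired = make_paired(level_times=(8.0,) * 5, dwells=(2.0,) * 5)  # overall = 40.0
        assert evaluate_run(paired.run_single, fixed_thresholds()) == frozenset()

    def test_slow_overall_time_triggers(self):
        paired = make_paired(level_times=(9.0,) * 5, dwells=(1.0,) * 5)  # overall = 45
        assert evaluate_run(paired.run_multi, fixed_thresholds()) == {Variable.overall_time}

    def test_missing_threshold_cell_is_an_error(self):
        thresholds = fixed_thresholds()
        cells = {k: v for k, v in thresholds.cells.items() if k[0] is not AgeGroup.G9_12}
        partial = ThresholdSet(cells=cells, accuracy_cutoff=4)
        paired = make_paired(age=10)
        with pytest.raises(KeyError, match="9-12"):
            evaluate_run(paired.run_single, partial)

    @given(
        bump_time=st.floats(0.0, 50.0),
        bump_dwell=st.floats(0.0, 3.0),
        drop_acc=st.integers(0, 2),
    )
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_worse_performance_never_removes_a_trigger(self, bump_time, bump_dwell, drop_acc):
        thresholds = fixed_thresholds()
        base = make_paired(level_times=(8.5,) * 5, dwells=(1.9,) * 5, correct=(1, 2, 3, 4, 5))
        worse_correct = (1, 2, 3, 4, 5 - drop_acc)
        worse = make_paired(
            level_times=tuple(8.5 + bump_time / 5 for _ in range(5)),
            dwells=tuple(min(1.9 + bump_dwell, 8.5 + bump_time / 5) for _ in range(5)),
            correct=worse_correct,
        )
        assert evaluate_run(base.run_single, thresholds) <= evaluate_run(
            worse.run_single, thresholds
        )


class TestScreenChild:
    def test_within_norms_not_flagged(self):
        outcome = screen_child(make_paired(level_times=(5.0,) * 5, dwells=(1.0,) * 5),
                               fixed_thresholds())
        assert not outcome.flagged and outcome.triggered == frozenset()
        assert not outcome.partial

    def test_single_version_trigger_flags_and_marks_partial(self):
        paired = make_paired(level_times=(9.0,) * 5, dwells=(1.0,) * 5, versions=("single",))
        outcome = screen_child(paired, fixed_thresholds())
        assert outcome.flagged and outcome.partial
        assert outcome.triggered == {(Version.single, Variable.overall_time)}

    def test_triggers_union_across_versions(self):
        thresholds = fixed_thresholds()
        child_runs = make_paired(level_times=(9.0,) * 5, dwells=(1.0,) * 5,
                                 correct=(1, 2, 3, 3, 4))
        outcome = screen_child(child_runs, thresholds)
        # both versions share the same performance here: union over versions
        assert (Version.multi, Variable.overall_time) in outcome.triggered
        assert (Version.single, Variable.accuracy) in outcome.triggered
        assert outcome.flagged


class TestNormativeScreener:
    def test_fit_exposes_thresholds_and_predict_flags(self, typical_cohort):
        screener = NormativeScreener().fit(typical_cohort)
        assert screener.n_children_ == len(typical_cohort)
        flags = screener.predict(typical_cohort)
        assert flags.dtype == bool and len(flags) == len(typical_cohort)

    def test_sklearn_param_protocol(self):
        screener = NormativeScreener(percentile_5_8=80.0)
        cloned = clone(screener)
        assert cloned.get_params()["percentile_5_8"] == 80.0

    def test_unfitted_predict_raises(self, typical_cohort):
        with pytest.raises(RuntimeError, match="not fitted"):
            NormativeScreener().predict(typical_cohort)

    def test_self_application_flags_near_nominal_tail_fraction(self, typical_cohort):
        """Thresholds applied back to their own reference cohort flag roughly
        the nominal per-variable tail (15% young / 5% older), within binomial
        error once the union over six correlated thresholds is accounted for."""
        screener = NormativeScreener().fit(typical_cohort)
        outcomes = screener.screen(typical_cohort)
        for version in Version:
            for variable in (Variable.overall_time, Variable.dwell):
                young_hits = older_hits = young_n = older_n = 0
                for paired, outcome in zip(typical_cohort, outcomes):
                    is_young = paired.child.age_years <= 8
                    hit = (version, variable) in outcome.triggered
                    if is_young:
                        young_n += 1
                        young_hits += hit
                    else:
                        older_n += 1
                        older_hits += hit
                for hits, n, nominal in ((young_hits, young_n, 0.15), (older_hits, older_n, 0.05)):
                    se = np.sqrt(nominal * (1 - nominal) / n)
                    assert abs(hits / n - nominal) < 4 * se + 2 / n

    def test_detects_full_severity_deficit_with_high_sensitivity(self, typical_cohort):
        screener = NormativeScreener().fit(typical_cohort)
        deficit, _ = simulate_cohort(
            SimulationConfig(n_children=200, deficit_prevalence=1.0, seed=31)
        )
        assert screener.predict(deficit).mean() >= 0.9


class TestQuestionnaireAndChecklist:
    @pytest.mark.parametrize("score,expected", [(30, True), (16, True), (15, False), (0, False)])
    def test_hvfqi_strictly_over_cutoff(self, score, expected):
        assert hvfqi_flag(score) is expected

    def test_hvfqi_negative_score_rejected(self):
        with pytest.raises(ValueError):
            hvfqi_flag(-1)

    @pytest.mark.parametrize(
        "n,cls",
        [(0, ChecklistClass.unlikely), (1, ChecklistClass.unlikely),
         (2, ChecklistClass.possible), (3, ChecklistClass.highly_likely)],
    )
    def test_checklist_mapping(self, n, cls):
        assert checklist_classify(n).classification is cls

    def test_checklist_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            checklist_classify(4)

    def test_published_followup_table_reproduces_known_discrepancy(self):
        """Among the ten follow-up children with checklist >= 2, eight scored
        at least 15 on the questionnaire but only seven scored strictly over
        15 (one child sat exactly at the cutoff)."""
        from cviscreen.datasets import followup_findings

        frame = followup_findings()
        suspects = frame[frame["checklist_criteria_met"] >= 2]
        assert len(suspects) == 10
        scored = suspects.dropna(subset=["hvfqi_score"])
        assert (scored["hvfqi_score"] >= 15).sum() == 8
        assert sum(hvfqi_flag(int(s)) for s in scored["hvfqi_score"]) == 7
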