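"""Generative-model behavior: determinism, calibration, deficit separation,
and the cancellation-test response models."""

import numpy as np
import pytest

from cviscreen import (
    LatentProfile,
    SimulationConfig,
    build_slct_reference,
    score_tbct,
    simulate_cohort,
    simulate_run,
)
from cviscreen.simulate import (
    generate_slct_grid,
    generate_tbct_sheet,
    simulate_slct_response,
    simulate_tbct_response,
)


def _net(grid, response):
    wrong = sum(0 if grid.is_target_cell(r, c) else 1 for r, c in response.cancellations)
    return len(response.cancellations) - wrong


class TestAssessmentModel:
    def test_identical_seed_reproduces_run_exactly(self):
        profile = LatentProfile(deficit=False)
        runs = [
            simulate_run(profile, age=9, version="single", rng=np.random.default_rng(7))
            for _ in range(2)
        ]
        assert runs[0].levels == runs[1].levels

    def test_identical_config_reproduces_cohort_exactly(self):
        cfg = SimulationConfig(n_children=30, seed=11)
        assert simulate_cohort(cfg)[0] == simulate_cohort(cfg)[0]

    def test_age_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError, match="age"):
            simulate_run(LatentProfile(deficit=False), age=3, version="multi", rng=rng)

    def test_severity_requires_deficit(self):
        with pytest.raises(ValueError):
            LatentProfile(deficit=False, severity=0.5)

    def test_deficit_doubles_mean_overall_time_at_matched_ages(self):
        # same seed => identical age and latent-speed draws; only the deficit
        # assignment differs between the two arms
        base = dict(n_children=500, seed=77)
        typical, _ = simulate_cohort(SimulationConfig(deficit_prevalence=0.0, **base))
        deficit, _ = simulate_cohort(SimulationConfig(deficit_prevalence=1.0, **base))
        mean = lambda cohort: np.mean(
            [r.overall_time_s for p in cohort for r in p.runs]
        )
        ratio = mean(deficit) / mean(typical)
        assert 1.8 <= ratio <= 2.2

    def test_deficit_accuracy_stochastically_dominated(self):
        base = dict(n_children=1000, seed=99)
        typical, _ = simulate_cohort(SimulationConfig(deficit_prevalence=0.0, **base))
        deficit, _ = simulate_cohort(SimulationConfig(deficit_prevalence=1.0, **base))
        acc = lambda cohort: np.sort([r.accurate_rounds for p in cohort for r in p.runs])
        acc_t, acc_d = acc(typical), acc(deficit)
        # empirical CDF of deficit accurate_rounds lies at or above typical's
        # at every cutpoint (lower scores), strictly above somewhere
        cdf = lambda x, k: np.mean(x <= k)
        diffs = [cdf(acc_d, k) - cdf(acc_t, k) for k in range(5)]
        assert all(d >= 0 for d in diffs) and max(diffs) > 0.3

    def test_truth_labels_match_prevalence_extremes(self):
        cohort, truth = simulate_cohort(SimulationConfig(n_children=25, deficit_prevalence=0.0, seed=3))
        assert all(t.value == "typical" for t in truth.values())
        assert all(p.run_multi and p.run_single for p in cohort)

    def test_age_histogram_tracks_weights(self):
        cfg = SimulationConfig(n_children=724, seed=8)
        cohort, _ = simulate_cohort(cfg)
        ages = np.array([p.child.age_years for p in cohort])
        weights = cfg.age_weights
        total = sum(weights.values())
        for age, w in weights.items():
            expected = 724 * w / total
            sd = np.sqrt(expected * (1 - w / total))
            assert abs(np.sum(ages == age) - expected) <= 4 * sd + 1


class TestTeddyBearModel:
    def test_sheet_counts_and_column_structure(self, rng):
        sheet = generate_tbct_sheet(rng)
        assert len(sheet.items) == 75
        for col in range(1, 6):
            col_items = [it for it in sheet.items if it.column == col]
            assert sum(it.is_target for it in col_items) == 3
            assert len(col_items) == 15

    def test_seeds_change_order_not_counts(self):
        a = generate_tbct_sheet(np.random.default_rng(1))
        b = generate_tbct_sheet(np.random.default_rng(2))
        assert a != b
        key = lambda s: sorted((it.column, it.is_target) for it in s.items)
        assert key(a) == key(b)

    def test_zero_omission_rate_marks_all_targets(self, rng):
        sheet = generate_tbct_sheet(rng)
        resp = simulate_tbct_response(sheet, LatentProfile(deficit=False), rng, omission_base=0.0)
        score = score_tbct(sheet, resp)
        assert score.O == 0 and not score.out_of_norm

    def test_severity_increases_mean_omissions(self, rng):
        sheet = generate_tbct_sheet(rng)
        omissions = {
            sev: np.mean(
                [
                    score_tbct(
                        sheet,
                        simulate_tbct_response(
                            sheet, LatentProfile(deficit=sev > 0, severity=sev), rng
                        ),
                    ).O
                    for _ in range(400)
                ]
            )
            for sev in (0.0, 1.0)
        }
        assert omissions[1.0] > omissions[0.0]

    def test_rightward_bias_concentrates_omissions_left(self, rng):
        sheet = generate_tbct_sheet(rng)
        profile = LatentProfile(deficit=True, severity=1.0)
        lo = np.mean(
            [
                score_tbct(sheet, simulate_tbct_response(sheet, profile, rng, lateral_bias=0.6)).LO_S
                for _ in range(400)
            ]
        )
        assert lo < 0


class TestLetterCancellationModel:
    def test_grid_has_308_cells_and_six_targets(self, rng):
        grid = generate_slct_grid(rng)
        assert sum(len(row) for row in grid.rows) == 308
        assert len(grid.target_letters) == 6

    def test_infinite_speed_no_errors_reaches_every_target(self, rng):
        grid = generate_slct_grid(rng)
        resp = simulate_slct_response(
            grid, LatentProfile(deficit=False), rng,
            per_item_median_s=1e-9, miss_base=0.0, confusion_base=0.0,
        )
        assert _net(grid, resp) == grid.n_target_cells

    def test_severity_lowers_mean_net_score(self, rng):
        grid = generate_slct_grid(rng)
        nets = {
            sev: np.mean(
                [
                    _net(grid, simulate_slct_response(
                        grid, LatentProfile(deficit=sev > 0, severity=sev), rng, age=12))
                    for _ in range(300)
                ]
            )
            for sev in (0.0, 1.0)
        }
        assert nets[1.0] < nets[0.0]

    def test_reference_cutoffs_nondecreasing_with_age(self, rng):
        grid = generate_slct_grid(rng)
        typical = LatentProfile(deficit=False)
        pairs = [
            (age, _net(grid, simulate_slct_response(grid, typical, rng, age=age)))
            for age in (9, 12, 15, 18)
            for _ in range(250)
        ]
        ref = build_slct_reference(pairs)
        cutoffs = [ref.cutoff(a) for a in (9, 12, 15, 18)]
        assert cutoffs == sorted(cutoffs)
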