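import numpy as np
import pytest

from cviscreen import (
    AssessmentRun,
    ChildRecord,
    LevelResult,
    PairedAssessment,
    SimulationConfig,
    simulate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_levels(level_times=(5.0, 6.0, 7.0, 8.0, 9.0), dwells=(1.0, 1.2, 1.4, 1.6, 1.8),
                correct=(1, 2, 3, 4, 5)):
    return tuple(
        LevelResult(level_index=i + 1, dwell_time_s=dwells[i], level_time_s=level_times[i],
                    n_correct_pairs=correct[i])
        for i in range(5)
    )


def make_paired(child_id="c1", age=10, level_times=(5.0, 6.0, 7.0, 8.0, 9.0),
                dwells=(1.0, 1.2, 1.4, 1.6, 1.8), correct=(1, 2, 3, 4, 5),
                versions=("multi", "single")):
    child = ChildRecord(child_id=child_id, age_years=age)
    runs = {
        v: AssessmentRun.from_levels(child, v, make_levels(level_times, dwells, correct))
        for v in versions
    }
    return PairedAssessment(child=child, run_multi=runs.get("multi"),
                            run_single=runs.get("single"))


@pytest.fixture(scope="session")
def typical_cohort():
    """A typical-only simulated cohort large enough for threshold estimation."""
    cohort, _ = simulate_cohort(SimulationConfig(n_children=400, deficit_prevalence=0.0, seed=2024))
    return cohort
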