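"""The any-of-six-thresholds screening rule, plus the auxiliary classifiers.

A child is screened on up to six thresholds: for each completed version
(multi / single color) the run can trigger on overall time, on mean dwell
time, or on accuracy.  Time triggers are strict (value > cutoff), so a child
exactly at the normative percentile is not flagged; the accuracy trigger is
``accurate_rounds < 4``.  Meeting *any one* threshold flags the child for
further assessment — a deliberately permissive union rule reflecting how
heterogeneously CVI-related visual issues present.

:class:`NormativeScreener` packages the rule as a scikit-learn estimator:
``fit`` estimates the age-stratified percentile cutoffs from a reference
cohort, ``predict`` returns the boolean flag per child.

Two small Phase-two helpers live here as well: the parental-questionnaire
total-score flag (:func:`hvfqi_flag`) and the three-criterion CVI checklist
classifier (:func:`checklist_classify`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .cohort import AssessmentRun, PairedAssessment, Version
from .normative import AgeGroup, ThresholdPolicy, ThresholdSet, assign_age_group, estimate_thresholds

__all__ = [
    "Variable",
    "ScreeningOutcome",
    "evaluate_run",
    "screen_child",
    "screen_cohort",
    "screening_report_frame",
    "NormativeScreener",
    "hvfqi_flag",
    "ChecklistClass",
    "ChecklistResult",
    "checklist_classify",
]


class Variable(str, enum.Enum):
    overall_time = "overall_time"
    dwell = "dwell"
    accuracy = "accuracy"


@dataclass(frozen=True)
class ScreeningOutcome:
    child_id: str
    flagged: bool
    triggered: frozenset[tuple[Version, Variable]]
    partial: bool  # only one version was available

    def __post_init__(self) -> None:
        if self.flagged != bool(self.triggered):
            raise ValueError("flagged must hold exactly when some threshold triggered")


def evaluate_run(run: AssessmentRun, thresholds: ThresholdSet) -> frozenset[Variable]:
    """Variables on which this run falls outside the normative range.

    Time comparisons are strict (``>``); accuracy triggers when fewer than
    ``thresholds.accuracy_cutoff`` rounds were accurate.
    """
    cell = thresholds.cell(assign_age_group(run.child.age_years), run.version)
    triggered = set()
    if run.overall_time_s > cell.overall_time_threshold_s:
        triggered.add(Variable.overall_time)
    if run.mean_dwell_s > cell.dwell_threshold_s:
        triggered.add(Variable.dwell)
    if run.accurate_rounds < thresholds.accuracy_cutoff:
        triggered.add(Variable.accuracy)
    return frozenset(triggered)


def screen_child(paired: PairedAssessment, thresholds: ThresholdSet) -> ScreeningOutcome:
    """Apply the any-of-six rule to a child's available runs.

    A child with a single version is screened on that version and marked
    ``partial`` rather than rejected.
    """
    triggered: set[tuple[Version, Variable]] = set()
    for run in paired.runs:
        for variable in evaluate_run(run, thresholds):
            triggered.add((run.version, variable))
    return ScreeningOutcome(
        child_id=paired.child.child_id,
        flagged=bool(triggered),
        triggered=frozenset(triggered),
        partial=len(paired.runs) < 2,
    )


def screen_cohort(
    cohort: Iterable[PairedAssessment], thresholds: ThresholdSet
) -> list[ScreeningOutcome]:
    return [screen_child(p, thresholds) for p in cohort]


def screening_report_frame(outcomes: Sequence[ScreeningOutcome],
                           cohort: Sequence[PairedAssessment]) -> pd.DataFrame:
    """Tabular screening report: child_id, age, flagged, triggered list, partial."""
    ages = {p.child.child_id: p.child.age_years for p in cohort}
    rows = []
    for o in outcomes:
        triggers = sorted(f"{v.value}:{var.value}" for v, var in o.triggered)
        rows.append(
            {
                "child_id": o.child_id,
                "age_years": ages.get(o.child_id),
                "flagged": o.flagged,
                "triggered": ";".join(triggers),
                "partial": o.partial,
            }
        )
    return pd.DataFrame(rows, columns=["child_id", "age_years", "flagged", "triggered", "partial"])


class NormativeScreener(BaseEstimator, ClassifierMixin):
    """Age-stratified normative screening as a fit/predict estimator.

    ``fit`` takes a reference cohort (a list of :class:`PairedAssessment`)
    and estimates the percentile cutoffs per (age band x version) cell;
    ``predict`` applies the any-of-six rule and returns one boolean per
    child.  ``y`` is accepted and ignored in ``fit`` so the estimator
    composes with scikit-learn model-selection utilities.

    Parameters
    ----------
    percentile_5_8, percentile_9_12, percentile_13_18:
        Percentile level defining the time/dwell cutoffs in each age band.
        Defaults mirror the screener's published policy (85 / 95 / 95).
    accuracy_cutoff:
        A run triggers on accuracy when ``accurate_rounds < accuracy_cutoff``.
    min_cell_size:
        Minimum reference runs per (age band x version) cell.

    Attributes
    ----------
    thresholds_ : ThresholdSet
        Estimated cutoffs with provenance.
    n_children_ : int
        Reference-cohort size.
    """

    def __init__(
        self,
        percentile_5_8: float = 85.0,
        percentile_9_12: float = 95.0,
        percentile_13_18: float = 95.0,
        accuracy_cutoff: int = 4,
        min_cell_size: int = 20,
    ) -> None:
        self.percentile_5_8 = percentile_5_8
        self.percentile_9_12 = percentile_9_12
        self.percentile_13_18 = percentile_13_18
        self.accuracy_cutoff = accuracy_cutoff
        self.min_cell_size = min_cell_size

    def _policy(self) -> ThresholdPolicy:
        return ThresholdPolicy(
            percentile_levels={
                AgeGroup.G5_8: self.percentile_5_8,
                AgeGroup.G9_12: self.percentile_9_12,
                AgeGroup.G13_18: self.percentile_13_18,
            },
            accuracy_cutoff=self.accuracy_cutoff,
            min_cell_size=self.min_cell_size,
        )

    def fit(self, X: Sequence[PairedAssessment], y: object = None) -> "NormativeScreener":
        self.thresholds_ = estimate_thresholds(X, self._policy())
        self.n_children_ = len(list(X))
        self.classes_ = np.array([False, True])
        return self

    def screen(self, X: Sequence[PairedAssessment]) -> list[ScreeningOutcome]:
        """Per-child outcomes including which thresholds triggered."""
        self._check_fitted()
        return screen_cohort(X, self.thresholds_)

    def predict(self, X: Sequence[PairedAssessment]) -> np.ndarray:
        return np.array([o.flagged for o in self.screen(X)], dtype=bool)

    def _check_fitted(self) -> None:
        if not hasattr(self, "thresholds_"):
            raise RuntimeError("NormativeScreener is not fitted; call fit() first")


def hvfqi_flag(total_score: int, cutoff: int = 15) -> bool:
    """Flag a parental-inventory total score as suggesting higher-visual-function issues.

    The 11-question inventory flags strictly above the cutoff ('over 15'
    under the default): scores at the cutoff do not flag.
    """
    if total_score < 0:
        raise ValueError(f"total_score must be non-negative, got {total_score}")
    return total_score > cutoff


class ChecklistClass(str, enum.Enum):
    unlikely = "unlikely"
    possible = "possible"
    highly_likely = "highly_likely"


@dataclass(frozen=True)
class ChecklistResult:
    n_criteria_met: int
    classification: ChecklistClass


def checklist_classify(n_criteria_met: int) -> ChecklistResult:
    """Three-criterion CVI checklist: risk factor, atypical visual behaviors,
    verifiable visual dysfunction.

    Meeting two criteria means CVI is possible; all three, highly likely.
    """
    if not 0 <= n_criteria_met <= 3:
        raise ValueError(f"n_criteria_met must be in 0..3, got {n_criteria_met}")
    if n_criteria_met <= 1:
        cls = ChecklistClass.unlikely
    elif n_criteria_met == 2:
        cls = ChecklistClass.possible
    else:
        cls = ChecklistClass.highly_likely
    return ChecklistResult(n_criteria_met=n_criteria_met, classification=cls)
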