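"""Domain types and cohort file I/O for the card-matching visual-search screener.

The screener is a timed card-matching task played over five levels of
increasing visual complexity: level ``l`` shows ``2*l + 2`` cards of which
``l`` form true pairs (4 cards / 1 pair at level one up to 12 cards / 5 pairs
at level five).  Two versions exist — ``multi`` (cards in mixed colors) and
``single`` (all cards one color) — and a child normally completes both.

Three performance variables are recorded per run:

* overall time to complete all five levels,
* per-level accuracy (a level is *accurate* when every matched pair is a
  true pair),
* dwell time — the time to match the first pair at each level.

This module defines the validated record types (:class:`ChildRecord`,
:class:`LevelResult`, :class:`AssessmentRun`, :class:`PairedAssessment`) and
the cohort CSV round trip (:func:`read_cohort` / :func:`write_cohort`).
Derived quantities (overall time, mean dwell, accurate-round count) are
stored redundantly in the CSV for human readability and re-checked on every
ingest: a mismatch is an error, never a silent fix.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "AGE_MIN",
    "AGE_MAX",
    "N_LEVELS",
    "CARD_COUNTS",
    "Gender",
    "Version",
    "TruthLabel",
    "CohortValidationError",
    "ChildRecord",
    "LevelResult",
    "AssessmentRun",
    "PairedAssessment",
    "read_cohort",
    "write_cohort",
    "cohort_to_frame",
]

AGE_MIN = 5
AGE_MAX = 18
N_LEVELS = 5

#: Cards shown at each level: ``l`` true pairs plus two unpaired cards.
CARD_COUNTS = {level: 2 * level + 2 for level in range(1, N_LEVELS + 1)}

# derived-value tolerance: times are stored at millisecond resolution, so any
# honest round trip agrees far inside 1e-3 s.
_TIME_ATOL = 1e-3


class Gender(str, enum.Enum):
    female = "female"
    male = "male"
    unspecified = "unspecified"


class Version(str, enum.Enum):
    multi = "multi"
    single = "single"


class TruthLabel(str, enum.Enum):
    """Latent ground truth, known only for simulated children."""

    typical = "typical"
    deficit = "deficit"


class CohortValidationError(ValueError):
    """An input record violates a domain invariant."""


@dataclass(frozen=True)
class ChildRecord:
    child_id: str
    age_years: int
    gender: Gender = Gender.unspecified
    conditions: frozenset[str] = field(default_factory=frozenset)
    truth_label: TruthLabel | None = None

    def __post_init__(self) -> None:
        if not self.child_id:
            raise CohortValidationError("child_id must be non-empty")
        if not isinstance(self.age_years, int) or isinstance(self.age_years, bool):
            raise CohortValidationError(
                f"child {self.child_id!r}: age_years must be an integer, "
                f"got {self.age_years!r}"
            )
        if not AGE_MIN <= self.age_years <= AGE_MAX:
            raise CohortValidationError(
                f"child {self.child_id!r}: age_years={self.age_years} outside "
                f"the studied range {AGE_MIN}-{AGE_MAX}"
            )
        object.__setattr__(self, "conditions", frozenset(self.conditions))


@dataclass(frozen=True)
class LevelResult:
    """Outcome of one level of one run.

    ``dwell_time_s`` is the time to match the first pair at this level;
    ``level_time_s`` the total time spent on the level.
    """

    level_index: int
    dwell_time_s: float
    level_time_s: float
    n_correct_pairs: int

    def __post_init__(self) -> None:
        if self.level_index not in CARD_COUNTS:
            raise CohortValidationError(f"level_index={self.level_index} not in 1..{N_LEVELS}")
        if not 0 <= self.n_correct_pairs <= self.n_pairs:
            raise CohortValidationError(
                f"level {self.level_index}: n_correct_pairs={self.n_correct_pairs} "
                f"outside 0..{self.n_pairs}"
            )
        if not (self.dwell_time_s > 0 and math.isfinite(self.dwell_time_s)):
            raise CohortValidationError(
                f"level {self.level_index}: dwell_time_s must be positive"
            )
        if self.dwell_time_s > self.level_time_s + _TIME_ATOL / 10:
            raise CohortValidationError(
                f"level {self.level_index}: dwell_time_s={self.dwell_time_s} exceeds "
                f"level_time_s={self.level_time_s}"
            )

    @property
    def n_pairs(self) -> int:
        return self.level_index

    @property
    def n_cards(self) -> int:
        return CARD_COUNTS[self.level_index]

    @property
    def accurate(self) -> bool:
        """A level is accurate when every matched pair is a true pair."""
        return self.n_correct_pairs == self.n_pairs


@dataclass(frozen=True)
class AssessmentRun:
    """One child x one screener version: five levels plus derived summaries."""

    child: ChildRecord
    version: Version
    levels: tuple[LevelResult, ...]
    overall_time_s: float
    mean_dwell_s: float
    accurate_rounds: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "version", Version(self.version))
        object.__setattr__(self, "levels", tuple(self.levels))
        if [lv.level_index for lv in self.levels] != list(range(1, N_LEVELS + 1)):
            raise CohortValidationError(
                f"child {self.child.child_id!r} ({self.version.value}): runs need "
                f"exactly levels 1..{N_LEVELS} in order"
            )
        checks = (
            ("overall_time_s", self.overall_time_s, sum(lv.level_time_s for lv in self.levels)),
            ("mean_dwell_s", self.mean_dwell_s, sum(lv.dwell_time_s for lv in self.levels) / N_LEVELS),
        )
        for name, stored, recomputed in checks:
            if abs(stored - recomputed) > _TIME_ATOL:
                raise CohortValidationError(
                    f"child {self.child.child_id!r} ({self.version.value}): stored "
                    f"{name}={stored} disagrees with value recomputed from levels "
                    f"({recomputed:.4f})"
                )
        n_acc = sum(lv.accurate for lv in self.levels)
        if self.accurate_rounds != n_acc:
            raise CohortValidationError(
                f"child {self.child.child_id!r} ({self.version.value}): stored "
                f"accurate_rounds={self.accurate_rounds} disagrees with levels ({n_acc})"
            )

    @classmethod
    def from_levels(
        cls, child: ChildRecord, version: Version | str, levels: Sequence[LevelResult]
    ) -> "AssessmentRun":
        """Build a run with the derived summaries computed from the levels."""
        levels = tuple(levels)
        return cls(
            child=child,
            version=Version(version),
            levels=levels,
            overall_time_s=round(sum(lv.level_time_s for lv in levels), 3),
            mean_dwell_s=round(sum(lv.dwell_time_s for lv in levels) / len(levels), 4),
            accurate_rounds=sum(lv.accurate for lv in levels),
        )


@dataclass(frozen=True)
class PairedAssessment:
    """A child's (up to) two runs, one per screener version."""

    child: ChildRecord
    run_multi: AssessmentRun | None = None
    run_single: AssessmentRun | None = None

    def __post_init__(self) -> None:
        if self.run_multi is None and self.run_single is None:
            raise CohortValidationError(
                f"child {self.child.child_id!r}: at least one run is required"
            )
        for run, expected in ((self.run_multi, Version.multi), (self.run_single, Version.single)):
            if run is None:
                continue
            if run.version is not expected:
                raise CohortValidationError(
                    f"child {self.child.child_id!r}: run in the {expected.value} slot "
                    f"has version {run.version.value}"
                )
            if run.child != self.child:
                raise CohortValidationError(
                    f"child {self.child.child_id!r}: run child record disagrees"
                )

    @property
    def runs(self) -> tuple[AssessmentRun, ...]:
        return tuple(r for r in (self.run_multi, self.run_single) if r is not None)

    def run(self, version: Version | str) -> AssessmentRun | None:
        return self.run_multi if Version(version) is Version.multi else self.run_single


# ---------------------------------------------------------------------------
# Cohort CSV schema: one row per (child, version).
# ---------------------------------------------------------------------------

_BASE_COLUMNS = ["child_id", "age_years", "gender", "conditions", "truth_label", "version"]
_LEVEL_COLUMNS = (
    [f"level_time_l{i}" for i in range(1, N_LEVELS + 1)]
    + [f"dwell_l{i}" for i in range(1, N_LEVELS + 1)]
    + [f"correct_pairs_l{i}" for i in range(1, N_LEVELS + 1)]
)
_DERIVED_COLUMNS = ["overall_time_s", "mean_dwell_s", "accurate_rounds"]
COHORT_COLUMNS = _BASE_COLUMNS + _LEVEL_COLUMNS + _DERIVED_COLUMNS


def _parse_row(row: Mapping[str, object], row_no: int) -> AssessmentRun:
    def fail(field_name: str, msg: str) -> CohortValidationError:
        return CohortValidationError(f"row {row_no}, field {field_name!r}: {msg}")

    def get(name: str) -> str:
        value = row.get(name)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return ""
        return str(value).strip()

    def get_float(name: str) -> float:
        raw = get(name)
        try:
            return float(raw)
        except ValueError:
            raise fail(name, f"not a number: {raw!r}") from None

    def get_int(name: str) -> int:
        raw = get(name)
        try:
            return int(raw)
        except ValueError:
            raise fail(name, f"not an integer: {raw!r}") from None

    raw_truth = get("truth_label")
    raw_conditions = get("conditions")
    try:
        child = ChildRecord(
            child_id=get("child_id"),
            age_years=get_int("age_years"),
            gender=Gender(get("gender") or "unspecified"),
            conditions=frozenset(t for t in raw_conditions.split(";") if t),
            truth_label=TruthLabel(raw_truth) if raw_truth else None,
        )
        levels = tuple(
            LevelResult(
                level_index=i,
                dwell_time_s=get_float(f"dwell_l{i}"),
                level_time_s=get_float(f"level_time_l{i}"),
                n_correct_pairs=get_int(f"correct_pairs_l{i}"),
            )
            for i in range(1, N_LEVELS + 1)
        )
        return AssessmentRun(
            child=child,
            version=Version(get("version")),
            levels=levels,
            overall_time_s=get_float("overall_time_s"),
            mean_dwell_s=get_float("mean_dwell_s"),
            accurate_rounds=get_int("accurate_rounds"),
        )
    except CohortValidationError as exc:
        raise CohortValidationError(f"row {row_no}: {exc}") from None
    except ValueError as exc:
        raise CohortValidationError(f"row {row_no}: {exc}") from None


def read_cohort(path: str | Path) -> list[PairedAssessment]:
    """Read and validate a cohort CSV, grouping rows into paired assessments.

    Every row is validated against the type invariants (including the stored
    derived quantities); rows are grouped by child and version.  Malformed
    rows raise :class:`CohortValidationError` naming the row and field.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortValidationError(f"cohort file {path}: missing columns {missing}")

    by_child: dict[str, dict[Version, AssessmentRun]] = {}
    order: list[str] = []
    for idx, row in enumerate(frame.to_dict("records")):
        run = _parse_row(row, row_no=idx + 2)  # +2: header line + 1-based
        slots = by_child.setdefault(run.child.child_id, {})
        if not slots:
            order.append(run.child.child_id)
        elif next(iter(slots.values())).child != run.child:
            raise CohortValidationError(
                f"row {idx + 2}: child {run.child.child_id!r} has inconsistent "
                f"demographic fields across rows"
            )
        if run.version in slots:
            raise CohortValidationError(
                f"row {idx + 2}: duplicate (child {run.child.child_id!r}, "
                f"version {run.version.value!r})"
            )
        slots[run.version] = run

    return [
        PairedAssessment(
            child=next(iter(by_child[cid].values())).child,
            run_multi=by_child[cid].get(Version.multi),
            run_single=by_child[cid].get(Version.single),
        )
        for cid in order
    ]


def _run_to_row(run: AssessmentRun) -> dict[str, object]:
    child = run.child
    row: dict[str, object] = {
        "child_id": child.child_id,
        "age_years": child.age_years,
        "gender": child.gender.value,
        "conditions": ";".join(sorted(child.conditions)),
        "truth_label": child.truth_label.value if child.truth_label else "",
        "version": run.version.value,
    }
    for lv in run.levels:
        row[f"level_time_l{lv.level_index}"] = lv.level_time_s
        row[f"dwell_l{lv.level_index}"] = lv.dwell_time_s
        row[f"correct_pairs_l{lv.level_index}"] = lv.n_correct_pairs
    row["overall_time_s"] = run.overall_time_s
    row["mean_dwell_s"] = run.mean_dwell_s
    row["accurate_rounds"] = run.accurate_rounds
    return row


def write_cohort(cohort: Iterable[PairedAssessment], path: str | Path) -> None:
    """Write a cohort CSV such that ``read_cohort`` reproduces it field-for-field."""
    rows = [_run_to_row(run) for paired in cohort for run in paired.runs]
    frame = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    frame.to_csv(path, index=False)


def cohort_to_frame(cohort: Iterable[PairedAssessment]) -> pd.DataFrame:
    """One row per run with the summary variables the analysis consumes."""
    rows = []
    for paired in cohort:
        for run in paired.runs:
            rows.append(
                {
                    "child_id": run.child.child_id,
                    "age_years": run.child.age_years,
                    "truth_label": run.child.truth_label.value if run.child.truth_label else None,
                    "version": run.version.value,
                    "overall_time_s": run.overall_time_s,
                    "mean_dwell_s": run.mean_dwell_s,
                    "accurate_rounds": run.accurate_rounds,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "child_id",
            "age_years",
            "truth_label",
            "version",
            "overall_time_s",
            "mean_dwell_s",
            "accurate_rounds",
        ],
    )
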