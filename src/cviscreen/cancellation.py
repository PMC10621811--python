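"""Scoring for the two paper-and-pencil visual-search comparison tests.

Teddy-bear cancellation (TBCT, ages 5-8): an untimed sheet of 15 target
teddy bears and 60 distractors laid out in five columns.  Columns carry
nominal values -1, -1, 0, +1, +1 from left to right.  Scores are the number
of omissions ``O``, the location-of-omissions score ``LO_S`` (sum of nominal
values over omitted targets) and the start score ``START_S`` (sum of nominal
values over the first three *targets* marked).  A result is out of norm when
there is one or more omission.

Six-letter cancellation (SLCT, ages 9+): a 22x14 grid of letters with six
designated targets, worked for 90 seconds.  The net score is total
cancellations minus wrong cancellations; a result is out of norm when the
net score sits at the 5th percentile of the age reference or below.  The
reference distribution is pluggable: load published tables from JSON, or
build one from simulated typical responses (then labelled synthetic in its
provenance).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .normative import percentile_closest_ranks

__all__ = [
    "TBCT_N_TARGETS",
    "TBCT_N_DISTRACTORS",
    "TBCT_COLUMN_NOMINAL",
    "TBCTItem",
    "TBCTSheet",
    "TBCTResponse",
    "TBCTScore",
    "score_tbct",
    "SLCT_ROWS",
    "SLCT_COLS",
    "SLCT_TIME_LIMIT_S",
    "SLCTGrid",
    "SLCTResponse",
    "SLCTScore",
    "score_slct",
    "SLCTNormativeReference",
    "build_slct_reference",
]

TBCT_N_TARGETS = 15
TBCT_N_DISTRACTORS = 60
TBCT_N_COLUMNS = 5
#: Nominal value of each column, numbered 1-5 left to right.
TBCT_COLUMN_NOMINAL = {1: -1, 2: -1, 3: 0, 4: 1, 5: 1}

SLCT_ROWS = 22
SLCT_COLS = 14
SLCT_N_TARGET_LETTERS = 6
SLCT_TIME_LIMIT_S = 90.0
SLCT_OUT_OF_NORM_PERCENTILE = 5.0


@dataclass(frozen=True)
class TBCTItem:
    item_id: str
    column: int
    row: int
    is_target: bool

    def __post_init__(self) -> None:
        if self.column not in TBCT_COLUMN_NOMINAL:
            raise ValueError(f"item {self.item_id!r}: column {self.column} not in 1-5")


@dataclass(frozen=True)
class TBCTSheet:
    items: tuple[TBCTItem, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        n_targets = sum(it.is_target for it in self.items)
        n_distractors = len(self.items) - n_targets
        if n_targets != TBCT_N_TARGETS or n_distractors != TBCT_N_DISTRACTORS:
            raise ValueError(
                f"sheet must hold {TBCT_N_TARGETS} targets and {TBCT_N_DISTRACTORS} "
                f"distractors, got {n_targets}/{n_distractors}"
            )
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item ids on sheet")

    def item(self, item_id: str) -> TBCTItem:
        try:
            return self._by_id[item_id]
        except KeyError:
            raise KeyError(f"mark references unknown item {item_id!r}") from None

    @property
    def _by_id(self) -> dict[str, TBCTItem]:
        cache = self.__dict__.get("_by_id_cache")
        if cache is None:
            cache = {it.item_id: it for it in self.items}
            self.__dict__["_by_id_cache"] = cache
        return cache

    def to_dict(self) -> dict[str, object]:
        return {
            "items": [
                {"item_id": it.item_id, "column": it.column, "row": it.row,
                 "is_target": it.is_target}
                for it in self.items
            ]
        }

    @classmethod
    def from_dict(cls, payload: Mapping[str, object]) -> "TBCTSheet":
        return cls(tuple(TBCTItem(**item) for item in payload["items"]))  # type: ignore[index]


@dataclass(frozen=True)
class TBCTResponse:
    """Ordered item ids the child crossed out, first to last."""

    marks: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "marks", tuple(self.marks))
        if len(set(self.marks)) != len(self.marks):
            raise ValueError("duplicate marks in response")

    def to_dict(self) -> dict[str, object]:
        return {"marks": list(self.marks)}

    @classmethod
    def from_dict(cls, payload: Mapping[str, object]) -> "TBCTResponse":
        return cls(tuple(payload["marks"]))  # type: ignore[arg-type]


@dataclass(frozen=True)
class TBCTScore:
    O: int
    LO_S: int
    START_S: int
    out_of_norm: bool

    def to_dict(self) -> dict[str, object]:
        return {"O": self.O, "LO_S": self.LO_S, "START_S": self.START_S,
                "out_of_norm": self.out_of_norm}


def score_tbct(sheet: TBCTSheet, response: TBCTResponse) -> TBCTScore:
    """Score a teddy-bear cancellation response.

    ``START_S`` sums the column nominal values of the first three marked
    *targets* (marks on distractors do not count toward the first three);
    with fewer than three targets marked, the sum runs over those marked.
    Out of norm iff at least one target was omitted.
    """
    marked_items = [sheet.item(mark) for mark in response.marks]
    marked_target_ids = {it.item_id for it in marked_items if it.is_target}
    omitted = [it for it in sheet.items if it.is_target and it.item_id not in marked_target_ids]
    first_three = [it for it in marked_items if it.is_target][:3]
    return TBCTScore(
        O=len(omitted),
        LO_S=sum(TBCT_COLUMN_NOMINAL[it.column] for it in omitted),
        START_S=sum(TBCT_COLUMN_NOMINAL[it.column] for it in first_three),
        out_of_norm=len(omitted) >= 1,
    )


@dataclass(frozen=True)
class SLCTGrid:
    """22x14 letter grid with six designated target letters."""

    rows: tuple[str, ...]  # 22 strings of 14 uppercase letters
    target_letters: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(self.rows))
        object.__setattr__(self, "target_letters", frozenset(self.target_letters))
        if len(self.rows) != SLCT_ROWS or any(len(r) != SLCT_COLS for r in self.rows):
            raise ValueError(f"grid must be {SLCT_ROWS} rows x {SLCT_COLS} columns")
        if len(self.target_letters) != SLCT_N_TARGET_LETTERS:
            raise ValueError(f"exactly {SLCT_N_TARGET_LETTERS} distinct target letters required")

    def letter(self, row: int, col: int) -> str:
        return self.rows[row][col]

    def is_target_cell(self, row: int, col: int) -> bool:
        return self.letter(row, col) in self.target_letters

    @property
    def n_target_cells(self) -> int:
        return sum(ch in self.target_letters for r in self.rows for ch in r)

    def to_dict(self) -> dict[str, object]:
        return {"rows": list(self.rows), "target_letters": sorted(self.target_letters)}

    @classmethod
    def from_dict(cls, payload: Mapping[str, object]) -> "SLCTGrid":
        return cls(tuple(payload["rows"]), frozenset(payload["target_letters"]))  # type: ignore[arg-type]


@dataclass(frozen=True)
class SLCTResponse:
    """(row, col) cells cancelled within the 90-second window, 0-based, in order."""

    cancellations: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        cells = tuple((int(r), int(c)) for r, c in self.cancellations)
        object.__setattr__(self, "cancellations", cells)
        for r, c in cells:
            if not (0 <= r < SLCT_ROWS and 0 <= c < SLCT_COLS):
                raise ValueError(f"cancellation ({r}, {c}) off the grid")
        if len(set(cells)) != len(cells):
            raise ValueError("duplicate cancellations on the same cell")

    def to_dict(self) -> dict[str, object]:
        return {"cancellations": [list(cell) for cell in self.cancellations]}

    @classmethod
    def from_dict(cls, payload: Mapping[str, object]) -> "SLCTResponse":
        return cls(tuple(tuple(cell) for cell in payload["cancellations"]))  # type: ignore[arg-type]


@dataclass(frozen=True)
class SLCTScore:
    total: int
    wrong: int
    net: int
    percentile_in_reference: float
    out_of_norm: bool

    def to_dict(self) -> dict[str, object]:
        return {"total": self.total, "wrong": self.wrong, "net": self.net,
                "percentile_in_reference": self.percentile_in_reference,
                "out_of_norm": self.out_of_norm}


@dataclass(frozen=True)
class SLCTNormativeReference:
    """Per-age empirical distributions of typical net scores.

    ``cutoff(age)`` is the 5th percentile (closest-ranks interpolation) of
    the age's reference scores; a score is out of norm when it sits at the
    cutoff or below.  ``percentile_of`` reports the midpoint-corrected rank
    percentile (fraction strictly below plus half the ties).
    """

    scores_by_age: Mapping[int, tuple[int, ...]]
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "scores_by_age",
            {int(a): tuple(sorted(int(s) for s in v)) for a, v in self.scores_by_age.items()},
        )
        for age, scores in self.scores_by_age.items():
            if not scores:
                raise ValueError(f"empty reference band for age {age}")

    def _band(self, age: int) -> tuple[int, ...]:
        if age not in self.scores_by_age:
            raise KeyError(
                f"no reference net-score distribution for age {age}; supply a "
                f"published table or build one with build_slct_reference()"
            )
        return self.scores_by_age[age]

    def cutoff(self, age: int) -> float:
        return percentile_closest_ranks(self._band(age), SLCT_OUT_OF_NORM_PERCENTILE)

    def percentile_of(self, net: int, age: int) -> float:
        band = np.asarray(self._band(age))
        below = np.count_nonzero(band < net)
        ties = np.count_nonzero(band == net)
        return 100.0 * (below + 0.5 * ties) / band.size

    def to_dict(self) -> dict[str, object]:
        return {
            "scores_by_age": {str(a): list(v) for a, v in sorted(self.scores_by_age.items())},
            "provenance": dict(self.provenance),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_dict(cls, payload: Mapping[str, object]) -> "SLCTNormativeReference":
        return cls(
            scores_by_age={int(a): tuple(v) for a, v in payload["scores_by_age"].items()},  # type: ignore[union-attr]
            provenance=dict(payload.get("provenance", {})),  # type: ignore[arg-type]
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SLCTNormativeReference":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_slct_reference(
    scores: Iterable[tuple[int, int]],
    min_per_age: int = 20,
    provenance: Mapping[str, object] | None = None,
) -> SLCTNormativeReference:
    """Build a per-age reference from (age, net score) pairs.

    An age band with fewer than ``min_per_age`` scores is an error naming
    the band.
    """
    by_age: dict[int, list[int]] = {}
    for age, net in scores:
        by_age.setdefault(int(age), []).append(int(net))
    if not by_age:
        raise ValueError("no reference scores supplied")
    for age, band in sorted(by_age.items()):
        if len(band) < min_per_age:
            raise ValueError(
                f"reference band for age {age} has {len(band)} scores; "
                f"at least {min_per_age} required"
            )
    return SLCTNormativeReference(
        scores_by_age={a: tuple(v) for a, v in by_age.items()},
        provenance=dict(provenance or {}),
    )


def score_slct(
    grid: SLCTGrid,
    response: SLCTResponse,
    reference: SLCTNormativeReference,
    age: int,
) -> SLCTScore:
    """Score a six-letter cancellation response against the age reference.

    ``net = total - wrong``; out of norm when the net score is at the
    reference's 5th-percentile value or below.
    """
    total = len(response.cancellations)
    wrong = sum(0 if grid.is_target_cell(r, c) else 1 for r, c in response.cancellations)
    net = total - wrong
    return SLCTScore(
        total=total,
        wrong=wrong,
        net=net,
        percentile_in_reference=reference.percentile_of(net, age),
        out_of_norm=net <= reference.cutoff(age),
    )
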