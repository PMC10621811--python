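"""Age-stratified normative thresholds and the age trend of overall time.

The reference cohort is split into three age bands — 5-8, 9-12 and 13-18
completed years — within which performance was found to cluster.  For each
(age band x screener version) cell, the normative cutoff for overall time
and for mean dwell time is an upper percentile of the cell's empirical
distribution: the 85th percentile for the 5-8 band (whose spread is much
wider) and the 95th percentile for the older bands.  The accuracy cutoff is
the same everywhere: fewer than 4 accurate rounds is out of norm.

Percentiles use linear interpolation between closest ranks,
``h = (n - 1) * p / 100 + 1`` (the numpy/R type-7 default); the convention is
recorded in the threshold provenance so cutoffs are reproducible bit-for-bit.

Normative cutoff *values* are always an artifact of the supplied reference
cohort — none are hard-coded.
"""

from __future__ import annotations

import enum
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import (
    AGE_MAX,
    AGE_MIN,
    CohortValidationError,
    PairedAssessment,
    Version,
    cohort_to_frame,
)

__all__ = [
    "AgeGroup",
    "assign_age_group",
    "percentile_closest_ranks",
    "ThresholdPolicy",
    "CellThresholds",
    "ThresholdSet",
    "estimate_thresholds",
    "AgeTrendFit",
    "fit_age_trend",
]

PERCENTILE_CONVENTION = "linear interpolation between closest ranks, h=(n-1)*p/100+1"


class AgeGroup(str, enum.Enum):
    G5_8 = "5-8"
    G9_12 = "9-12"
    G13_18 = "13-18"


def assign_age_group(age_years: int) -> AgeGroup:
    """Map completed years of age to its normative band (5-8 / 9-12 / 13-18)."""
    if not AGE_MIN <= age_years <= AGE_MAX:
        raise ValueError(f"age_years={age_years} outside the studied range {AGE_MIN}-{AGE_MAX}")
    if age_years <= 8:
        return AgeGroup.G5_8
    if age_years <= 12:
        return AgeGroup.G9_12
    return AgeGroup.G13_18


def percentile_closest_ranks(values: Iterable[float], level: float) -> float:
    """Percentile by linear interpolation between closest ranks.

    Equivalent to the rank position ``h = (n - 1) * level / 100 + 1`` in the
    sorted sample, interpolating linearly between the two bracketing order
    statistics (numpy's default ``linear`` method).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot take a percentile of an empty sample")
    if not 0 <= level <= 100:
        raise ValueError(f"percentile level {level} outside [0, 100]")
    return float(np.percentile(arr, level, method="linear"))


@dataclass(frozen=True)
class ThresholdPolicy:
    """Which percentile defines the normative cutoff in each age band."""

    percentile_levels: Mapping[AgeGroup, float] = field(
        default_factory=lambda: {
            AgeGroup.G5_8: 85.0,
            AgeGroup.G9_12: 95.0,
            AgeGroup.G13_18: 95.0,
        }
    )
    accuracy_cutoff: int = 4  # out of norm when accurate_rounds < cutoff
    min_cell_size: int = 20

    def __post_init__(self) -> None:
        levels = dict(self.percentile_levels)
        missing = [g for g in AgeGroup if g not in levels]
        if missing:
            raise ValueError(f"percentile_levels missing age groups {missing}")
        for group, level in levels.items():
            if not 0 < level < 100:
                raise ValueError(f"percentile level for {group.value} must be in (0, 100)")
        object.__setattr__(self, "percentile_levels", levels)
        if self.min_cell_size < 1:
            raise ValueError("min_cell_size must be positive")


@dataclass(frozen=True)
class CellThresholds:
    overall_time_threshold_s: float
    dwell_threshold_s: float
    percentile_level: float
    n: int


@dataclass(frozen=True)
class ThresholdSet:
    """Per (age band x version) normative cutoffs, with provenance."""

    cells: Mapping[tuple[AgeGroup, Version], CellThresholds]
    accuracy_cutoff: int
    provenance: Mapping[str, object] = field(default_factory=dict)

    def cell(self, group: AgeGroup, version: Version) -> CellThresholds:
        key = (group, version)
        if key not in self.cells:
            raise KeyError(f"no thresholds for cell ({group.value}, {version.value})")
        return self.cells[key]

    def to_dict(self) -> dict[str, object]:
        return {
            "accuracy_cutoff": self.accuracy_cutoff,
            "cells": {
                f"{g.value}|{v.value}": {
                    "overall_time_threshold_s": c.overall_time_threshold_s,
                    "dwell_threshold_s": c.dwell_threshold_s,
                    "percentile_level": c.percentile_level,
                    "n": c.n,
                }
                for (g, v), c in sorted(
                    self.cells.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
                )
            },
            "provenance": dict(self.provenance),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_dict(cls, payload: Mapping[str, object]) -> "ThresholdSet":
        cells = {}
        for key, cell in payload["cells"].items():  # type: ignore[index]
            group_s, version_s = key.split("|")
            cells[(AgeGroup(group_s), Version(version_s))] = CellThresholds(
                overall_time_threshold_s=float(cell["overall_time_threshold_s"]),
                dwell_threshold_s=float(cell["dwell_threshold_s"]),
                percentile_level=float(cell["percentile_level"]),
                n=int(cell["n"]),
            )
        return cls(
            cells=cells,
            accuracy_cutoff=int(payload["accuracy_cutoff"]),  # type: ignore[arg-type]
            provenance=dict(payload.get("provenance", {})),  # type: ignore[arg-type]
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _cohort_hash(frame: pd.DataFrame) -> str:
    return hashlib.sha256(frame.to_csv(index=False).encode()).hexdigest()[:16]


def estimate_thresholds(
    cohort: Iterable[PairedAssessment], policy: ThresholdPolicy | None = None
) -> ThresholdSet:
    """Estimate the normative cutoffs from a reference cohort.

    Every (age band x version) cell must hold at least ``policy.min_cell_size``
    runs; an undersized cell is an error naming the cell.
    """
    policy = policy or ThresholdPolicy()
    frame = cohort_to_frame(cohort)
    if frame.empty:
        raise CohortValidationError("reference cohort is empty")
    frame["age_group"] = frame["age_years"].map(lambda a: assign_age_group(int(a)))

    cells: dict[tuple[AgeGroup, Version], CellThresholds] = {}
    for group in AgeGroup:
        for version in Version:
            cell = frame[(frame["age_group"] == group) & (frame["version"] == version.value)]
            if len(cell) < policy.min_cell_size:
                raise CohortValidationError(
                    f"cell ({group.value}, {version.value}) has {len(cell)} runs; "
                    f"at least {policy.min_cell_size} required"
                )
            level = policy.percentile_levels[group]
            cells[(group, version)] = CellThresholds(
                overall_time_threshold_s=percentile_closest_ranks(cell["overall_time_s"], level),
                dwell_threshold_s=percentile_closest_ranks(cell["mean_dwell_s"], level),
                percentile_level=level,
                n=len(cell),
            )
    return ThresholdSet(
        cells=cells,
        accuracy_cutoff=policy.accuracy_cutoff,
        provenance={
            "percentile_convention": PERCENTILE_CONVENTION,
            "reference_cohort_sha256_16": _cohort_hash(frame.drop(columns=["age_group"])),
            "n_children": int(frame["child_id"].nunique()),
            "n_runs": int(len(frame)),
        },
    )


@dataclass(frozen=True)
class AgeTrendFit:
    """OLS fit of overall completion time on age (one screener version)."""

    version: Version
    slope_s_per_year: float
    intercept_s: float
    f_statistic: float
    df: tuple[int, int]
    r_squared: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("age-trend fit needs at least 3 observations")

    def to_dict(self) -> dict[str, object]:
        return {
            "version": self.version.value,
            "slope_s_per_year": self.slope_s_per_year,
            "intercept_s": self.intercept_s,
            "f_statistic": self.f_statistic,
            "df": list(self.df),
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "n": self.n,
        }


def fit_age_trend(cohort: Iterable[PairedAssessment], version: Version | str) -> AgeTrendFit:
    """Simple OLS regression of overall completion time on age in years."""
    version = Version(version)
    frame = cohort_to_frame(cohort)
    frame = frame[frame["version"] == version.value]
    if frame["age_years"].nunique() < 3:
        raise ValueError(
            f"age-trend fit for version {version.value!r} needs >= 3 distinct ages, "
            f"got {frame['age_years'].nunique()}"
        )
    X = sm.add_constant(frame["age_years"].to_numpy(dtype=float))
    res = sm.OLS(frame["overall_time_s"].to_numpy(dtype=float), X).fit()
    return AgeTrendFit(
        version=version,
        slope_s_per_year=float(res.params[1]),
        intercept_s=float(res.params[0]),
        f_statistic=float(res.fvalue),
        df=(int(res.df_model), int(res.df_resid)),
        r_squared=float(res.rsquared),
        p_value=float(res.pvalues[1]),
        n=int(res.nobs),
    )
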