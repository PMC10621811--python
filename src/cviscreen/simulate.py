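"""Synthetic cohorts with the statistical structure the analysis assumes.

No child-level data from the screener studies is public, so every pipeline
stage is exercised on simulated cohorts built from a serial self-terminating
visual-search model:

* At each level a child inspects cards one at a time; locating the next pair
  among ``R`` remaining cards costs ``1 + Poisson(rate * (R - 2))``
  inspections, each inspection time drawn lognormal.  The dwell time is the
  first pair's search time; the level time is the sum over pairs.
* Ages change speed multiplicatively.  The multiplier is calibrated
  analytically so the *cohort-level* expected overall time is linear in age
  with the configured slope (-3.34 s/yr single-colored, -2.83 s/yr
  multi-colored by default), anchored at the expected time implied by the
  per-card inspection median at age 10.
* A latent visual-search deficit (severity in [0, 1]) multiplies search
  times — by 2.0 at full severity, matching the "twice as long"
  characterization of affected children — and shifts the per-pair mismatch
  probability, a logistic function of severity and card count.
* Children carry a lognormal latent speed factor shared by both versions,
  which is what makes the two runs of a child correlate.

The module also generates the two cancellation tests and simulates responses
to them driven by the same latent deficit: omission probability (teddy-bear
test) and scan speed / confusion rate (six-letter test) worsen with severity.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cohort import (
    AGE_MAX,
    AGE_MIN,
    CARD_COUNTS,
    N_LEVELS,
    AssessmentRun,
    ChildRecord,
    LevelResult,
    PairedAssessment,
    TruthLabel,
    Version,
)
from .cancellation import (
    SLCT_COLS,
    SLCT_N_TARGET_LETTERS,
    SLCT_ROWS,
    SLCT_TIME_LIMIT_S,
    TBCT_COLUMN_NOMINAL,
    SLCTGrid,
    SLCTResponse,
    TBCTItem,
    TBCTResponse,
    TBCTSheet,
)
from .datasets import normative_cohort_age_counts

__all__ = [
    "LatentProfile",
    "SimulationConfig",
    "simulate_run",
    "simulate_cohort",
    "simulation_manifest",
    "generate_tbct_sheet",
    "simulate_tbct_response",
    "generate_slct_grid",
    "simulate_slct_response",
]


@dataclass(frozen=True)
class LatentProfile:
    """Latent stand-in for a CVI-related visual-search impairment."""

    deficit: bool
    severity: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError(f"severity={self.severity} outside [0, 1]")
        if not self.deficit and self.severity != 0.0:
            raise ValueError("severity must be 0 for a non-deficit profile")


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for cohort simulation.

    Defaults encode the published study's stated conditions: the normative
    cohort's age composition as default age weights, a 2x time multiplier at
    full deficit severity, and age slopes of -3.34 (single) and -2.83
    (multi) seconds per year of age.  The remaining parameters set realistic
    response-time scale and spread (see the package methods note).
    """

    n_children: int = 200
    age_weights: Mapping[int, float] = field(
        default_factory=normative_cohort_age_counts
    )
    deficit_prevalence: float = 0.1
    deficit_severity: float = 1.0
    deficit_time_multiplier: float = 2.0
    deficit_mismatch_boost: float = 0.25
    age_slope_single_s_per_year: float = -3.34
    age_slope_multi_s_per_year: float = -2.83
    per_card_inspection_median_s: float = 0.85
    inspection_lognormal_sigma: float = 0.5
    child_speed_sigma: float = 0.35
    scan_rate_per_card: float = 0.5
    mismatch_intercept: float = _logit(0.01)
    mismatch_card_slope: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_children < 1:
            raise ValueError("n_children must be positive")
        weights = {int(a): float(w) for a, w in self.age_weights.items()}
        if not weights or any(w < 0 for w in weights.values()) or sum(weights.values()) <= 0:
            raise ValueError("age_weights must be non-negative with positive total")
        if any(not AGE_MIN <= a <= AGE_MAX for a in weights):
            raise ValueError(f"age_weights keys must lie in {AGE_MIN}..{AGE_MAX}")
        object.__setattr__(self, "age_weights", weights)
        for name in ("deficit_prevalence", "deficit_severity"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        for name in (
            "deficit_time_multiplier",
            "per_card_inspection_median_s",
            "inspection_lognormal_sigma",
            "scan_rate_per_card",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.child_speed_sigma < 0 or self.deficit_mismatch_boost < 0:
            raise ValueError("sigmas and boosts must be non-negative")
        for version in Version:
            t = self.mean_overall_time_s(AGE_MAX, version)
            if t <= 1.0:
                raise ValueError(
                    f"expected overall time at age {AGE_MAX} ({version.value}) is "
                    f"{t:.2f} s; the configured slope/anchor imply non-physical times"
                )

    # -- analytic calibration -------------------------------------------------

    @property
    def expected_inspections(self) -> float:
        """Expected total card inspections over the five levels (both endpoints
        of a pair search included: 1 + rate*(R-2) per pair with R cards left)."""
        total = 0.0
        for level in range(1, N_LEVELS + 1):
            cards = CARD_COUNTS[level]
            for k in range(level):
                total += 1.0 + self.scan_rate_per_card * (cards - 2 * k - 2)
        return total

    @property
    def base_mean_time_s(self) -> float:
        """Expected overall time at the anchor age (10 y), typical child."""
        mean_inspection = self.per_card_inspection_median_s * math.exp(
            self.inspection_lognormal_sigma**2 / 2
        )
        return self.expected_inspections * mean_inspection

    def slope(self, version: Version) -> float:
        return (
            self.age_slope_single_s_per_year
            if Version(version) is Version.single
            else self.age_slope_multi_s_per_year
        )

    def mean_overall_time_s(self, age: float, version: Version) -> float:
        """Cohort-level expected overall time at an age (linear in age)."""
        return self.base_mean_time_s + self.slope(version) * (np.asarray(age, float) - 10.0)

    def age_speed_factor(self, age: np.ndarray | float, version: Version) -> np.ndarray | float:
        """Multiplicative speed term making E[overall time | age] linear."""
        return self.mean_overall_time_s(age, version) / self.base_mean_time_s

    def mismatch_probability(
        self, n_cards: np.ndarray | int, severity: np.ndarray | float
    ) -> np.ndarray | float:
        """Per-placed-pair probability of a false pair; logistic in severity
        and card count.  ``deficit_mismatch_boost`` is the probability
        increment a full-severity deficit adds at the mid card count (8)."""
        base_logit = self.mismatch_intercept + self.mismatch_card_slope * (
            np.asarray(n_cards, float) - 4.0
        )
        q_mid = _sigmoid(self.mismatch_intercept + self.mismatch_card_slope * 4.0)
        shift = _logit(min(q_mid + self.deficit_mismatch_boost, 0.999)) - _logit(q_mid)
        return _sigmoid(base_logit + np.asarray(severity, float) * shift)

    def to_dict(self) -> dict[str, object]:
        return {
            "n_children": self.n_children,
            "age_weights": {str(a): w for a, w in sorted(self.age_weights.items())},
            "deficit_prevalence": self.deficit_prevalence,
            "deficit_severity": self.deficit_severity,
            "deficit_time_multiplier": self.deficit_time_multiplier,
            "deficit_mismatch_boost": self.deficit_mismatch_boost,
            "age_slope_single_s_per_year": self.age_slope_single_s_per_year,
            "age_slope_multi_s_per_year": self.age_slope_multi_s_per_year,
            "per_card_inspection_median_s": self.per_card_inspection_median_s,
            "inspection_lognormal_sigma": self.inspection_lognormal_sigma,
            "child_speed_sigma": self.child_speed_sigma,
            "scan_rate_per_card": self.scan_rate_per_card,
            "mismatch_intercept": self.mismatch_intercept,
            "mismatch_card_slope": self.mismatch_card_slope,
            "seed": self.seed,
        }


def _simulate_version_batch(
    ages: np.ndarray,
    severities: np.ndarray,
    speed_factors: np.ndarray,
    version: Version,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Vectorized serial-search draws for a batch of children, one version.

    Returns per-level arrays ``level_time[level][child]``,
    ``dwell[level][child]`` and ``n_correct[level][child]`` (times rounded
    to milliseconds; invariants dwell <= level time and dwell > 0 hold by
    construction).
    """
    n = ages.size
    deficit_mult = 1.0 + severities * (cfg.deficit_time_multiplier - 1.0)
    median = (
        cfg.per_card_inspection_median_s
        * np.asarray(cfg.age_speed_factor(ages, version), float)
        * deficit_mult
        * speed_factors
    )
    log_median = np.log(median)
    sigma = cfg.inspection_lognormal_sigma

    level_time = np.zeros((N_LEVELS, n))
    dwell = np.zeros((N_LEVELS, n))
    n_correct = np.zeros((N_LEVELS, n), dtype=int)

    for level in range(1, N_LEVELS + 1):
        cards = CARD_COUNTS[level]
        total = np.zeros(n)
        for pair_k in range(level):
            remaining = cards - 2 * pair_k
            lam = cfg.scan_rate_per_card * (remaining - 2)
            counts = 1 + rng.poisson(lam, size=n)
            draws = rng.standard_normal(int(counts.sum()))
            times = np.exp(np.repeat(log_median, counts) + sigma * draws)
            offsets = np.concatenate(([0], np.cumsum(counts)[:-1]))
            pair_time = np.add.reduceat(times, offsets)
            total += pair_time
            if pair_k == 0:
                dwell[level - 1] = pair_time
        level_time[level - 1] = total
        q = np.asarray(cfg.mismatch_probability(cards, severities), float)
        wrong = rng.binomial(level, q)
        n_correct[level - 1] = level - wrong

    dwell = np.maximum(np.round(dwell, 3), 0.001)
    level_time = np.maximum(np.round(level_time, 3), dwell)
    return {"level_time": level_time, "dwell": dwell, "n_correct": n_correct}


def _runs_from_batch(
    children: Sequence[ChildRecord],
    version: Version,
    batch: dict[str, np.ndarray],
) -> list[AssessmentRun]:
    runs = []
    for i, child in enumerate(children):
        levels = tuple(
            LevelResult(
                level_index=level,
                dwell_time_s=float(batch["dwell"][level - 1, i]),
                level_time_s=float(batch["level_time"][level - 1, i]),
                n_correct_pairs=int(batch["n_correct"][level - 1, i]),
            )
            for level in range(1, N_LEVELS + 1)
        )
        runs.append(AssessmentRun.from_levels(child, version, levels))
    return runs


def simulate_run(
    profile: LatentProfile,
    age: int,
    version: Version | str,
    rng: np.random.Generator,
    config: SimulationConfig | None = None,
    child: ChildRecord | None = None,
    speed_factor: float = 1.0,
) -> AssessmentRun:
    """Simulate a single run for one child.

    ``speed_factor`` is the child's latent speed multiplier (1.0 = cohort
    average); :func:`simulate_cohort` draws it once per child so the two
    versions correlate.
    """
    cfg = config or SimulationConfig()
    if not AGE_MIN <= age <= AGE_MAX:
        raise ValueError(f"age={age} outside the studied range {AGE_MIN}-{AGE_MAX}")
    if child is None:
        child = ChildRecord(
            child_id="sim",
            age_years=int(age),
            truth_label=TruthLabel.deficit if profile.deficit else TruthLabel.typical,
        )
    batch = _simulate_version_batch(
        ages=np.array([age], dtype=float),
        severities=np.array([profile.severity]),
        speed_factors=np.array([speed_factor]),
        version=Version(version),
        cfg=cfg,
        rng=rng,
    )
    return _runs_from_batch([child], Version(version), batch)[0]


def simulate_cohort(
    config: SimulationConfig | None = None,
) -> tuple[list[PairedAssessment], dict[str, TruthLabel]]:
    """Simulate a full cohort, both versions per child.

    Returns the cohort and the per-child truth labels (also embedded in each
    :class:`ChildRecord`).  Identical config (including seed) reproduces the
    cohort exactly.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_children

    age_values = np.array(sorted(cfg.age_weights), dtype=int)
    weights = np.array([cfg.age_weights[a] for a in age_values], dtype=float)
    ages = rng.choice(age_values, size=n, p=weights / weights.sum())
    deficit = rng.random(n) < cfg.deficit_prevalence
    severities = np.where(deficit, cfg.deficit_severity, 0.0)
    speed = rng.lognormal(
        mean=-cfg.child_speed_sigma**2 / 2, sigma=cfg.child_speed_sigma, size=n
    ) if cfg.child_speed_sigma > 0 else np.ones(n)

    width = max(4, len(str(n)))
    children = [
        ChildRecord(
            child_id=f"sim-{i:0{width}d}",
            age_years=int(ages[i]),
            truth_label=TruthLabel.deficit if deficit[i] else TruthLabel.typical,
        )
        for i in range(n)
    ]

    paired: dict[str, dict[Version, AssessmentRun]] = {c.child_id: {} for c in children}
    for version in (Version.multi, Version.single):
        batch = _simulate_version_batch(
            ages.astype(float), severities, speed, version, cfg, rng
        )
        for run in _runs_from_batch(children, version, batch):
            paired[run.child.child_id][version] = run

    cohort = [
        PairedAssessment(
            child=c,
            run_multi=paired[c.child_id][Version.multi],
            run_single=paired[c.child_id][Version.single],
        )
        for c in children
    ]
    truth = {c.child_id: c.truth_label for c in children}
    return cohort, truth


def simulation_manifest(config: SimulationConfig) -> dict[str, object]:
    """Reproducibility manifest: full config, seed and package version."""
    from . import __version__

    return {"config": config.to_dict(), "seed": config.seed, "package_version": __version__}


# ---------------------------------------------------------------------------
# Teddy-bear cancellation test
# ---------------------------------------------------------------------------

_TBCT_ROWS_PER_COLUMN = 15
_TBCT_TARGETS_PER_COLUMN = 3


def generate_tbct_sheet(rng: np.random.Generator) -> TBCTSheet:
    """Generate a sheet with targets distributed proportionally: each of the
    five columns holds 3 targets and 12 distractors, vertical order random."""
    items = []
    for col in range(1, 6):
        is_target = np.zeros(_TBCT_ROWS_PER_COLUMN, dtype=bool)
        is_target[:_TBCT_TARGETS_PER_COLUMN] = True
        rng.shuffle(is_target)
        for row in range(1, _TBCT_ROWS_PER_COLUMN + 1):
            items.append(
                TBCTItem(
                    item_id=f"c{col}r{row:02d}",
                    column=col,
                    row=row,
                    is_target=bool(is_target[row - 1]),
                )
            )
    return TBCTSheet(tuple(items))


def simulate_tbct_response(
    sheet: TBCTSheet,
    profile: LatentProfile,
    rng: np.random.Generator,
    omission_base: float = 0.02,
    omission_severity_gain: float = 0.25,
    lateral_bias: float = 0.0,
    scan_noise: float = 3.0,
) -> TBCTResponse:
    """Simulate which targets a child marks and in what order.

    Per-target omission probability is ``omission_base + severity * gain``,
    modulated by ``lateral_bias`` in [-1, 1]: a positive bias (attention
    drawn rightward) concentrates omissions in the left, negatively-valued
    columns.  Marking order follows a noisy column-wise scan from a start
    column that drifts rightward with severity.
    """
    if not -1.0 <= lateral_bias <= 1.0:
        raise ValueError("lateral_bias must lie in [-1, 1]")
    p_base = omission_base + profile.severity * omission_severity_gain
    marked = []
    for item in sheet.items:
        if not item.is_target:
            continue
        p = np.clip(p_base * (1.0 - lateral_bias * TBCT_COLUMN_NOMINAL[item.column]), 0.0, 1.0)
        if rng.random() >= p:
            marked.append(item)

    # start column: typical children start hard left; severity flattens the bias
    tau = 0.4 + 2.6 * profile.severity
    col_weights = np.exp(-(np.arange(5)) / tau)
    start = int(rng.choice(np.arange(1, 6), p=col_weights / col_weights.sum()))
    scan_order = {c: i for i, c in enumerate(list(range(start, 6)) + list(range(start - 1, 0, -1)))}
    keys = [
        scan_order[item.column] * (_TBCT_ROWS_PER_COLUMN + 5)
        + item.row
        + rng.normal(0.0, scan_noise)
        for item in marked
    ]
    ordered = [item.item_id for _, item in sorted(zip(keys, marked), key=lambda t: t[0])]
    return TBCTResponse(tuple(ordered))


# ---------------------------------------------------------------------------
# Six-letter cancellation task
# ---------------------------------------------------------------------------

_SLCT_DEFAULT_TARGETS = frozenset("AEIMRT")


def generate_slct_grid(
    rng: np.random.Generator, target_letters: frozenset[str] | None = None
) -> SLCTGrid:
    """Generate a 22x14 grid of uniformly random uppercase letters."""
    targets = frozenset(target_letters or _SLCT_DEFAULT_TARGETS)
    if len(targets) != SLCT_N_TARGET_LETTERS:
        raise ValueError(f"need exactly {SLCT_N_TARGET_LETTERS} target letters")
    alphabet = np.array(list(string.ascii_uppercase))
    cells = rng.choice(alphabet, size=(SLCT_ROWS, SLCT_COLS))
    return SLCTGrid(tuple("".join(row) for row in cells), targets)


def simulate_slct_response(
    grid: SLCTGrid,
    profile: LatentProfile,
    rng: np.random.Generator,
    age: int = 12,
    per_item_median_s: float = 0.5,
    sigma: float = 0.4,
    age_speed_per_year: float = 0.05,
    deficit_time_multiplier: float = 2.0,
    miss_base: float = 0.02,
    miss_severity_gain: float = 0.2,
    confusion_base: float = 0.005,
    confusion_severity_gain: float = 0.04,
    time_limit_s: float = SLCT_TIME_LIMIT_S,
) -> SLCTResponse:
    """Simulate a 90-second letter-cancellation response.

    The child scans cells in reading order, spending a lognormal time per
    cell (slower when younger, slower with deficit severity), marking target
    letters with probability ``1 - miss`` and wrongly marking non-targets
    with a severity-dependent confusion probability, until the time budget
    is spent.  With infinite speed, no misses and no confusion the net score
    equals the number of target-letter cells.
    """
    age_factor = max(1.0 + age_speed_per_year * (12 - age), 0.1)
    median = per_item_median_s * age_factor * (
        1.0 + profile.severity * (deficit_time_multiplier - 1.0)
    )
    n_cells = SLCT_ROWS * SLCT_COLS
    times = np.exp(np.log(median) + sigma * rng.standard_normal(n_cells))
    scanned = int(np.searchsorted(np.cumsum(times), time_limit_s, side="right"))
    scanned = min(scanned, n_cells)

    miss = min(miss_base + profile.severity * miss_severity_gain, 1.0)
    confusion = min(confusion_base + profile.severity * confusion_severity_gain, 1.0)
    u = rng.random(n_cells)

    cancellations = []
    for idx in range(scanned):
        row, col = divmod(idx, SLCT_COLS)
        if grid.is_target_cell(row, col):
            if u[idx] >= miss:
                cancellations.append((row, col))
        elif u[idx] < confusion:
            cancellations.append((row, col))
    return SLCTResponse(tuple(cancellations))
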