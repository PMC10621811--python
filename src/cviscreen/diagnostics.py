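"""Agreement and diagnostic-accuracy statistics for binary screen-vs-reference data.

Implements the validation arithmetic used for the screener: Cohen's kappa
with its large-sample null-hypothesis test, and sensitivity/specificity with
Wald (normal-approximation) confidence intervals.

Conventions
-----------
For a 2x2 table with cells ``a`` (reference+, index+), ``b`` (reference+,
index-), ``c`` (reference-, index+), ``d`` (reference-, index-) and
``n = a+b+c+d``:

* observed agreement ``po = (a + d) / n``;
* chance agreement ``pe`` from the products of row and column marginal
  proportions;
* ``kappa = (po - pe) / (1 - pe)``;
* the null standard error is the marginal-based (Fleiss) form

  ``se0 = sqrt(pe + pe^2 - sum_i p_i. p_.i (p_i. + p_.i)) / ((1 - pe) sqrt(n))``

  giving ``z = kappa / se0`` and a two-sided normal p-value with no
  continuity correction;
* ``sensitivity = a / (a + b)``, ``specificity = d / (c + d)``, each with the
  Wald interval ``p +/- z * sqrt(p (1 - p) / m)`` reported *unclipped* (the
  bounds may leave [0, 1]; this is deliberate and noted in reports).

Kappa bands follow the Landis-Koch scale.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "KappaBand",
    "AgreementStats",
    "BinomialRate",
    "build_contingency",
    "cohen_kappa",
    "sensitivity_specificity",
    "interpret_kappa",
    "grouped_agreement",
]


class KappaBand(str, enum.Enum):
    poor = "poor"
    slight = "slight"
    fair = "fair"
    moderate = "moderate"
    substantial = "substantial"
    almost_perfect = "almost_perfect"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Reference-vs-index cross-classification counts.

    ``a``: reference+/index+, ``b``: reference+/index-,
    ``c``: reference-/index+, ``d``: reference-/index-.
    """

    a: int
    b: int
    c: int
    d: int
    reference_label: str = "reference"
    index_label: str = "index"

    def __post_init__(self) -> None:
        for name in "abcd":
            count = getattr(self, name)
            if not isinstance(count, (int, np.integer)) or count < 0:
                raise ValueError(f"cell {name!r} must be a non-negative integer, got {count!r}")
        if self.n < 1:
            raise ValueError("contingency table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def transposed(self) -> "ContingencyTable2x2":
        """Swap the roles of reference and index test."""
        return ContingencyTable2x2(
            self.a, self.c, self.b, self.d,
            reference_label=self.index_label, index_label=self.reference_label,
        )

    def to_dict(self) -> dict[str, object]:
        return {
            "a": int(self.a), "b": int(self.b), "c": int(self.c), "d": int(self.d),
            "n": self.n,
            "reference": self.reference_label,
            "index": self.index_label,
        }


@dataclass(frozen=True)
class AgreementStats:
    kappa: float
    po: float
    pe: float
    se0: float | None
    z: float | None
    p_value: float | None
    n: int
    band: KappaBand
    degenerate: bool = False

    def to_dict(self) -> dict[str, object]:
        return {
            "kappa": self.kappa, "po": self.po, "pe": self.pe,
            "se0": self.se0, "z": self.z, "p_value": self.p_value,
            "n": self.n, "band": self.band.value, "degenerate": self.degenerate,
        }


@dataclass(frozen=True)
class BinomialRate:
    """A proportion with a Wald confidence interval (bounds unclipped)."""

    estimate: float
    ci_low: float
    ci_high: float
    numerator: int
    denominator: int
    z_level: float = 1.96

    def to_dict(self) -> dict[str, object]:
        return {
            "estimate": self.estimate,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "numerator": self.numerator, "denominator": self.denominator,
            "z_level": self.z_level,
        }


def build_contingency(
    reference_flags: Mapping[str, bool],
    index_flags: Mapping[str, bool],
    *,
    reference_label: str = "reference",
    index_label: str = "index",
) -> ContingencyTable2x2:
    """Cross-classify per-child boolean flags from two tests.

    Both mappings must cover exactly the same children.
    """
    if not reference_flags:
        raise ValueError("empty input: no children to cross-classify")
    if set(reference_flags) != set(index_flags):
        extra_ref = sorted(set(reference_flags) - set(index_flags))[:5]
        extra_idx = sorted(set(index_flags) - set(reference_flags))[:5]
        raise ValueError(
            f"mismatched child sets (only in reference: {extra_ref}, "
            f"only in index: {extra_idx})"
        )
    a = b = c = d = 0
    for child, ref in reference_flags.items():
        idx = index_flags[child]
        if ref and idx:
            a += 1
        elif ref:
            b += 1
        elif idx:
            c += 1
        else:
            d += 1
    return ContingencyTable2x2(a, b, c, d, reference_label=reference_label, index_label=index_label)


def interpret_kappa(kappa: float) -> KappaBand:
    """Landis-Koch interpretation band for a kappa value."""
    if not -1 - 1e-9 <= kappa <= 1 + 1e-9:
        raise ValueError(f"kappa={kappa} outside [-1, 1]")
    if kappa < 0:
        return KappaBand.poor
    if kappa <= 0.20:
        return KappaBand.slight
    if kappa <= 0.40:
        return KappaBand.fair
    if kappa <= 0.60:
        return KappaBand.moderate
    if kappa <= 0.80:
        return KappaBand.substantial
    return KappaBand.almost_perfect


def cohen_kappa(table: ContingencyTable2x2) -> AgreementStats:
    """Cohen's kappa with the marginal-based null-hypothesis test.

    When the chance agreement ``pe`` is 1 (both margins degenerate) kappa is
    defined as 1 for perfect observed agreement and 0 otherwise, flagged
    ``degenerate``; the standard error is then undefined and reported as None.
    """
    n = table.n
    po = (table.a + table.d) / n
    p_row = np.array([table.a + table.b, table.c + table.d]) / n  # reference margins
    p_col = np.array([table.a + table.c, table.b + table.d]) / n  # index margins
    pe = float(p_row @ p_col)

    if math.isclose(pe, 1.0, abs_tol=1e-12):
        kappa = 1.0 if math.isclose(po, 1.0, abs_tol=1e-12) else 0.0
        return AgreementStats(
            kappa=kappa, po=po, pe=pe, se0=None, z=None, p_value=None,
            n=n, band=interpret_kappa(kappa), degenerate=True,
        )

    kappa = (po - pe) / (1 - pe)
    var_num = pe + pe**2 - float(np.sum(p_row * p_col * (p_row + p_col)))
    se0 = math.sqrt(max(var_num, 0.0)) / ((1 - pe) * math.sqrt(n))
    if se0 == 0.0:
        z = p_value = None
    else:
        z = kappa / se0
        p_value = 2 * stats.norm.sf(abs(z))
    return AgreementStats(
        kappa=kappa, po=po, pe=pe, se0=se0, z=z, p_value=p_value,
        n=n, band=interpret_kappa(kappa),
    )


def _wald_rate(numerator: int, denominator: int, z_level: float) -> BinomialRate:
    p = numerator / denominator
    half = z_level * math.sqrt(p * (1 - p) / denominator)
    return BinomialRate(
        estimate=p, ci_low=p - half, ci_high=p + half,
        numerator=numerator, denominator=denominator, z_level=z_level,
    )


def sensitivity_specificity(
    table: ContingencyTable2x2, z_level: float = 1.96
) -> tuple[BinomialRate | None, BinomialRate | None]:
    """Sensitivity ``a/(a+b)`` and specificity ``d/(c+d)`` with Wald intervals.

    A rate whose reference margin is empty is undefined and returned as None.
    Interval bounds are deliberately not clipped to [0, 1].
    """
    pos = table.a + table.b
    neg = table.c + table.d
    sens = _wald_rate(table.a, pos, z_level) if pos else None
    spec = _wald_rate(table.d, neg, z_level) if neg else None
    return sens, spec


def grouped_agreement(
    reference_flags: Mapping[str, bool],
    index_flags: Mapping[str, bool],
    groups: Mapping[str, str],
    *,
    reference_label: str = "reference",
    index_label: str = "index",
    z_level: float = 1.96,
) -> dict[str, dict[str, object]]:
    """Per-group validation report: 2x2 counts, kappa block, rate blocks.

    ``groups`` maps each child id to a group label (e.g. an age band); the
    child sets of all three mappings must coincide.
    """
    if set(groups) != set(reference_flags):
        raise ValueError("groups must cover exactly the children in the flag mappings")
    report: dict[str, dict[str, object]] = {}
    for label in sorted(set(groups.values())):
        members = [cid for cid, g in groups.items() if g == label]
        table = build_contingency(
            {cid: reference_flags[cid] for cid in members},
            {cid: index_flags[cid] for cid in members},
            reference_label=reference_label,
            index_label=index_label,
        )
        sens, spec = sensitivity_specificity(table, z_level=z_level)
        report[label] = {
            "table": table.to_dict(),
            "kappa": cohen_kappa(table).to_dict(),
            "sensitivity": sens.to_dict() if sens else None,
            "specificity": spec.to_dict() if spec else None,
            "note": "Wald interval bounds are reported unclipped and may leave [0, 1].",
        }
    return report
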