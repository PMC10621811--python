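"""Printed tables from the published validation study of the screener.

These small tables are the study's public inputs: the age composition of the
724-child normative cohort, the follow-up vision-assessment findings for the
23 children flagged in the school screening phase, and the 2x2
cross-classifications from the diagnostic-validation phase (screener vs
cancellation test, and screener vs known-condition status).  They let the
agreement and diagnostic-accuracy statistics be recomputed exactly.
"""

from __future__ import annotations

import pandas as pd

from .diagnostics import ContingencyTable2x2

__all__ = [
    "normative_cohort_age_counts",
    "followup_findings",
    "screener_vs_cancellation_tables",
    "screener_vs_condition_tables",
]


def normative_cohort_age_counts() -> dict[int, int]:
    """Number of children per completed year of age in the normative cohort (n=724)."""
    counts = dict(
        zip(
            range(5, 19),
            [58, 97, 67, 70, 70, 50, 77, 72, 43, 35, 28, 24, 27, 6],
        )
    )
    assert sum(counts.values()) == 724
    return counts


def followup_findings() -> pd.DataFrame:
    """Follow-up vision assessments for the 23 children flagged by screening.

    Columns: ``child`` (1-based id), ``age``, ``hvfqi_score`` (total over the
    11-question parental inventory; NA where the informant could not answer),
    ``checklist_criteria_met`` (0-3 criteria of the three-part CVI checklist:
    risk factor, atypical visual behaviors, verifiable dysfunction; NA for
    children with no clinical findings, for whom no checklist was reported)
    and ``clinical_findings`` (whether the assessment found a verifiable
    reason for the out-of-norm screener result).
    """
    rows = [
        # child, age, hvfqi, checklist, findings
        (1, 12, 30, 3, True),
        (2, 6, 26, 2, True),
        (3, 5, 26, 2, True),
        (4, 10, 24, 3, True),
        (5, 8, 21, 2, True),
        (6, 7, 21, 2, True),
        (7, 7, 15, 2, True),
        (8, 7, 8, 1, True),
        (9, 8, 6, 3, True),
        (10, 5, 5, 1, True),
        (11, 5, 4, 1, True),
        (12, 10, 17, 3, True),
        (13, 6, 12, 1, True),
        (14, 5, 10, 1, True),
        (15, 12, 8, 1, True),
        (16, 7, 2, 1, True),
        (17, 6, None, 3, True),
        (18, 7, 15, None, False),
        (19, 8, 12, None, False),
        (20, 8, 11, None, False),
        (21, 5, 8, None, False),
        (22, 7, 7, None, False),
        (23, 6, 2, None, False),
    ]
    return pd.DataFrame(
        rows,
        columns=["child", "age", "hvfqi_score", "checklist_criteria_met", "clinical_findings"],
    ).astype({"hvfqi_score": "Int64", "checklist_criteria_met": "Int64"})


def screener_vs_cancellation_tables() -> dict[str, ContingencyTable2x2]:
    """Validation-phase 2x2 tables: cancellation test (reference) vs screener (index).

    The 5-8 group was compared against the teddy-bear cancellation test and
    the older groups against the six-letter cancellation task.
    """
    def table(a: int, b: int, c: int, d: int, ref: str) -> ContingencyTable2x2:
        return ContingencyTable2x2(a, b, c, d, reference_label=ref, index_label="screener")

    return {
        "5-8": table(8, 3, 24, 18, "TBCT"),
        "9-12": table(3, 0, 5, 55, "SLCT"),
        "13-18": table(6, 2, 8, 17, "SLCT"),
    }


def screener_vs_condition_tables() -> dict[str, ContingencyTable2x2]:
    """Validation-phase 2x2 tables: known-condition status (reference) vs screener.

    Neurodiverse-only participants were excluded from this comparison in the
    source study as their condition could not be equated with a pre-existing
    visual issue.
    """
    def table(a: int, b: int, c: int, d: int) -> ContingencyTable2x2:
        return ContingencyTable2x2(
            a, b, c, d, reference_label="known condition", index_label="screener"
        )

    return {
        "5-8": table(18, 3, 7, 6),
        "9-12": table(8, 7, 0, 21),
        "13-18": table(8, 3, 1, 4),
    }
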