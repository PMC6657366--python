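"""Cohort table schema and CSV round-trip.

A cohort table is a :class:`pandas.DataFrame` with a fixed set of leading
columns followed by one column per cytokine (concentrations in pg/mL).
Missing clinical values (controls, or reconstructed subjects for whom only
cytokines are known) are stored as NaN and written as empty CSV fields.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np
import pandas as pd

#: Fixed non-cytokine columns, in on-disk order.
BASE_COLUMNS: List[str] = [
    "subject_id",
    "cohort",
    "status",
    "course",
    "age",
    "gender",
    "duration",
    "edss",
    "msss",
    "treatment",
]

STATUS_MS = "MS"
STATUS_CONTROL = "control"

COURSE_RR = "relapsing_remitting"
COURSE_SP = "secondary_progressive"
COURSE_PP = "primary_progressive"
COURSE_NONE = "none"
COURSES = (COURSE_RR, COURSE_SP, COURSE_PP)

REMITTING = "remitting"
NON_REMITTING = "non_remitting"

#: The eight-analyte serum panel; the two optional extras extend it.
CORE_CYTOKINES: List[str] = [
    "IL1b", "IL2", "IL4", "IL8", "IL10", "IL13", "IFNg", "TNFa",
]
EXTENDED_CYTOKINES: List[str] = CORE_CYTOKINES[:4] + ["IL6"] + CORE_CYTOKINES[4:] + ["IFNa"]


def cytokine_columns(table: pd.DataFrame) -> List[str]:
    """Return the cytokine columns of *table* (everything after the base set)."""
    return [c for c in table.columns if c not in BASE_COLUMNS]


def remitting_label(course: str) -> str:
    """Collapse an MS course into the remitting / non-remitting dichotomy.

    Relapsing-remitting MS is 'remitting'; the two progressive courses are
    'non_remitting'; controls (course 'none') get 'n/a'.
    """
    if course == COURSE_RR:
        return REMITTING
    if course in (COURSE_SP, COURSE_PP):
        return NON_REMITTING
    return "n/a"


def with_remitting_labels(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of *table* with a derived ``remitting`` column."""
    out = table.copy()
    out["remitting"] = out["course"].map(remitting_label)
    return out


def validate_cohort_table(table: pd.DataFrame) -> None:
    """Check the structural invariants of a cohort table.

    Raises ``ValueError`` naming the first violated constraint: base columns
    present, known status labels, controls carrying course 'none', MS rows
    carrying a real course.
    """
    missing = [c for c in BASE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    bad_status = set(table["status"]) - {STATUS_MS, STATUS_CONTROL}
    if bad_status:
        raise ValueError(f"unknown status labels: {sorted(bad_status)}")
    ctrl = table[table["status"] == STATUS_CONTROL]
    if not (ctrl["course"] == COURSE_NONE).all():
        raise ValueError("control records must have course 'none'")
    ms = table[table["status"] == STATUS_MS]
    # Reconstructed subjects carry no clinical record, hence course may be
    # 'none' even for MS; anything else must be a real course.
    bad_course = set(ms["course"]) - set(COURSES) - {COURSE_NONE}
    if bad_course:
        raise ValueError(f"MS records with invalid course: {sorted(bad_course)}")


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV with empty fields for missing values."""
    cols = BASE_COLUMNS + cytokine_columns(table)
    table.loc[:, cols].to_csv(path, index=False, na_rep="")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort table CSV written by :func:`write_cohort_csv`."""
    table = pd.read_csv(path, dtype={"subject_id": str, "cohort": str})
    validate_cohort_table(table)
    return table


def concat_cohorts(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Stack cohort tables; all must share the same cytokine panel."""
    panels = {tuple(cytokine_columns(t)) for t in tables}
    if len(panels) > 1:
        raise ValueError(f"cohorts carry different cytokine panels: {panels}")
    out = pd.concat(tables, ignore_index=True)
    if out["subject_id"].duplicated().any():
        dups = out.loc[out["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids across cohorts: {dups[:5]}")
    return out


def class_counts(table: pd.DataFrame, label_column: str = "status") -> dict:
    """Count records per class label."""
    return table[label_column].value_counts().to_dict()


def empty_clinical_row() -> dict:
    """Clinical covariates of a record for which only cytokines are known."""
    return {
        "course": COURSE_NONE,
        "age": np.nan,
        "gender": "",
        "duration": np.nan,
        "edss": np.nan,
        "msss": np.nan,
        "treatment": np.nan,
    }
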