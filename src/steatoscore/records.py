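"""Subject records: the canonical per-person input row, validation and CSV I/O.

A cohort is a :class:`pandas.DataFrame` with the canonical columns listed in
:data:`CANONICAL_COLUMNS`; :class:`SubjectRecord` is the single-row view used
by the scalar scoring API. All analytes are stored in mg/dL, enzymes in U/L,
anthropometrics in cm/kg; unit conversions happen inside the score formulas.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InputError

#: Canonical cohort columns. Optional columns may be absent or empty.
CANONICAL_COLUMNS = [
    "subject_id",
    "sex",            # "male" / "female"
    "age",            # years
    "height",         # cm
    "weight",         # kg
    "waist",          # cm
    "hip",            # cm
    "sbp",            # mmHg
    "dbp",            # mmHg
    "glucose",        # mg/dL, fasting
    "total_chol",     # mg/dL
    "hdl",            # mg/dL
    "ldl",            # mg/dL (optional; recomputed via Friedewald when absent)
    "triglycerides",  # mg/dL
    "ggt",            # U/L
    "ast",            # U/L
    "alt",            # U/L
    "body_fat_pct",   # %
    "visceral_fat_rating",  # Tanita-style integer rating
    "diabetes",       # bool
    "smoker",         # bool, optional
    "social_class",   # "I"/"II"/"III", optional
    "physical_activity",  # "none"/"1-3"/">3" days per week, optional
]

OPTIONAL_COLUMNS = {"ldl", "smoker", "social_class", "physical_activity",
                    "hip", "subject_id"}

#: Study inclusion window for age, configurable off in validation.
AGE_RANGE = (18, 69)


@dataclass
class SubjectRecord:
    """One person's raw measurements and flags."""

    sex: str
    age: int
    height: float
    weight: float
    waist: float
    sbp: float
    dbp: float
    glucose: float
    total_chol: float
    hdl: float
    triglycerides: float
    ggt: float
    ast: float
    alt: float
    body_fat_pct: float
    visceral_fat_rating: float
    diabetes: bool = False
    hip: float | None = None
    ldl: float | None = None
    smoker: bool | None = None
    social_class: str | None = None
    physical_activity: str | None = None
    subject_id: str = ""

    def validate(self, enforce_age_range: bool = True) -> list[str]:
        """Return a list of violated invariants (empty when valid)."""
        problems = []
        if self.sex not in ("male", "female"):
            problems.append("sex must be 'male' or 'female'")
        if enforce_age_range and not (AGE_RANGE[0] <= self.age <= AGE_RANGE[1]):
            problems.append(f"age {self.age} outside {AGE_RANGE[0]}-{AGE_RANGE[1]}")
        for name in ("height", "weight", "waist"):
            if not getattr(self, name) > 0:
                problems.append(f"{name} must be > 0")
        for name in ("glucose", "total_chol", "hdl", "triglycerides",
                     "ggt", "ast", "alt"):
            if not getattr(self, name) > 0:
                problems.append(f"{name} must be > 0 (log transforms apply)")
        if not (0 <= self.body_fat_pct < 100):
            problems.append("body_fat_pct must be in [0, 100)")
        if self.visceral_fat_rating < 0:
            problems.append("visceral_fat_rating must be >= 0")
        return problems


_RECORD_FIELDS = [f.name for f in fields(SubjectRecord)]


def record_from_row(row: Mapping) -> SubjectRecord:
    """Build a :class:`SubjectRecord` from a cohort-table row."""
    kwargs = {}
    for name in _RECORD_FIELDS:
        if name in row and not (isinstance(row[name], float) and np.isnan(row[name])):
            kwargs[name] = row[name]
    return SubjectRecord(**kwargs)


# validation rule ids applied column-wise to a cohort frame
_NUMERIC_POSITIVE = ["height", "weight", "waist", "glucose", "total_chol",
                     "hdl", "triglycerides", "ggt", "ast", "alt"]


def validate_cohort(
    frame: pd.DataFrame,
    enforce_age_range: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate a cohort table against the record invariants.

    Returns ``(valid_rows, rejection_log)`` where the log has one row per
    (subject, violated rule) with columns ``row``, ``rule``, ``detail``.
    """
    entries: list[tuple[int, str, str]] = []

    def flag(mask: pd.Series, rule: str, detail: str) -> None:
        for idx in frame.index[mask.fillna(True).astype(bool)]:
            entries.append((idx, rule, detail))

    missing = [c for c in CANONICAL_COLUMNS
               if c not in frame.columns and c not in OPTIONAL_COLUMNS]
    if missing:
        raise InputError(f"missing required columns: {missing}")

    flag(~frame["sex"].isin(["male", "female"]), "sex", "sex not male/female")
    if enforce_age_range:
        flag(~frame["age"].between(*AGE_RANGE), "age_range",
             f"age outside {AGE_RANGE[0]}-{AGE_RANGE[1]}")
    for col in _NUMERIC_POSITIVE:
        flag(~(pd.to_numeric(frame[col], errors="coerce") > 0),
             f"{col}_positive", f"{col} must be > 0")
    flag(~(pd.to_numeric(frame["body_fat_pct"], errors="coerce")
           .between(0, 100, inclusive="left")),
         "body_fat_range", "body_fat_pct must be in [0, 100)")
    flag(~(pd.to_numeric(frame["visceral_fat_rating"], errors="coerce") >= 0),
         "visceral_fat_range", "visceral_fat_rating must be >= 0")

    log = pd.DataFrame(entries, columns=["row", "rule", "detail"])
    bad_rows = set(log["row"])
    valid = frame.loc[[i for i in frame.index if i not in bad_rows]].copy()
    return valid, log


def read_cohort(
    path,
    column_map: Mapping[str, str] | None = None,
    enforce_age_range: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a cohort CSV, apply an optional ``{file column -> canonical}``
    rename, validate, and return ``(valid_rows, rejection_log)``.

    Raises :class:`InputError` on an empty file or when more than half of
    the rows are rejected (a rate that usually means mis-mapped columns).
    """
    frame = pd.read_csv(path)
    if frame.empty:
        raise InputError(f"{path}: no data rows")
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    for col in ("diabetes", "smoker"):
        if col in frame.columns and frame[col].dtype == object:
            frame[col] = frame[col].map(
                {"True": True, "False": False, "1": True, "0": False,
                 True: True, False: False})
    valid, log = validate_cohort(frame, enforce_age_range=enforce_age_range)
    if len(valid) < 0.5 * len(frame):
        raise InputError(
            f"{path}: {len(frame) - len(valid)} of {len(frame)} rows rejected; "
            "check the column mapping")
    return valid, log


def write_cohort(frame: pd.DataFrame, path) -> None:
    """Write a cohort table as canonical CSV (UTF-8, header row)."""
    cols = [c for c in CANONICAL_COLUMNS if c in frame.columns]
    frame.to_csv(path, index=False, columns=cols)
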