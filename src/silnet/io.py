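"""Reading and writing cohorts as delimited text.

A cohort directory holds ``students.csv`` (one row per respondent, header
row, comma separated, empty cell = missing) and ``edges.csv`` (columns
``ego_id, alter_id``).  ``write_cohort`` followed by ``read_cohort`` is the
identity on every field, including missingness.
"""

from __future__ import annotations

import os
from typing import Optional, Sequence

import pandas as pd

from .types import NominationEdge, StudentRecord, validate_cohort

STUDENT_COLUMNS = [
    "student_id", "school_id", "country", "grade", "sex", "age",
    "father_edu", "mother_edu", "subjective_rank", "father_working",
    "mother_working", "fas_ratio", "housing", "tried_smoking",
    "regular_smoker", "dependence_score", "household_smokers",
]

_BOOL_FIELDS = ("father_working", "mother_working", "tried_smoking",
                "regular_smoker")
_OPTIONAL_FIELDS = ("father_edu", "mother_edu", "subjective_rank",
                    "father_working", "mother_working", "fas_ratio")


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def cohort_to_frames(records: Sequence[StudentRecord],
                     edges: Sequence[NominationEdge]):
    students = pd.DataFrame(
        [{c: _fmt(getattr(r, c)) for c in STUDENT_COLUMNS} for r in records],
        columns=STUDENT_COLUMNS,
    )
    edge_df = pd.DataFrame(
        [{"ego_id": e.ego_id, "alter_id": e.alter_id} for e in edges],
        columns=["ego_id", "alter_id"],
    )
    return students, edge_df


def write_cohort(records: Sequence[StudentRecord],
                 edges: Sequence[NominationEdge], path: str) -> None:
    """Write students.csv and edges.csv under ``path`` (created if needed)."""
    validate_cohort(records, edges)
    os.makedirs(path, exist_ok=True)
    students, edge_df = cohort_to_frames(records, edges)
    students.to_csv(os.path.join(path, "students.csv"), index=False)
    edge_df.to_csv(os.path.join(path, "edges.csv"), index=False)


def _parse_bool(text: str, row: int, col: str) -> bool:
    if text == "true":
        return True
    if text == "false":
        return False
    raise ValueError(f"students.csv row {row}: bad boolean {text!r} in {col}")


def _parse_student(row_values: dict, row: int) -> StudentRecord:
    def get(col):
        v = row_values.get(col, "")
        return "" if v is None else str(v)

    def opt(col, parse):
        v = get(col)
        return None if v == "" else parse(v)

    try:
        return StudentRecord(
            student_id=get("student_id"),
            school_id=get("school_id"),
            country=get("country"),
            grade=int(get("grade")),
            sex=get("sex"),
            age=int(get("age")),
            father_edu=opt("father_edu", str),
            mother_edu=opt("mother_edu", str),
            subjective_rank=opt("subjective_rank", int),
            father_working=opt("father_working",
                               lambda v: _parse_bool(v, row, "father_working")),
            mother_working=opt("mother_working",
                               lambda v: _parse_bool(v, row, "mother_working")),
            fas_ratio=opt("fas_ratio", float),
            housing=get("housing"),
            tried_smoking=_parse_bool(get("tried_smoking"), row, "tried_smoking"),
            regular_smoker=_parse_bool(get("regular_smoker"), row,
                                       "regular_smoker"),
            dependence_score=int(get("dependence_score")),
            household_smokers=int(get("household_smokers")),
        )
    except ValueError as err:
        raise ValueError(f"students.csv row {row}: {err}") from err


def read_cohort(path: str):
    """Read a cohort directory; validates and returns (records, edges)."""
    students_path = os.path.join(path, "students.csv")
    edges_path = os.path.join(path, "edges.csv")
    for p in (students_path, edges_path):
        if not os.path.exists(p):
            raise FileNotFoundError(f"missing cohort file: {p}")
    students = pd.read_csv(students_path, dtype=str, keep_default_na=False)
    missing_cols = set(STUDENT_COLUMNS) - set(students.columns)
    if missing_cols:
        raise ValueError(f"students.csv lacks columns {sorted(missing_cols)}")
    records = [
        _parse_student(row, i + 2)  # +2: header row is line 1
        for i, row in enumerate(students.to_dict("records"))
    ]
    edge_df = pd.read_csv(edges_path, dtype=str, keep_default_na=False)
    if list(edge_df.columns) != ["ego_id", "alter_id"]:
        raise ValueError("edges.csv must have columns ego_id, alter_id")
    edges = []
    for i, row in enumerate(edge_df.to_dict("records")):
        try:
            edges.append(NominationEdge(row["ego_id"], row["alter_id"]))
        except ValueError as err:
            raise ValueError(f"edges.csv row {i + 2}: {err}") from err
    try:
        validate_cohort(records, edges)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err
    return records, edges


def write_table(df: pd.DataFrame, path: str) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, index=False)


def read_metrics_table(path: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(f"missing metrics table: {path}")
    return pd.read_csv(path)
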