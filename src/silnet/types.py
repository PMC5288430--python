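"""Core record types for the school smoking-network analysis.

A cohort is a list of :class:`StudentRecord` (one per respondent) plus a
list of :class:`NominationEdge` (directed "best friend" nominations, at most
five per ego, confined to the ego's school).  Fields that the survey allows
to be missing are ``Optional`` and hold ``None`` until the imputation step
fills them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

EDUCATION_LEVELS = ("low", "medium", "high", "unknown")
HOUSING_LEVELS = ("owner", "tenant")
SEX_LEVELS = ("female", "male")

#: SES indicators that can contribute to the "number of lowest categories"
#: composite (seven indicators, capped at the "5+" band for reporting).
SES_INDICATORS = (
    "father_edu",
    "mother_edu",
    "subjective_rank",
    "father_working",
    "mother_working",
    "fas_ratio",
    "housing",
)


@dataclass
class StudentRecord:
    """One adolescent's attributes, SES indicators and smoking outcomes."""

    student_id: str
    school_id: str
    country: str
    grade: int                       # 1 or 2 (the two surveyed grades)
    sex: str                         # "female" | "male"
    age: int                         # years, 13..18
    father_edu: Optional[str]        # low/medium/high/unknown, None = missing
    mother_edu: Optional[str]
    subjective_rank: Optional[int]   # MacArthur ladder 1..10, None = missing
    father_working: Optional[bool]
    mother_working: Optional[bool]
    fas_ratio: Optional[float]       # family affluence / national mean, > 0
    housing: str                     # "owner" | "tenant"
    tried_smoking: bool
    regular_smoker: bool
    dependence_score: int            # Stanford nicotine dependence, 0..25
    household_smokers: int           # smokers in the household, >= 0
    imputed_fields: frozenset = field(default_factory=frozenset)

    def validate(self) -> None:
        if self.grade not in (1, 2):
            raise ValueError(f"{self.student_id}: grade must be 1 or 2")
        if self.sex not in SEX_LEVELS:
            raise ValueError(f"{self.student_id}: bad sex {self.sex!r}")
        if not 13 <= self.age <= 18:
            raise ValueError(f"{self.student_id}: age {self.age} outside 13-18")
        for f in ("father_edu", "mother_edu"):
            v = getattr(self, f)
            if v is not None and v not in EDUCATION_LEVELS:
                raise ValueError(f"{self.student_id}: bad {f} {v!r}")
        if self.subjective_rank is not None and not 1 <= self.subjective_rank <= 10:
            raise ValueError(f"{self.student_id}: subjective_rank outside 1-10")
        if self.fas_ratio is not None and self.fas_ratio <= 0:
            raise ValueError(f"{self.student_id}: fas_ratio must be > 0")
        if self.housing not in HOUSING_LEVELS:
            raise ValueError(f"{self.student_id}: bad housing {self.housing!r}")
        if self.regular_smoker and not self.tried_smoking:
            raise ValueError(f"{self.student_id}: regular smoker who never tried")
        if not 0 <= self.dependence_score <= 25:
            raise ValueError(f"{self.student_id}: dependence outside 0-25")
        if self.dependence_score > 0 and not self.tried_smoking:
            raise ValueError(f"{self.student_id}: dependence > 0 without trying")
        if self.household_smokers < 0:
            raise ValueError(f"{self.student_id}: negative household smokers")

    def with_updates(self, **kwargs) -> "StudentRecord":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class NominationEdge:
    """A directed friendship nomination ego -> alter (same school)."""

    ego_id: str
    alter_id: str

    def __post_init__(self):
        if self.ego_id == self.alter_id:
            raise ValueError(f"self-nomination by {self.ego_id}")


@dataclass
class SESComposite:
    """Composite deprivation score: number of lowest-category memberships."""

    student_id: str
    lowest_count: int                # 0..7 over the seven indicators
    lowest_count_banded: str         # "0".."4", "5+"
    fas_band: str                    # "<=60%", "61-90%", "91-120%", ">120%"
    imputed_fields: frozenset


def validate_cohort(records, edges, max_nominations: int = 5):
    """Check cohort-level invariants; raise ValueError naming the offender.

    Verifies unique ids, per-record validity, edge endpoints existing and
    sharing a school, no duplicate edges, and the out-degree cap.
    """
    by_id = {}
    for r in records:
        if r.student_id in by_id:
            raise ValueError(f"duplicate student_id {r.student_id}")
        r.validate()
        by_id[r.student_id] = r
    out_deg: dict[str, int] = {}
    seen = set()
    for i, e in enumerate(edges):
        for endpoint in (e.ego_id, e.alter_id):
            if endpoint not in by_id:
                raise ValueError(f"edge {i}: unknown student id {endpoint!r}")
        if by_id[e.ego_id].school_id != by_id[e.alter_id].school_id:
            raise ValueError(
                f"edge {i}: {e.ego_id} -> {e.alter_id} crosses schools"
            )
        if (e.ego_id, e.alter_id) in seen:
            raise ValueError(f"edge {i}: duplicate nomination {e.ego_id} -> {e.alter_id}")
        seen.add((e.ego_id, e.alter_id))
        out_deg[e.ego_id] = out_deg.get(e.ego_id, 0) + 1
        if out_deg[e.ego_id] > max_nominations:
            raise ValueError(
                f"{e.ego_id}: out-degree exceeds {max_nominations} nominations"
            )
    return by_id
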