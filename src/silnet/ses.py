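"""Socio-economic indicators and the composite deprivation score.

Six survey instruments yield seven indicators of socio-economic status:
father's and mother's education, the MacArthur ladder of subjective social
status, father's and mother's working status, the family affluence ratio
(FAS relative to the national mean) and housing tenure.  The composite SES
score counts on how many of the seven an adolescent falls in the lowest
category; for reporting it is banded 0..4 and "5+".

Missing-data substitution rules
-------------------------------
* parental education missing -> kept as its own level ``"unknown"`` and
  never counted as lowest;
* subjective rank missing    -> assigned the lowest band (rank 5);
* FAS ratio missing          -> the national average (ratio 1.0);
* working status missing     -> assumed working.
"""

from __future__ import annotations

from .types import SESComposite, StudentRecord

#: FAS bands as fractions of the national mean; ties go to the lower band.
FAS_BAND_EDGES = (0.60, 0.90, 1.20)
FAS_BAND_LABELS = ("<=60%", "61-90%", "91-120%", ">120%")

#: Subjective social rank at or below this ladder rung is the lowest band.
SUBJECTIVE_RANK_LOW = 5

LOWEST_BAND_CAP = 5  # banding caps the composite at "5+"


def fas_band(fas_ratio: float) -> str:
    """Band a family-affluence ratio into the four reporting bands."""
    if fas_ratio <= 0:
        raise ValueError(f"fas_ratio must be > 0, got {fas_ratio}")
    for edge, label in zip(FAS_BAND_EDGES, FAS_BAND_LABELS):
        if fas_ratio <= edge:
            return label
    return FAS_BAND_LABELS[-1]


def impute_ses(record: StudentRecord, national_fas_mean: float = 1.0) -> StudentRecord:
    """Fill missing SES indicators with the survey's substitution rules.

    Returns a new record with no missing SES values; every substituted
    field name is recorded in ``imputed_fields``.  ``national_fas_mean`` is
    the FAS denominator (the stored ratio is relative to it, so a missing
    ratio becomes exactly 1.0); it must be positive.
    """
    if national_fas_mean <= 0:
        raise ValueError("national_fas_mean must be > 0")
    updates = {}
    imputed = set(record.imputed_fields)
    for f in ("father_edu", "mother_edu"):
        if getattr(record, f) is None:
            updates[f] = "unknown"
            imputed.add(f)
    if record.subjective_rank is None:
        updates["subjective_rank"] = SUBJECTIVE_RANK_LOW
        imputed.add("subjective_rank")
    if record.fas_ratio is None:
        updates["fas_ratio"] = 1.0
        imputed.add("fas_ratio")
    for f in ("father_working", "mother_working"):
        if getattr(record, f) is None:
            updates[f] = True
            imputed.add(f)
    if not updates:
        return record
    return record.with_updates(imputed_fields=frozenset(imputed), **updates)


def _check_complete(record: StudentRecord) -> None:
    for f in ("father_edu", "mother_edu", "subjective_rank",
              "father_working", "mother_working", "fas_ratio"):
        if getattr(record, f) is None:
            raise ValueError(
                f"{record.student_id}: field {f!r} is missing; run impute_ses first"
            )


def composite_score(record: StudentRecord) -> SESComposite:
    """Count lowest-category memberships over the seven SES indicators.

    Lowest categories: education "low" (never "unknown"), subjective rank
    <= 5, parent not working, FAS ratio <= 60% of the national mean, and
    tenant housing.
    """
    _check_complete(record)
    record.validate()
    lowest = [
        record.father_edu == "low",
        record.mother_edu == "low",
        record.subjective_rank <= SUBJECTIVE_RANK_LOW,
        not record.father_working,
        not record.mother_working,
        record.fas_ratio <= FAS_BAND_EDGES[0],
        record.housing == "tenant",
    ]
    count = int(sum(lowest))
    banded = str(count) if count < LOWEST_BAND_CAP else f"{LOWEST_BAND_CAP}+"
    return SESComposite(
        student_id=record.student_id,
        lowest_count=count,
        lowest_count_banded=banded,
        fas_band=fas_band(record.fas_ratio),
        imputed_fields=record.imputed_fields,
    )


def score_cohort(records, national_fas_mean: float = 1.0):
    """Impute and score every record; returns (imputed_records, composites)."""
    imputed = [impute_ses(r, national_fas_mean) for r in records]
    return imputed, [composite_score(r) for r in imputed]
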