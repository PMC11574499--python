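"""Sequential exclusion classifier for TDF/FTC exposure eras.

Every exposure era of the TDF/FTC, FTC or TDF drug class is assessed against
seven criteria, in fixed order; an era surviving all of them is classified as
PrEP. The criteria, with the exclusion reason each records:

1. HIV diagnosis or opportunistic-infection diagnosis on or before the index
   date (the era start) — ``HIV_DX_PRIOR`` / ``OI_PRIOR``;
2. previous use of other antiretrovirals (an other-ARV era ending before the
   index date) — ``ARV_PRIOR``;
3. concomitant use of other antiretrovirals (an other-ARV era overlapping the
   TDF/FTC era) — ``ARV_CONCOMITANT``;
4. chronic hepatitis B diagnosis on or before the index date —
   ``CHB_DX_PRIOR``;
5. concurrent or previous use of hepatitis-B agents — ``HBV_AGENT_USE``;
6. era categorized as post-exposure prophylaxis (needle-stick or prophylaxis
   code near the index date) — ``PEP_MARKER``;
7. no encounter evidence (by default: fewer than one diagnosis record or one
   procedure record for the patient) — ``NO_ENCOUNTER_EVIDENCE``.

The criteria are not mutually exclusive: every firing reason is recorded, in
criterion order, and the *first* reason determines the label (HIV, CHB, PEP
or NOT_CLASSIFIABLE). "Before the index date" is implemented as on-or-before:
a diagnosis made the day an era starts already rules out PrEP.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

from .claims_model import CohortDataset, ResultRow
from .codebook import Codebook, CodeSystem
from .era_engine import (
    ExposureEra,
    PatientHistory,
    build_patient_history,
    era_duration,
)

__all__ = [
    "ClassifierParams",
    "IndicationResult",
    "ClassifierError",
    "classify_era",
    "classify_cohort",
    "is_pep",
    "has_encounter_evidence",
    "patient_level_labels",
    "predicted_era_labels",
    "summarize_durations",
    "PREP_DRUG_CLASSES",
    "LABELS",
]

#: Drug classes whose eras the algorithm classifies.
PREP_DRUG_CLASSES = ("TDF_FTC", "FTC", "TDF")

LABELS = ("HIV", "CHB", "PEP", "NOT_CLASSIFIABLE", "PREP")

_REASON_LABEL = {
    "HIV_DX_PRIOR": "HIV",
    "OI_PRIOR": "HIV",
    "ARV_PRIOR": "HIV",
    "ARV_CONCOMITANT": "HIV",
    "CHB_DX_PRIOR": "CHB",
    "HBV_AGENT_USE": "CHB",
    "PEP_MARKER": "PEP",
    "NO_ENCOUNTER_EVIDENCE": "NOT_CLASSIFIABLE",
}


class ClassifierError(ValueError):
    pass


@dataclass(frozen=True)
class ClassifierParams:
    """Tunable parameters of the exclusion algorithm.

    gap_days
        Maximum tolerated supply gap within an era, in days (strict ``<``).
    pep_code_window_days
        Half-width of the symmetric window around the index date within which
        a needle-stick / prophylaxis code marks the era as PEP.
    pep_duration_heuristic / pep_max_duration_days
        Optional (off by default) auxiliary PEP rule: a patient's only
        TDF/FTC-class era, no longer than ``pep_max_duration_days`` (a PEP
        course is ~28 days) and carrying an exposure-contact code from the
        codebook's extension list, is also flagged PEP.
    encounter_rule
        ``REQUIRE_DX_AND_PX`` (default) demands at least one diagnosis and
        one procedure record; ``REQUIRE_DX_OR_PX`` accepts either.
    encounter_window
        ``ANY_TIME`` (default) counts records anywhere in the patient's
        history; ``ON_OR_BEFORE_ERA_END`` restricts to records dated no later
        than the era end.
    """

    gap_days: int = 30
    pep_code_window_days: int = 30
    pep_max_duration_days: int = 28
    pep_duration_heuristic: bool = False
    encounter_rule: str = "REQUIRE_DX_AND_PX"
    encounter_window: str = "ANY_TIME"

    def __post_init__(self) -> None:
        if self.gap_days < 1:
            raise ClassifierError("gap_days must be >= 1")
        if self.pep_code_window_days < 0 or self.pep_max_duration_days < 0:
            raise ClassifierError("windows must be >= 0")
        if self.encounter_rule not in ("REQUIRE_DX_AND_PX", "REQUIRE_DX_OR_PX"):
            raise ClassifierError(f"unknown encounter_rule {self.encounter_rule!r}")
        if self.encounter_window not in ("ANY_TIME", "ON_OR_BEFORE_ERA_END"):
            raise ClassifierError(f"unknown encounter_window {self.encounter_window!r}")


@dataclass(frozen=True)
class IndicationResult:
    """Per-era classification: label plus the ordered exclusion reasons.

    ``label == "PREP"`` iff ``reasons`` is empty; otherwise the label is
    determined by the first reason.
    """

    patient_id: str
    era: ExposureEra
    index_date: dt.date
    label: str
    reasons: tuple[str, ...]

    def to_row(self) -> ResultRow:
        return ResultRow(
            patient_id=self.patient_id,
            drug_class=self.era.drug_class,
            index_date=self.index_date,
            era_start=self.era.start_date,
            era_end=self.era.end_date,
            duration_days=era_duration(self.era),
            label=self.label,
            reasons=self.reasons,
        )


def is_pep(
    era: ExposureEra,
    history: PatientHistory,
    book: Codebook,
    params: ClassifierParams,
) -> bool:
    """PEP detection: prophylaxis-specific code near the index date.

    True iff a needle-stick or prophylaxis event falls within
    ``pep_code_window_days`` of the index date (era start). With the optional
    duration heuristic enabled, a short, isolated era carrying an
    exposure-contact extension code also qualifies.
    """
    index = era.start_date
    w = params.pep_code_window_days
    if history.has_event_within("NEEDLESTICK", index, w) or history.has_event_within(
        "PROPHYLAXIS", index, w
    ):
        return True
    if params.pep_duration_heuristic:
        n_tdf_eras = sum(len(history.eras_of(c)) for c in PREP_DRUG_CLASSES)
        if (
            era_duration(era) <= params.pep_max_duration_days
            and n_tdf_eras == 1
            and any(
                abs((ev.date - index).days) <= w and book.is_pep_extension(ev.system, ev.code)
                for ev in history.events
            )
        ):
            return True
    return False


def has_encounter_evidence(
    history: PatientHistory,
    era: ExposureEra,
    params: ClassifierParams,
) -> bool:
    """Whether the patient has the encounter records PrEP classification requires."""
    cutoff = era.end_date if params.encounter_window == "ON_OR_BEFORE_ERA_END" else None
    n_dx = history.count_records(CodeSystem.ICD9_DX, cutoff)
    n_px = history.count_records(CodeSystem.CPT, cutoff)
    if params.encounter_rule == "REQUIRE_DX_AND_PX":
        return n_dx >= 1 and n_px >= 1
    return n_dx >= 1 or n_px >= 1


def classify_era(
    era: ExposureEra,
    history: PatientHistory,
    book: Codebook,
    params: ClassifierParams | None = None,
) -> IndicationResult:
    """Run the seven sequential criteria on one TDF/FTC-class era."""
    params = params or ClassifierParams()
    if era.drug_class not in PREP_DRUG_CLASSES:
        raise ClassifierError(
            f"classify_era expects a {'/'.join(PREP_DRUG_CLASSES)} era, got {era.drug_class!r}"
        )
    if history.patient_id != era.patient_id:
        raise ClassifierError("history belongs to a different patient")

    index = era.start_date
    reasons: list[str] = []

    # 1. HIV / opportunistic-infection diagnosis on or before index
    if history.has_event_on_or_before("HIV_DX", index):
        reasons.append("HIV_DX_PRIOR")
    if history.has_event_on_or_before("OI_DX", index):
        reasons.append("OI_PRIOR")
    # 2. previous use of other antiretrovirals
    if history.has_era_ending_before("ARV_OTHER", index):
        reasons.append("ARV_PRIOR")
    # 3. concomitant use of other antiretrovirals
    if history.has_era_overlapping("ARV_OTHER", era.start_date, era.end_date):
        reasons.append("ARV_CONCOMITANT")
    # 4. chronic hepatitis B diagnosis on or before index
    if history.has_event_on_or_before("CHB_DX", index):
        reasons.append("CHB_DX_PRIOR")
    # 5. concurrent or previous use of hepatitis-B agents
    if history.has_era_overlapping("HBV_AGENT", era.start_date, era.end_date) or \
            history.has_era_ending_before("HBV_AGENT", index):
        reasons.append("HBV_AGENT_USE")
    # 6. post-exposure prophylaxis
    if is_pep(era, history, book, params):
        reasons.append("PEP_MARKER")
    # 7. encounter evidence
    if not has_encounter_evidence(history, era, params):
        reasons.append("NO_ENCOUNTER_EVIDENCE")

    label = _REASON_LABEL[reasons[0]] if reasons else "PREP"
    return IndicationResult(
        patient_id=era.patient_id,
        era=era,
        index_date=index,
        label=label,
        reasons=tuple(reasons),
    )


def classify_cohort(
    dataset: CohortDataset,
    book: Codebook | None = None,
    params: ClassifierParams | None = None,
) -> list[IndicationResult]:
    """Classify every TDF/FTC-class era in the cohort.

    Patients may contribute multiple eras with different labels (for example
    an early PrEP era followed, after an HIV diagnosis, by a treatment era).
    Output is sorted by (patient_id, era start) and fully deterministic.
    """
    book = book or Codebook()
    params = params or ClassifierParams()
    histories = build_patient_history(dataset, book, gap_days=params.gap_days)
    results: list[IndicationResult] = []
    for pid in sorted(histories):
        hist = histories[pid]
        eras = [e for cls in PREP_DRUG_CLASSES for e in hist.eras_of(cls)]
        for era in sorted(eras, key=lambda e: (e.start_date, e.drug_class)):
            results.append(classify_era(era, hist, book, params))
    return results


def predicted_era_labels(results: list[IndicationResult]) -> dict[tuple[str, dt.date], str]:
    """Map (patient_id, era_start) -> PREP / NOT_PREP for era-level validation."""
    return {
        (r.patient_id, r.era.start_date): ("PREP" if r.label == "PREP" else "NOT_PREP")
        for r in results
    }


def patient_level_labels(results: list[IndicationResult]) -> dict[str, str]:
    """Collapse era results to patient level: PREP iff any era is labeled PREP."""
    out: dict[str, str] = {}
    for r in results:
        if r.label == "PREP":
            out[r.patient_id] = "PREP"
        else:
            out.setdefault(r.patient_id, "NOT_PREP")
    return out


def summarize_durations(results: list[IndicationResult]) -> dict[str, float]:
    """Arithmetic mean era duration (days) per label; absent labels omitted."""
    sums: dict[str, list[int]] = {}
    for r in results:
        sums.setdefault(r.label, []).append(era_duration(r.era))
    return {label: sum(v) / len(v) for label, v in sorted(sums.items())}
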