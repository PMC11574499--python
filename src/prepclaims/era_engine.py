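"""Exposure-era construction and patient-history temporal queries.

An *exposure era* is a maximal period of continuous medication supply for one
patient and one drug class. A fill on date ``d`` with ``days_supply`` ``s``
covers days ``d .. d+s-1`` inclusive; a subsequent fill on date ``f`` extends
the era when the gap between the end of covered supply and ``f`` is strictly
less than ``gap_days`` (default 30). Overlapping or same-day refills merge
unconditionally and coverage is the union of covered days — stockpiling is
not modeled. The era's index date is its start (the earliest fill); the index
date anchors all "prior history" lookups in the classifier.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

from .claims_model import ClinicalEvent, CohortDataset, PharmacyClaim
from .codebook import Codebook, CodeSystem

__all__ = [
    "ExposureEra",
    "PatientHistory",
    "EraEngineError",
    "build_exposure_eras",
    "era_duration",
    "build_patient_history",
]

ONE_DAY = dt.timedelta(days=1)


class EraEngineError(ValueError):
    pass


@dataclass(frozen=True)
class ExposureEra:
    """A maximal run of same-class prescriptions with supply gaps < gap_days."""

    patient_id: str
    drug_class: str
    start_date: dt.date
    end_date: dt.date
    claim_ids: tuple[str, ...]

    def overlaps(self, start: dt.date, end: dt.date) -> bool:
        return self.start_date <= end and start <= self.end_date


def era_duration(era: ExposureEra) -> int:
    """Era length in days, inclusive of both endpoints."""
    return (era.end_date - era.start_date).days + 1


def build_exposure_eras(
    claims: list[PharmacyClaim],
    gap_days: int = 30,
    drug_class: str = "",
) -> list[ExposureEra]:
    """Merge one patient's same-class claims into maximal exposure eras.

    Claims are processed in fill-date order; a claim starts a new era exactly
    when the uncovered stretch since the running supply end is >= gap_days.
    Raises :class:`EraEngineError` on mixed patients or gap_days < 1.
    """
    if gap_days < 1:
        raise EraEngineError(f"gap_days must be >= 1, got {gap_days}")
    if not claims:
        return []
    patients = {c.patient_id for c in claims}
    if len(patients) > 1:
        raise EraEngineError(f"claims span multiple patients: {sorted(patients)}")
    pid = claims[0].patient_id

    ordered = sorted(claims, key=lambda c: (c.fill_date, c.claim_id))
    eras: list[ExposureEra] = []
    start = ordered[0].fill_date
    cover_end = start + dt.timedelta(days=ordered[0].days_supply - 1)
    ids: list[str] = [ordered[0].claim_id]
    for c in ordered[1:]:
        gap = (c.fill_date - cover_end).days - 1  # uncovered days between supply end and next fill
        if gap >= gap_days:
            eras.append(ExposureEra(pid, drug_class, start, cover_end, tuple(ids)))
            start = c.fill_date
            cover_end = c.fill_date + dt.timedelta(days=c.days_supply - 1)
            ids = [c.claim_id]
        else:
            cover_end = max(cover_end, c.fill_date + dt.timedelta(days=c.days_supply - 1))
            ids.append(c.claim_id)
    eras.append(ExposureEra(pid, drug_class, start, cover_end, tuple(ids)))
    return eras


@dataclass
class PatientHistory:
    """One patient's categorized events and per-class exposure eras.

    Supports the exact temporal queries the classifier needs: "any event of
    category C on or before date D", "any era of class K overlapping [a, b]"
    and "any era of class K ending before D".
    """

    patient_id: str
    events: list[ClinicalEvent] = field(default_factory=list)
    event_categories: list[set[str]] = field(default_factory=list)  # parallel to events
    eras: dict[str, list[ExposureEra]] = field(default_factory=dict)

    def eras_of(self, drug_class: str) -> list[ExposureEra]:
        return self.eras.get(drug_class, [])

    def has_event_on_or_before(self, category: str, date: dt.date) -> bool:
        return any(
            category in cats and ev.date <= date
            for ev, cats in zip(self.events, self.event_categories)
        )

    def has_event_within(self, category: str, center: dt.date, window_days: int) -> bool:
        return any(
            category in cats and abs((ev.date - center).days) <= window_days
            for ev, cats in zip(self.events, self.event_categories)
        )

    def has_era_overlapping(self, drug_class: str, start: dt.date, end: dt.date) -> bool:
        return any(e.overlaps(start, end) for e in self.eras_of(drug_class))

    def has_era_ending_before(self, drug_class: str, date: dt.date) -> bool:
        return any(e.end_date < date for e in self.eras_of(drug_class))

    def count_records(self, system: CodeSystem, on_or_before: dt.date | None = None) -> int:
        return sum(
            1
            for ev in self.events
            if ev.system is system and (on_or_before is None or ev.date <= on_or_before)
        )


def build_patient_history(
    dataset: CohortDataset,
    book: Codebook,
    gap_days: int = 30,
) -> dict[str, PatientHistory]:
    """Build a :class:`PatientHistory` for every patient in the dataset.

    Claims are grouped by patient and by :meth:`Codebook.categorize_drug`
    class, then merged into eras per class; clinical events are categorized
    once. Deterministic for a given dataset.
    """
    histories: dict[str, PatientHistory] = {}

    by_patient_class: dict[tuple[str, str], list[PharmacyClaim]] = {}
    for claim in dataset.claims:
        cls = book.categorize_drug(claim.gpi)
        by_patient_class.setdefault((claim.patient_id, cls), []).append(claim)

    for (pid, cls), claims in sorted(by_patient_class.items()):
        hist = histories.setdefault(pid, PatientHistory(patient_id=pid))
        hist.eras[cls] = build_exposure_eras(claims, gap_days=gap_days, drug_class=cls)

    for ev in sorted(dataset.events, key=lambda e: (e.patient_id, e.date, e.system.value, e.code)):
        hist = histories.setdefault(ev.patient_id, PatientHistory(patient_id=ev.patient_id))
        hist.events.append(ev)
        hist.event_categories.append(book.categorize_event(ev.system, ev.code))

    return histories
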