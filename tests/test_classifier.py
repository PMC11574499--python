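"""Sequential exclusion criteria, reason ordering, and cohort-level behavior."""

import datetime as dt

import pytest

from prepclaims import (
    ClassifierParams,
    ClinicalEvent,
    CodeSystem,
    CohortDataset,
    classify_cohort,
    classify_era,
    patient_level_labels,
    predicted_era_labels,
    summarize_durations,
)
from prepclaims.classifier import ClassifierError, is_pep, has_encounter_evidence
from prepclaims.era_engine import build_patient_history

from conftest import day, tdf_claim

ICD = CodeSystem.ICD9_DX
CPT = CodeSystem.CPT


def dx(pid, d, code):
    return ClinicalEvent(pid, day(d), ICD, code)


def px(pid, d, code="99213"):
    return ClinicalEvent(pid, day(d), CPT, code)


def classify_patient(book, claims, events, params=None):
    """Build the patient's history from raw rows and classify the first TDF/FTC era."""
    ds = CohortDataset(claims=claims, events=events).sorted()
    results = classify_cohort(ds, book, params)
    assert results, "no TDF/FTC era built"
    return results


BASE = [tdf_claim("p", 100, 30, "t1"), tdf_claim("p", 130, 30, "t2")]


def test_prior_hiv_dx_labels_hiv(book):
    (r,) = classify_patient(book, BASE, [dx("p", 50, "042"), px("p", 100)])
    assert r.label == "HIV"
    assert r.reasons[0] == "HIV_DX_PRIOR"
    assert r.index_date == day(100)


def test_same_day_hiv_dx_excludes(book):
    """'Before the index date' is read as on-or-before: a same-day diagnosis counts."""
    (r,) = classify_patient(book, BASE, [dx("p", 100, "V08"), px("p", 100)])
    assert r.label == "HIV" and "HIV_DX_PRIOR" in r.reasons


def test_hiv_dx_after_index_does_not_fire(book):
    (r,) = classify_patient(book, BASE, [dx("p", 161, "042"), px("p", 100)])
    # diagnosis after era end: era stays PrEP (temporal locality)
    assert r.label == "PREP" and r.reasons == ()


def test_oi_dx_prior(book):
    (r,) = classify_patient(book, BASE, [dx("p", 90, "130.0"), px("p", 100)])
    assert r.label == "HIV" and r.reasons == ("OI_PRIOR",)


def test_arv_prior_vs_concomitant(book):
    arv_prior = [tdf_claim("p", 10, 30, "a1", gpi="1210300010")]
    (r,) = classify_patient(book, BASE + arv_prior, [dx("p", 5, "780.60"), px("p", 100)])
    assert r.label == "HIV" and r.reasons == ("ARV_PRIOR",)

    arv_concom = [tdf_claim("p", 110, 30, "a2", gpi="1210300010")]
    (r,) = classify_patient(book, BASE + arv_concom, [dx("p", 5, "780.60"), px("p", 100)])
    assert r.label == "HIV" and r.reasons == ("ARV_CONCOMITANT",)


def test_chb_dx_and_hbv_agent(book):
    (r,) = classify_patient(book, BASE, [dx("p", 40, "070.22"), px("p", 100)])
    assert r.label == "CHB" and r.reasons == ("CHB_DX_PRIOR",)

    hbv = [tdf_claim("p", 120, 30, "h1", gpi="1235201510")]
    (r,) = classify_patient(book, BASE + hbv, [dx("p", 5, "780.60"), px("p", 100)])
    assert r.label == "CHB" and r.reasons == ("HBV_AGENT_USE",)


def test_multiple_reasons_recorded_in_criterion_order(book):
    """Concomitant ARV plus a prior CHB diagnosis: label HIV, both reasons kept."""
    arv = [tdf_claim("p", 110, 30, "a1", gpi="1210300010")]
    (r,) = classify_patient(book, BASE + arv, [dx("p", 40, "070.22"), px("p", 100)])
    assert r.label == "HIV"
    assert r.reasons == ("ARV_CONCOMITANT", "CHB_DX_PRIOR")


def test_clean_era_with_encounters_is_prep(book):
    (r,) = classify_patient(book, BASE, [dx("p", 105, "V69.2"), px("p", 105, "99401")])
    assert r.label == "PREP" and r.reasons == ()


def test_meds_only_not_classifiable(book):
    (r,) = classify_patient(book, BASE, [])
    assert r.label == "NOT_CLASSIFIABLE"
    assert r.reasons == ("NO_ENCOUNTER_EVIDENCE",)


def test_label_always_matches_first_reason(book, mixed_cohort):
    from prepclaims.classifier import _REASON_LABEL

    order = list(_REASON_LABEL)
    for r in classify_cohort(mixed_cohort.dataset, book):
        if r.reasons:
            assert r.label == _REASON_LABEL[r.reasons[0]]
            idx = [order.index(x) for x in r.reasons]
            assert idx == sorted(idx)
        else:
            assert r.label == "PREP"


class TestPep:
    def test_needlestick_near_index(self, book):
        (r,) = classify_patient(book, BASE, [dx("p", 97, "E920.5"), px("p", 100)])
        assert r.label == "PEP" and r.reasons == ("PEP_MARKER",)

    def test_prophylaxis_code_outside_window(self, book):
        (r,) = classify_patient(book, BASE, [dx("p", 145, "V07.9"), px("p", 100)])
        assert r.label == "PREP"  # 45 days after index, window is 30

    def test_no_prophylaxis_codes_anywhere(self, book):
        ds = CohortDataset(claims=BASE, events=[dx("p", 99, "V69.2"), px("p", 100)]).sorted()
        hist = build_patient_history(ds, book)["p"]
        era = hist.eras_of("TDF_FTC")[0]
        assert is_pep(era, hist, book, ClassifierParams()) is False


class TestEncounterEvidence:
    @pytest.mark.parametrize(
        "events, rule, expected",
        [
            ([("dx", 10), ("px", 10)], "REQUIRE_DX_AND_PX", True),
            ([("dx", 10)], "REQUIRE_DX_AND_PX", False),
            ([("dx", 10)], "REQUIRE_DX_OR_PX", True),
            ([("px", 10)], "REQUIRE_DX_OR_PX", True),
            ([], "REQUIRE_DX_OR_PX", False),
        ],
    )
    def test_rules(self, book, events, rule, expected):
        evs = [dx("p", d, "780.60") if kind == "dx" else px("p", d) for kind, d in events]
        ds = CohortDataset(claims=list(BASE), events=evs).sorted()
        hist = build_patient_history(ds, book)["p"]
        era = hist.eras_of("TDF_FTC")[0]
        params = ClassifierParams(encounter_rule=rule)
        assert has_encounter_evidence(hist, era, params) is expected

    def test_window_restriction(self, book):
        # records dated after the era end don't count under the windowed rule
        evs = [dx("p", 200, "780.60"), px("p", 200)]
        ds = CohortDataset(claims=list(BASE), events=evs).sorted()
        hist = build_patient_history(ds, book)["p"]
        era = hist.eras_of("TDF_FTC")[0]
        assert has_encounter_evidence(hist, era, ClassifierParams()) is True
        windowed = ClassifierParams(encounter_window="ON_OR_BEFORE_ERA_END")
        assert has_encounter_evidence(hist, era, windowed) is False


def test_wrong_drug_class_rejected(book):
    ds = CohortDataset(claims=[tdf_claim("p", 0, 30, "a", gpi="1210300010")]).sorted()
    hist = build_patient_history(ds, book)["p"]
    era = hist.eras_of("ARV_OTHER")[0]
    with pytest.raises(ClassifierError):
        classify_era(era, hist, book, ClassifierParams())


def test_patient_can_have_prep_then_hiv_eras(book):
    """An early clean era stays PrEP; a later era after seroconversion is HIV."""
    claims = [tdf_claim("p", 0, 30, "t1"), tdf_claim("p", 300, 30, "t2")]
    events = [dx("p", 5, "V69.2"), px("p", 5, "99401"), dx("p", 200, "042")]
    results = classify_patient(book, claims, events)
    assert [r.label for r in results] == ["PREP", "HIV"]
    assert patient_level_labels(results) == {"p": "PREP"}


def test_patient_level_labels():
    from prepclaims.classifier import IndicationResult
    from prepclaims.era_engine import ExposureEra

    def res(pid, start, label):
        era = ExposureEra(pid, "TDF_FTC", day(start), day(start + 29), ("c",))
        return IndicationResult(pid, era, day(start), label,
                                () if label == "PREP" else ("HIV_DX_PRIOR",))

    assert patient_level_labels([res("a", 0, "HIV")]) == {"a": "NOT_PREP"}
    nc = res("b", 0, "NOT_CLASSIFIABLE")
    assert patient_level_labels([nc]) == {"b": "NOT_PREP"}
    assert patient_level_labels([res("c", 0, "HIV"), res("c", 60, "PREP")]) == {"c": "PREP"}


def test_summarize_durations():
    from prepclaims.classifier import IndicationResult
    from prepclaims.era_engine import ExposureEra

    def res(start, length, label):
        era = ExposureEra("p", "TDF_FTC", day(start), day(start + length - 1), ("c",))
        return IndicationResult("p", era, day(start), label, ())

    assert summarize_durations([res(0, 10, "PREP")]) == {"PREP": 10.0}
    assert summarize_durations([res(0, 10, "PREP"), res(100, 20, "PREP")]) == {"PREP": 15.0}


def test_empty_cohort(book):
    assert classify_cohort(CohortDataset(), book) == []


def test_zero_noise_cohort_labels_equal_truth(book, mixed_cohort):
    """On a noise-free synthetic cohort every era recovers its generating truth."""
    results = classify_cohort(mixed_cohort.dataset, book)
    truth = {(t.patient_id, t.era_start): t.true_indication for t in mixed_cohort.truth}
    assert len(results) == len(truth)
    for r in results:
        want = truth[(r.patient_id, r.era.start_date)]
        assert r.label == ("NOT_CLASSIFIABLE" if want == "MEDS_ONLY" else want)


def test_determinism(book, mixed_cohort):
    r1 = classify_cohort(mixed_cohort.dataset, book)
    r2 = classify_cohort(mixed_cohort.dataset, book)
    assert r1 == r2
    assert predicted_era_labels(r1) == predicted_era_labels(r2)
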