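"""Agreement and diagnostic-performance statistics."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prepclaims.validation import (
    ContingencyTable,
    ValidationError,
    build_contingency,
    code_enrichment,
    cohen_kappa,
    diagnostic_metrics,
    kappa_band,
    wald_ci,
    wilson_ci,
)

from oracles import brute_metrics, label_maps_from_counts

# 2x2 tables from the two validation studies (era-level EMR chart review,
# patient-level clinic administrative records).
EMR_TABLE = ContingencyTable(tp=531, fp=193, fn=2, tn=190)
CLINIC_TABLE = ContingencyTable(tp=274, fp=262, fn=1, tn=1739)


def test_build_contingency_from_label_maps():
    pred, gold = label_maps_from_counts(531, 193, 2, 190)
    table = build_contingency(pred, gold)
    assert (table.tp, table.fp, table.fn, table.tn) == (531, 193, 2, 190)
    assert table.total == 916 and table.n_excluded == 0


def test_build_contingency_excludes_units_without_gold():
    pred, gold = label_maps_from_counts(2, 1, 1, 2)
    pred["orphan"] = "PREP"
    table = build_contingency(pred, gold)
    assert table.total == 6 and table.n_excluded == 1
    with pytest.raises(ValidationError):
        build_contingency({"x": "PREP"}, {"y": "PREP"})


def test_identical_all_prep_maps():
    pred, gold = label_maps_from_counts(5, 0, 0, 0)
    table = build_contingency(pred, gold)
    assert (table.fp, table.fn, table.tn) == (0, 0, 0)


@pytest.mark.parametrize(
    "table, expected",
    [(EMR_TABLE, 0.53), (CLINIC_TABLE, 0.61), (ContingencyTable(5, 0, 0, 7), 1.0)],
)
def test_cohen_kappa_values(table, expected):
    assert round(cohen_kappa(table), 2) == expected


def test_kappa_transpose_symmetry():
    for t in (EMR_TABLE, CLINIC_TABLE):
        swapped = ContingencyTable(t.tp, t.fn, t.fp, t.tn)
        assert cohen_kappa(swapped) == pytest.approx(cohen_kappa(t))


def test_kappa_zero_when_agreement_is_chance():
    # independent rater margins: observed agreement equals expected agreement
    assert cohen_kappa(ContingencyTable(10, 10, 10, 10)) == pytest.approx(0.0)


def test_kappa_one_iff_no_discordance():
    assert cohen_kappa(ContingencyTable(3, 0, 0, 4)) == 1.0
    assert cohen_kappa(ContingencyTable(3, 1, 0, 4)) < 1.0


@given(st.tuples(st.integers(0, 60), st.integers(0, 60),
                 st.integers(0, 60), st.integers(0, 60)).filter(lambda t: sum(t) > 0))
@settings(max_examples=100, deadline=None)
def test_kappa_matches_sklearn(counts):
    """Cross-check the closed-form 2x2 kappa against scikit-learn's."""
    sklearn = pytest.importorskip("sklearn.metrics")
    tp, fp, fn, tn = counts
    pred, gold = label_maps_from_counts(tp, fp, fn, tn)
    keys = sorted(pred)
    y_pred = [pred[k] for k in keys]
    y_gold = [gold[k] for k in keys]
    if len(set(y_pred) | set(y_gold)) == 1:
        return  # single observed category: sklearn returns nan by convention
    ours = cohen_kappa(ContingencyTable(tp, fp, fn, tn))
    theirs = sklearn.cohen_kappa_score(y_gold, y_pred)
    if math.isnan(theirs):
        return
    assert ours == pytest.approx(theirs, abs=1e-12)


@pytest.mark.parametrize(
    "kappa, band",
    [
        (0.53, "moderate"),
        (0.41, "moderate"),
        (0.60, "moderate"),
        (0.61, "substantial"),
        (0.80, "substantial"),
        (0.95, "almost perfect"),
        (0.40, "below moderate"),
        (-0.2, "below moderate"),
    ],
)
def test_kappa_band(kappa, band):
    assert kappa_band(kappa) == band


def test_diagnostic_metrics_emr_table():
    m = diagnostic_metrics(EMR_TABLE)
    assert round(m.sensitivity.pct, 1) == 99.6
    assert round(m.specificity.pct, 1) == 49.6
    assert round(m.ppv.pct, 1) == 73.3
    assert round(m.npv.pct, 1) == 99.0
    assert round(m.accuracy.pct, 1) == 78.7
    assert m.kappa_band == "moderate"


def test_diagnostic_metrics_clinic_table():
    m = diagnostic_metrics(CLINIC_TABLE)
    assert round(m.sensitivity.pct, 1) == 99.6
    assert round(m.ppv.pct, 1) == 51.1
    assert round(m.npv.pct, 1) == 99.9
    assert round(m.accuracy.pct, 1) == 88.4
    assert m.kappa_band == "substantial"


def test_undefined_metric_reported_as_none():
    m = diagnostic_metrics(ContingencyTable(0, 3, 0, 5))
    assert m.sensitivity is None  # no gold-positive units
    assert m.specificity is not None and m.accuracy is not None


def test_metrics_agree_with_brute_force_on_random_fixtures():
    rng = random.Random(17)
    for _ in range(50):
        counts = [rng.randrange(0, 40) for _ in range(4)]
        if sum(counts) == 0:
            continue
        tp, fp, fn, tn = counts
        pred, gold = label_maps_from_counts(tp, fp, fn, tn)
        keys = sorted(pred)
        ref = brute_metrics([pred[k] for k in keys], [gold[k] for k in keys])
        m = diagnostic_metrics(build_contingency(pred, gold))
        assert m.kappa == pytest.approx(ref["kappa"])
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            ours = getattr(m, name)
            if name in ref:
                assert ours.point == pytest.approx(ref[name])
            else:
                assert ours is None


class TestWaldCI:
    def test_closed_form(self):
        lo, hi = wald_ci(0.5, 100)
        assert (round(lo, 3), round(hi, 3)) == (0.402, 0.598)

    @pytest.mark.parametrize("p, expected", [(1.0, (1.0, 1.0)), (0.0, (0.0, 0.0))])
    def test_degenerate_truncation(self, p, expected):
        assert wald_ci(p, 50) == expected

    def test_widening_alpha_never_narrows(self):
        for p in (0.1, 0.5, 0.9):
            narrow = wald_ci(p, 80, alpha=0.10)
            wide = wald_ci(p, 80, alpha=0.01)
            assert wide[0] <= narrow[0] and wide[1] >= narrow[1]

    def test_bounds_contain_point(self):
        for p in np.linspace(0, 1, 11):
            for ci in (wald_ci, wilson_ci):
                lo, hi = ci(float(p), 37)
                assert 0.0 <= lo <= hi <= 1.0

    def test_invalid_n(self):
        with pytest.raises(ValidationError):
            wald_ci(0.5, 0)


class TestCodeEnrichment:
    def test_printed_counts_give_34x(self):
        # high-risk-behavior code on 123/531 PrEP vs 4/593 other periods
        r = code_enrichment(123, 531, 4, 593)
        assert r.ratio == pytest.approx(34.3, abs=0.05)
        assert r.ci_low < r.ratio < r.ci_high and not r.infinite

    def test_identity_and_zero(self):
        assert code_enrichment(10, 100, 10, 100).ratio == 1.0
        assert code_enrichment(0, 100, 10, 100).ratio == 0.0

    def test_infinite_flag(self):
        r = code_enrichment(5, 100, 0, 100)
        assert r.infinite and math.isinf(r.ratio)

    def test_zero_denominator_raises(self):
        with pytest.raises(ValidationError):
            code_enrichment(1, 0, 1, 10)
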