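"""Diagnostic-agreement statistics for algorithm-vs-gold-standard comparison.

The evaluation design treats the reference classification (clinician chart
review, or a clinic's own administrative PrEP list) as the gold standard and
the claims algorithm as a new diagnostic "test" for PrEP indication. Given
matched PREP / NOT_PREP labels per unit (exposure era or patient) this module
computes the 2x2 contingency table, Cohen's unweighted kappa with the
conventional agreement bands (0.41-0.60 moderate, 0.61-0.80 substantial,
>0.80 almost perfect), and sensitivity / specificity / PPV / NPV / accuracy,
each with a two-sided Wald (Gaussian-approximation) confidence interval
truncated to [0, 1]. Predictive values depend on prevalence, so the same
algorithm shows different PPV in populations with different PrEP prevalence.

Wilson score intervals are available behind a flag; Wald is the default
because it is the interval the evaluation design prescribes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Mapping

from scipy.stats import norm

__all__ = [
    "ContingencyTable",
    "Metric",
    "MetricsReport",
    "EnrichmentResult",
    "ValidationError",
    "build_contingency",
    "cohen_kappa",
    "kappa_band",
    "diagnostic_metrics",
    "wald_ci",
    "wilson_ci",
    "code_enrichment",
]

PREP = "PREP"
NOT_PREP = "NOT_PREP"


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 cross-tabulation of algorithm vs gold-standard PrEP labels.

    tp: both PrEP; fp: algorithm PrEP, gold not; fn: algorithm not, gold
    PrEP; tn: both not PrEP. ``n_excluded`` counts predicted units that had
    no gold label and were dropped from the comparison.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def build_contingency(
    predicted: Mapping[Hashable, str],
    gold: Mapping[Hashable, str],
) -> ContingencyTable:
    """Cross-tabulate predicted vs gold labels over their shared unit keys.

    Units present in ``predicted`` but missing a gold label are excluded and
    tallied in ``n_excluded``. Raises if no unit carries both labels.
    """
    tp = fp = fn = tn = excluded = 0
    for key, pred in predicted.items():
        if key not in gold:
            excluded += 1
            continue
        g = gold[key]
        if pred == PREP:
            tp += g == PREP
            fp += g != PREP
        else:
            fn += g == PREP
            tn += g != PREP
    table = ContingencyTable(tp, fp, fn, tn, n_excluded=excluded)
    if table.total == 0:
        raise ValidationError("no units carry both a predicted and a gold label")
    return table


def cohen_kappa(table: ContingencyTable) -> float:
    """Cohen's unweighted kappa for the 2x2 table.

    kappa = (p_obs - p_exp) / (1 - p_exp), with p_obs the observed agreement
    and p_exp the chance agreement from the marginals. Perfect agreement with
    degenerate marginals (p_exp == 1) returns 1.0.
    """
    n = table.total
    if n == 0:
        raise ValidationError("empty contingency table")
    p_obs = (table.tp + table.tn) / n
    p_exp = (
        (table.tp + table.fp) * (table.tp + table.fn)
        + (table.fn + table.tn) * (table.fp + table.tn)
    ) / (n * n)
    if p_exp == 1.0:
        return 1.0 if p_obs == 1.0 else 0.0
    return (p_obs - p_exp) / (1.0 - p_exp)


def kappa_band(kappa: float) -> str:
    """Agreement band for a kappa value, closed on the printed cut points."""
    if not -1.0 - 1e-12 <= kappa <= 1.0 + 1e-12:
        raise ValidationError(f"kappa out of range: {kappa}")
    if kappa > 0.80:
        return "almost perfect"
    if kappa >= 0.61:
        return "substantial"
    if kappa >= 0.41:
        return "moderate"
    return "below moderate"


def wald_ci(p: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Two-sided Gaussian-approximation CI for a proportion, truncated to [0, 1]."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"proportion out of range: {p}")
    z = norm.ppf(1.0 - alpha / 2.0)
    half = z * math.sqrt(p * (1.0 - p) / n)
    return (max(0.0, p - half), min(1.0, p + half))


def wilson_ci(p: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval — a flagged alternative to the default Wald CI."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    z = norm.ppf(1.0 - alpha / 2.0)
    z2 = z * z
    denom = 1.0 + z2 / n
    center = (p + z2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1.0 - p) / n + z2 / (4 * n * n)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


@dataclass(frozen=True)
class Metric:
    """A proportion with its CI and denominator; ``None`` point = undefined."""

    point: float
    ci_low: float
    ci_high: float
    n: int

    @property
    def pct(self) -> float:
        return 100.0 * self.point


@dataclass(frozen=True)
class MetricsReport:
    """Full diagnostic report for one algorithm-vs-gold comparison."""

    table: ContingencyTable
    kappa: float
    kappa_band: str
    sensitivity: Metric | None
    specificity: Metric | None
    ppv: Metric | None
    npv: Metric | None
    accuracy: Metric
    alpha: float

    def to_dict(self) -> dict:
        def metric(m: Metric | None) -> dict | None:
            if m is None:
                return None
            return {
                "pct": round(m.pct, 1),
                "point": m.point,
                "ci_low": m.ci_low,
                "ci_high": m.ci_high,
                "n": m.n,
            }

        t = self.table
        return {
            "counts": {"tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn,
                       "total": t.total, "excluded": t.n_excluded},
            "kappa": round(self.kappa, 4),
            "kappa_band": self.kappa_band,
            "sensitivity": metric(self.sensitivity),
            "specificity": metric(self.specificity),
            "ppv": metric(self.ppv),
            "npv": metric(self.npv),
            "accuracy": metric(self.accuracy),
            "alpha": self.alpha,
        }


def _metric(numerator: int, denominator: int, alpha: float,
            interval) -> Metric | None:
    if denominator == 0:
        return None
    p = numerator / denominator
    lo, hi = interval(p, denominator, alpha)
    return Metric(point=p, ci_low=lo, ci_high=hi, n=denominator)


def diagnostic_metrics(
    table: ContingencyTable,
    alpha: float = 0.05,
    interval: str = "wald",
) -> MetricsReport:
    """Sensitivity, specificity, PPV, NPV and accuracy with CIs, plus kappa.

    A metric whose denominator is zero is reported as ``None`` (undefined)
    rather than raising, so batch validation never aborts.
    """
    if table.total == 0:
        raise ValidationError("empty contingency table")
    ci = {"wald": wald_ci, "wilson": wilson_ci}[interval]
    t = table
    return MetricsReport(
        table=t,
        kappa=cohen_kappa(t),
        kappa_band=kappa_band(cohen_kappa(t)),
        sensitivity=_metric(t.tp, t.tp + t.fn, alpha, ci),
        specificity=_metric(t.tn, t.tn + t.fp, alpha, ci),
        ppv=_metric(t.tp, t.tp + t.fp, alpha, ci),
        npv=_metric(t.tn, t.tn + t.fn, alpha, ci),
        accuracy=_metric(t.tp + t.tn, t.total, alpha, ci),
        alpha=alpha,
    )


@dataclass(frozen=True)
class EnrichmentResult:
    """Risk ratio of a code's presence between two sets of exposure periods."""

    ratio: float
    ci_low: float
    ci_high: float
    infinite: bool = False


def code_enrichment(
    count_a: int, n_a: int, count_b: int, n_b: int, alpha: float = 0.05
) -> EnrichmentResult:
    """Risk ratio (count_a/n_a)/(count_b/n_b) with a log-normal Wald CI.

    Used to quantify how much more often a marker code (for example a
    high-risk-behavior diagnosis or a prevention-counseling procedure)
    appears on PrEP periods than on other periods. ``count_b == 0`` yields an
    infinite ratio with a flag; zero denominators raise.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValidationError("denominators must be positive")
    if count_a == 0:
        return EnrichmentResult(0.0, 0.0, 0.0)
    if count_b == 0:
        return EnrichmentResult(math.inf, math.inf, math.inf, infinite=True)
    rr = (count_a / n_a) / (count_b / n_b)
    z = norm.ppf(1.0 - alpha / 2.0)
    se = math.sqrt(1 / count_a - 1 / n_a + 1 / count_b - 1 / n_b)
    return EnrichmentResult(
        ratio=rr,
        ci_low=rr * math.exp(-z * se),
        ci_high=rr * math.exp(z * se),
    )
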