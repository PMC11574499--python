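"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: the era oracle works on a
literal day calendar, and the metric oracle recounts raw label lists.
"""

from __future__ import annotations

import math


def day_coverage_eras(fills: list[tuple[int, int]], gap_days: int) -> list[tuple[int, int]]:
    """Brute-force era construction on integer days.

    Mark every supplied day on a calendar, bridge uncovered runs shorter
    than ``gap_days``, and return the connected components as (start, end)
    day pairs.
    """
    covered: set[int] = set()
    for day, supply in fills:
        covered.update(range(day, day + supply))
    if not covered:
        return []
    days = sorted(covered)
    eras: list[tuple[int, int]] = []
    start = prev = days[0]
    for d in days[1:]:
        if d - prev - 1 >= gap_days:
            eras.append((start, prev))
            start = d
        prev = d
    eras.append((start, prev))
    return eras


def brute_metrics(pred: list[str], gold: list[str]) -> dict[str, float]:
    """Recount diagnostic metrics directly from parallel label lists."""
    assert len(pred) == len(gold)
    tp = sum(p == "PREP" and g == "PREP" for p, g in zip(pred, gold))
    fp = sum(p == "PREP" and g != "PREP" for p, g in zip(pred, gold))
    fn = sum(p != "PREP" and g == "PREP" for p, g in zip(pred, gold))
    tn = sum(p != "PREP" and g != "PREP" for p, g in zip(pred, gold))
    n = len(pred)
    out: dict[str, float] = {"tp": tp, "fp": fp, "fn": fn, "tn": tn}
    if tp + fn:
        out["sensitivity"] = tp / (tp + fn)
    if tn + fp:
        out["specificity"] = tn / (tn + fp)
    if tp + fp:
        out["ppv"] = tp / (tp + fp)
    if tn + fn:
        out["npv"] = tn / (tn + fn)
    out["accuracy"] = (tp + tn) / n
    p_obs = (tp + tn) / n
    p_exp = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    out["kappa"] = 1.0 if math.isclose(p_exp, 1.0) else (p_obs - p_exp) / (1 - p_exp)
    return out


def label_maps_from_counts(tp: int, fp: int, fn: int, tn: int):
    """Predicted/gold label maps over synthetic unit keys realizing a 2x2 table."""
    pred: dict[str, str] = {}
    gold: dict[str, str] = {}
    i = 0
    for count, p, g in ((tp, "PREP", "PREP"), (fp, "PREP", "NOT_PREP"),
                        (fn, "NOT_PREP", "PREP"), (tn, "NOT_PREP", "NOT_PREP")):
        for _ in range(count):
            key = f"u{i}"
            pred[key] = p
            gold[key] = g
            i += 1
    return pred, gold
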