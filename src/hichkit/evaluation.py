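"""Assessment machinery: confusion metrics, ROC/AUC, Cohen kappa, and the
100-point treatment-plan rubric.

The rubric splits a plan into diagnostic measures (15 points) and
therapeutic measures (85 points: surgical 40 + rescue 35 + drug 10).  The
surgical category is all-or-nothing; the other categories award each
decisive item's share when prediction and gold agree on its presence or
absence.  Score distributions are binned >80% / 60-80% / <60% of the
category maximum.  When binary plan decisions are scored with ROC curves,
the rule engine's summed fired weight serves as the ranking score.

Reported metrics follow the 0-100 percent convention and round half-up to
two decimals at the reporting boundary; internal values keep full
precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .hws import TreatmentPlan, SURGICAL_ITEM

__all__ = [
    "ConfusionCounts",
    "RubricConfig",
    "RaterTable",
    "classification_metrics",
    "roc_auc",
    "cohens_kappa",
    "rubric_score",
    "score_distribution",
    "pooled_accuracy",
    "f1_from_pr",
    "round2",
    "POSITIVE_EVENTS",
]

# Binary events treated as positives when computing sensitivity/specificity:
# repeat head CT, surgical intervention, airway clearance, ICP lowering.
POSITIVE_EVENTS = ("repeat-head-ct", SURGICAL_ITEM, "airway-clearance", "icp-lowering")


def round2(x: float) -> float:
    """Round half-up to 2 decimals (reporting convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Confusion-matrix metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("confusion counts must have a positive total")


def classification_metrics(counts: ConfusionCounts) -> dict:
    """Sensitivity, specificity, accuracy, PPV, NPV on the 0-100 scale.

    A zero denominator yields ``None`` for that metric (flagged undefined,
    never silently 0).
    """
    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else 100.0 * num / den

    c = counts
    return {
        "sensitivity": ratio(c.tp, c.tp + c.fn),
        "specificity": ratio(c.tn, c.tn + c.fp),
        "accuracy": ratio(c.tp + c.tn, c.tp + c.fp + c.tn + c.fn),
        "ppv": ratio(c.tp, c.tp + c.fp),
        "npv": ratio(c.tn, c.tn + c.fn),
    }


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the ROC curve via the Mann-Whitney rank formulation.

    Equals the probability that a random positive outscores a random
    negative, counting ties as one half.  Both classes must be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be parallel 1-D sequences")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC AUC needs both a positive and a negative class")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def cohens_kappa(table) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e) from a square
    contingency table of two raters' category counts."""
    t = np.asarray(getattr(table, "counts", table), dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("rater table must be square")
    if (t < 0).any():
        raise ValueError("rater table entries must be non-negative")
    total = t.sum()
    if total == 0:
        raise ValueError("rater table must have a positive total")
    p_o = np.trace(t) / total
    p_e = float((t.sum(axis=1) / total) @ (t.sum(axis=0) / total))
    if abs(1.0 - p_e) < 1e-12:
        raise ValueError("expected agreement is 1; kappa is undefined")
    return float((p_o - p_e) / (1.0 - p_e))


@dataclass
class RaterTable:
    """Square contingency table of category counts for two raters."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        cohens_kappa(self.counts)  # validates shape/margins

    @classmethod
    def from_categories(cls, a: Sequence, b: Sequence,
                        categories: Sequence | None = None) -> "RaterTable":
        if len(a) != len(b):
            raise ValueError("both raters must rate the same cases")
        cats = list(categories) if categories is not None else sorted(set(a) | set(b))
        idx = {c: i for i, c in enumerate(cats)}
        t = np.zeros((len(cats), len(cats)))
        for x, y in zip(a, b):
            t[idx[x], idx[y]] += 1
        return cls(t)


# ---------------------------------------------------------------------------
# The 100-point rubric
# ---------------------------------------------------------------------------

_DEFAULT_ITEMS = {
    "diagnostic": ("repeat-head-ct", "cta", "mra", "dsa", "multimodal-mri",
                   "coagulation-panel"),
    "rescue": ("vital-sign-monitoring", "venous-access", "cpr",
               "airway-clearance", "tracheal-intubation", "ventilator"),
    "drug": ("antihypertensive", "icp-lowering", "anti-gi-bleeding"),
}


@dataclass
class RubricConfig:
    """Category maxima, per-item shares and score bins.

    Defaults: diagnostic 15 + therapeutic 85 (surgical 40 all-or-nothing,
    rescue 35, drug 10); equal shares across each category's decisive items;
    bins at >80% / 60-80% / <60% of the maximum.
    """

    diagnostic_points: float = 15.0
    surgical_points: float = 40.0
    rescue_points: float = 35.0
    drug_points: float = 10.0
    items: Mapping = field(default_factory=lambda: dict(_DEFAULT_ITEMS))
    bin_fractions: tuple = (0.8, 0.6)  # edges as fractions of the maximum

    @property
    def total(self) -> float:
        return (self.diagnostic_points + self.surgical_points
                + self.rescue_points + self.drug_points)

    @property
    def therapeutic_points(self) -> float:
        return self.surgical_points + self.rescue_points + self.drug_points

    def category_points(self, category: str) -> float:
        return {"diagnostic": self.diagnostic_points, "surgical": self.surgical_points,
                "rescue": self.rescue_points, "drug": self.drug_points}[category]


def _branch_set(plan: TreatmentPlan, category: str) -> frozenset:
    return {"diagnostic": plan.diagnostic, "rescue": plan.rescue,
            "drug": plan.drugs}[category]


def rubric_score(predicted: TreatmentPlan, gold: TreatmentPlan,
                 config: RubricConfig | None = None) -> dict:
    """Score a predicted plan against gold; returns per-category points,
    the therapeutic subtotal and the total.

    Surgical is all-or-nothing; each other category splits its points
    equally over its decisive items, awarding a share when predicted and
    gold agree the item is present or agree it is absent.
    """
    config = config or RubricConfig()
    known = {i for items in config.items.values() for i in items} | {SURGICAL_ITEM}
    for plan in (predicted, gold):
        stray = plan.selected_items() - known
        if stray:
            raise ValueError(f"plan items outside the rubric taxonomy: {sorted(stray)}")
    out: dict = {}
    for category, items in config.items.items():
        share = config.category_points(category) / len(items)
        got = _branch_set(predicted, category)
        want = _branch_set(gold, category)
        agree = sum(1 for i in items if (i in got) == (i in want))
        out[category] = share * agree
    out["surgical"] = config.surgical_points if predicted.surgical == gold.surgical else 0.0
    out["therapeutic"] = out["surgical"] + out["rescue"] + out["drug"]
    out["total"] = out["therapeutic"] + out["diagnostic"]
    return out


def score_distribution(scores: Sequence[float], config: RubricConfig | None = None,
                       maximum: float | None = None) -> tuple[float, float, float]:
    """Percent of scores in the >80% / 60-80% / <60% bins of the maximum.

    The returned percentages sum to 100 (within rounding).  An empty score
    list is a contract error, not a NaN.
    """
    if len(scores) == 0:
        raise ValueError("score distribution of an empty list is undefined")
    config = config or RubricConfig()
    maximum = config.total if maximum is None else maximum
    hi, lo = (f * maximum for f in config.bin_fractions)
    scores = np.asarray(scores, dtype=float)
    top = float((scores > hi).mean() * 100.0)
    bottom = float((scores < lo).mean() * 100.0)
    return (top, 100.0 - top - bottom, bottom)


def pooled_accuracy(per_group: Sequence[tuple[float, float]]) -> float:
    """Case-weighted mean accuracy over (n, accuracy) groups."""
    per_group = list(per_group)
    if not per_group:
        raise ValueError("pooled accuracy needs at least one group")
    ns = np.array([n for n, _ in per_group], dtype=float)
    accs = np.array([a for _, a in per_group], dtype=float)
    if (ns <= 0).any():
        raise ValueError("group sizes must be positive")
    return float((ns * accs).sum() / ns.sum())


def f1_from_pr(p: float, r: float) -> float:
    """Harmonic mean 2PR/(P+R) on the 0-100 scale."""
    if p < 0 or r < 0:
        raise ValueError("precision and recall must be non-negative")
    return 0.0 if p + r == 0 else 2.0 * p * r / (p + r)
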