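"""Diagnostic-test statistics for screening evaluation.

Covers the full reporting battery for a binary cancer screen: the
confusion-matrix proportions (accuracy, sensitivity, specificity, PPV,
NPV) with exact Clopper–Pearson or normal-approximation Wald 95%
confidence intervals, ROC/AUC by pairwise concordance, segmentation
intersection-over-union, Cohen's kappa for rater agreement, and the
two-sided McNemar test for paired classifier comparison.

Conventions: a metric with zero denominator is *undefined* (returned as
None, never 0); IoU of two empty masks is 1.0 (agreement that there is no
lesion); median IoU is computed over truth-positive images only; the
exact McNemar p doubles the smaller binomial tail and caps at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ConfusionCounts",
    "MetricWithCI",
    "EvalReport",
    "confusion_metrics",
    "binomial_ci",
    "metric_with_ci",
    "roc_curve_points",
    "roc_auc",
    "iou",
    "median_iou",
    "cohens_kappa",
    "mcnemar_test",
    "compare_paired_classifiers",
    "build_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_calls(cls, predictions, truths) -> "ConfusionCounts":
        pred = np.asarray(predictions, dtype=bool)
        tru = np.asarray(truths, dtype=bool)
        if pred.shape != tru.shape:
            raise ValueError("predictions and truths must align")
        return cls(
            tp=int(np.sum(pred & tru)),
            fp=int(np.sum(pred & ~tru)),
            fn=int(np.sum(~pred & tru)),
            tn=int(np.sum(~pred & ~tru)),
        )


@dataclass(frozen=True)
class MetricWithCI:
    estimate: float
    ci_low: float
    ci_high: float
    method: str = "clopper_pearson"
    level: float = 0.95

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.estimate <= self.ci_high <= 1):
            raise ValueError(
                f"CI ordering violated: {self.ci_low} <= {self.estimate} "
                f"<= {self.ci_high} within [0,1]"
            )


def confusion_metrics(c: ConfusionCounts) -> dict[str, Optional[float]]:
    """The five screening proportions; undefined metrics are None.

    accuracy = (TP+TN)/total, sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN).
    """

    def ratio(num, den):
        return num / den if den > 0 else None

    return {
        "accuracy": ratio(c.tp + c.tn, c.total),
        "sensitivity": ratio(c.tp, c.tp + c.fn),
        "specificity": ratio(c.tn, c.tn + c.fp),
        "ppv": ratio(c.tp, c.tp + c.fp),
        "npv": ratio(c.tn, c.tn + c.fn),
    }


def binomial_ci(successes: int, n: int, level: float = 0.95,
                method: str = "clopper_pearson") -> tuple[float, float]:
    """Binomial proportion confidence interval.

    ``clopper_pearson``: the exact interval by inverting the binomial
    tails, in its beta-quantile form — lower = Beta(α/2; k, n−k+1),
    upper = Beta(1−α/2; k+1, n−k), with 0 at k=0 and 1 at k=n.
    ``wald``: p̂ ± z·√(p̂(1−p̂)/n), clipped to [0, 1].
    """
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    if not 0 <= successes <= n or n <= 0:
        raise ValueError("need 0 <= successes <= n with n > 0")
    alpha = 1 - level
    k = successes
    if method == "clopper_pearson":
        low = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
        high = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
        return low, high
    if method == "wald":
        p = k / n
        z = float(sps.norm.ppf(1 - alpha / 2))
        half = z * np.sqrt(p * (1 - p) / n)
        return max(0.0, p - half), min(1.0, p + half)
    raise ValueError(f"unknown CI method {method!r}")


def metric_with_ci(successes: int, n: int, level: float = 0.95,
                   method: str = "clopper_pearson") -> MetricWithCI:
    low, high = binomial_ci(successes, n, level, method)
    return MetricWithCI(estimate=successes / n, ci_low=low, ci_high=high,
                        method=method, level=level)


def roc_curve_points(scores, labels):
    """Empirical ROC curve: (fpr, tpr) points swept over score thresholds."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    tps = np.cumsum(y)
    fps = np.cumsum(~y)
    # keep the last point of each tied-score block
    distinct = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    return fpr, tpr


def roc_auc(scores, labels):
    """AUC by pairwise concordance (ties count ½) plus the curve points.

    Equals the Mann–Whitney U statistic normalised by n⁺·n⁻, and equals
    trapezoidal integration of the empirical ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    ranks = sps.rankdata(scores)  # midranks give the half-tie convention
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr = roc_curve_points(scores, labels)
    return float(auc), (fpr, tpr)


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks; empty∪empty ≡ 1.0."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def median_iou(pred_masks: Sequence[np.ndarray], true_masks: Sequence[np.ndarray],
               positive_only: bool = True) -> float:
    """Median IoU across images, over truth-positive images by default
    (segmentation quality is assessed where a lesion exists)."""
    if len(pred_masks) != len(true_masks):
        raise ValueError("mask lists must align")
    vals = [
        iou(p, t)
        for p, t in zip(pred_masks, true_masks)
        if not positive_only or np.asarray(t).any()
    ]
    if not vals:
        raise ValueError("no truth-positive images to evaluate")
    return float(np.median(vals))


def cohens_kappa(ratings_a, ratings_b) -> Optional[float]:
    """Chance-corrected agreement κ = (p_o − p_e)/(1 − p_e).

    p_e comes from the product of the two raters' marginal distributions.
    Returns None when p_e = 1 (both raters constant and identical), where
    κ is undefined.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("ratings must be equal-length 1-D sequences")
    if len(a) < 2:
        raise ValueError("need at least 2 rated items")
    cats = np.unique(np.concatenate([a, b]))
    n = len(a)
    p_o = float(np.mean(a == b))
    pa = np.array([np.mean(a == c) for c in cats])
    pb = np.array([np.mean(b == c) for c in cats])
    p_e = float(pa @ pb)
    if p_e >= 1.0 - 1e-12:
        return None
    return (p_o - p_e) / (1 - p_e)


def mcnemar_test(b: int, c: int, mode: str = "auto") -> float:
    """Two-sided McNemar p-value from the discordant-pair counts.

    ``b`` and ``c`` count the two kinds of discordant pairs.  ``exact``
    doubles the smaller binomial tail of Bin(b+c, ½) at b (capped at 1);
    ``cc_chi2`` is the continuity-corrected (|b−c|−1)²/(b+c) against χ²₁.
    ``auto`` uses exact when b+c < 25.  b = c = 0 returns 1.0 by
    convention (no discordance, no evidence of difference).
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    if mode == "auto":
        mode = "exact" if n < 25 else "cc_chi2"
    if mode == "exact":
        tail = sps.binom.cdf(min(b, c), n, 0.5)
        return float(min(1.0, 2 * tail))
    if mode == "cc_chi2":
        stat = (abs(b - c) - 1) ** 2 / n
        return float(sps.chi2.sf(stat, df=1))
    raise ValueError(f"unknown McNemar mode {mode!r}")


def compare_paired_classifiers(pred_a, pred_b, truths, mode: str = "auto"):
    """McNemar comparison of two classifiers on the same cases.

    Discordant pairs are cases where exactly one classifier is correct:
    b = A correct & B wrong, c = A wrong & B correct.  Returns (b, c, p).
    """
    a_ok = np.asarray(pred_a, dtype=bool) == np.asarray(truths, dtype=bool)
    b_ok = np.asarray(pred_b, dtype=bool) == np.asarray(truths, dtype=bool)
    b_count = int(np.sum(a_ok & ~b_ok))
    c_count = int(np.sum(~a_ok & b_ok))
    return b_count, c_count, mcnemar_test(b_count, c_count, mode=mode)


@dataclass
class EvalReport:
    """Full evaluation report for one test set (optionally stratified)."""

    counts: ConfusionCounts
    accuracy: Optional[MetricWithCI]
    sensitivity: Optional[MetricWithCI]
    specificity: Optional[MetricWithCI]
    ppv: Optional[MetricWithCI]
    npv: Optional[MetricWithCI]
    auc: Optional[float] = None
    roc: Optional[tuple] = None
    median_iou: Optional[float] = None
    kappa: Optional[float] = None
    mcnemar_p: Optional[float] = None
    strata: dict = field(default_factory=dict)  # e.g. per-modality sub-reports

    def to_dict(self, include_strata: bool = True) -> dict:
        def m(x: Optional[MetricWithCI]):
            if x is None:
                return None
            return {"estimate": x.estimate, "ci_low": x.ci_low,
                    "ci_high": x.ci_high, "method": x.method, "level": x.level}

        out = {
            "counts": {"tp": self.counts.tp, "fp": self.counts.fp,
                       "fn": self.counts.fn, "tn": self.counts.tn},
            "accuracy": m(self.accuracy),
            "sensitivity": m(self.sensitivity),
            "specificity": m(self.specificity),
            "ppv": m(self.ppv),
            "npv": m(self.npv),
            "auc": self.auc,
            "median_iou": self.median_iou,
            "kappa": self.kappa,
            "mcnemar_p": self.mcnemar_p,
        }
        if include_strata and self.strata:
            out["strata"] = {k: v.to_dict(include_strata=False)
                             for k, v in self.strata.items()}
        return out

    def to_markdown(self) -> str:
        rows = ["| metric | estimate (95% CI) |", "|---|---|"]

        def fmt(name, x: Optional[MetricWithCI]):
            if x is None:
                return f"| {name} | undefined |"
            return (f"| {name} | {x.estimate:.3f} "
                    f"({x.ci_low:.3f}–{x.ci_high:.3f}) |")

        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            rows.append(fmt(name, getattr(self, name)))
        if self.auc is not None:
            rows.append(f"| AUC | {self.auc:.3f} |")
        if self.median_iou is not None:
            rows.append(f"| median IoU | {self.median_iou:.3f} |")
        if self.kappa is not None:
            rows.append(f"| kappa | {self.kappa:.3f} |")
        if self.mcnemar_p is not None:
            rows.append(f"| McNemar p | {self.mcnemar_p:.4g} |")
        return "\n".join(rows)


def build_report(
    predictions,
    truths,
    scores=None,
    pred_masks=None,
    true_masks=None,
    paired_rater=None,
    modalities=None,
    ci_method: str = "clopper_pearson",
    level: float = 0.95,
) -> EvalReport:
    """Assemble every applicable statistic for one evaluation set.

    ``predictions``/``truths`` are binary calls; ``scores`` (continuous,
    e.g. largest-component area or longest-run seconds) enable ROC/AUC;
    mask pairs enable median IoU; ``paired_rater`` (a second classifier's
    calls on the same cases) enables kappa and the McNemar comparison;
    ``modalities`` adds per-modality (WLI / NBI) sub-reports whose counts
    partition the pooled table.
    """
    pred = np.asarray(predictions, dtype=bool)
    tru = np.asarray(truths, dtype=bool)
    counts = ConfusionCounts.from_calls(pred, tru)

    def prop(num, den):
        if den == 0:
            return None
        return metric_with_ci(num, den, level=level, method=ci_method)

    report = EvalReport(
        counts=counts,
        accuracy=prop(counts.tp + counts.tn, counts.total),
        sensitivity=prop(counts.tp, counts.tp + counts.fn),
        specificity=prop(counts.tn, counts.tn + counts.fp),
        ppv=prop(counts.tp, counts.tp + counts.fp),
        npv=prop(counts.tn, counts.tn + counts.fn),
    )
    if scores is not None:
        auc, curve = roc_auc(scores, tru)
        report.auc = auc
        report.roc = curve
    if pred_masks is not None and true_masks is not None:
        report.median_iou = median_iou(pred_masks, true_masks)
    if paired_rater is not None:
        rater = np.asarray(paired_rater, dtype=bool)
        report.kappa = cohens_kappa(pred.astype(int), rater.astype(int))
        _, _, report.mcnemar_p = compare_paired_classifiers(pred, rater, tru)
    if modalities is not None:
        mods = np.asarray([getattr(m, "value", m) for m in modalities])
        for mod in ("WLI", "NBI"):
            sel = mods == mod
            if sel.any() and 0 < tru[sel].sum() < sel.sum():
                report.strata[mod] = build_report(
                    pred[sel], tru[sel],
                    scores=None if scores is None else np.asarray(scores, float)[sel],
                    ci_method=ci_method, level=level,
                )
            elif sel.any():
                report.strata[mod] = build_report(
                    pred[sel], tru[sel], ci_method=ci_method, level=level
                )
    return report
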