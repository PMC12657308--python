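"""Binary-classification evaluation: confusion metrics, curves, agreement.

Provides the six standard confusion-matrix metrics (sensitivity,
specificity, PPV, NPV, F1, accuracy) with Wilson-score confidence
intervals, ROC/PR curves with AUROC (trapezoid, equal to the Mann-Whitney
ranking probability) and step-wise AUPRC, Cohen's kappa for label-set
agreement, and a reconstruction bridge that turns printed
sensitivity/specificity plus class sizes back into an integer confusion
matrix so published metric grids can be checked cell by cell.

Numerical conventions:
- metrics with a zero denominator are *flagged undefined* (NaN + tag),
  never silently coerced to 0;
- AUROC confidence intervals use DeLong's method; AUPRC uses a stratified
  bootstrap; the method tag is always carried along;
- rounding to 3 decimals happens only at report-rendering time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve
from sklearn.metrics import auc as _trapezoid_auc
from statsmodels.stats.proportion import proportion_confint

METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv", "f1", "accuracy")


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix must contain at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_labels(cls, predicted, truth) -> "ConfusionMatrix":
        p = np.asarray(predicted)
        t = np.asarray(truth)
        if p.shape != t.shape:
            raise ValueError("predicted and true labels must have equal length")
        for arr in (p, t):
            vals = np.unique(arr)
            if not np.all(np.isin(vals, [0, 1, True, False])):
                raise ValueError("labels must be binary")
        p = p.astype(bool)
        t = t.astype(bool)
        return cls(
            tp=int((p & t).sum()),
            fp=int((p & ~t).sum()),
            fn=int((~p & t).sum()),
            tn=int((~p & ~t).sum()),
        )


@dataclass
class MetricSet:
    """Point estimates with CIs; undefined metrics flagged, not zeroed."""

    points: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    undefined: set[str] = field(default_factory=set)
    ci_method: str = "wilson"

    def __getitem__(self, name: str) -> float:
        return self.points[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "point": self.points,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "undefined": {m: m in self.undefined for m in self.points},
            }
        )


def proportion_ci(numerator: int, denominator: int, level: float = 0.95,
                  method: str = "wilson") -> tuple[float, float]:
    """Confidence interval for a binomial proportion (Wilson by default)."""
    if denominator <= 0 or not 0 <= numerator <= denominator:
        raise ValueError("need 0 <= numerator <= denominator, denominator > 0")
    sm_method = {"wilson": "wilson", "clopper-pearson": "beta"}[method]
    lo, hi = proportion_confint(numerator, denominator, alpha=1 - level,
                                method=sm_method)
    # degenerate counts hit the exact boundary (avoids float dust from the
    # Wilson closed form)
    lo = 0.0 if numerator == 0 else float(lo)
    hi = 1.0 if numerator == denominator else float(hi)
    return lo, hi


def classification_metrics(cm: ConfusionMatrix, level: float = 0.95,
                           ci_method: str = "wilson") -> MetricSet:
    """The six confusion-matrix metrics with proportion CIs.

    Each metric is a ratio of counts, so its CI is computed as a binomial
    proportion on its own numerator/denominator (F1 uses the 2tp out of
    2tp+fp+fn representation).
    """
    pairs = {
        "sensitivity": (cm.tp, cm.tp + cm.fn),
        "specificity": (cm.tn, cm.tn + cm.fp),
        "ppv": (cm.tp, cm.tp + cm.fp),
        "npv": (cm.tn, cm.tn + cm.fn),
        "f1": (2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn),
        "accuracy": (cm.tp + cm.tn, cm.total),
    }
    points, lo, hi = {}, {}, {}
    undefined: set[str] = set()
    for name, (num, den) in pairs.items():
        if den == 0:
            points[name] = float("nan")
            lo[name] = float("nan")
            hi[name] = float("nan")
            undefined.add(name)
        else:
            points[name] = num / den
            lo[name], hi[name] = proportion_ci(num, den, level, ci_method)
    return MetricSet(points, lo, hi, undefined, ci_method)


def reconstruct_matrix_from_rates(sens: float, spec: float, n_pos: int,
                                  n_neg: int) -> ConfusionMatrix:
    """Integer confusion matrix consistent with printed sens/spec and class sizes.

    ``tp = round(sens * n_pos)``, ``tn = round(spec * n_neg)``; the
    remaining cells follow by subtraction.  Raises if rounding produces a
    negative cell.  Recomputing metrics from the result checks a published
    grid for integer consistency.
    """
    if not (0 <= sens <= 1 and 0 <= spec <= 1):
        raise ValueError("rates must lie in [0, 1]")
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("class sizes must be positive")
    tp = round(sens * n_pos)
    tn = round(spec * n_neg)
    return ConfusionMatrix(tp=tp, fp=n_neg - tn, fn=n_pos - tp, tn=tn)


@dataclass
class CurveSet:
    """ROC and/or PR curve points with areas and CI pairs."""

    roc_points: pd.DataFrame | None = None  # threshold, fpr, tpr
    pr_points: pd.DataFrame | None = None  # threshold, recall, precision
    auroc: float | None = None
    auroc_ci: tuple[float, float] | None = None
    auprc: float | None = None
    auprc_ci: tuple[float, float] | None = None
    methods: dict[str, str] = field(default_factory=dict)


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")


def _delong_auc_ci(scores: np.ndarray, labels: np.ndarray,
                   level: float) -> tuple[float, float, float]:
    """AUROC with DeLong variance (midrank formulation, ties counted 1/2)."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    all_s = np.concatenate([pos, neg])
    rank_all = pd.Series(all_s).rank(method="average").to_numpy()
    rank_pos = pd.Series(pos).rank(method="average").to_numpy()
    rank_neg = pd.Series(neg).rank(method="average").to_numpy()
    auc_hat = (rank_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (rank_all[:m] - rank_pos) / n  # structural components, positives
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m  # negatives
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return float(auc_hat), float(np.clip(auc_hat - half, 0, 1)), float(
        np.clip(auc_hat + half, 0, 1)
    )


def roc_and_auc(scores, labels, level: float = 0.95) -> CurveSet:
    """ROC curve and trapezoidal AUROC with a DeLong confidence interval.

    The trapezoidal area equals the Mann-Whitney probability that a random
    positive outranks a random negative (ties counted half).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    _check_two_classes(y)
    fpr, tpr, thr = roc_curve(y, s)
    auroc, lo, hi = _delong_auc_ci(s, y, level)
    points = pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
    return CurveSet(
        roc_points=points,
        auroc=float(_trapezoid_auc(fpr, tpr)),
        auroc_ci=(lo, hi),
        methods={"auroc": "trapezoid", "auroc_ci": "delong"},
    )


def pr_and_auc(scores, labels, level: float = 0.95, bootstrap: int = 2000,
               seed: int = 0) -> CurveSet:
    """PR curve and step-wise (interpolation-free) AUPRC.

    The area is average precision, i.e. sum of precision * recall
    increments — linear interpolation between PR points is biased and is
    deliberately not used.  The CI is a stratified bootstrap (resampling
    positives and negatives separately).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    _check_two_classes(y)
    precision, recall, thr = precision_recall_curve(y, s)
    auprc = float(average_precision_score(y, s))
    ci = None
    if bootstrap and bootstrap > 0:
        rng = np.random.default_rng(seed)
        pos_idx = np.flatnonzero(y)
        neg_idx = np.flatnonzero(~y)
        draws = np.empty(bootstrap)
        for b in range(bootstrap):
            take = np.concatenate(
                [
                    rng.choice(pos_idx, size=pos_idx.size, replace=True),
                    rng.choice(neg_idx, size=neg_idx.size, replace=True),
                ]
            )
            draws[b] = average_precision_score(y[take], s[take])
        alpha = 1 - level
        ci = (
            float(np.quantile(draws, alpha / 2)),
            float(np.quantile(draws, 1 - alpha / 2)),
        )
    points = pd.DataFrame(
        {
            "threshold": np.concatenate([thr, [np.inf]]),
            "recall": recall,
            "precision": precision,
        }
    )
    return CurveSet(
        pr_points=points,
        auprc=auprc,
        auprc_ci=ci,
        methods={
            "auprc": "step-wise (average precision)",
            "auprc_ci": f"stratified bootstrap ({bootstrap} draws)",
        },
    )


def cohens_kappa(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two binary label vectors.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with expected agreement from the
    marginal products; degenerate marginals (``p_e == 1``) yield NaN.
    """
    a = np.asarray(labels_a).astype(bool)
    b = np.asarray(labels_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    n = a.size
    if n == 0:
        raise ValueError("need at least one pair")
    p_o = float((a == b).mean())
    pa, pb = a.mean(), b.mean()
    p_e = pa * pb + (1 - pa) * (1 - pb)
    if p_e >= 1.0:
        return float("nan")
    return float((p_o - p_e) / (1.0 - p_e))


@dataclass
class AgreementReport:
    """Gold-vs-silver label agreement on the overlapping patients."""

    n_overlap: int
    accuracy: float
    kappa: float
    crosstab: pd.DataFrame

    def to_text(self) -> str:
        return (
            f"agreement on n = {self.n_overlap} overlapping patients\n"
            f"accuracy = {self.accuracy:.3f}   Cohen's kappa = {self.kappa:.3f}\n"
            f"{self.crosstab.to_string()}"
        )


def agreement_report(labels_a: pd.Series, labels_b: pd.Series) -> AgreementReport:
    """Cross-tabulate two patient-indexed label series on their overlap."""
    common = labels_a.index.intersection(labels_b.index)
    if len(common) == 0:
        raise ValueError("label sets share no patients")
    a = labels_a.loc[common].astype(bool)
    b = labels_b.loc[common].astype(bool)
    ct = pd.crosstab(a, b, rownames=["a"], colnames=["b"], dropna=False)
    return AgreementReport(
        n_overlap=len(common),
        accuracy=float((a == b).mean()),
        kappa=cohens_kappa(a.to_numpy(), b.to_numpy()),
        crosstab=ct,
    )


def render_metric_table(rows: dict[str, MetricSet]) -> str:
    """Aligned-column, forest-plot-ready table (3-decimal rendering)."""
    lines = [f"{'classifier':<24}{'metric':<14}{'point':>8}{'ci_low':>8}{'ci_high':>8}"]
    for name, ms in rows.items():
        for metric in METRIC_NAMES:
            if metric in ms.undefined:
                lines.append(f"{name:<24}{metric:<14}{'--':>8}{'--':>8}{'--':>8}")
            else:
                lines.append(
                    f"{name:<24}{metric:<14}{ms.points[metric]:8.3f}"
                    f"{ms.ci_low[metric]:8.3f}{ms.ci_high[metric]:8.3f}"
                )
    return "\n".join(lines)
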