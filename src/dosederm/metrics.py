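"""Classification metrics, fold statistics and cohort-table tests.

All confusion-matrix metrics follow the standard definitions

    ACC  = (TP + TN) / (TP + TN + FP + FN)
    Recall = Sensitivity = TP / (TP + FN)
    Specificity = TN / (TN + FP)
    PPV = Precision = TP / (TP + FP)
    NPV = TN / (TN + FN)
    F1  = 2 * PPV * Recall / (PPV + Recall)

with the conventions PPV = 0 when TP+FP = 0, NPV = 0 when TN+FN = 0 and
F1 = 0 when PPV+Recall = 0 (degenerate predictors yield defined outputs).

AUC uses the Mann-Whitney formulation (ties count 1/2).  Fold confidence
intervals use the t distribution with k-1 degrees of freedom.  The cohort
comparison tests are Pearson chi-square without continuity correction
(categorical 2xk tables) and the pooled-variance Student t computed from
per-group (mean, SD, n) summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class MetricSet:
    """Confusion counts plus derived fractions for one evaluation."""

    tp: int
    fp: int
    tn: int
    fn: int
    acc: float
    recall: float
    specificity: float
    ppv: float
    npv: float
    f1: float
    auc: float | None = None
    brier: float | None = None

    def as_dict(self) -> dict:
        d = {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "ACC": self.acc, "Recall": self.recall,
            "Specificity": self.specificity, "PPV": self.ppv,
            "NPV": self.npv, "F1": self.f1,
        }
        if self.auc is not None:
            d["AUC"] = self.auc
        if self.brier is not None:
            d["Brier"] = self.brier
        return d


@dataclass
class SummaryPair:
    """(mean, SD, n) summary of one group of a continuous variable."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("summary requires n >= 2")
        if self.sd < 0:
            raise ValueError("SD must be >= 0")


def confusion_metrics(y_true, y_pred) -> MetricSet:
    """Metric set from binary labels and binary predictions."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.size == 0:
        raise ValueError("no samples")
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    n = tp + fp + tn + fn
    acc = (tp + tn) / n
    recall = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    ppv = tp / (tp + fp) if tp + fp else 0.0
    npv = tn / (tn + fn) if tn + fn else 0.0
    f1 = 2 * ppv * recall / (ppv + recall) if ppv + recall else 0.0
    return MetricSet(tp, fp, tn, fn, acc, recall, spec, ppv, npv, f1)


def auc(y_true, scores) -> float:
    """Mann-Whitney AUC; ties contribute 1/2."""
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(y_true.sum())
    n_neg = int(y_true.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("undefined AUC: only one class present")
    ranks = stats.rankdata(scores)  # midranks handle ties
    r_pos = ranks[y_true == 1].sum()
    u = r_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def brier_score(y_true, probs) -> float:
    """Mean squared error of predicted probabilities."""
    y_true = np.asarray(y_true, dtype=float)
    probs = np.asarray(probs, dtype=float)
    return float(np.mean((probs - y_true) ** 2))


def fold_ci(values, confidence: float = 0.95) -> tuple[float, float, float]:
    """Mean and t-based CI of k per-fold metric values: mean +/- t * sd/sqrt(k)."""
    values = np.asarray(values, dtype=float)
    k = values.size
    if k < 2:
        raise ValueError("insufficient folds: need k >= 2")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, df=k - 1)
    half = tcrit * sd / np.sqrt(k)
    return mean, mean - half, mean + half


def cohens_d(a, b) -> float:
    """Effect size (mean_a - mean_b) / pooled SD between two metric samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    diff = a.mean() - b.mean()
    na, nb = a.size, b.size
    pooled_var = (
        ((na - 1) * a.var(ddof=1) if na > 1 else 0.0)
        + ((nb - 1) * b.var(ddof=1) if nb > 1 else 0.0)
    ) / max(na + nb - 2, 1)
    pooled_sd = np.sqrt(pooled_var)
    if pooled_sd == 0:
        if diff == 0:
            return 0.0
        return float(np.sign(diff) * np.inf)  # flagged degenerate case
    return float(diff / pooled_sd)


@dataclass
class MetricReport:
    """Per-outer-fold metric sets plus pooled out-of-fold predictions."""

    folds: list[MetricSet]
    pooled_y: np.ndarray = None
    pooled_probs: np.ndarray = None
    thresholds: float = 0.5

    def metric_values(self, name: str) -> np.ndarray:
        return np.array([m.as_dict()[name] for m in self.folds], dtype=float)

    def summary(self, confidence: float = 0.95) -> dict:
        """Mean and t-based 95% CI per metric across the outer folds."""
        out = {}
        for name in self.folds[0].as_dict():
            if name in ("TP", "FP", "TN", "FN"):
                continue
            mean, lo, hi = fold_ci(self.metric_values(name), confidence)
            out[name] = {"mean": mean, "ci_low": lo, "ci_high": hi}
        return out


def compare_reports(a: MetricReport, b: MetricReport, metric: str = "AUC") -> float:
    """Cohen's d between two models' per-fold values of one metric."""
    return cohens_d(a.metric_values(metric), b.metric_values(metric))


@dataclass
class NetBenefitCurve:
    """Decision-curve analysis output over a threshold range."""

    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_treat_all: np.ndarray
    nb_treat_none: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.nb_treat_none is None:
            self.nb_treat_none = np.zeros_like(self.thresholds)


@dataclass
class ThresholdReport:
    threshold: float
    ppv: float
    npv: float
    fpr: float
    fnr: float
    youden_j: float


def _threshold_report(y_true, probs, thr) -> ThresholdReport:
    m = confusion_metrics(y_true, (np.asarray(probs) >= thr).astype(int))
    fpr = 1.0 - m.specificity
    fnr = 1.0 - m.recall
    return ThresholdReport(float(thr), m.ppv, m.npv, fpr, fnr,
                           m.recall + m.specificity - 1.0)


def decision_curve(y_true, probs, thresholds):
    """Net-benefit curve plus operating-point reports at 0.5 and the Youden cut.

    NB_model(t) = TP/n - (FP/n) * t/(1-t); treat-all uses all-positive calls;
    treat-none is identically zero.  The Youden threshold maximizes
    Sensitivity + Specificity - 1 over the observed score cut-points.
    """
    y_true = np.asarray(y_true).astype(int)
    probs = np.asarray(probs, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("invalid threshold: must lie in (0,1)")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0,1]")
    n = y_true.size
    prevalence = y_true.mean()
    nb_model = np.empty_like(thresholds)
    for i, t in enumerate(thresholds):
        pred = (probs >= t).astype(int)
        tp = np.sum((y_true == 1) & (pred == 1))
        fp = np.sum((y_true == 0) & (pred == 1))
        nb_model[i] = tp / n - (fp / n) * t / (1 - t)
    nb_all = prevalence - (1 - prevalence) * thresholds / (1 - thresholds)
    curve = NetBenefitCurve(thresholds, nb_model, nb_all)

    cuts = np.unique(probs)
    best = max(cuts, key=lambda c: _threshold_report(y_true, probs, c).youden_j)
    return curve, {
        "default": _threshold_report(y_true, probs, 0.5),
        "youden": _threshold_report(y_true, probs, best),
    }


def chi_square_2xk(table) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on a 2xk count table."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("table must be 2-D")
    if np.any(table < 0) or np.any(table != np.round(table)):
        raise ValueError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate table: zero marginal")
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / table.sum()
    chi2 = float(((table - expected) ** 2 / expected).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def pooled_t_from_summary(a: SummaryPair, b: SummaryPair) -> tuple[float, int, float]:
    """Two-sided pooled-variance Student t test from group summaries."""
    df = a.n + b.n - 2
    pooled_var = ((a.n - 1) * a.sd ** 2 + (b.n - 1) * b.sd ** 2) / df
    se = np.sqrt(pooled_var * (1 / a.n + 1 / b.n))
    if se == 0:
        return 0.0, df, 1.0
    t = float((a.mean - b.mean) / se)
    p = float(2 * stats.t.sf(abs(t), df))
    return t, df, p
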