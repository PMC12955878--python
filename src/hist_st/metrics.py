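"""Evaluation metrics: segmentation confusion metrics and ROC/AUC, per-gene
correlations with t-based confidence intervals, Harrell's concordance index,
median-split Kaplan-Meier with the log-rank test, and classification metrics.

Segmentation metrics are computed at a stated probability threshold over the
valid (spot-bearing) grid cells by default; "SE" follows the segmentation
literature's usage as sensitivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex
from scipy import stats
from sklearn import metrics as skm

from .grid import LabelGrid

__all__ = [
    "ConfusionCounts", "CorrelationSummary",
    "confusion_metrics", "roc_auc", "per_gene_correlation", "mean_t_ci",
    "concordance_index", "median_split", "km_logrank", "km_curve",
    "classification_metrics",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class CorrelationSummary:
    per_gene_r: pd.Series
    mean_r: float
    ci95: tuple[float, float]


def _flatten_valid(probs, truth, valid_only: bool):
    if isinstance(probs, LabelGrid):
        probs = probs.values
    p = np.asarray(probs)
    if p.ndim == 3 and p.shape[0] == 1:
        p = p[0]
    if isinstance(truth, LabelGrid):
        mask = truth.validity if valid_only else np.ones(truth.values.shape, bool)
        t = truth.values
    else:
        t = np.asarray(truth)
        mask = np.ones(t.shape, dtype=bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: probs {p.shape} vs truth {t.shape}")
    return p[mask], t[mask]


def confusion_metrics(probs, truth, threshold: float = 0.5,
                      valid_only: bool = True) -> dict[str, float]:
    """IOU, Dice, sensitivity (SE), precision (PC), F1, specificity (SP), ACC.

    With an empty positive class, sensitivity-family metrics are reported as
    nan (missing) rather than raising.
    """
    p, t = _flatten_valid(probs, truth, valid_only)
    pred = p >= threshold
    pos = t >= 0.5
    tp = int((pred & pos).sum())
    fp = int((pred & ~pos).sum())
    fn = int((~pred & pos).sum())
    tn = int((~pred & ~pos).sum())

    def _safe(num, den):
        return num / den if den > 0 else float("nan")

    se = _safe(tp, tp + fn)
    pc = _safe(tp, tp + fp)
    return {
        "iou": _safe(tp, tp + fp + fn),
        "dice": _safe(2 * tp, 2 * tp + fp + fn),
        "se": se,
        "pc": pc,
        "f1": _safe(2 * pc * se, pc + se) if np.isfinite(pc) and np.isfinite(se)
              else float("nan"),
        "sp": _safe(tn, tn + fp),
        "acc": _safe(tp + tn, tp + fp + tn + fn),
        "counts": ConfusionCounts(tp, fp, tn, fn),
    }


def roc_auc(probs, truth, valid_only: bool = True) -> float:
    """Rank-based AUC over valid cells; ties count one half."""
    p, t = _flatten_valid(probs, truth, valid_only)
    labels = (t >= 0.5).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: a single class among evaluated cells")
    return float(skm.roc_auc_score(labels, p))


def roc_curve_points(probs, truth, valid_only: bool = True) -> pd.DataFrame:
    p, t = _flatten_valid(probs, truth, valid_only)
    fpr, tpr, thr = skm.roc_curve((t >= 0.5).astype(int), p)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def mean_t_ci(values: Sequence[float], confidence: float = 0.95):
    """Mean with its Student-t confidence interval (e.g. across CV folds)."""
    v = np.asarray(values, dtype=float)
    m = float(v.mean())
    if len(v) < 2:
        return m, (float("nan"), float("nan"))
    half = stats.t.ppf(0.5 + confidence / 2, df=len(v) - 1) * stats.sem(v)
    return m, (m - float(half), m + float(half))


def per_gene_correlation(pred: pd.DataFrame, truth: pd.DataFrame,
                         kind: Literal["pearson", "spearman"] = "pearson"
                         ) -> CorrelationSummary:
    """One correlation per gene between predicted and observed spot profiles.

    Inputs are genes x spots tables sharing index and columns.  Genes with
    zero variance on either side are excluded with a warning.  The summary
    CI is the t-based interval over the per-gene values; for fold-level
    summaries, pass per-fold means to :func:`mean_t_ci` instead.
    """
    if list(pred.index) != list(truth.index):
        truth = truth.loc[pred.index]
    if list(pred.columns) != list(truth.columns):
        truth = truth[pred.columns]
    if pred.shape[1] < 2:
        raise ValueError("need at least two spots per gene")
    p = pred.to_numpy(dtype=float)
    t = truth.to_numpy(dtype=float)
    const = (p.std(axis=1) == 0) | (t.std(axis=1) == 0)
    if const.any():
        warnings.warn(f"{int(const.sum())} gene(s) with zero variance excluded "
                      "from correlation")
    rs = {}
    fn = stats.pearsonr if kind == "pearson" else stats.spearmanr
    for gi, gene in enumerate(pred.index):
        if const[gi]:
            continue
        rs[gene] = float(fn(p[gi], t[gi])[0])
    series = pd.Series(rs, name=f"{kind}_r")
    mean_r, ci = mean_t_ci(series.to_numpy())
    return CorrelationSummary(per_gene_r=series, mean_r=mean_r, ci95=ci)


def concordance_index(risks, times, events) -> float:
    """Harrell's C: among comparable pairs (t_i < t_j, event_i = 1), the
    fraction where the earlier-event subject has the higher risk (risk ties
    count one half)."""
    risks = np.asarray(risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() == 0:
        raise ValueError("concordance undefined: no comparable pairs (no events)")
    # lifelines scores "higher prediction = longer survival"; risks invert that
    return float(_lifelines_cindex(times, -risks, events))


def median_split(risks) -> np.ndarray:
    """High/low risk groups about the median; ties assigned to low."""
    risks = np.asarray(risks, dtype=float)
    return np.where(risks > np.median(risks), "high", "low")


def km_logrank(times, events, groups) -> dict:
    """Two-group log-rank test (1 df) plus per-group KM curves."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    names = np.unique(groups)
    if len(names) != 2:
        raise ValueError(f"expected exactly two nonempty groups, got {list(names)}")
    a = groups == names[0]
    res = logrank_test(times[a], times[~a], events[a], events[~a])
    curves = {str(name): km_curve(times[groups == name], events[groups == name])
              for name in names}
    return {"statistic": float(res.test_statistic), "p_value": float(res.p_value),
            "groups": [str(n) for n in names], "curves": curves}


def km_curve(times, events) -> pd.DataFrame:
    """Kaplan-Meier step-function coordinates (time, survival)."""
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(),
                         "survival": sf.iloc[:, 0].to_numpy()})


def classification_metrics(pred_labels, truth, positive: int = 1,
                           average: Literal["binary", "macro", "micro"] = "binary"
                           ) -> dict[str, float]:
    """Accuracy, precision, recall, F1 (positive class = responder)."""
    y, t = np.asarray(pred_labels), np.asarray(truth)
    kwargs = {"zero_division": 0.0}
    if average == "binary":
        kwargs["pos_label"] = positive
    kwargs["average"] = average
    return {
        "accuracy": float(skm.accuracy_score(t, y)),
        "precision": float(skm.precision_score(t, y, **kwargs)),
        "recall": float(skm.recall_score(t, y, **kwargs)),
        "f1": float(skm.f1_score(t, y, **kwargs)),
    }
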