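"""Classifier performance evaluation.

Confusion-table metrics (accuracy, sensitivity, specificity, PPV, NPV,
baseline response rate) are computed as exact rationals of counts so that
the rounded integer percentages compared with reported values are not
at the mercy of floating-point rounding.  ROC AUC is the rank statistic
(Mann-Whitney U / (n+ * n-), half credit for ties), which equals the
trapezoidal area over all distinct thresholds.  Cross-validation is
repeated stratified k-fold with any feature selection re-run inside each
training fold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from . import bayes
from .discovery import as_sensitive_mask

__all__ = [
    "ConfusionTable", "confusion_metrics", "percent",
    "roc_auc", "roc_curve_points", "pr_curve", "cross_validate",
    "fisher_exact_2x2",
]


@dataclass(frozen=True)
class ConfusionTable:
    """Counts with predicted-sensitive as the positive call."""
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.total == 0:
            raise ValueError("confusion table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_calls(cls, truth, predicted) -> "ConfusionTable":
        t = as_sensitive_mask(truth)
        p = as_sensitive_mask(predicted)
        return cls(tp=int((t & p).sum()), fp=int((~t & p).sum()),
                   fn=int((t & ~p).sum()), tn=int((~t & ~p).sum()))


def _ratio(num: int, den: int) -> Fraction | None:
    return Fraction(num, den) if den > 0 else None


def percent(value) -> int | None:
    """Round a proportion to integer percent, half away from zero."""
    if value is None:
        return None
    x = Fraction(value) * 100
    q, r = divmod(abs(x.numerator), x.denominator)
    pct = q + (1 if 2 * r >= x.denominator else 0)
    return int(math.copysign(pct, x))


def confusion_metrics(table: ConfusionTable) -> dict:
    """Standard confusion metrics as exact fractions (None when the
    denominator is zero), plus the baseline response rate (TP+FN)/total."""
    t = table
    return {
        "accuracy": _ratio(t.tp + t.tn, t.total),
        "sensitivity": _ratio(t.tp, t.tp + t.fn),
        "specificity": _ratio(t.tn, t.tn + t.fp),
        "ppv": _ratio(t.tp, t.tp + t.fp),
        "npv": _ratio(t.tn, t.tn + t.fn),
        "baseline_response_rate": _ratio(t.tp + t.fn, t.total),
    }


def roc_auc(posteriors, labels) -> float:
    """AUC as the pairwise-comparison (rank) statistic with tie credit."""
    y = as_sensitive_mask(labels)
    if y.all() or not y.any():
        raise ValueError("AUC needs both classes")
    s = np.asarray(posteriors, dtype=float)
    ranks = stats.rankdata(s)
    n1 = int(y.sum())
    n0 = y.size - n1
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_curve_points(posteriors, labels) -> pd.DataFrame:
    """(FPR, TPR) at every distinct threshold, descending threshold order
    (ties step simultaneously)."""
    y = as_sensitive_mask(labels)
    s = np.asarray(posteriors, dtype=float)
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)) , s.size - 1]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(~y)[distinct]
    n1, n0 = y.sum(), (~y).sum()
    return pd.DataFrame({
        "threshold": np.r_[np.inf, s[distinct]],
        "fpr": np.r_[0, fp / n0],
        "tpr": np.r_[0, tp / n1],
    })


def pr_curve(posteriors, labels) -> pd.DataFrame:
    """Precision/recall at every distinct threshold (descending)."""
    y = as_sensitive_mask(labels)
    s = np.asarray(posteriors, dtype=float)
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tp = np.cumsum(y)[distinct]
    called = distinct + 1
    return pd.DataFrame({
        "threshold": s[distinct],
        "precision": tp / called,
        "recall": tp / y.sum(),
    })


def cross_validate(matrix: pd.DataFrame, labels, fit_fn=None, folds: int = 5,
                   repeats: int = 5, seed: int = 0,
                   threshold_objective: str = "youden") -> dict:
    """Repeated stratified k-fold cross-validation.

    ``fit_fn(train_matrix, train_mask) -> SignatureModel`` is called inside
    each training fold, so any feature selection it performs never sees the
    held-out fold.  The decision threshold is tuned on the training-fold
    posteriors (Youden-style by default).  Metrics are pooled per repeat
    and reported as mean +/- SEM over repeats; per-repeat ROC curves are
    returned for plotting.
    """
    mask = as_sensitive_mask(labels, matrix.columns)
    n_min = min(mask.sum(), (~mask).sum())
    if n_min < folds:
        raise ValueError(f"smallest class ({n_min}) smaller than folds={folds}")
    seeds = np.random.SeedSequence(seed).generate_state(repeats)
    if fit_fn is None:
        fit_fn = bayes.fit
    per_repeat = []
    curves = []
    y_int = mask.astype(int)
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(seeds[r] % (2 ** 31)))
        post = np.empty(mask.size)
        pred = np.zeros(mask.size, dtype=bool)
        for train, test in skf.split(np.zeros(mask.size), y_int):
            model = fit_fn(matrix.iloc[:, train], mask[train])
            train_post = bayes.predict_posterior(model, matrix.iloc[:, train])
            try:
                thr = bayes.choose_threshold(train_post, mask[train],
                                             objective=threshold_objective)
            except ValueError:
                thr = model.threshold_default
            fold_post = bayes.predict_posterior(model, matrix.iloc[:, test])
            post[test] = fold_post.to_numpy()
            pred[test] = fold_post.to_numpy() >= thr
        table = ConfusionTable.from_calls(mask, pred)
        metrics = {k: (float(v) if v is not None else np.nan)
                   for k, v in confusion_metrics(table).items()}
        metrics["auc"] = roc_auc(post, mask)
        per_repeat.append(metrics)
        curves.append(roc_curve_points(post, mask))
    df = pd.DataFrame(per_repeat)
    if repeats > 1:
        sem = df.std(ddof=1) / math.sqrt(repeats)
    else:
        sem = pd.Series(np.nan, index=df.columns)
    return {"mean": df.mean().to_dict(), "sem": sem.to_dict(),
            "per_repeat": df, "roc_curves": curves}


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test (probability-mass summation) and the
    sample odds ratio (a*d)/(b*c).  A zero margin yields p = 1 with a
    warning."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("zero margin in 2x2 table: p = 1")
        return 1.0, float("nan")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return float(p), float(odds)
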