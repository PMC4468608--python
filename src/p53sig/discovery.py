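"""Bootstrapped gene-signature discovery.

The procedure mirrors the published protocol: a variance filter drops the
low-variance half of the genes; within each of 20 bootstrapped 2/3 / 1/3
stratified splits the genes are ranked by two-sided Wilcoxon rank-sum
p-value on the training split, a naive Bayes classifier is trained on the
top-k genes and scored on the held-out third, for k = 5..100; the model
size is the smallest k whose mean accuracy is within one SEM of the
maximum; a final 100-bootstrap stability selection tabulates how often
each gene enters the top-k, and the signature is the k most frequently
selected genes (with a substitution rule for excluded/unannotated
features).

"Bootstrapped data splits" are repeated stratified random subsampling
WITHOUT replacement (2/3 train / 1/3 test), matching the split description
rather than classical resampling with replacement.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import bayes

__all__ = [
    "variance_filter", "wilcoxon_pvalues", "rank_features",
    "stratified_split", "size_scan", "select_size_1sem", "stability_select",
    "StabilityResult",
]

#: largest group size for which the exact rank-sum null distribution is used
EXACT_MAX_N = 25


def as_sensitive_mask(labels, columns=None) -> np.ndarray:
    """Normalize labels (bool array, or 'sensitive'/'insensitive' strings,
    optionally a Series indexed by sample id) to a boolean mask."""
    if isinstance(labels, pd.Series) and columns is not None:
        labels = labels.reindex(columns)
        if labels.isna().any():
            missing = list(labels.index[labels.isna()])[:5]
            raise ValueError(f"labels missing for samples {missing}")
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr
    return arr == "sensitive"


def variance_filter(matrix: pd.DataFrame, keep_fraction: float = 0.5) -> pd.DataFrame:
    """Retain the ceil(keep_fraction * F) features of highest sample
    variance, preserving the original feature order."""
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError(f"keep_fraction {keep_fraction} not in (0, 1]")
    if matrix.empty:
        raise ValueError("empty expression matrix")
    n_keep = math.ceil(keep_fraction * matrix.shape[0])
    var = matrix.var(axis=1, ddof=1).to_numpy()
    # ties at the cutoff are broken toward earlier rows (stable sort on -var)
    order = np.argsort(-var, kind="stable")[:n_keep]
    mask = np.zeros(matrix.shape[0], dtype=bool)
    mask[order] = True
    return matrix.loc[mask]


def _ranksum_asymptotic(X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    """Vectorized two-sided rank-sum p-values, normal approximation with
    continuity and tie correction.  X1, X2: (features, n1) and (features, n2)."""
    n1, n2 = X1.shape[1], X2.shape[1]
    n = n1 + n2
    X = np.concatenate([X1, X2], axis=1)
    order = np.argsort(X, axis=1, kind="stable")
    srt = np.take_along_axis(X, order, axis=1)
    ranks = np.empty_like(order, dtype=float)
    rows = np.arange(X.shape[0])[:, None]
    ranks[rows, order] = np.arange(1, n + 1, dtype=float)
    tie_term = np.zeros(X.shape[0])
    tied_rows = np.nonzero((srt[:, 1:] == srt[:, :-1]).any(axis=1))[0]
    for i in tied_rows:
        ranks[i] = stats.rankdata(X[i])
        _, cnt = np.unique(srt[i], return_counts=True)
        tie_term[i] = (cnt ** 3 - cnt).sum()
    U1 = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    sd = np.sqrt(n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.abs(U1 - mu) - 0.5) / sd
    p = np.where(sd > 0, 2.0 * stats.norm.sf(z), 1.0)
    return np.clip(p, np.nextafter(0, 1), 1.0)


def wilcoxon_pvalues(X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-values, one per feature row.

    Uses the exact null distribution when both groups have <= 25 samples
    (tie-free data; falls back to the corrected normal approximation for
    rows with ties), the normal approximation otherwise.
    """
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    n1, n2 = X1.shape[1], X2.shape[1]
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes must be nonempty")
    if max(n1, n2) > EXACT_MAX_N:
        return _ranksum_asymptotic(X1, X2)
    p = np.empty(X1.shape[0])
    for i in range(X1.shape[0]):
        row = np.concatenate([X1[i], X2[i]])
        method = "asymptotic" if np.unique(row).size < row.size else "exact"
        p[i] = stats.mannwhitneyu(X1[i], X2[i], alternative="two-sided",
                                  method=method).pvalue
    return p


def rank_features(matrix: pd.DataFrame, labels) -> pd.DataFrame:
    """Rank features by two-sided Wilcoxon rank-sum p-value (ascending).

    Fold change is 2**(mean log2 sensitive - mean log2 insensitive).  Ties
    in p are broken by |log2 fold change| descending, then feature id.
    Returns a DataFrame with columns feature_id, p_value, fold_change,
    direction, sorted best-first.
    """
    mask = as_sensitive_mask(labels, matrix.columns)
    if mask.all() or not mask.any():
        raise ValueError("both classes must be present to rank features")
    X = matrix.to_numpy(dtype=float)
    p = wilcoxon_pvalues(X[:, mask], X[:, ~mask])
    log2fc = X[:, mask].mean(axis=1) - X[:, ~mask].mean(axis=1)
    out = pd.DataFrame({
        "feature_id": matrix.index.to_numpy(),
        "p_value": p,
        "fold_change": np.exp2(log2fc),
        "direction": np.where(log2fc >= 0, "up", "down"),
        "_abs_l2fc": np.abs(log2fc),
    })
    out = out.sort_values(["p_value", "_abs_l2fc", "feature_id"],
                          ascending=[True, False, True], kind="stable")
    return out.drop(columns="_abs_l2fc").reset_index(drop=True)


def stratified_split(mask: np.ndarray, train_fraction: float,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random split without replacement.  Per-class training
    counts are the class size times train_fraction rounded to the nearest
    integer (clamped so both sides are nonempty)."""
    train_idx = []
    test_idx = []
    for cls_mask in (mask, ~mask):
        idx = np.flatnonzero(cls_mask)
        if idx.size < 3:
            raise ValueError(
                f"class with {idx.size} samples cannot be split (need >= 3)")
        n_train = int(np.clip(round(idx.size * train_fraction), 1, idx.size - 1))
        perm = rng.permutation(idx)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def _top_k_features(matrix: pd.DataFrame, mask: np.ndarray,
                    train: np.ndarray, k_max: int) -> np.ndarray:
    """Feature ids of the k_max best-ranked features on the training split."""
    sub = matrix.iloc[:, train]
    ranked = rank_features(sub, mask[train])
    return ranked["feature_id"].to_numpy()[:k_max]


def size_scan(matrix: pd.DataFrame, labels, sizes=range(5, 101),
              repeats: int = 20, train_fraction: float = 2 / 3,
              seed: int = 0) -> pd.DataFrame:
    """Scan signature sizes by bootstrapped split / rank / fit / score.

    For each repeat a stratified 2/3 split is drawn, features are ranked on
    the training split only, and for each size k the top-k features feed a
    naive Bayes classifier scored on the held-out third.  Returns a
    DataFrame indexed by k with mean/SEM accuracy and mean sensitivity /
    specificity over repeats.
    """
    sizes = sorted(sizes)
    if sizes[-1] > matrix.shape[0]:
        raise ValueError(
            f"largest size {sizes[-1]} exceeds {matrix.shape[0]} features")
    mask = as_sensitive_mask(labels, matrix.columns)
    rng = np.random.default_rng(seed)
    acc = np.empty((repeats, len(sizes)))
    sens = np.empty((repeats, len(sizes)))
    spec = np.empty((repeats, len(sizes)))
    for r in range(repeats):
        train, test = stratified_split(mask, train_fraction, rng)
        top = _top_k_features(matrix, mask, train, sizes[-1])
        y_test = mask[test]
        for j, k in enumerate(sizes):
            model = bayes.fit(matrix.loc[top[:k]].iloc[:, train], mask[train])
            post = bayes.predict_posterior(model, matrix.loc[top[:k]].iloc[:, test])
            pred = post.to_numpy() >= model.threshold_default
            acc[r, j] = (pred == y_test).mean()
            sens[r, j] = pred[y_test].mean() if y_test.any() else np.nan
            spec[r, j] = (~pred[~y_test]).mean() if (~y_test).any() else np.nan
    if repeats == 1:
        warnings.warn("size_scan with repeats=1: SEM reported as 0")
        sem = np.zeros(len(sizes))
    else:
        sem = acc.std(axis=0, ddof=1) / math.sqrt(repeats)
    return pd.DataFrame({
        "mean_accuracy": acc.mean(axis=0), "sem_accuracy": sem,
        "mean_sensitivity": np.nanmean(sens, axis=0),
        "mean_specificity": np.nanmean(spec, axis=0),
        "repeats": repeats,
    }, index=pd.Index(sizes, name="k"))


def select_size_1sem(scan: pd.DataFrame) -> int:
    """Smallest size whose mean accuracy is within one SEM (at the argmax)
    of the maximum mean accuracy."""
    if scan.empty:
        raise ValueError("empty size scan")
    best = scan["mean_accuracy"].idxmax()
    floor = scan.loc[best, "mean_accuracy"] - scan.loc[best, "sem_accuracy"]
    ok = scan.index[scan["mean_accuracy"] >= floor]
    return int(ok.min())


@dataclass
class StabilityResult:
    counts: pd.Series          # feature_id -> selection count (desc)
    signature: list[str]       # final k features after exclusions
    repeats: int
    k: int


def stability_select(matrix: pd.DataFrame, labels, k: int,
                     repeats: int = 100, train_fraction: float = 2 / 3,
                     seed: int = 0, exclusion_list=()) -> StabilityResult:
    """Tabulate top-k selection frequency over bootstrapped training splits
    and assemble the final signature.

    The signature is the k most frequently selected features; any feature
    on ``exclusion_list`` is removed and replaced by the next most frequent
    candidate (the published run replaced one unannotated feature this
    way).  Frequency ties are broken by the feature's aggregate (all-sample)
    Wilcoxon p ascending, then by feature id.
    """
    if k > matrix.shape[0]:
        raise ValueError(f"k={k} exceeds {matrix.shape[0]} features")
    mask = as_sensitive_mask(labels, matrix.columns)
    rng = np.random.default_rng(seed)
    counts: dict[str, int] = {}
    for _ in range(repeats):
        train, _test = stratified_split(mask, train_fraction, rng)
        for f in _top_k_features(matrix, mask, train, k):
            counts[f] = counts.get(f, 0) + 1
    aggregate = rank_features(matrix, mask).set_index("feature_id")["p_value"]
    candidates = sorted(
        counts, key=lambda f: (-counts[f], aggregate.get(f, 1.0), f))
    excluded = set(exclusion_list)
    pool = [f for f in candidates if f not in excluded]
    if len(pool) < k:
        raise ValueError(
            f"exclusion list leaves {len(pool)} candidates, need {k}")
    count_series = pd.Series({f: counts[f] for f in candidates},
                             name="count").astype(int)
    return StabilityResult(counts=count_series, signature=pool[:k],
                           repeats=repeats, k=k)
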