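"""Multi-type significant-feature selection.

Reproduces the broader feature-landscape procedure that complements the
expression-only signature: features of several types (expression, copy
number, mutation, tumor-suppressor status, lineage, pathway) are first
deduplicated by affinity-propagation clustering (exemplars only are
tested), then tested for association with the sensitivity class -
two-sided Wilcoxon for continuous types, Fisher's exact test for discrete
types - corrected by Benjamini-Hochberg FDR *within* each feature type
("local" FDR, cutoff 0.25), with per-type minimum/maximum feature counts
enforced irrespective of the FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .discovery import as_sensitive_mask, wilcoxon_pvalues
from .evaluate import fisher_exact_2x2

__all__ = [
    "CONTINUOUS_TYPES", "DISCRETE_TYPES",
    "test_features", "bh_fdr", "affinity_propagation", "APResult",
    "assemble_set", "significant_features",
]

CONTINUOUS_TYPES = frozenset({"expression", "copy_number", "pathway"})
DISCRETE_TYPES = frozenset({"mutation", "tumor_suppressor_status", "lineage"})


def _pivot(table: pd.DataFrame) -> pd.DataFrame:
    """Long (feature_id, feature_type, sample_id, value) -> wide feature x sample."""
    wide = table.pivot_table(index=["feature_type", "feature_id"],
                             columns="sample_id", values="value",
                             aggfunc="first", observed=True)
    return wide


def test_features(table: pd.DataFrame, labels) -> pd.DataFrame:
    """Association of every feature with the sensitivity class.

    Continuous features get a two-sided Wilcoxon rank-sum test (direction =
    sign of the mean difference); discrete features get Fisher's exact test
    on the class x category table (2x2 for binary; >2 levels collapse to
    level-vs-rest with a Bonferroni factor over levels).  Constant features
    are flagged with p = 1.
    """
    wide = _pivot(table)
    samples = wide.columns
    mask = as_sensitive_mask(labels, samples)
    if mask.all() or not mask.any():
        raise ValueError("both classes must be present")
    rows = []
    for (ftype, fid), vals in wide.iterrows():
        if ftype in CONTINUOUS_TYPES:
            x = vals.to_numpy(dtype=float)
            if np.unique(x).size == 1:
                rows.append((fid, ftype, 1.0, "none", "constant", True))
                continue
            p = float(wilcoxon_pvalues(x[None, mask], x[None, ~mask])[0])
            direction = "up" if x[mask].mean() >= x[~mask].mean() else "down"
            rows.append((fid, ftype, p, direction, "wilcoxon", False))
        else:
            v = vals.astype(str)
            levels = sorted(v.unique())
            if len(levels) == 1:
                rows.append((fid, ftype, 1.0, "none", "constant", True))
                continue
            if len(levels) == 2:
                a = int((v[mask] == levels[0]).sum())
                b = int((v[mask] == levels[1]).sum())
                c = int((v[~mask] == levels[0]).sum())
                d = int((v[~mask] == levels[1]).sum())
                p, _ = fisher_exact_2x2([[a, b], [c, d]])
                enr_s = a / mask.sum() >= c / (~mask).sum()
                direction = "up" if enr_s else "down"
                rows.append((fid, ftype, p, direction, "fisher", False))
            else:
                # level-vs-rest, Bonferroni over levels
                best = 1.0
                direction = "none"
                for lv in levels:
                    a = int((v[mask] == lv).sum())
                    c = int((v[~mask] == lv).sum())
                    p, _ = fisher_exact_2x2(
                        [[a, int(mask.sum()) - a], [c, int((~mask).sum()) - c]])
                    if p < best:
                        best = p
                        direction = ("up" if a / mask.sum() >= c / (~mask).sum()
                                     else "down")
                rows.append((fid, ftype, min(1.0, best * len(levels)),
                             direction, "fisher_levels", False))
    return pd.DataFrame(rows, columns=["feature_id", "feature_type", "p_value",
                                       "direction", "test", "constant"])


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class APResult:
    exemplars: np.ndarray   # indices of exemplar points
    labels: np.ndarray      # exemplar index assigned to each point
    converged: bool
    n_iter: int


def affinity_propagation(similarity, preference: float | None = None,
                         damping: float = 0.9, max_iter: int = 1000,
                         convergence_window: int = 50) -> APResult:
    """Exemplar clustering by responsibility/availability message passing.

    ``similarity`` is square and symmetric; ``preference`` (the diagonal
    self-similarity) defaults to the median off-diagonal similarity.
    Exemplars must stay unchanged for ``convergence_window`` consecutive
    iterations; otherwise the current assignment is returned with
    ``converged=False``.
    """
    S = np.array(similarity, dtype=float)
    n = S.shape[0]
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("similarity must be square")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("similarity must be symmetric")
    if not 0.5 <= damping < 1.0:
        raise ValueError("damping must be in [0.5, 1)")
    if n == 1:
        return APResult(np.array([0]), np.array([0]), True, 0)
    if preference is None:
        off = S[~np.eye(n, dtype=bool)]
        preference = float(np.median(off))
    np.fill_diagonal(S, preference)
    # deterministic tie-breaking jitter: exact duplicates otherwise make the
    # message passing oscillate between equivalent exemplar sets
    scale = 1e-9 * (S.max() - S.min() + 1.0)
    S = S + scale * np.random.default_rng(0).standard_normal((n, n))

    R = np.zeros((n, n))
    A = np.zeros((n, n))
    idx = np.arange(n)
    stable = 0
    prev = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # responsibilities
        AS = A + S
        first_k = AS.argmax(axis=1)
        first = AS[idx, first_k]
        AS[idx, first_k] = -np.inf
        second = AS.max(axis=1)
        Rnew = S - first[:, None]
        Rnew[idx, first_k] = S[idx, first_k] - second
        R = damping * R + (1 - damping) * Rnew
        # availabilities
        Rp = np.maximum(R, 0)
        Rp[idx, idx] = R[idx, idx]
        col = Rp.sum(axis=0)
        Anew = col[None, :] - Rp
        diag = Anew[idx, idx].copy()
        Anew = np.minimum(Anew, 0)
        Anew[idx, idx] = diag
        A = damping * A + (1 - damping) * Anew

        exemplars = np.flatnonzero((A + R)[idx, idx] > 0)
        key = exemplars.tobytes()
        if prev is not None and key == prev and exemplars.size > 0:
            stable += 1
            if stable >= convergence_window:
                converged = True
                break
        else:
            stable = 0
        prev = key

    if exemplars.size == 0:
        exemplars = np.array([int((A + R)[idx, idx].argmax())])
    labels = exemplars[S[:, exemplars].argmax(axis=1)]
    labels[exemplars] = exemplars
    return APResult(exemplars=exemplars, labels=labels, converged=converged,
                    n_iter=it)


def assemble_set(tested: pd.DataFrame, q_cutoff: float = 0.25,
                 min_per_type: int = 1, max_per_type: int = 100) -> pd.DataFrame:
    """Apply local (per-type) BH FDR and per-type min/max bounds.

    Returns the tested frame with columns ``q``, ``selected`` and
    ``forced`` (features added beyond the FDR to satisfy the per-type
    minimum).  Within each type features above the maximum are truncated by
    ascending p.
    """
    if min_per_type > max_per_type:
        raise ValueError("min_per_type exceeds max_per_type")
    out = tested.copy()
    out["q"] = np.nan
    out["selected"] = False
    out["forced"] = False
    for ftype, grp in tested.groupby("feature_type", sort=False):
        q = bh_fdr(grp["p_value"].to_numpy())
        out.loc[grp.index, "q"] = q
        order = grp.index[np.lexsort((grp["feature_id"], grp["p_value"]))]
        passing = [i for i in order if out.loc[i, "q"] <= q_cutoff]
        chosen = passing[:max_per_type]
        if len(chosen) < min_per_type:
            forced = [i for i in order if i not in chosen]
            need = min(min_per_type, len(grp.index)) - len(chosen)
            out.loc[forced[:need], "forced"] = True
            chosen = chosen + forced[:need]
        out.loc[chosen, "selected"] = True
    return out


def _feature_similarity(wide: pd.DataFrame) -> np.ndarray:
    """Pearson correlation between feature value vectors (categorical
    features are encoded as category codes)."""
    X = np.vstack([
        pd.Categorical(row).codes.astype(float)
        if row.dtype == object else row.to_numpy(dtype=float)
        for _, row in wide.iterrows()])
    X = X - X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1)
    sd[sd == 0] = 1.0
    X = X / sd[:, None]
    return (X @ X.T) / X.shape[1]


def significant_features(table: pd.DataFrame, labels, q_cutoff: float = 0.25,
                         min_per_type: int = 1, max_per_type: int = 100,
                         cluster_first: bool = True, damping: float = 0.9,
                         max_iter: int = 1000) -> pd.DataFrame:
    """End-to-end landscape selection: (optionally) AP-deduplicate features
    within each type, test exemplars, apply local FDR and per-type bounds."""
    if cluster_first:
        kept = []
        wide = _pivot(table)
        for ftype in wide.index.get_level_values(0).unique():
            sub = wide.loc[ftype]
            if len(sub) == 1:
                kept.extend([(ftype, f) for f in sub.index])
                continue
            S = _feature_similarity(sub)
            res = affinity_propagation(S, damping=damping, max_iter=max_iter)
            kept.extend([(ftype, sub.index[e]) for e in res.exemplars])
        keep_ids = {fid for _, fid in kept}
        table = table[table["feature_id"].isin(keep_ids)]
    tested = test_features(table, labels)
    return assemble_set(tested, q_cutoff=q_cutoff, min_per_type=min_per_type,
                        max_per_type=max_per_type)
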