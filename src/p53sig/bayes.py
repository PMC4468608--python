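"""Naive Bayes sensitivity classifier over signature features.

Continuous features (log2 expression) get class-conditional normal
densities with per-class mean and sd; the sd is floored at
``1e-6 + 1e-3 * pooled_sd`` to avoid singularities on degenerate features.
Discrete features (e.g. TP53 status) get add-alpha smoothed categorical
tables with one reserved "unseen" bucket.  Priors are the empirical class
frequencies.  Posteriors are computed in log space and a sample is called
sensitive when its posterior meets the decision threshold (>=, so a
posterior exactly at threshold is called sensitive).

Two thresholds are carried by the model: ``threshold_default`` (0.5 unless
retuned, e.g. by the Youden-style rule) and ``threshold_pdx`` (0.2), the
precision-oriented cut used for xenograft predictions.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = ["SignatureModel", "fit", "predict_posterior", "predict",
           "choose_threshold", "save_model", "load_model"]

PDX_THRESHOLD = 0.2


@dataclass
class SignatureModel:
    features: list[str]
    prior_sensitive: float
    continuous: dict[str, dict[str, tuple[float, float]]]  # feat -> class -> (mean, sd)
    discrete: dict[str, dict] = field(default_factory=dict)
    threshold_default: float = 0.5
    threshold_pdx: float = PDX_THRESHOLD
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SignatureModel":
        d = dict(d)
        d["continuous"] = {f: {c: tuple(v) for c, v in byc.items()}
                           for f, byc in d["continuous"].items()}
        return cls(**d)


def fit(matrix: pd.DataFrame, labels, discrete_features: pd.DataFrame | None = None,
        alpha: float = 1.0, metadata: dict | None = None) -> SignatureModel:
    """Fit the classifier on a feature x sample matrix.

    ``labels`` is a boolean sensitive mask or 'sensitive'/'insensitive'
    values aligned with the columns.  ``discrete_features`` is an optional
    feature x sample frame of categorical values.
    """
    from .discovery import as_sensitive_mask  # local import to avoid cycle

    mask = as_sensitive_mask(labels, matrix.columns)
    n_s, n_i = int(mask.sum()), int((~mask).sum())
    if n_s < 2 or n_i < 2:
        raise ValueError(
            f"need >= 2 samples per class, got {n_s} sensitive / {n_i} insensitive")
    continuous: dict[str, dict[str, tuple[float, float]]] = {}
    X = matrix.to_numpy(dtype=float)
    for i, feat in enumerate(matrix.index):
        xs, xi = X[i, mask], X[i, ~mask]
        # pooled within-class sd for the floor
        pooled = math.sqrt(((n_s - 1) * xs.var(ddof=1) + (n_i - 1) * xi.var(ddof=1))
                           / (n_s + n_i - 2))
        floor = 1e-6 + 1e-3 * pooled
        continuous[str(feat)] = {
            "sensitive": (float(xs.mean()), float(max(xs.std(ddof=1), floor))),
            "insensitive": (float(xi.mean()), float(max(xi.std(ddof=1), floor))),
        }
    discrete: dict[str, dict] = {}
    if discrete_features is not None:
        for feat in discrete_features.index:
            vals = discrete_features.loc[feat].reindex(matrix.columns).astype(str)
            levels = sorted(vals.unique())
            tables = {}
            for cls, cmask in (("sensitive", mask), ("insensitive", ~mask)):
                counts = vals[cmask].value_counts()
                denom = cmask.sum() + alpha * (len(levels) + 1)  # +1 unseen bucket
                tables[cls] = {lv: (counts.get(lv, 0) + alpha) / denom
                               for lv in levels}
                tables[cls]["__unseen__"] = alpha / denom
            discrete[str(feat)] = {"levels": levels, "alpha": alpha,
                                   "tables": tables}
    md = {"n_sensitive": n_s, "n_insensitive": n_i}
    md.update(metadata or {})
    return SignatureModel(
        features=[str(f) for f in matrix.index],
        prior_sensitive=n_s / (n_s + n_i),
        continuous=continuous, discrete=discrete, metadata=md)


def _log_likelihoods(model: SignatureModel, matrix: pd.DataFrame,
                     discrete_values: pd.DataFrame | None,
                     on_missing: str) -> tuple[np.ndarray, np.ndarray, list]:
    """Per-sample log likelihoods under each class; returns (ll_s, ll_i, samples)."""
    samples = list(matrix.columns)
    ll = {"sensitive": np.zeros(len(samples)),
          "insensitive": np.zeros(len(samples))}
    for feat in model.features:
        if feat in model.continuous:
            if feat not in matrix.index:
                if on_missing == "drop":
                    warnings.warn(f"feature {feat!r} missing; dropped")
                    continue
                raise KeyError(f"model feature {feat!r} absent from matrix")
            x = matrix.loc[feat].to_numpy(dtype=float)
            for cls in ("sensitive", "insensitive"):
                mu, sd = model.continuous[feat][cls]
                ll[cls] += -0.5 * ((x - mu) / sd) ** 2 - math.log(sd) \
                    - 0.5 * math.log(2 * math.pi)
        else:
            spec = model.discrete[feat]
            if discrete_values is None or feat not in discrete_values.index:
                if on_missing == "drop":
                    warnings.warn(f"discrete feature {feat!r} missing; dropped")
                    continue
                raise KeyError(f"model feature {feat!r} absent from input")
            vals = discrete_values.loc[feat].reindex(matrix.columns).astype(str)
            for cls in ("sensitive", "insensitive"):
                table = spec["tables"][cls]
                ll[cls] += np.log([table.get(v, table["__unseen__"])
                                   for v in vals])
    return ll["sensitive"], ll["insensitive"], samples


def predict_posterior(model: SignatureModel, matrix: pd.DataFrame,
                      discrete_values: pd.DataFrame | None = None,
                      on_missing: str = "error") -> pd.Series:
    """Posterior probability of the sensitive class per sample (log-space)."""
    ll_s, ll_i, samples = _log_likelihoods(model, matrix, discrete_values,
                                           on_missing)
    log_prior_s = math.log(model.prior_sensitive)
    log_prior_i = math.log1p(-model.prior_sensitive)
    a = ll_s + log_prior_s
    b = ll_i + log_prior_i
    m = np.maximum(a, b)
    post = np.exp(a - m) / (np.exp(a - m) + np.exp(b - m))
    return pd.Series(post, index=samples, name="posterior_sensitive")


def predict(model: SignatureModel, matrix: pd.DataFrame,
            discrete_values: pd.DataFrame | None = None,
            threshold: float | None = None, threshold_mode: str = "default",
            on_missing: str = "error") -> pd.DataFrame:
    """Per-sample posterior and call.  ``threshold_mode`` selects the
    model's default or PDX threshold unless an explicit value is given."""
    if threshold is None:
        threshold = (model.threshold_pdx if threshold_mode == "pdx"
                     else model.threshold_default)
    post = predict_posterior(model, matrix, discrete_values, on_missing)
    return pd.DataFrame({
        "sample_id": post.index,
        "posterior_sensitive": post.to_numpy(),
        "call": np.where(post.to_numpy() >= threshold, "sensitive", "insensitive"),
        "threshold": threshold,
    }).reset_index(drop=True)


def choose_threshold(posteriors, labels, objective: str = "youden",
                     fixed: float = PDX_THRESHOLD) -> float:
    """Decision threshold from posteriors and true labels.

    ``youden``: the cut maximizing sensitivity + specificity, returned as
    the midpoint of the two adjacent distinct posterior values bracketing
    the optimal region (ties broken toward higher sensitivity, then the
    lowest threshold; an all-sensitive optimum returns the lowest posterior
    with a warning).  ``fixed``: returns ``fixed`` unchanged.
    """
    if objective == "fixed":
        return float(fixed)
    if objective != "youden":
        raise ValueError(f"unknown objective {objective!r}")
    from .discovery import as_sensitive_mask

    post = np.asarray(posteriors, dtype=float)
    y = as_sensitive_mask(labels)
    if y.all() or not y.any():
        raise ValueError("youden threshold needs both classes")
    distinct = np.unique(post)
    # candidate behaviors: threshold at each distinct value (call >= value),
    # plus "call nothing sensitive"
    best = None
    for j, t in enumerate(distinct):
        pred = post >= t
        sens = pred[y].mean()
        spec = (~pred[~y]).mean()
        key = (sens + spec, sens, -t)
        if best is None or key > best[0]:
            best = (key, j, False)
    key_none = (0.0 + 1.0, 0.0, -np.inf)  # call nothing sensitive
    if key_none > best[0]:
        best = (key_none, len(distinct) - 1, True)
    _, j, call_none = best
    if call_none:
        warnings.warn("optimal cut calls no sample sensitive; returning a "
                      "threshold above the largest posterior")
        return float(min(1.0, distinct[-1] + 0.5 * (1.0 - distinct[-1])))
    if j == 0:
        warnings.warn("optimal cut calls every sample sensitive; returning "
                      "the lowest posterior")
        return float(distinct[0])
    return float(0.5 * (distinct[j - 1] + distinct[j]))


def save_model(model: SignatureModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model.to_dict(), fh, indent=2, sort_keys=True)


def load_model(path) -> SignatureModel:
    with open(path, encoding="utf-8") as fh:
        return SignatureModel.from_dict(json.load(fh))
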