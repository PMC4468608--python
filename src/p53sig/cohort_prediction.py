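"""Applying a trained signature model to external cohorts.

Covers the in-silico validation stages: per-sample posterior predictions
on an external expression cohort (cell lines, primary tumors or PDX
models, the latter with the precision-oriented 0.2 threshold),
lineage-level predicted-sensitive prevalence restricted to lineages with
more than ``min_group_size`` samples, and the concordance (Pearson r,
identity-line residuals) between predicted prevalence and observed
sensitivity ratios per lineage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import bayes

__all__ = ["predict_cohort", "lineage_prevalence", "prevalence_concordance"]


def predict_cohort(model: bayes.SignatureModel, expression: pd.DataFrame,
                   annotation: pd.DataFrame,
                   threshold_mode: str = "default") -> dict:
    """Predict a cohort and aggregate by lineage.

    Returns ``{"predictions": per-sample frame, "by_lineage": per-lineage
    frame (n, n_predicted_sensitive, fraction), "threshold": used}``.
    """
    missing = [f for f in model.features if f not in expression.index]
    if missing:
        raise KeyError(f"model features absent from cohort matrix: {missing}")
    preds = bayes.predict(model, expression, threshold_mode=threshold_mode)
    preds = preds.merge(annotation.reset_index()[["sample_id", "lineage"]],
                        on="sample_id", how="left")
    grp = preds.groupby("lineage", dropna=False)
    by_lineage = pd.DataFrame({
        "n": grp.size(),
        "n_predicted_sensitive": grp["call"].apply(
            lambda c: int((c == "sensitive").sum())),
    })
    by_lineage["fraction_predicted_sensitive"] = (
        by_lineage["n_predicted_sensitive"] / by_lineage["n"])
    return {"predictions": preds, "by_lineage": by_lineage,
            "threshold": float(preds["threshold"].iloc[0])}


def lineage_prevalence(report: dict, min_group_size: int = 50,
                       strict: bool = True) -> pd.DataFrame:
    """Per-lineage predicted-sensitive fractions for groups with n >
    ``min_group_size`` (strict) or n >= (non-strict); smaller groups are
    returned flagged as excluded, without a fraction."""
    by = report["by_lineage"].copy()
    included = (by["n"] > min_group_size) if strict else (by["n"] >= min_group_size)
    by["included"] = included
    by.loc[~included, "fraction_predicted_sensitive"] = np.nan
    return by


def prevalence_concordance(predicted: pd.Series, observed: pd.Series) -> dict:
    """Pearson correlation between predicted prevalence and observed
    sensitivity ratios over shared lineages (>= 3 required), with
    identity-line residuals."""
    shared = predicted.index.intersection(observed.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared lineages, need >= 3")
    x = predicted.loc[shared].astype(float)
    y = observed.loc[shared].astype(float)
    r = float(stats.pearsonr(x, y).statistic)
    table = pd.DataFrame({"predicted": x, "observed": y,
                          "identity_residual": x - y})
    return {"pearson_r": r, "n_lineages": len(shared), "table": table}
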