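"""Global compound selectivity analysis.

For every compound in a panel, a selectivity score is computed per sample
from the (positive) sensitivity metric: the metric is log2-transformed,
Z-scored across samples, and the Z-score is weighted by the magnitude of
the transformed metric (score = z * |log2 metric|; a raw-scale weighting
is available by flag).  TP53 wild-type and mutant strata are then compared
per compound with a two-sided Wilcoxon test, BH-corrected across
compounds, and compound target classes are tested for enrichment in
selective compounds with Fisher's exact test at FDR 0.25, followed by a
second BH pass across classes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .discovery import wilcoxon_pvalues
from .evaluate import fisher_exact_2x2
from .landscape import bh_fdr

__all__ = ["selectivity_score", "stratified_test", "compound_tests",
           "class_enrichment"]


def selectivity_score(metric, abs_scale: str = "log2") -> tuple[np.ndarray, bool]:
    """Selectivity scores for one compound across samples.

    score = Z(log2 metric) * |log2 metric| (or * |metric| when
    ``abs_scale='raw'``).  Returns (scores, degenerate): a constant metric
    vector yields all-zero scores with ``degenerate=True``.
    """
    x = np.asarray(metric, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 samples")
    if (x <= 0).any():
        raise ValueError("metric must be positive (log2-transformable)")
    m = np.log2(x)
    sd = m.std(ddof=1)
    if sd == 0:
        return np.zeros_like(m), True
    z = (m - m.mean()) / sd
    w = np.abs(m) if abs_scale == "log2" else np.abs(x)
    return z * w, False


def stratified_test(scores, genotype) -> tuple[float, str]:
    """Two-sided Wilcoxon of selectivity scores, WT vs mutant strata.

    Direction is assigned from the median difference: a compound whose
    scores are lower in the wild-type stratum (more potent there) is
    labeled "WT"-selective, the converse "MUT"-selective, equal medians
    "none".
    """
    s = np.asarray(scores, dtype=float)
    g = np.asarray(genotype)
    wt = g == "WT"
    if not wt.any() or wt.all():
        raise ValueError("both genotype strata must be nonempty")
    p = float(wilcoxon_pvalues(s[wt][None, :], s[~wt][None, :])[0])
    diff = np.median(s[wt]) - np.median(s[~wt])
    direction = "WT" if diff < 0 else ("MUT" if diff > 0 else "none")
    return p, direction


def compound_tests(panel: pd.DataFrame, annotation: pd.DataFrame,
                   abs_scale: str = "log2") -> pd.DataFrame:
    """Per-compound selectivity p/q/direction.

    ``panel`` is long-format (compound_id, target_class, sample_id,
    metric); genotype comes from ``annotation['tp53_status']``.
    """
    genotype = annotation["tp53_status"]
    rows = []
    for cpd, grp in panel.groupby("compound_id", sort=True):
        g = genotype.reindex(grp["sample_id"]).to_numpy()
        scores, degenerate = selectivity_score(grp["metric"].to_numpy(),
                                               abs_scale=abs_scale)
        if degenerate:
            p, direction = 1.0, "none"
        else:
            p, direction = stratified_test(scores, g)
        rows.append((cpd, grp["target_class"].iloc[0], p, direction, degenerate))
    out = pd.DataFrame(rows, columns=["compound_id", "target_class", "p_value",
                                      "direction", "degenerate"])
    out["q"] = bh_fdr(out["p_value"].to_numpy())
    return out


def class_enrichment(compounds: pd.DataFrame, q_cutoff: float = 0.25) -> pd.DataFrame:
    """Target-class enrichment in selective compounds.

    A compound is selective when its BH q is <= ``q_cutoff``.  Each class
    gets a Fisher's exact test on (in-class vs out-of-class) x (selective
    vs not), a second BH pass across classes, and the directional
    proportions of its selective compounds.
    """
    df = compounds.copy()
    df["selective"] = df["q"] <= q_cutoff
    classes = [c for c, g in df.groupby("target_class") if len(g) > 0]
    if len(classes) < 2:
        raise ValueError("need >= 2 target classes with compounds")
    rows = []
    for cls in classes:
        inc = df["target_class"] == cls
        a = int((inc & df["selective"]).sum())
        b = int((inc & ~df["selective"]).sum())
        c = int((~inc & df["selective"]).sum())
        d = int((~inc & ~df["selective"]).sum())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p, odds = fisher_exact_2x2([[a, b], [c, d]])
        if not df["selective"].any():
            p = 1.0
        sel = df[inc & df["selective"]]
        n_sel = max(len(sel), 1)
        rows.append((cls, int(inc.sum()), a, p,
                     (sel["direction"] == "WT").sum() / n_sel,
                     (sel["direction"] == "MUT").sum() / n_sel))
    out = pd.DataFrame(rows, columns=["target_class", "n_compounds",
                                      "n_selective", "p_value",
                                      "prop_wt_selective", "prop_mut_selective"])
    out["q"] = bh_fdr(out["p_value"].to_numpy())
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)
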