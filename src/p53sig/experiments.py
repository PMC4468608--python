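"""Multi-seed validation experiments on synthetic cohorts.

These routines exercise the full discovery/classification stack under
controlled conditions - planted signatures, genotype-coupled response
rates, and null (no-signal) cohorts - and are shared by the analysis
drivers, the acceptance script and the test suite.

Cohorts use the study-sized training strata (47 sensitive vs 204
insensitive).  Gene-space sizes default to a few thousand background
genes rather than the full array size: the selection statistics scale
with log(G), so this preserves the competitive structure while keeping
the bootstrap loops quick.
"""

from __future__ import annotations

import numpy as np

from . import bayes, cohort, discovery, evaluate

__all__ = [
    "signature_recovery", "ppv_vs_mutation", "null_cv_auc", "null_stability",
]


def _seeds(base_seed: int, n: int) -> list[int]:
    return [int(s % (2 ** 31))
            for s in np.random.SeedSequence(base_seed).generate_state(n)]


def _cohort(seed: int, n_genes: int, null: bool = False) -> cohort.SyntheticCohort:
    fcs = dict(cohort.SIGNATURE_FOLD_CHANGES)
    if null:
        fcs = {g: 1.0 for g in fcs}
    cfg = cohort.GeneratorConfig(n_genes=n_genes, seed=seed,
                                 signature_fold_changes=fcs)
    return cohort.generate_cohort(cfg)


def signature_recovery(n_seeds: int = 20, n_genes: int = 2000,
                       k: int = 13, repeats: int = 100,
                       base_seed: int = 1000) -> dict:
    """End-to-end discovery (variance filter + stability selection) on
    planted cohorts; counts how many of the 13 planted genes reach the
    final signature per seed."""
    planted = set(cohort.SIGNATURE_FOLD_CHANGES)
    recovered = []
    for seed in _seeds(base_seed, n_seeds):
        syn = _cohort(seed, n_genes)
        labels = syn.annotation["true_class"]
        filtered = discovery.variance_filter(syn.expression, 0.5)
        res = discovery.stability_select(filtered, labels, k=k,
                                         repeats=repeats, seed=seed)
        recovered.append(len(set(res.signature) & planted))
    return {"recovered": recovered,
            "n_seeds_ge_12": int(sum(r >= 12 for r in recovered)),
            "n_seeds": n_seeds}


def ppv_vs_mutation(n_seeds: int = 20, n_genes: int = 500, k: int = 13,
                    base_seed: int = 2000) -> dict:
    """Signature-model PPV vs the mutation-only predictor (wild-type TP53
    predicts sensitive) on a held-out third of each cohort."""
    wins = []
    ppv_sig_all, ppv_mut_all = [], []
    for seed in _seeds(base_seed, n_seeds):
        syn = _cohort(seed, n_genes)
        mask = (syn.annotation["true_class"] == "sensitive").to_numpy()
        rng = np.random.default_rng(seed)
        train, test = discovery.stratified_split(mask, 2 / 3, rng)
        filtered = discovery.variance_filter(syn.expression, 0.5)
        top = discovery._top_k_features(filtered, mask, train, k)
        model = bayes.fit(filtered.loc[top].iloc[:, train], mask[train])
        thr = bayes.choose_threshold(
            bayes.predict_posterior(model, filtered.loc[top].iloc[:, train]),
            mask[train])
        post = bayes.predict_posterior(model, filtered.loc[top].iloc[:, test])
        pred_sig = post.to_numpy() >= thr
        pred_mut = (syn.annotation["tp53_status"].to_numpy()[test] == "WT")
        y = mask[test]

        def ppv(pred):
            return (pred & y).sum() / pred.sum() if pred.any() else np.nan
        ps, pm = ppv(pred_sig), ppv(pred_mut)
        ppv_sig_all.append(ps)
        ppv_mut_all.append(pm)
        wins.append(bool(np.nan_to_num(ps) > np.nan_to_num(pm)))
    return {"ppv_signature": ppv_sig_all, "ppv_mutation": ppv_mut_all,
            "n_seeds_signature_wins": int(sum(wins)), "n_seeds": n_seeds}


def null_cv_auc(n_seeds: int = 20, n_genes: int = 300, k: int = 13,
                folds: int = 5, repeats: int = 5,
                base_seed: int = 3000) -> dict:
    """Cross-validated AUC on null cohorts (all fold changes 1), with
    per-fold feature selection so no signal can leak."""

    def fit_fn(M, y):
        top = discovery.rank_features(M, y)["feature_id"].head(k)
        return bayes.fit(M.loc[top], y)

    aucs = []
    for seed in _seeds(base_seed, n_seeds):
        syn = _cohort(seed, n_genes, null=True)
        labels = syn.annotation["true_class"]
        filtered = discovery.variance_filter(syn.expression, 0.5)
        cv = evaluate.cross_validate(filtered, labels, fit_fn=fit_fn,
                                     folds=folds, repeats=repeats, seed=seed)
        aucs.append(cv["mean"]["auc"])
    aucs = np.array(aucs)
    sem = float(aucs.std(ddof=1) / np.sqrt(n_seeds))
    return {"aucs": aucs.tolist(), "mean_auc": float(aucs.mean()),
            "sem": sem, "n_seeds": n_seeds}


def null_stability(n_seeds: int = 20, n_genes: int = 2000, k: int = 13,
                   repeats: int = 100, base_seed: int = 4000) -> dict:
    """Stability-selection frequency of the most-selected feature on null
    cohorts.  Because each 2/3 bootstrap split is strongly correlated with
    the full data, the luckiest null gene is re-selected in a substantial
    fraction of bootstraps; the max frequency is reported per seed."""
    max_counts = []
    for seed in _seeds(base_seed, n_seeds):
        syn = _cohort(seed, n_genes, null=True)
        labels = syn.annotation["true_class"]
        filtered = discovery.variance_filter(syn.expression, 0.5)
        res = discovery.stability_select(filtered, labels, k=k,
                                         repeats=repeats, seed=seed)
        max_counts.append(int(res.counts.iloc[0]))
    return {"max_counts": max_counts,
            "n_seeds_le_60": int(sum(c <= 60 for c in max_counts)),
            "n_seeds": n_seeds}
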