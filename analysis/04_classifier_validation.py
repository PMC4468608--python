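#!/usr/bin/env python
"""Train and cross-validate the signature classifier.

Fits the naive Bayes model on the discovered signature, tunes the
decision threshold (Youden-style), evaluates with 5 repeats of 5-fold
cross-validation (feature selection re-run inside every training fold),
and compares against the mutation-only predictor (TP53 wild-type =>
predicted sensitive).  Writes the model, the CV report and pooled ROC
curve points.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from p53sig import bayes, discovery, evaluate, io
from p53sig.evaluate import ConfusionTable, confusion_metrics, percent


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--calls", type=Path, default=Path("results/calls.tsv"))
    ap.add_argument("--signature", type=Path,
                    default=Path("results/signature.json"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    matrix = io.read_expression(args.cohort / "expression.tsv")
    ann = io.read_annotation(args.cohort / "annotation.tsv")
    call_df = io.read_calls(args.calls)
    training = call_df[call_df["call"].isin(["sensitive", "insensitive"])]
    labels = training.set_index("sample_id")["call"]
    matrix_t = matrix[labels.index]
    sig = json.loads(args.signature.read_text())["signature"]
    k = len(sig)

    model = bayes.fit(matrix_t.loc[sig], labels)
    post = bayes.predict_posterior(model, matrix_t.loc[sig])
    model.threshold_default = bayes.choose_threshold(post, labels)
    bayes.save_model(model, args.outdir / "model.json")
    print(f"model: prior(sensitive) = {model.prior_sensitive:.3f}, "
          f"Youden threshold = {model.threshold_default:.3f}")

    filtered = discovery.variance_filter(matrix_t, 0.5)

    def fit_fn(M, y):
        top = discovery.rank_features(M, y)["feature_id"].head(k)
        return bayes.fit(M.loc[top], y)

    cv = evaluate.cross_validate(filtered, labels, fit_fn=fit_fn, folds=5,
                                 repeats=5, seed=args.seed)
    print("5x5 CV (mean +/- SEM):")
    for key in ("accuracy", "sensitivity", "specificity", "ppv", "npv", "auc"):
        print(f"  {key:12s} {cv['mean'][key]:.3f} +/- {cv['sem'][key]:.3f}")

    # mutation-only comparison on the same samples
    wt = ann.loc[labels.index, "tp53_status"] == "WT"
    truth = labels == "sensitive"
    t = ConfusionTable.from_calls(truth.to_numpy(), wt.to_numpy())
    m = confusion_metrics(t)
    print(f"mutation-only predictor: PPV {percent(m['ppv'])}%, "
          f"sensitivity {percent(m['sensitivity'])}% "
          f"(signature CV PPV {100 * cv['mean']['ppv']:.0f}%)")

    (args.outdir / "cv_report.json").write_text(json.dumps(
        {"mean": cv["mean"], "sem": cv["sem"]}, indent=2))
    curves = pd.concat([c.assign(repeat=i)
                        for i, c in enumerate(cv["roc_curves"])])
    io.write_table(curves, args.outdir / "roc_curves.tsv")


if __name__ == "__main__":
    main()
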