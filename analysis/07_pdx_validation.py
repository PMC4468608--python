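#!/usr/bin/env python
"""In-vivo (PDX-style) validation.

Derives RECIST-adapted response calls from the simulated tumor-volume
trajectories (best response = most negative percent change; progressive
disease > +35 % growth = insensitive), predicts sensitivity with the
trained model at the precision-oriented 0.2 posterior threshold, and
reports the confusion metrics for all models and for the TP53 wild-type
subset.
"""

import argparse
from pathlib import Path

from p53sig import bayes, calls, io
from p53sig.evaluate import ConfusionTable, confusion_metrics, percent


def _report(truth, predicted, label):
    t = ConfusionTable.from_calls(truth, predicted)
    m = confusion_metrics(t)
    print(f"{label}: n={t.total}  TP={t.tp} FP={t.fp} FN={t.fn} TN={t.tn}")
    print(f"  PPV {percent(m['ppv'])}%  NPV {percent(m['npv'])}%  "
          f"sensitivity {percent(m['sensitivity'])}%  "
          f"specificity {percent(m['specificity'])}%  "
          f"baseline response rate {percent(m['baseline_response_rate'])}%")


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--model", type=Path, default=Path("results/model.json"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    traj = io.read_trajectories(args.cohort / "trajectories.csv")
    ann = io.read_annotation(args.cohort / "annotation.tsv")
    matrix = io.read_expression(args.cohort / "expression.tsv")
    model = bayes.load_model(args.model)

    recist = calls.call_recist_table(traj).set_index("sample_id")
    io.write_table(recist.reset_index(), args.outdir / "recist_calls.tsv")
    print("RECIST categories:", recist["category"].value_counts().to_dict())

    preds = bayes.predict(model, matrix, threshold_mode="pdx")
    preds = preds.set_index("sample_id").loc[recist.index]
    io.write_table(preds.reset_index(), args.outdir / "pdx_predictions.tsv")

    truth = recist["sensitive"].to_numpy()
    predicted = (preds["call"] == "sensitive").to_numpy()
    _report(truth, predicted, "all models")
    wt = (ann.loc[recist.index, "tp53_status"] == "WT").to_numpy()
    _report(truth[wt], predicted[wt], "TP53 wild-type models")


if __name__ == "__main__":
    main()
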