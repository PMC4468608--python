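#!/usr/bin/env python
"""Discover the gene signature.

Runs the published discovery protocol on the simulated training strata:
variance filter (drop the low-variance half), a 5-100 feature-count scan
over 20 bootstrapped 2/3 splits with naive Bayes scoring, the one-SEM
model-size rule, and 100-bootstrap stability selection.  Writes the size
scan, the stability table, and the final signature.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from p53sig import cohort, discovery, io


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--calls", type=Path, default=Path("results/calls.tsv"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    matrix = io.read_expression(args.cohort / "expression.tsv")
    call_df = io.read_calls(args.calls)
    training = call_df[call_df["call"].isin(["sensitive", "insensitive"])]
    labels = training.set_index("sample_id")["call"]
    matrix = matrix[labels.index]

    filtered = discovery.variance_filter(matrix, 0.5)
    print(f"variance filter: {matrix.shape[0]} -> {filtered.shape[0]} genes")

    scan = discovery.size_scan(filtered, labels, sizes=range(5, 101),
                               repeats=20, seed=args.seed)
    k_star = discovery.select_size_1sem(scan)
    best_k = int(scan["mean_accuracy"].idxmax())
    print(f"size scan: max accuracy {scan['mean_accuracy'].max():.3f} at "
          f"k={best_k}; smallest k within 1 SEM: k*={k_star}")

    stab = discovery.stability_select(filtered, labels, k_star, repeats=100,
                                      seed=args.seed + 1)
    planted = set(cohort.SIGNATURE_FOLD_CHANGES)
    hit = len(set(stab.signature) & planted)
    print(f"stability selection: {len(stab.counts)} features seen at least "
          f"once; final signature ({k_star} genes) recovers {hit} planted "
          f"signature genes")
    print("signature:", ", ".join(stab.signature))

    io.write_table(scan.reset_index(), args.outdir / "size_scan.tsv")
    io.write_table(stab.counts.rename_axis("feature_id").reset_index(),
                   args.outdir / "stability_counts.tsv")
    (args.outdir / "signature.json").write_text(json.dumps(
        {"signature": stab.signature, "k": k_star, "seed": args.seed},
        indent=2))


if __name__ == "__main__":
    main()
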