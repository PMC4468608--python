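#!/usr/bin/env python
"""Call sensitivity strata and test the genotype association.

Applies the screen calling rules (sensitive: IC50 <= 4 uM and
Amax <= -50 %; training-insensitive: IC50 >= 8 uM) to the simulated
dose-response table, writes the calls, and runs Fisher's exact test on
the sensitivity x TP53-status contingency - the association that
motivates an expression signature beyond genotype alone.
"""

import argparse
from pathlib import Path

import pandas as pd

from p53sig import calls, evaluate, io


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    dr = io.read_dose_response(args.cohort / "dose_response.csv")
    ann = io.read_annotation(args.cohort / "annotation.tsv")
    call_df = calls.call_screen_table(dr)
    io.write_table(call_df, args.outdir / "calls.tsv")

    merged = call_df.merge(ann.reset_index(), on="sample_id")
    sens = merged["call"] == "sensitive"
    wt = merged["tp53_status"] == "WT"
    table = [[int((sens & wt).sum()), int((sens & ~wt).sum())],
             [int((~sens & wt).sum()), int((~sens & ~wt).sum())]]
    p, odds = evaluate.fisher_exact_2x2(table)
    print(f"calls: {sens.sum()} sensitive / "
          f"{(merged['call'] == 'insensitive').sum()} training-insensitive / "
          f"{(merged['call'] == 'intermediate').sum()} intermediate")
    print(f"sensitivity x TP53 2x2 {table}: Fisher p = {p:.3g}, OR = {odds:.1f}")
    print(f"calls written to {args.outdir}/calls.tsv")


if __name__ == "__main__":
    main()
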