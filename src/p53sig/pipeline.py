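"""End-to-end pipeline driver: simulate -> call -> discover -> train ->
evaluate, with a manifest recording parameters, seeds and content hashes
of every artifact so that two runs with the same config are verifiably
identical."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import bayes, calls, cohort, discovery, evaluate, io
from .config import PipelineConfig, save_config

__all__ = ["run_pipeline"]

log = logging.getLogger("p53sig")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir, write_inputs: bool = False) -> dict:
    """Run the full synthetic-cohort pipeline and write artifacts to
    ``outdir``.  Returns the manifest dict (also written as
    ``manifest.json``).  A failing stage raises with the stage named;
    artifacts written so far keep a ``.partial`` marker file next to them.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), "INFO"))
    marker = outdir / ".partial"
    marker.write_text("pipeline in progress\n")
    manifest: dict = {"config": config.to_dict(), "stages": {}, "outputs": {}}
    t0 = time.time()
    stage = "simulate"
    try:
        # --- simulate ------------------------------------------------
        syn = cohort.generate_cohort(config.generator, pdx=True)
        log.info("simulate: %d genes x %d samples", *syn.expression.shape)
        if write_inputs:
            io.write_expression(syn.expression, outdir / "expression.tsv")
            io.write_annotation(syn.annotation, outdir / "annotation.tsv")
            io.write_table(syn.dose_response, outdir / "dose_response.csv")
            io.write_table(syn.trajectories, outdir / "trajectories.csv")
        manifest["stages"][stage] = {
            "n_genes": int(syn.expression.shape[0]),
            "n_samples": int(syn.expression.shape[1])}

        # --- call ----------------------------------------------------
        stage = "call"
        call_df = calls.call_screen_table(
            syn.dose_response,
            sens_ic50_cutoff=config.sens_ic50_cutoff,
            amax_cutoff=config.amax_cutoff,
            insens_ic50_cutoff=config.insens_ic50_cutoff,
            rule_version=config.rule_version)
        io.write_table(call_df, outdir / "calls.tsv")
        n_sens = int((call_df["call"] == "sensitive").sum())
        n_ins = int((call_df["call"] == "insensitive").sum())
        log.info("call: %d screened -> %d sensitive / %d training-insensitive",
                 len(call_df), n_sens, n_ins)
        manifest["stages"][stage] = {"n_sensitive": n_sens,
                                     "n_insensitive": n_ins}

        # --- discover ------------------------------------------------
        stage = "discover"
        training = call_df[call_df["call"] != "intermediate"]
        labels = training.set_index("sample_id")["call"]
        matrix = syn.expression[labels.index]
        filtered = discovery.variance_filter(matrix, config.variance_keep_fraction)
        lo, hi = config.scan_sizes
        seed_scan, seed_stab, seed_cv = (
            int(s % (2 ** 31))
            for s in np.random.SeedSequence(config.seed).generate_state(3))
        scan = discovery.size_scan(filtered, labels, sizes=range(lo, hi + 1),
                                   repeats=config.scan_repeats,
                                   train_fraction=config.train_fraction,
                                   seed=seed_scan)
        k_star = discovery.select_size_1sem(scan)
        stab = discovery.stability_select(
            filtered, labels, k_star, repeats=config.stability_repeats,
            train_fraction=config.train_fraction, seed=seed_stab,
            exclusion_list=config.exclusion_list)
        io.write_table(scan.reset_index(), outdir / "size_scan.tsv")
        io.write_table(stab.counts.rename_axis("feature_id").reset_index(),
                       outdir / "stability_counts.tsv")
        (outdir / "signature.json").write_text(json.dumps({
            "signature": stab.signature, "k": k_star,
            "seed": config.seed, "scan_repeats": config.scan_repeats,
            "stability_repeats": config.stability_repeats}, indent=2))
        log.info("discover: %d genes after filter, k*=%d", len(filtered), k_star)
        manifest["stages"][stage] = {"n_filtered": int(len(filtered)),
                                     "k_star": int(k_star),
                                     "signature": stab.signature}

        # --- train ---------------------------------------------------
        stage = "train"
        model = bayes.fit(matrix.loc[stab.signature], labels,
                          metadata={"seed": config.seed})
        model.threshold_pdx = config.pdx_threshold
        bayes.save_model(model, outdir / "model.json")
        manifest["stages"][stage] = {
            "prior_sensitive": model.prior_sensitive}

        # --- evaluate ------------------------------------------------
        stage = "evaluate"

        def fit_signature(train_matrix, train_mask):
            ranked = discovery.rank_features(train_matrix, train_mask)
            top = ranked["feature_id"].head(k_star)
            return bayes.fit(train_matrix.loc[top], train_mask)

        cv = evaluate.cross_validate(filtered, labels, fit_fn=fit_signature,
                                     folds=config.cv_folds,
                                     repeats=config.cv_repeats, seed=seed_cv)
        report = {"mean": cv["mean"], "sem": cv["sem"]}
        (outdir / "cv_report.json").write_text(json.dumps(report, indent=2))
        log.info("evaluate: CV accuracy %.3f, AUC %.3f",
                 cv["mean"]["accuracy"], cv["mean"]["auc"])
        manifest["stages"][stage] = report

        # --- manifest ------------------------------------------------
        save_config(config, outdir / "config.yaml")
        for f in sorted(outdir.iterdir()):
            if f.is_file() and f.name not in ("manifest.json", ".partial"):
                manifest["outputs"][f.name] = _sha256(f)
        manifest["elapsed_s"] = round(time.time() - t0, 2)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                         sort_keys=True))
        marker.unlink(missing_ok=True)
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
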