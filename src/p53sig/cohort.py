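"""Synthetic cohort generation.

Emulates the statistical structure of a cell-line / PDX drug-sensitivity
study: a two-class cohort (sensitive vs insensitive to a p53-HDM2
inhibitor) whose signature genes are up-regulated in sensitive samples by
configurable linear fold changes, whose TP53 genotype is coupled to the
sensitivity class through conditional response rates, and whose
dose-response summaries (IC50, Amax) and tumor-volume trajectories fall
into the strata that the downstream calling rules expect.

All randomness flows from a single root seed; each component (expression,
genotype, dose-response, trajectories, compound panel) draws from its own
child stream so components are individually reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SIGNATURE_FOLD_CHANGES",
    "GeneratorConfig",
    "SyntheticCohort",
    "generate_expression",
    "generate_dose_response",
    "generate_trajectories",
    "generate_compound_panel",
    "generate_cohort",
]

#: Linear fold changes (sensitive / insensitive) of the 13 signature genes,
#: all p53 transcriptional targets up-regulated in sensitive samples.
SIGNATURE_FOLD_CHANGES: dict[str, float] = {
    "HDM2": 2.18,
    "CDKN1A": 3.88,
    "ZMAT3": 2.81,
    "DDB2": 2.55,
    "FDXR": 2.42,
    "RPS27L": 1.97,
    "BAX": 2.12,
    "RRM2B": 2.06,
    "SESN1": 2.27,
    "CCNG1": 1.69,
    "XPC": 1.62,
    "TNFRSF10B": 1.91,
    "AEN": 1.46,
}

_LINEAGES = (
    "melanoma", "colorectal", "liposarcoma", "renal", "hepatocellular",
    "breast", "pancreatic", "lung", "blood", "ovarian",
)

_CLASSES = ("sensitive", "insensitive", "intermediate")


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the training strata of the study this emulates:
    47 sensitive vs 204 insensitive samples, the published signature fold
    changes, and TP53-genotype/response rates read off the screen's
    contingency table (43/100 wild-type and 4/256 mutant lines sensitive).
    """

    n_sensitive: int = 47
    n_insensitive: int = 204
    n_intermediate: int = 0
    n_genes: int = 18106
    signature_fold_changes: Mapping[str, float] = field(
        default_factory=lambda: dict(SIGNATURE_FOLD_CHANGES))
    within_group_sd: float = 0.5          # log2 units, signature genes
    baseline_mean_range: tuple[float, float] = (5.0, 10.0)  # log2 units
    baseline_sd: float = 1.0              # log2 units, median background sd
    p_sensitive_given_wt: float = 43 / 100
    p_sensitive_given_mut: float = 4 / 256
    p_wt: float = 100 / 356               # marginal P(TP53 wild-type)
    # lognormal (median uM, sigma in ln units) per class; draws are truncated
    # to the class's calling band so strata are exact.
    ic50_params_by_class: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "sensitive": (0.8, 0.9),
            "insensitive": (20.0, 0.5),
            "intermediate": (5.7, 0.3),
        })
    # Amax mean/sd in % per class
    amax_params_by_class: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "sensitive": (-80.0, 10.0),
            "insensitive": (-30.0, 25.0),
            "intermediate": (-60.0, 15.0),
        })
    # best tumor-volume response mean/sd in % per class (PDX mode)
    best_response_params_by_class: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "sensitive": (-55.0, 30.0),
            "insensitive": (80.0, 35.0),
            "intermediate": (20.0, 15.0),
        })
    trajectory_days: tuple[int, ...] = (7, 14, 21, 28)
    trajectory_noise_sd: float = 3.0      # %
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_sensitive, self.n_insensitive, self.n_intermediate) < 0:
            raise ConfigurationError("sample counts must be >= 0")
        if self.n_genes < len(self.signature_fold_changes):
            raise ConfigurationError(
                f"n_genes={self.n_genes} is smaller than the "
                f"{len(self.signature_fold_changes)} signature features")
        for name, p in (("p_sensitive_given_wt", self.p_sensitive_given_wt),
                        ("p_sensitive_given_mut", self.p_sensitive_given_mut),
                        ("p_wt", self.p_wt)):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} not in [0, 1]")
        if any(fc <= 0 for fc in self.signature_fold_changes.values()):
            raise ConfigurationError("fold changes must be > 0")
        if self.within_group_sd <= 0 or self.baseline_sd <= 0:
            raise ConfigurationError("standard deviations must be > 0")
        lo, hi = self.baseline_mean_range
        if not lo <= hi:
            raise ConfigurationError("baseline_mean_range must be (low, high)")
        if len(self.trajectory_days) == 0:
            raise ConfigurationError("trajectory day grid must be nonempty")
        if any(d2 <= d1 for d1, d2 in zip(self.trajectory_days,
                                          self.trajectory_days[1:])):
            raise ConfigurationError("trajectory days must strictly increase")

    @property
    def n_samples(self) -> int:
        return self.n_sensitive + self.n_insensitive + self.n_intermediate

    def to_dict(self) -> dict:
        d = asdict(self)
        d["signature_fold_changes"] = dict(self.signature_fold_changes)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        for key in ("baseline_mean_range", "trajectory_days"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        for key in ("ic50_params_by_class", "amax_params_by_class",
                    "best_response_params_by_class"):
            if key in d and d[key] is not None:
                d[key] = {k: tuple(v) for k, v in d[key].items()}
        return cls(**d)


@dataclass
class SyntheticCohort:
    """Bundle of the generated components, keyed by consistent sample ids."""

    expression: pd.DataFrame          # features x samples, log2
    annotation: pd.DataFrame          # index sample_id: true_class, tp53_status, lineage
    dose_response: pd.DataFrame       # sample_id, ic50_um, amax_pct
    trajectories: pd.DataFrame | None = None  # sample_id, day, pct_change
    config: GeneratorConfig | None = None


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _sample_ids(config: GeneratorConfig) -> list[str]:
    width = max(4, len(str(config.n_samples)))
    return [f"S{i:0{width}d}" for i in range(1, config.n_samples + 1)]


def _true_classes(config: GeneratorConfig) -> np.ndarray:
    return np.repeat(
        np.array(_CLASSES, dtype=object),
        [config.n_sensitive, config.n_insensitive, config.n_intermediate])


def generate_expression(
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    genotype_rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the log2 expression matrix and the sample annotation.

    Non-signature genes are class-independent normals: gene g has a mean
    drawn uniformly from ``baseline_mean_range`` and a per-gene sd drawn
    lognormally around ``baseline_sd`` (so a variance filter has a real
    spread to act on).  Signature genes have sd ``within_group_sd`` in both
    classes and their mean is shifted by log2(fold change) in sensitive
    samples (half the shift in intermediate samples).

    TP53 status is sampled per class from the posterior genotype
    probabilities implied by Bayes' rule applied to
    ``p_sensitive_given_wt/mut`` and the marginal ``p_wt``.
    """
    config.validate()
    if rng is None or genotype_rng is None:
        expr_rng, geno_rng = _child_rngs(config.seed, 5)[:2]
        rng = rng or expr_rng
        genotype_rng = genotype_rng or geno_rng

    sig_names = list(config.signature_fold_changes)
    n_noise = config.n_genes - len(sig_names)
    width = max(5, len(str(n_noise)))
    feature_ids = sig_names + [f"G{i:0{width}d}" for i in range(1, n_noise + 1)]

    classes = _true_classes(config)
    n = config.n_samples
    lo, hi = config.baseline_mean_range

    means = rng.uniform(lo, hi, size=config.n_genes)
    # Background genes draw a per-gene sd log-normally around within_group_sd
    # (log2-scale spread baseline_sd / 2).  Signature genes use exactly
    # within_group_sd, so their planted class shift adds variance and places
    # them in the upper half of the variance distribution, as the variance
    # filter assumes of real informative genes.
    sds = config.within_group_sd * np.exp2(
        rng.normal(0.0, config.baseline_sd / 2.0, size=config.n_genes))
    sds[: len(sig_names)] = config.within_group_sd

    values = means[:, None] + sds[:, None] * rng.standard_normal((config.n_genes, n))

    shift = np.log2([config.signature_fold_changes[g] for g in sig_names])
    values[: len(sig_names), classes == "sensitive"] += shift[:, None]
    values[: len(sig_names), classes == "intermediate"] += 0.5 * shift[:, None]

    samples = _sample_ids(config)
    expression = pd.DataFrame(values, index=pd.Index(feature_ids, name="feature_id"),
                              columns=samples)

    # genotype: P(WT | class) via Bayes on the configured conditional rates
    p_s = config.p_sensitive_given_wt * config.p_wt \
        + config.p_sensitive_given_mut * (1.0 - config.p_wt)
    if p_s in (0.0, 1.0):
        p_wt_given = {c: config.p_wt for c in _CLASSES}
    else:
        p_wt_s = config.p_sensitive_given_wt * config.p_wt / p_s
        p_wt_i = (1 - config.p_sensitive_given_wt) * config.p_wt / (1 - p_s)
        p_wt_given = {"sensitive": p_wt_s, "insensitive": p_wt_i,
                      "intermediate": p_wt_i}
    u = genotype_rng.random(n)
    status = np.where(
        u < np.array([p_wt_given[c] for c in classes]), "WT", "MUT")
    lineage = genotype_rng.choice(_LINEAGES, size=n)

    annotation = pd.DataFrame(
        {"true_class": classes, "tp53_status": status, "lineage": lineage},
        index=pd.Index(samples, name="sample_id"))
    return expression, annotation


def generate_dose_response(
    config: GeneratorConfig,
    annotation: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-sample IC50 (uM) / Amax (%) summaries.

    Draws are lognormal (IC50) and normal (Amax) per class, truncated to the
    class's calling band: sensitive IC50 <= 4 and Amax <= -50, insensitive
    IC50 >= 8, intermediate IC50 in (4, 8).  Truncation makes the strata
    exact, which downstream calling-rule tests rely on.
    """
    config.validate()
    if rng is None:
        rng = _child_rngs(config.seed, 5)[2]
    classes = annotation["true_class"].to_numpy()
    n = len(classes)
    ic50 = np.empty(n)
    amax = np.empty(n)
    eps = 1e-6
    for cls in _CLASSES:
        mask = classes == cls
        if not mask.any():
            continue
        med, sigma = config.ic50_params_by_class[cls]
        x = med * np.exp(sigma * rng.standard_normal(mask.sum()))
        mu, sd = config.amax_params_by_class[cls]
        a = rng.normal(mu, sd, size=mask.sum())
        if cls == "sensitive":
            x = np.clip(x, eps, 4.0)
            a = np.clip(a, -100.0, -50.0)
        elif cls == "insensitive":
            x = np.maximum(x, 8.0)
            a = np.clip(a, -100.0, 100.0)
        else:
            # margin survives 6-significant-digit round trips
            x = np.clip(x, 4.01, 7.99)
            a = np.clip(a, -100.0, 100.0)
        ic50[mask] = x
        amax[mask] = a
    return pd.DataFrame({"sample_id": annotation.index, "ic50_um": ic50,
                         "amax_pct": amax}).reset_index(drop=True)


def generate_trajectories(
    config: GeneratorConfig,
    annotation: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Tumor-volume trajectories (% change vs day 0) in long format.

    Each sample gets a best (most negative) response drawn per class and a
    piecewise trajectory that attains it: a ramp from 0 to the best response
    at the maximum-effect day, then partial regrowth.  Deep regressions
    (best <= -50) keep shrinking through the last day, so those series are
    monotone non-increasing.  Sensitive best responses are truncated to
    <= +35 %, insensitive to > +35 %, matching the response-calling bands.
    """
    config.validate()
    if rng is None:
        rng = _child_rngs(config.seed, 5)[3]
    days = np.asarray(config.trajectory_days, dtype=float)
    m = len(days)
    rows = []
    for sample_id, cls in annotation["true_class"].items():
        mu, sd = config.best_response_params_by_class[cls]
        best = rng.normal(mu, sd)
        if cls == "sensitive":
            best = float(np.clip(best, -100.0, 35.0))
        elif cls == "insensitive":
            # bounded away from the +35% progression boundary so the call
            # survives 6-significant-digit round trips
            best = float(np.clip(best, 36.0, None))
        else:
            best = float(np.clip(best, -100.0, None))
        if m == 1:
            series = np.array([best])
        else:
            if best > 0.0:
                # never regresses: the minimum change is already at the
                # first measurement and the tumor grows from there
                i_star = 0
            elif best <= -50.0:
                i_star = m - 1
            else:
                i_star = int(rng.integers(m // 2, m))
            if i_star == 0:
                growth = abs(rng.normal(0.0, 20.0))
                series = best + growth * (days - days[0]) / days[0]
            else:
                frac = days / days[i_star]
                series = np.where(frac <= 1.0, best * frac,
                                  best + abs(rng.normal(0.0, 20.0)) * (frac - 1.0))
            noise = rng.normal(0.0, config.trajectory_noise_sd, size=m)
            noise[i_star] = 0.0
            series = series + noise
            # keep the planted best response exactly the minimum
            series[:i_star + 1] = np.minimum.accumulate(series[:i_star + 1])
            series = np.maximum(series, best)
            series[i_star] = best
        series = np.maximum(series, -100.0)
        rows.append(pd.DataFrame({"sample_id": sample_id, "day": days.astype(int),
                                  "pct_change": series}))
    return pd.concat(rows, ignore_index=True)


def generate_compound_panel(
    n_compounds: int,
    n_classes: int,
    planted_class: str,
    annotation: pd.DataFrame,
    effect_size: float = 1.0,
    metric_median: float = 1.0,
    metric_sd_log2: float = 1.0,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Compound-panel sensitivity metrics with one optionally selective class.

    Compounds are assigned round-robin to ``n_classes`` target classes named
    ``TC00..``; every compound's per-sample metric is lognormal
    (median ``metric_median``, sd ``metric_sd_log2`` in log2 units).
    Compounds in ``planted_class`` have their metric divided by
    ``2**effect_size`` in TP53 wild-type samples (lower metric = more
    potent), all other compounds are genotype-independent.

    Returns the long-format panel (compound_id, target_class, sample_id,
    metric) and the compound -> target-class map.
    """
    class_names = [f"TC{i:02d}" for i in range(n_classes)]
    if planted_class not in class_names:
        raise ConfigurationError(
            f"planted_class {planted_class!r} not among {class_names}")
    if rng is None:
        rng = np.random.default_rng(seed)
    compounds = [f"CPD{i:04d}" for i in range(n_compounds)]
    target = pd.Series([class_names[i % n_classes] for i in range(n_compounds)],
                       index=pd.Index(compounds, name="compound_id"),
                       name="target_class")
    wt = (annotation["tp53_status"] == "WT").to_numpy()
    n = len(annotation)
    log2m = np.log2(metric_median) + metric_sd_log2 * rng.standard_normal(
        (n_compounds, n))
    planted = (target.to_numpy() == planted_class)
    log2m[np.ix_(planted, wt)] -= effect_size
    panel = pd.DataFrame({
        "compound_id": np.repeat(compounds, n),
        "target_class": np.repeat(target.to_numpy(), n),
        "sample_id": np.tile(annotation.index.to_numpy(), n_compounds),
        "metric": np.exp2(log2m).ravel(),
    })
    return panel, target


def generate_cohort(config: GeneratorConfig, pdx: bool = False) -> SyntheticCohort:
    """Generate a full cohort (expression, annotation, dose-response and,
    in PDX mode, tumor-volume trajectories) from one root seed."""
    config.validate()
    expr_rng, geno_rng, dr_rng, traj_rng, _ = _child_rngs(config.seed, 5)
    expression, annotation = generate_expression(config, expr_rng, geno_rng)
    dose_response = generate_dose_response(config, annotation, dr_rng)
    trajectories = generate_trajectories(config, annotation, traj_rng) if pdx else None
    return SyntheticCohort(expression=expression, annotation=annotation,
                           dose_response=dose_response, trajectories=trajectories,
                           config=config)
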