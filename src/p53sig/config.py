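"""Pipeline configuration: one YAML-serializable object holding every
stage parameter (calling cut-offs, scan sizes and repeat counts, CV
layout, FDR and decision thresholds) plus the generator settings and the
root seed from which all per-stage streams are derived."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .cohort import GeneratorConfig

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    # sensitivity calling (uM / %)
    sens_ic50_cutoff: float = 4.0
    insens_ic50_cutoff: float = 8.0
    amax_cutoff: float = -50.0
    external_ic50_cutoff: float = 3.0
    rule_version: str = "v1"
    # discovery
    variance_keep_fraction: float = 0.5
    scan_sizes: tuple[int, int] = (5, 100)
    scan_repeats: int = 20
    stability_repeats: int = 100
    train_fraction: float = 2 / 3
    exclusion_list: tuple[str, ...] = ()
    # evaluation
    cv_folds: int = 5
    cv_repeats: int = 5
    # landscape / selectivity
    fdr_cutoff: float = 0.25
    # prediction
    pdx_threshold: float = 0.2
    min_group_size: int = 50
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        self.generator.validate()
        if not 0 < self.variance_keep_fraction <= 1:
            raise ValueError("variance_keep_fraction not in (0, 1]")
        lo, hi = self.scan_sizes
        if not 1 <= lo <= hi:
            raise ValueError(f"bad scan size range {self.scan_sizes}")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if not 0 < self.pdx_threshold < 1:
            raise ValueError("pdx_threshold must be in (0, 1)")
        if not 0 < self.fdr_cutoff <= 1:
            raise ValueError("fdr_cutoff must be in (0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["generator"] = self.generator.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "generator" in d and not isinstance(d["generator"], GeneratorConfig):
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        for key in ("scan_sizes", "exclusion_list"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def load_config(path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh))
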