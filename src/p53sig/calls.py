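"""Categorical sensitivity calls from dose-response summaries and
tumor-volume trajectories.

Two families of rules are implemented:

* screen / training calls from (IC50, Amax): sensitive iff IC50 <= 4 uM and
  Amax <= -50 %; the training-insensitive stratum is IC50 >= 8 uM (rule
  version "v1"; "v2" additionally requires Amax <= -50 %); everything else
  is intermediate and excluded from model training.  External-panel calls
  are binary at IC50 <= 3 uM.
* RECIST-style calls from the best (most negative) percent change in tumor
  volume: CR at -100, PR in (-100, -50), SD in [-50, +35], PD above +35;
  a model is sensitive unless it progresses (PD).

Right-censored IC50 values ("> assay max") are expected to be passed as the
censoring bound; thresholds then compare against that bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SensitivityCall", "RecistCall",
    "call_screen", "call_external", "best_response", "call_recist",
    "call_screen_table", "call_recist_table",
]

SENS_IC50_CUTOFF = 4.0      # uM
INSENS_IC50_CUTOFF = 8.0    # uM
AMAX_CUTOFF = -50.0         # %
EXTERNAL_IC50_CUTOFF = 3.0  # uM
RECIST_PR_BOUND = -50.0     # %
RECIST_PD_BOUND = 35.0      # %


@dataclass(frozen=True)
class SensitivityCall:
    sample_id: str
    call: str                 # sensitive | insensitive | intermediate
    stratum: str              # screen | training | external
    rule_version: str = "v1"


@dataclass(frozen=True)
class RecistCall:
    sample_id: str
    best_response: float      # %
    category: str             # CR | PR | SD | PD
    sensitive: bool


def call_screen(sample_id: str, ic50: float, amax: float,
                sens_ic50_cutoff: float = SENS_IC50_CUTOFF,
                amax_cutoff: float = AMAX_CUTOFF,
                insens_ic50_cutoff: float = INSENS_IC50_CUTOFF,
                rule_version: str = "v1") -> SensitivityCall:
    """Call one screened sample sensitive / insensitive / intermediate."""
    if not np.isfinite(ic50) or ic50 <= 0:
        raise ValueError(f"ic50 must be positive and finite, got {ic50!r}")
    if not np.isfinite(amax):
        raise ValueError(f"amax must be finite, got {amax!r}")
    if rule_version not in ("v1", "v2"):
        raise ValueError(f"unknown rule_version {rule_version!r}")
    if ic50 <= sens_ic50_cutoff and amax <= amax_cutoff:
        call, stratum = "sensitive", "training"
    elif ic50 >= insens_ic50_cutoff and (
            rule_version == "v1" or amax <= amax_cutoff):
        call, stratum = "insensitive", "training"
    else:
        call, stratum = "intermediate", "screen"
    return SensitivityCall(sample_id, call, stratum, rule_version)


def call_external(sample_id: str, ic50: float,
                  cutoff: float = EXTERNAL_IC50_CUTOFF) -> SensitivityCall:
    """Binary external-panel call: sensitive iff IC50 <= cutoff (inclusive)."""
    if not np.isfinite(ic50) or ic50 <= 0:
        raise ValueError(f"ic50 must be positive and finite, got {ic50!r}")
    call = "sensitive" if ic50 <= cutoff else "insensitive"
    return SensitivityCall(sample_id, call, "external", "external")


def best_response(series) -> float:
    """Best response = minimum percent change over the treatment period.

    ``series`` is a sequence of (day, pct_change) pairs or a pct_change
    sequence; days must be strictly increasing when given.
    """
    arr = np.asarray(list(series), dtype=float)
    if arr.size == 0:
        raise ValueError("trajectory has no time points")
    if arr.ndim == 2:
        days, pct = arr[:, 0], arr[:, 1]
        if np.any(np.diff(days) <= 0):
            raise ValueError("trajectory days must be strictly increasing")
    else:
        pct = arr
    if np.any(pct < -100.0):
        raise ValueError("pct_change below -100% is not a valid volume change")
    return float(pct.min())


def call_recist(sample_id: str, best: float) -> RecistCall:
    """RECIST-adapted category from the best percent volume change."""
    if best < -100.0:
        raise ValueError(f"best response {best} below -100%")
    if best == -100.0:
        category = "CR"
    elif best < RECIST_PR_BOUND:
        category = "PR"
    elif best <= RECIST_PD_BOUND:
        category = "SD"
    else:
        category = "PD"
    return RecistCall(sample_id, float(best), category, category != "PD")


def call_screen_table(dose_response: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Vectorised :func:`call_screen` over a dose-response table
    (columns sample_id, ic50_um, amax_pct)."""
    calls = [call_screen(r.sample_id, r.ic50_um, r.amax_pct, **kwargs)
             for r in dose_response.itertuples(index=False)]
    return pd.DataFrame([c.__dict__ for c in calls])


def call_recist_table(trajectories: pd.DataFrame) -> pd.DataFrame:
    """Best response and RECIST call per sample from a long-format
    trajectory table (columns sample_id, day, pct_change)."""
    rows = []
    for sample_id, grp in trajectories.groupby("sample_id", sort=False):
        grp = grp.sort_values("day")
        best = best_response(zip(grp["day"], grp["pct_change"]))
        rows.append(call_recist(sample_id, best).__dict__)
    out = pd.DataFrame(rows)
    out["call"] = np.where(out["sensitive"], "sensitive", "insensitive")
    return out
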