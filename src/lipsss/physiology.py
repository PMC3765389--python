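"""Oxygen consumption from the estimated fluxes.

Per sample, MVO2 = (2 + p_dil) * j_tca: complete oxidation of an acetyl
unit consumes 2 O2, and the endogenous-substrate fraction p_dil adds one
further O2 per turn on average.  Per heart, sample values are averaged with
dry-weight weights; the SEM over a heart's samples is unweighted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

__all__ = [
    "SampleMVO2",
    "HeartSummary",
    "mvo2_sample",
    "mvo2_heart",
    "validate_against_gold",
]


@dataclass(frozen=True)
class SampleMVO2:
    sample_id: str
    mvo2: float          # umol O2 / (min * g dry weight)
    dry_weight_g: float

    def __post_init__(self):
        if self.mvo2 < 0:
            raise ValueError("mvo2 must be >= 0")
        if not self.dry_weight_g > 0:
            raise ValueError("dry_weight_g must be > 0")


@dataclass(frozen=True)
class HeartSummary:
    heart_id: str
    mvo2: float
    sem: float
    n_samples: int


def mvo2_sample(j_tca: float, p_dil: float) -> float:
    """MVO2 of one sample: (2 + p_dil) * j_tca, umol/(min*gdw)."""
    if not j_tca > 0:
        raise ValueError(f"j_tca must be > 0, got {j_tca}")
    if not 0.0 <= p_dil <= 1.0:
        raise ValueError(f"p_dil must be in [0, 1], got {p_dil}")
    return (2.0 + p_dil) * j_tca


def mvo2_heart(samples: Sequence[SampleMVO2], heart_id: str = "") -> HeartSummary:
    """Dry-weight-weighted mean over a heart's (quality-passing) samples."""
    if not samples:
        raise ValueError("need at least one sample")
    w = np.array([s.dry_weight_g for s in samples])
    v = np.array([s.mvo2 for s in samples])
    mean = float(w @ v / w.sum())
    sem = float(np.std(v, ddof=1) / math.sqrt(v.size)) if v.size > 1 else math.nan
    return HeartSummary(heart_id, mean, sem, int(v.size))


def validate_against_gold(hearts: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of model-derived vs gold-standard MVO2 per heart.

    ``hearts`` needs columns heart_id, group, mvo2_lipsss, mvo2_gold.
    Returns one row per group plus an ``all`` row with n, r and the
    two-sided p-value; groups with fewer than 3 pairs are reported with a
    warning (r is meaningless there).
    """
    required = {"heart_id", "group", "mvo2_lipsss", "mvo2_gold"}
    missing = required - set(hearts.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []

    def _one(label, df):
        n = len(df)
        if n < 3:
            warnings.warn(
                f"group {label!r}: only {n} pairs; correlation unreliable",
                stacklevel=2)
        if n >= 2 and df["mvo2_lipsss"].std() > 0 and df["mvo2_gold"].std() > 0:
            r, p = pearsonr(df["mvo2_gold"], df["mvo2_lipsss"])
        else:
            r, p = math.nan, math.nan
        rows.append({"group": label, "n": n, "pearson_r": float(r),
                     "p_value": float(p) if n >= 3 else math.nan})

    for label, df in hearts.groupby("group", sort=True):
        _one(label, df)
    _one("all", hearts)
    return pd.DataFrame(rows)
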