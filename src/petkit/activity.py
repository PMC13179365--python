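"""Gravimetric activity metrics: weight loss, fold-activity, residual activity.

Fold-activity is the ratio of a variant's PET weight-loss percentage to the
wild type's under matched buffer/temperature/duration. It is a conversion
ratio, not a rate ratio: near-complete conversion compresses differences,
which is documented rather than corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError


@dataclass(frozen=True)
class WeightLossRecord:
    variant: str
    buffer_molarity: float
    temperature_c: float
    duration_h: float
    initial_mg: float
    final_mg: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.initial_mg <= 0 or self.final_mg < 0:
            raise DataError("masses must be positive (final may be 0)")
        if self.final_mg > self.initial_mg:
            raise DataError(
                f"{self.variant}: final mass {self.final_mg} mg exceeds "
                f"initial {self.initial_mg} mg"
            )

    @property
    def condition(self) -> tuple[float, float, float]:
        return (self.buffer_molarity, self.temperature_c, self.duration_h)


def weight_loss(record: WeightLossRecord) -> float:
    """Percent mass lost: 100*(initial - final)/initial."""
    return 100.0 * (record.initial_mg - record.final_mg) / record.initial_mg


@dataclass
class FoldActivity:
    value: float
    lower_bound_only: bool = False  # set when the WT reference lost no mass


def fold_activity(variant_wl_pct: float, wt_wl_pct: float) -> FoldActivity:
    """Variant weight loss over WT weight loss at a matched condition."""
    if variant_wl_pct < 0 or wt_wl_pct < 0:
        raise DataError("weight-loss percentages must be non-negative")
    if wt_wl_pct == 0:
        return FoldActivity(math.inf, lower_bound_only=True)
    return FoldActivity(variant_wl_pct / wt_wl_pct)


@dataclass
class ResidualActivityResult:
    times: np.ndarray
    percent_remaining: np.ndarray
    half_life: float  # same units as times; inf when 50% is never crossed
    half_life_is_lower_bound: bool


def residual_activity(times, activities) -> ResidualActivityResult:
    """Percent activity remaining vs the t=0 reference, plus a half-life.

    The half-life is the first crossing of 50%, located by log-linear
    interpolation between the bracketing samples (exact for exponential
    decay). Without a crossing the last time point is returned as a lower
    bound (``half_life_is_lower_bound``).
    """
    t = np.asarray(times, dtype=float)
    a = np.asarray(activities, dtype=float)
    if t.size != a.size or t.size < 2:
        raise DataError("need matching time/activity arrays with >= 2 points")
    if np.any(np.diff(t) <= 0):
        raise DataError("times must be strictly increasing")
    if t[0] != 0:
        raise DataError("series must include the t=0 reference")
    if a[0] <= 0:
        raise DataError("reference activity at t=0 must be positive")
    pct = 100.0 * a / a[0]

    below = np.nonzero(pct <= 50.0)[0]
    if below.size == 0:
        return ResidualActivityResult(t, pct, float(t[-1]), True)
    i = int(below[0])
    if pct[i] == 50.0 or i == 0:
        return ResidualActivityResult(t, pct, float(t[i]), False)
    p0, p1 = pct[i - 1], pct[i]
    if p1 <= 0:
        # linear fallback when the log interpolation is undefined
        hl = t[i - 1] + (p0 - 50.0) * (t[i] - t[i - 1]) / (p0 - p1)
    else:
        hl = t[i - 1] + (np.log(p0 / 50.0) / np.log(p0 / p1)) * (t[i] - t[i - 1])
    return ResidualActivityResult(t, pct, float(hl), False)


def summarize_weight_loss(records: pd.DataFrame, wt_name: str = "PHL7") -> pd.DataFrame:
    """Per-variant/per-condition mean weight loss and fold-activity vs WT.

    Expects columns variant, buffer_m, temp_c, duration_h, initial_mg,
    final_mg (replicate optional). Conditions without a WT reference get a
    NaN fold.
    """
    required = {"variant", "buffer_m", "temp_c", "duration_h", "initial_mg", "final_mg"}
    if not required.issubset(records.columns):
        raise DataError(f"weight-loss table must have columns {sorted(required)}")
    df = records.copy()
    if np.any(df["final_mg"] > df["initial_mg"]):
        raise DataError("final mass exceeds initial mass in at least one record")
    df["weight_loss_pct"] = 100.0 * (df["initial_mg"] - df["final_mg"]) / df["initial_mg"]
    keys = ["variant", "buffer_m", "temp_c", "duration_h"]
    summary = df.groupby(keys, as_index=False)["weight_loss_pct"].mean()

    wt = summary[summary["variant"] == wt_name].set_index(["buffer_m", "temp_c", "duration_h"])
    folds = []
    for row in summary.itertuples(index=False):
        key = (row.buffer_m, row.temp_c, row.duration_h)
        if key in wt.index and wt.loc[key, "weight_loss_pct"] > 0:
            folds.append(row.weight_loss_pct / wt.loc[key, "weight_loss_pct"])
        else:
            folds.append(float("nan"))
    summary["fold_vs_wt"] = folds
    return summary
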