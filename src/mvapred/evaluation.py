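"""Sensitivity, specificity and execution-time reporting.

SE = 100*TP/(TP+FN) is the proportion of pre-arrhythmic segments
flagged; SP = 100*TN/(TN+FP) the proportion of normal segments cleared.
Execution time (exT) is the median wall-clock duration of one
prediction call; it is hardware-dependent and is reported for ordinal
comparisons only (fewer features should not be slower).

Aggregate report rows follow the convention of an Average row (simple
mean over the five interval values) and an SD row (sample standard
deviation over those values; population SD behind a flag).
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_labels(cls, truth, pred) -> "ConfusionCounts":
        truth = np.asarray(truth, int)
        pred = np.asarray(pred, int)
        return cls(
            TP=int(((truth == 1) & (pred == 1)).sum()),
            FP=int(((truth == 0) & (pred == 1)).sum()),
            TN=int(((truth == 0) & (pred == 0)).sum()),
            FN=int(((truth == 1) & (pred == 0)).sum()),
        )

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.FP + other.FP,
                               self.TN + other.TN, self.FN + other.FN)


def sensitivity(c: ConfusionCounts) -> float:
    """SE in percent: 100*TP/(TP+FN); NaN when no positives."""
    if c.TP + c.FN == 0:
        warnings.warn("sensitivity undefined: no positives", stacklevel=2)
        return float("nan")
    return 100.0 * c.TP / (c.TP + c.FN)


def specificity(c: ConfusionCounts) -> float:
    """SP in percent: 100*TN/(TN+FP); NaN when no negatives."""
    if c.TN + c.FP == 0:
        warnings.warn("specificity undefined: no negatives", stacklevel=2)
        return float("nan")
    return 100.0 * c.TN / (c.TN + c.FP)


def measure_execution_time(model, rows, repetitions: int = 25) -> float:
    """Median wall-clock time of one prediction call, in ms.

    One warm-up call precedes timing. The absolute value is
    hardware-dependent; use it for ordinal comparisons.
    """
    if repetitions < 5:
        raise ValueError("need at least 5 repetitions")
    X = np.asarray(rows, float)
    model.predict(X)  # warm-up
    times = np.empty(repetitions)
    for i in range(repetitions):
        t0 = time.perf_counter()
        model.predict(X)
        times[i] = time.perf_counter() - t0
    return float(np.median(times) * 1000.0)


def aggregate_report(interval_values: pd.DataFrame,
                     sd_mode: str = "sample") -> pd.DataFrame:
    """Append Average and SD rows to a per-interval results table.

    Parameters
    ----------
    interval_values : DataFrame
        Indexed by interval, numeric columns (SE, SP, exT, ...).
    sd_mode : {"sample", "population"}
        Convention for the SD row; sample (n-1) by default, which
        matches how repeated-trial SDs are conventionally reported.
    """
    if sd_mode not in ("sample", "population"):
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    ddof = 1 if sd_mode == "sample" else 0
    out = interval_values.copy()
    num = out.select_dtypes("number")
    avg = num.mean()
    if len(num) >= 2:
        sd = num.std(ddof=ddof)
    else:
        sd = pd.Series(np.nan, index=num.columns)
        warnings.warn("SD undefined for a single interval", stacklevel=2)
    out.loc["Average"] = avg
    out.loc["SD"] = sd
    return out


def pooled_counts(counts: list[ConfusionCounts]) -> ConfusionCounts:
    """Sum confusion counts (pooling mode, non-default for reports)."""
    total = ConfusionCounts()
    for c in counts:
        total = total + c
    return total
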