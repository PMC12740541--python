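"""Repetition statistics: confidence intervals, significance, volume accuracy.

Repeated-scan scores are summarized as mean with a 95% confidence interval
(normal approximation, z = 1.96, by default; Student-t optional).  Two
summaries differ significantly when their confidence intervals do not overlap
— touching endpoints count as overlapping, a conservative reading.  Volume
accuracy is reported as the relative difference from the physical
calcification volume (377 mm^3 for the ring inserts); calcium-free regions
are summarized by their absolute volume instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RepeatedMeasure",
    "mean_ci",
    "compare_ci",
    "relative_volume_difference",
    "summarize_scores",
]


@dataclass(frozen=True)
class RepeatedMeasure:
    """Mean and 95% CI of one quantity over scan repetitions."""

    values: tuple[float, ...]
    mean: float
    ci_low: float
    ci_high: float
    method: str = "normal"

    def __post_init__(self) -> None:
        if not self.ci_low <= self.mean <= self.ci_high:
            raise ValueError("CI must bracket the mean")


def mean_ci(
    values, confidence: float = 0.95, method: str = "normal"
) -> RepeatedMeasure:
    """Mean +- critical * sd / sqrt(n) over >= 2 repetitions.

    ``method='normal'`` uses the z critical value (1.96 at 95%);
    ``method='t'`` uses the Student-t value with n - 1 degrees of freedom.
    """
    vals = tuple(float(v) for v in values)
    n = len(vals)
    if n < 2:
        raise ValueError("need at least 2 repetitions")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    if method == "normal":
        crit = float(stats.norm.ppf((1 + confidence) / 2))
    elif method == "t":
        crit = float(stats.t.ppf((1 + confidence) / 2, df=n - 1))
    else:
        raise ValueError(f"unknown method {method!r}")
    half = crit * sd / math.sqrt(n)
    return RepeatedMeasure(vals, mean, mean - half, mean + half, method)


def compare_ci(a: RepeatedMeasure, b: RepeatedMeasure) -> bool:
    """True when the two 95% CIs do not overlap (touching counts as overlap)."""
    return a.ci_high < b.ci_low or b.ci_high < a.ci_low


def relative_volume_difference(volume_mm3: float, reference_mm3: float) -> float:
    """Percent difference of a measured volume from the physical reference."""
    if reference_mm3 <= 0:
        raise ValueError("reference volume must be > 0")
    return 100.0 * (volume_mm3 - reference_mm3) / reference_mm3


def summarize_scores(
    scores: pd.DataFrame,
    reference: pd.DataFrame | None = None,
    group_columns: tuple[str, ...] = ("method", "thickness_mm", "contrast", "name"),
    value_column: str = "agatston_3mm",
    volume_column: str = "volume_mm3",
    reference_volume_column: str = "reference_volume_mm3",
    ci_method: str = "normal",
) -> pd.DataFrame:
    """Aggregate per-repetition scores into mean/CI cells.

    ``scores`` holds one row per (group x repetition).  When ``reference`` is
    given (same grouping minus ``method``), each cell is additionally tested
    for significance against the reference cell by the non-overlapping-CI
    rule.  When a reference physical volume column is present, the mean
    relative volume difference is reported; rows with reference volume 0
    (calcium-free regions) report the absolute mean volume instead.
    """
    rows = []
    ref_columns: list[str] = []
    ref_measures: dict[tuple, RepeatedMeasure] = {}
    if reference is not None:
        ref_columns = [
            c for c in group_columns if c != "method" and c in reference.columns
        ]
        for key, grp in reference.groupby(ref_columns, sort=True):
            key = key if isinstance(key, tuple) else (key,)
            ref_measures[key] = mean_ci(grp[value_column], method=ci_method)

    for key, grp in scores.groupby(list(group_columns), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        measure = mean_ci(grp[value_column], method=ci_method)
        row = dict(zip(group_columns, key))
        row.update(
            {
                "n": len(grp),
                "mean": measure.mean,
                "ci_low": measure.ci_low,
                "ci_high": measure.ci_high,
                "ci_method": ci_method,
            }
        )
        if ref_measures:
            ref_key = tuple(row[c] for c in ref_columns)
            ref = ref_measures.get(ref_key)
            if ref is not None:
                row["reference_mean"] = ref.mean
                row["significant_vs_reference"] = compare_ci(measure, ref)
        if volume_column in grp.columns and reference_volume_column in grp.columns:
            ref_vol = float(grp[reference_volume_column].iloc[0])
            mean_vol = float(grp[volume_column].mean())
            if ref_vol > 0:
                row["relative_volume_difference_pct"] = relative_volume_difference(
                    mean_vol, ref_vol
                )
            else:
                row["absolute_volume_mm3"] = mean_vol
        rows.append(row)
    return pd.DataFrame(rows)
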