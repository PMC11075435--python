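"""Community-assembly time-series summaries and association statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "correlate_strains",
    "paired_ttest",
    "summarise_series",
    "wilcoxon_test",
]


@dataclass
class CorrelationResult:
    """Pearson correlation between two abundance series."""

    r: float
    r2: float
    p: float
    n: int


def summarise_series(
    table: pd.DataFrame,
    value: str = "egr_corrected",
    strain_col: str = "strain",
    time_col: str = "timepoint",
) -> pd.DataFrame:
    """Mean / SEM / n per strain x timepoint.

    SEM is SD/sqrt(n) with sample SD (ddof=1); single-replicate cells get
    SEM 0 and are flagged via ``n == 1``.  Cells with no replicates simply
    do not appear -- they are never zero-filled.
    """
    if table.empty:
        raise ValueError("empty abundance table")
    rows = []
    for (strain, tp), group in table.groupby([strain_col, time_col], sort=True):
        vals = group[value].to_numpy(dtype=float)
        n = len(vals)
        sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append(
            {
                strain_col: strain,
                time_col: tp,
                "mean": float(np.mean(vals)),
                "sem": sem,
                "n": n,
            }
        )
    return pd.DataFrame(rows)


def correlate_strains(series_a, series_b) -> CorrelationResult:
    """Pearson correlation on paired replicate-level abundances.

    Inputs are aligned sequences (same replicate x timepoint ordering).
    Raises on fewer than 3 pairs or zero variance in either series.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"series lengths differ: {a.shape} vs {b.shape}")
    if len(a) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in one of the series")
    res = stats.pearsonr(a, b)
    r = float(res.statistic)
    return CorrelationResult(r=r, r2=r * r, p=float(res.pvalue), n=len(a))


def pair_series(
    table: pd.DataFrame,
    strain_a: str,
    strain_b: str,
    value: str = "egr_corrected",
    level: str = "replicate",
) -> tuple:
    """Extract two strains' abundances paired at replicate-timepoint level.

    ``level="replicate"`` pairs on (timepoint, replicate); ``level="mean"``
    pairs timepoint means (for when replicate pairing is not meaningful).
    """
    if level not in ("replicate", "mean"):
        raise ValueError(f"unknown pairing level {level!r}")
    keys = ["timepoint", "replicate"] if level == "replicate" else ["timepoint"]
    a = table[table["strain"] == strain_a]
    b = table[table["strain"] == strain_b]
    if level == "mean":
        a = a.groupby("timepoint", as_index=False)[value].mean()
        b = b.groupby("timepoint", as_index=False)[value].mean()
    merged = a.merge(b, on=keys, suffixes=("_a", "_b"))
    return merged[f"{value}_a"].to_numpy(), merged[f"{value}_b"].to_numpy()


def paired_ttest(series_a, series_b) -> tuple:
    """Paired t-test convenience wrapper; returns (statistic, p)."""
    res = stats.ttest_rel(np.asarray(series_a, float), np.asarray(series_b, float))
    return float(res.statistic), float(res.pvalue)


def wilcoxon_test(series_a, series_b) -> tuple:
    """Wilcoxon signed-rank convenience wrapper; returns (statistic, p)."""
    res = stats.wilcoxon(np.asarray(series_a, float), np.asarray(series_b, float))
    return float(res.statistic), float(res.pvalue)
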