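"""Descriptive statistics of the genome summary table.

Reproduces the study-level "general features" analysis from a strain
summary table (genome size in Mb, GC mol%, CDS count, group label):
a pooled two-sided t-test comparing AC-origin genome sizes (focal + ACiM)
with the non-AC rhizobia, a pooled t-test comparing ACiM GC content with
the non-AC rhizobia, the CDS-count vs genome-size coefficient of
determination, and per-group ranges. Outgroup strains never enter the
two-group tests.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError

__all__ = [
    "TTestResult",
    "pooled_t_test",
    "welch_t_test",
    "pearson_r2",
    "group_ranges",
    "general_features_report",
]

#: Group labels whose strains enter the two-group comparisons.
AC_LABELS = ("FOCAL", "ACiM")
NON_AC_LABELS = ("nonACiM", "nonACiR")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    degenerate: bool = False

    def __iter__(self):
        return iter((self.t, self.df, self.p))


def pooled_t_test(x, y) -> TTestResult:
    """Two-sided Student t-test with pooled variance, df = |x|+|y|−2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ConfigurationError("both samples need at least two values")
    sx = x.var(ddof=1)
    sy = y.var(ddof=1)
    df = x.size + y.size - 2
    if sx == 0.0 and sy == 0.0:
        if x.mean() == y.mean():
            return TTestResult(0.0, df, 1.0, degenerate=True)
        raise DataError("both samples constant with unequal means: zero pooled variance")
    pooled = ((x.size - 1) * sx + (y.size - 1) * sy) / df
    t = (x.mean() - y.mean()) / np.sqrt(pooled * (1 / x.size + 1 / y.size))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(float(t), float(df), p)


def welch_t_test(x, y) -> TTestResult:
    """Welch's unequal-variance alternative (not the default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ConfigurationError("both samples need at least two values")
    t, p = stats.ttest_ind(x, y, equal_var=False)
    vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
    if vx + vy == 0:
        return TTestResult(0.0, float(x.size + y.size - 2), 1.0, degenerate=True)
    df = (vx + vy) ** 2 / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))
    return TTestResult(float(t), float(df), float(p))


def pearson_r2(x, y) -> float:
    """Coefficient of determination: squared Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ConfigurationError("samples must have equal size >= 3")
    if x.var() == 0 or y.var() == 0:
        raise DataError("zero variance sample in correlation")
    r, _ = stats.pearsonr(x, y)
    return float(r) ** 2


def group_ranges(table: pd.DataFrame, column: str, group) -> tuple:
    """(min, max) of a summary column within a group (or tuple of groups)."""
    if column not in table.columns:
        raise DataError(f"unknown column {column!r}")
    labels = (group,) if isinstance(group, str) else tuple(group)
    known = set(table["group"])
    unknown = [g for g in labels if g not in known]
    if unknown:
        raise DataError(f"unknown group(s) {unknown}")
    sub = table[table["group"].isin(labels)][column]
    return float(sub.min()), float(sub.max())


def general_features_report(table: pd.DataFrame) -> pd.DataFrame:
    """Compute the full genome-features report as (statistic, value) rows.

    Size test: AC-origin strains (FOCAL + ACiM) vs non-AC rhizobia.
    GC test: ACiM vs non-AC rhizobia (the focal strain's GC is an outlier
    and is excluded, as in the original comparison). Outgroups excluded
    from everything. The GC p-value is additionally reported rounded to two
    decimals, matching how such values are printed.
    """
    for lbl in ("FOCAL", "ACiM", "nonACiM", "nonACiR"):
        if lbl not in set(table["group"]):
            raise ConfigurationError(f"summary table has no rows for group {lbl}")
    rhizobia = table[table["group"].isin(AC_LABELS + NON_AC_LABELS)]
    ac = rhizobia[rhizobia["group"].isin(AC_LABELS)]
    non_ac = rhizobia[rhizobia["group"].isin(NON_AC_LABELS)]
    acim = rhizobia[rhizobia["group"] == "ACiM"]

    size_test = pooled_t_test(ac["size_mb"], non_ac["size_mb"])
    gc_test = pooled_t_test(acim["gc_pct"], non_ac["gc_pct"])
    r2 = pearson_r2(rhizobia["size_mb"], rhizobia["cds"])

    rows = [
        ("size_ttest_t", size_test.t),
        ("size_ttest_df", size_test.df),
        ("size_ttest_p", size_test.p),
        ("gc_ttest_t", gc_test.t),
        ("gc_ttest_df", gc_test.df),
        ("gc_ttest_p", gc_test.p),
        ("gc_ttest_p_2dp", round(gc_test.p, 2)),
        ("cds_size_r2", r2),
    ]
    for name, column, group in [
        ("ac_size", "size_mb", AC_LABELS),
        ("acim_gc", "gc_pct", "ACiM"),
        ("nonac_size", "size_mb", NON_AC_LABELS),
        ("nonac_gc", "gc_pct", NON_AC_LABELS),
    ]:
        lo, hi = group_ranges(rhizobia, column, group)
        rows.append((f"{name}_min", lo))
        rows.append((f"{name}_max", hi))
    return pd.DataFrame(rows, columns=["statistic", "value"])
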