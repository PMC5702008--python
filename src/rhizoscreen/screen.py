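"""The anchored conservation screen: per-gene ANOVA, FDR, island detection.

For every anchor (focal-strain) gene, the best-hit bit scores against the
three strain groups (ACiM, nonACiM, nonACiR) are compared by one-way ANOVA;
Benjamini–Hochberg adjustment over the tested genes yields q-values, and a
gene is selected when q falls below the cutoff (default 0.001) *and* the
ACiM group mean strictly exceeds both other group means — the directional
contrast behind "conserved specifically between the anchor strain and the
AC-originating Mesorhizobium group". Missing hits enter as bit score 0:
absence is the strongest divergence signal. Anchor genes with no hit in any
strain are not testable and are reported with p = q = NA.

Selected genes are then grouped into conserved islands: maximal runs along
the focal gene order in which consecutive selected genes are separated by
at most ``max_gap`` unselected genes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError
from .proteome import GroupAssignment

__all__ = [
    "AnovaResult",
    "ConservedIsland",
    "anova_oneway",
    "bh_fdr",
    "select_conserved",
    "detect_islands",
]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    degenerate: bool = False

    def __iter__(self):  # allows F, p = anova_oneway(...)
        return iter((self.F, self.p))


def anova_oneway(groups) -> AnovaResult:
    """One-way fixed-effects ANOVA over k >= 2 groups of >= 2 values each.

    F = [SSB/(k-1)] / [SSW/(N-k)]; the p-value is the upper tail of the
    F(k-1, N-k) distribution. Degenerate inputs are flagged: zero
    within-group variance with between-group spread gives p = 0; all values
    identical gives F = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ConfigurationError("ANOVA needs at least two groups")
    if any(g.size < 2 for g in groups):
        raise ConfigurationError("every group needs at least two values")
    n = sum(g.size for g in groups)
    k = len(groups)
    grand = sum(g.sum() for g in groups) / n
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(0.0, 1.0, degenerate=True)
        return AnovaResult(math.inf, 0.0, degenerate=True)
    f = (ssb / (k - 1)) / (ssw / (n - k))
    p = float(stats.f.sf(f, k - 1, n - k))
    return AnovaResult(float(f), p)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def select_conserved(matrix: pd.DataFrame, groups: GroupAssignment,
                     q_threshold: float = 0.001) -> pd.DataFrame:
    """Run the screen over a bit-score matrix.

    Returns one row per anchor gene (matrix row order) with per-group mean
    bit scores, F, p, q and the selected flag. Genes with zero bit score in
    every non-focal strain are excluded from testing (p = q = NA).
    """
    if not (0 < q_threshold < 1):
        raise ConfigurationError("q_threshold must lie in (0, 1)")
    group_cols = {}
    for lbl in ("ACiM", "nonACiM", "nonACiR"):
        cols = [s for s in groups.strains(lbl) if s in matrix.columns]
        if len(cols) < 2:
            raise ConfigurationError(
                f"bit-score matrix covers {len(cols)} strains of group {lbl}; need >= 2"
            )
        missing = set(groups.strains(lbl)) - set(cols)
        if missing:
            raise DataError(f"matrix is missing strains {sorted(missing)} of group {lbl}")
        group_cols[lbl] = cols

    records = []
    for gene, row in matrix.iterrows():
        vals = {lbl: row[cols].to_numpy(dtype=float) for lbl, cols in group_cols.items()}
        means = {lbl: float(v.mean()) for lbl, v in vals.items()}
        tested = any(v.any() for v in vals.values())
        if tested:
            res = anova_oneway(list(vals.values()))
            p = res.p
        else:
            res, p = None, math.nan
        records.append(
            {
                "gene": gene,
                "mean_ACiM": means["ACiM"],
                "mean_nonACiM": means["nonACiM"],
                "mean_nonACiR": means["nonACiR"],
                "F": res.F if res else math.nan,
                "p": p,
                "tested": tested,
            }
        )
    df = pd.DataFrame(records).set_index("gene")
    df["q"] = math.nan
    tested_mask = df["tested"].to_numpy()
    if tested_mask.any():
        df.loc[tested_mask, "q"] = bh_fdr(df.loc[tested_mask, "p"].to_numpy())
    directional = (df["mean_ACiM"] > df["mean_nonACiM"]) & (
        df["mean_ACiM"] > df["mean_nonACiR"]
    )
    df["selected"] = tested_mask & (df["q"] < q_threshold) & directional
    return df.reset_index()


@dataclass(frozen=True)
class ConservedIsland:
    """A contiguous run of selected genes along one scaffold.

    ``start``/``end`` are 0-based half-open gene indices on the scaffold;
    ``size`` counts the selected genes in the run (interior unselected genes
    allowed up to the gap limit are not counted).
    """

    scaffold: str
    genes: tuple
    start: int
    end: int

    @property
    def size(self) -> int:
        return len(self.genes)


def detect_islands(selected, gene_order: pd.DataFrame,
                   max_gap: int = 1, min_size: int = 3) -> list:
    """Group selected genes into conserved islands along the gene order.

    ``gene_order`` must carry the focal strain's (scaffold, index, gene_id)
    rows. Per scaffold, maximal runs of selected genes separated by at most
    ``max_gap`` unselected genes form islands; runs with fewer than
    ``min_size`` selected genes are discarded. The result is independent of
    the input ordering of the selected set.
    """
    if max_gap < 0 or min_size < 1:
        raise ConfigurationError("max_gap must be >= 0 and min_size >= 1")
    selected = set(selected)
    known = set(gene_order["gene_id"])
    missing = selected - known
    if missing:
        raise DataError(f"selected gene(s) missing from gene order: {sorted(missing)[:5]}")
    dup = gene_order.duplicated(subset=["scaffold", "index"])
    if dup.any():
        raise DataError("gene order has duplicate per-scaffold indices")

    islands = []
    for scaffold, sub in gene_order.groupby("scaffold", sort=True):
        sub = sub.sort_values("index")
        hits = [(int(i), g) for i, g in zip(sub["index"], sub["gene_id"]) if g in selected]
        if not hits:
            continue
        run: list = [hits[0]]
        for idx, gene in hits[1:]:
            if idx - run[-1][0] - 1 <= max_gap:
                run.append((idx, gene))
            else:
                islands.append((scaffold, run))
                run = [(idx, gene)]
        islands.append((scaffold, run))

    out = []
    for scaffold, run in islands:
        if len(run) < min_size:
            continue
        out.append(
            ConservedIsland(
                scaffold=scaffold,
                genes=tuple(g for _, g in run),
                start=run[0][0],
                end=run[-1][0] + 1,
            )
        )
    out.sort(key=lambda isl: (isl.scaffold, isl.start))
    return out


def islands_to_frame(islands) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scaffold": isl.scaffold,
                "start": isl.start,
                "end": isl.end,
                "n_genes": isl.size,
                "gene_ids": ",".join(isl.genes),
            }
            for isl in islands
        ],
        columns=["scaffold", "start", "end", "n_genes", "gene_ids"],
    )
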