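"""Alignment, p-distances, neighbor-joining trees and similarity summaries.

Per-family alignment is positional when all members have equal length (the
default simulator emits no indels); otherwise a center-star alignment is
built around the longest member using affine-gap global alignments under
the package's scoring system. Distances are p-distances with pairwise
deletion of gapped columns; trees come from neighbor joining (exact on
additive matrices, negative branch estimates clamped to zero) and are
serialized as Newick. scikit-bio provides the tree machinery.
"""
from __future__ import annotations

import io as _io
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .errors import ConfigurationError, DataError
from .homology import ScoringParams
from .proteome import GroupAssignment

__all__ = [
    "align_family",
    "concatenate",
    "p_distance",
    "distance_matrix",
    "neighbor_joining",
    "similarity_ranges",
    "robinson_foulds",
    "round_half_away",
    "write_newick",
    "read_newick",
]

GAP = "-"


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (65.25 → 65.3), as percentages are printed."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Alignment


def _pairwise_global(a: str, b: str, params: ScoringParams):
    """Affine-gap global alignment (gapped strings) under the scoring system."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    aligner.mode = "global"
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def _merge_into_star(center_rows: dict, center_key: str, c_aln: str, s_aln: str,
                     new_key: str) -> dict:
    """Merge one pairwise (center, sequence) alignment into the growing MSA,
    following 'once a gap, always a gap' on the center sequence."""
    master = center_rows[center_key]
    out = {k: [] for k in center_rows}
    out[new_key] = []
    i = j = 0  # i walks master columns, j walks c_aln columns
    while i < len(master) or j < len(c_aln):
        m_res = master[i] if i < len(master) else None
        c_res = c_aln[j] if j < len(c_aln) else None
        if m_res == GAP and (c_res != GAP or j >= len(c_aln)):
            # gap column already in the master but not in this pairwise aln
            for k in center_rows:
                out[k].append(center_rows[k][i])
            out[new_key].append(GAP)
            i += 1
        elif c_res == GAP and (m_res != GAP or i >= len(master)):
            # this pairwise alignment inserts a new gap into the center
            for k in center_rows:
                out[k].append(GAP)
            out[new_key].append(s_aln[j])
            j += 1
        else:
            # both show the same center residue (or both gaps)
            for k in center_rows:
                out[k].append(center_rows[k][i])
            out[new_key].append(s_aln[j])
            i += 1
            j += 1
    return {k: "".join(v) for k, v in out.items()}


def align_family(members, params: ScoringParams | None = None):
    """Align a family's member sequences.

    ``members`` is a mapping id → sequence (or a list of (id, seq) pairs).
    Equal-length inputs are returned unchanged (positional alignment);
    otherwise a center-star alignment is built around the longest member
    (ties broken by smallest id).
    """
    if not isinstance(members, dict):
        members = dict(members)
    if len(members) < 2:
        raise ConfigurationError("alignment needs at least two sequences")
    lengths = {len(s) for s in members.values()}
    if len(lengths) == 1:
        return dict(members)
    params = params or ScoringParams()
    center = min(members, key=lambda k: (-len(members[k]), k))
    rows = {center: members[center]}
    for key in sorted(k for k in members if k != center):
        c_aln, s_aln = _pairwise_global(
            rows[center].replace(GAP, ""), members[key], params
        )
        rows = _merge_into_star(rows, center, c_aln, s_aln, key)
    assert len({len(r) for r in rows.values()}) == 1
    return {k: rows[k] for k in members}


def concatenate(alignments, taxa) -> dict:
    """Concatenate per-family alignments into a supermatrix (fixed order).

    Every family must contain exactly the given taxa (single-copy core
    requirement); a missing taxon raises a DataError.
    """
    taxa = list(taxa)
    if not alignments:
        raise ConfigurationError("no alignments to concatenate")
    parts = {t: [] for t in taxa}
    for k, aln in enumerate(alignments):
        missing = [t for t in taxa if t not in aln]
        if missing:
            raise DataError(
                f"family #{k} is missing taxa {missing}: not single-copy core"
            )
        width = {len(aln[t]) for t in taxa}
        if len(width) != 1:
            raise DataError(f"family #{k} rows are not equal-length")
        for t in taxa:
            parts[t].append(aln[t])
    return {t: "".join(parts[t]) for t in taxa}


# ---------------------------------------------------------------------------
# Distances


def p_distance(row_a: str, row_b: str) -> float:
    """Proportion of differing sites among sites where neither row is gapped."""
    if len(row_a) != len(row_b):
        raise DataError("aligned rows have different lengths")
    a = np.frombuffer(row_a.encode(), dtype=np.uint8)
    b = np.frombuffer(row_b.encode(), dtype=np.uint8)
    gap = ord(GAP)
    comparable = (a != gap) & (b != gap)
    n = int(comparable.sum())
    if n == 0:
        raise DataError("no comparable (gap-free) sites between rows")
    return float((a[comparable] != b[comparable]).sum() / n)


def distance_matrix(rows: dict) -> DistanceMatrix:
    """Pairwise p-distance matrix over aligned rows (taxon → row)."""
    taxa = list(rows)
    n = len(taxa)
    if n < 2:
        raise ConfigurationError("distance matrix needs at least two taxa")
    D = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = p_distance(rows[taxa[i]], rows[taxa[j]])
    return DistanceMatrix(D, ids=taxa)


# ---------------------------------------------------------------------------
# Trees


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Standard neighbor joining; negative branch estimates clamped to 0."""
    if not isinstance(dm, DistanceMatrix):
        dm = DistanceMatrix(np.asarray(dm, dtype=float))
    if dm.shape[0] < 3:
        raise ConfigurationError("neighbor joining needs at least three taxa")
    return _skbio_nj(dm, neg_as_zero=True)


def similarity_ranges(dm: DistanceMatrix, groups: GroupAssignment, pair) -> tuple:
    """(min %, max %) similarity over all cross-group taxon pairs.

    Similarity = 100·(1 − p-distance), rounded to one decimal half away
    from zero. ``pair`` names two group labels, e.g. ("FOCAL", "ACiM").
    """
    g1, g2 = pair
    taxa1 = [t for t in groups.strains(g1) if t in dm.ids]
    taxa2 = [t for t in groups.strains(g2) if t in dm.ids]
    if not taxa1 or not taxa2:
        raise ConfigurationError(f"empty group in similarity pair {pair}")
    sims = [
        100.0 * (1.0 - dm[a, b]) for a in taxa1 for b in taxa2 if a != b
    ]
    if not sims:
        raise ConfigurationError(f"no cross-group pairs for {pair}")
    return round_half_away(min(sims), 1), round_half_away(max(sims), 1)


def _bipartitions(tree: TreeNode) -> set:
    """Non-trivial unrooted bipartitions, each as a frozenset of both sides."""
    leaves = frozenset(tip.name for tip in tree.tips())
    bips = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            bips.add(frozenset((side, leaves - side)))
    return bips


def robinson_foulds(t1: TreeNode, t2: TreeNode) -> int:
    """Number of unrooted bipartitions present in exactly one of the trees."""
    leaves1 = {n.name for n in t1.tips()}
    leaves2 = {n.name for n in t2.tips()}
    if leaves1 != leaves2:
        raise DataError("trees have different leaf sets")
    return len(_bipartitions(t1) ^ _bipartitions(t2))


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(source) -> TreeNode:
    """Read a Newick tree from a path or a string."""
    if isinstance(source, str) and source.lstrip().startswith("("):
        return TreeNode.read(_io.StringIO(source), format="newick")
    return TreeNode.read(str(source), format="newick")
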