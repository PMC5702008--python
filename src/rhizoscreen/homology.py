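"""Protein homology engine: local alignment, bit scores, E-values, best hits.

Two interchangeable engines stand behind the search operations:

``engine="sw"``
    Exact affine-gap Smith–Waterman dynamic programming (numba-compiled),
    with Karlin–Altschul conversion of raw scores to bits and per-pair
    E-values ``E = m·n·2^(−bits)``. Deterministic and fully auditable; used
    for all unit-scale work and as the reference semantics.

``engine="phmmer"``
    HMMER's phmmer search via pyhmmer, the program the field uses for this
    task. Bit scores are phmmer full-sequence scores, E-values use the
    target-set size, and coverage comes from the best domain alignment.
    Used at pipeline scale where exact all-vs-all DP is not sensible.

Both engines apply the same hit filters: E-value at most ``evalue_max``
(default 1e-5) and min(query coverage, target coverage) at least
``coverage_min`` (default 0.5) — the thresholds of the original screen.
Coverage is aligned span length divided by full sequence length, computed
for both sequences; the filter applies to the smaller of the two.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .errors import ConfigurationError, DataError
from .proteome import AMINO_ACIDS, Proteome

__all__ = [
    "ScoringParams",
    "AlignmentResult",
    "smith_waterman",
    "to_bit_score",
    "evalue",
    "search_best_hits",
    "build_bitscore_matrix",
    "reciprocal_best_hits",
    "all_hits",
]

LN2 = math.log(2.0)

# ---------------------------------------------------------------------------
# Scoring system


@dataclass(frozen=True)
class ScoringParams:
    """Scoring system and hit filters.

    Gap convention: a gap of length L costs ``gap_open + L * gap_extend``
    (the first gapped residue pays both the opening and one extension).
    ``lam`` (nats per score unit) and ``K`` are the Karlin–Altschul
    constants of the gapped BLOSUM62 11/1 system.
    """

    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041
    evalue_max: float = 1e-5
    coverage_min: float = 0.5

    def __post_init__(self):
        if self.lam <= 0 or self.K <= 0:
            raise ConfigurationError("lambda and K must be positive")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ConfigurationError("gap penalties must be positive")
        if self.evalue_max <= 0 or not (0 < self.coverage_min <= 1):
            raise ConfigurationError("thresholds must be positive (coverage in (0,1])")


@dataclass(frozen=True)
class AlignmentResult:
    """Best local alignment between a query and a target.

    Spans are 0-based half-open. A raw score of 0 means no positive-scoring
    local alignment exists; spans are then empty.
    """

    query_id: str
    target_id: str
    raw: float
    bits: float
    evalue: float
    qstart: int
    qend: int
    tstart: int
    tend: int
    qcov: float
    tcov: float

    def passes(self, params: ScoringParams) -> bool:
        return (
            self.evalue <= params.evalue_max
            and min(self.qcov, self.tcov) >= params.coverage_min
        )


# ---------------------------------------------------------------------------
# Residue encoding and substitution matrix

_X_CODE = 20
_CODE = np.full(128, -1, dtype=np.int8)
for _i, _aa in enumerate(AMINO_ACIDS):
    _CODE[ord(_aa)] = _i
_CODE[ord("X")] = _X_CODE

_MATRIX_CACHE: dict = {}


def _substitution_matrix(name: str) -> np.ndarray:
    """21x21 integer matrix over the 20 residues plus X (X scores 0 vs all)."""
    if name not in _MATRIX_CACHE:
        from Bio.Align import substitution_matrices

        try:
            m = substitution_matrices.load(name)
        except Exception as exc:  # unknown matrix name
            raise ConfigurationError(f"unknown substitution matrix {name!r}") from exc
        S = np.zeros((21, 21), dtype=np.int32)
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                S[i, j] = int(m[a, b])
        # X row/column stay 0
        _MATRIX_CACHE[name] = S
    return _MATRIX_CACHE[name]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a protein sequence to integer codes, validating the alphabet."""
    if not seq:
        raise ValueError("empty sequence")
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = _CODE[arr]
    if (codes < 0).any():
        bad = chr(arr[int(np.argmax(codes < 0))])
        raise ValueError(f"unknown residue {bad!r} in sequence")
    return codes.astype(np.int8)


# ---------------------------------------------------------------------------
# Exact Smith–Waterman


@njit(cache=True)
def _sw_kernel(a, b, S, go, ge):  # pragma: no cover - exercised via smith_waterman
    m = a.shape[0]
    n = b.shape[0]
    NEG = np.int32(-(10**9))
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    HOi = np.zeros((m + 1, n + 1), dtype=np.int32)
    HOj = np.zeros((m + 1, n + 1), dtype=np.int32)
    EOi = np.zeros((m + 1, n + 1), dtype=np.int32)
    EOj = np.zeros((m + 1, n + 1), dtype=np.int32)
    FOi = np.zeros((m + 1, n + 1), dtype=np.int32)
    FOj = np.zeros((m + 1, n + 1), dtype=np.int32)
    best = np.int32(0)
    bi = 0
    bj = 0
    boi = 0
    boj = 0
    open_cost = np.int32(go + ge)
    ext_cost = np.int32(ge)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            # gap in query (consume target residue j)
            e_open = H[i, j - 1] - open_cost
            e_ext = E[i, j - 1] - ext_cost
            if e_open >= e_ext:
                E[i, j] = e_open
                if H[i, j - 1] > 0:
                    EOi[i, j] = HOi[i, j - 1]
                    EOj[i, j] = HOj[i, j - 1]
                else:
                    EOi[i, j] = i
                    EOj[i, j] = j - 1
            else:
                E[i, j] = e_ext
                EOi[i, j] = EOi[i, j - 1]
                EOj[i, j] = EOj[i, j - 1]
            # gap in target (consume query residue i)
            f_open = H[i - 1, j] - open_cost
            f_ext = F[i - 1, j] - ext_cost
            if f_open >= f_ext:
                F[i, j] = f_open
                if H[i - 1, j] > 0:
                    FOi[i, j] = HOi[i - 1, j]
                    FOj[i, j] = HOj[i - 1, j]
                else:
                    FOi[i, j] = i - 1
                    FOj[i, j] = j
            else:
                F[i, j] = f_ext
                FOi[i, j] = FOi[i - 1, j]
                FOj[i, j] = FOj[i - 1, j]
            diag = H[i - 1, j - 1] + S[a[i - 1], b[j - 1]]
            # tie priority: diagonal, then E, then F, then restart at 0
            h = np.int32(0)
            oi = 0
            oj = 0
            if diag >= h and diag >= E[i, j] and diag >= F[i, j]:
                h = diag
                if H[i - 1, j - 1] > 0:
                    oi = HOi[i - 1, j - 1]
                    oj = HOj[i - 1, j - 1]
                else:
                    oi = i - 1
                    oj = j - 1
            elif E[i, j] >= h and E[i, j] >= F[i, j]:
                h = E[i, j]
                oi = EOi[i, j]
                oj = EOj[i, j]
            elif F[i, j] >= h:
                h = F[i, j]
                oi = FOi[i, j]
                oj = FOj[i, j]
            if h < 0:
                h = np.int32(0)
                oi = 0
                oj = 0
            H[i, j] = h
            HOi[i, j] = oi
            HOj[i, j] = oj
            if h > best:
                best = h
                bi = i
                bj = j
                boi = oi
                boj = oj
    return best, boi, boj, bi, bj


def smith_waterman(
    a: str, b: str, params: ScoringParams | None = None,
    query_id: str = "", target_id: str = "",
) -> AlignmentResult:
    """Optimal affine-gap local alignment of two protein sequences.

    Returns score 0 with empty spans when no positive-scoring alignment
    exists. ``X`` residues are allowed and score 0 against everything;
    any other non-standard residue raises ``ValueError``.
    """
    params = params or ScoringParams()
    ca = encode_sequence(a)
    cb = encode_sequence(b)
    S = _substitution_matrix(params.matrix)
    raw, qs, ts, qe, te = _sw_kernel(ca, cb, S, params.gap_open, params.gap_extend)
    raw = int(raw)
    if raw <= 0:
        raw, qs, ts, qe, te = 0, 0, 0, 0, 0
    bits = to_bit_score(raw, params)
    ev = evalue(bits, len(a), len(b))
    return AlignmentResult(
        query_id=query_id,
        target_id=target_id,
        raw=float(raw),
        bits=bits,
        evalue=ev,
        qstart=int(qs),
        qend=int(qe),
        tstart=int(ts),
        tend=int(te),
        qcov=(qe - qs) / len(a),
        tcov=(te - ts) / len(b),
    )


def to_bit_score(raw: float, params: ScoringParams | None = None) -> float:
    """Karlin–Altschul conversion: bits = (lambda·raw − ln K) / ln 2."""
    params = params or ScoringParams()
    if raw < 0:
        raise ValueError("raw score must be non-negative")
    return (params.lam * raw - math.log(params.K)) / LN2


def evalue(bits: float, m: int, n: int) -> float:
    """Expected chance hits at or above ``bits`` in an m x n search space."""
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    return m * n * math.pow(2.0, -bits)


# ---------------------------------------------------------------------------
# Batch searches


def _sw_hits(queries: Proteome, targets: Proteome, params: ScoringParams):
    """All filtered query→target alignments between two proteomes (exact DP)."""
    out = []
    enc_t = [(rec, encode_sequence(rec.seq)) for rec in targets]
    S = _substitution_matrix(params.matrix)
    for q in queries:
        cq = encode_sequence(q.seq)
        for t, ct in enc_t:
            raw, qs, ts, qe, te = _sw_kernel(cq, ct, S, params.gap_open, params.gap_extend)
            raw = int(raw)
            if raw <= 0:
                continue
            bits = to_bit_score(raw, params)
            ev = evalue(bits, len(q.seq), len(t.seq))
            res = AlignmentResult(
                q.id, t.id, float(raw), bits, ev,
                int(qs), int(qe), int(ts), int(te),
                (qe - qs) / len(q.seq), (te - ts) / len(t.seq),
            )
            if res.passes(params):
                out.append(res)
    return out


def _phmmer_hits(queries: Proteome, targets: Proteome, params: ScoringParams):
    """All filtered query→target hits found by phmmer (pyhmmer backend)."""
    import pyhmmer

    alpha = pyhmmer.easel.Alphabet.amino()
    qseqs = [
        pyhmmer.easel.TextSequence(name=rec.id, sequence=rec.seq).digitize(alpha)
        for rec in queries
    ]
    tseqs = [
        pyhmmer.easel.TextSequence(name=rec.id, sequence=rec.seq).digitize(alpha)
        for rec in targets
    ]
    qlen = {rec.id: len(rec.seq) for rec in queries}
    tlen = {rec.id: len(rec.seq) for rec in targets}
    ln_k = math.log(params.K)
    out = []
    for tophits in pyhmmer.hmmer.phmmer(qseqs, tseqs, cpus=1, E=params.evalue_max):
        qid = tophits.query.name
        for hit in tophits:
            tid = hit.name
            aln = hit.best_domain.alignment
            qs, qe = aln.hmm_from - 1, aln.hmm_to
            ts, te = aln.target_from - 1, aln.target_to
            bits = float(hit.score)
            res = AlignmentResult(
                qid, tid,
                raw=max(0.0, (bits * LN2 + ln_k) / params.lam),
                bits=bits,
                evalue=float(hit.evalue),
                qstart=qs, qend=qe, tstart=ts, tend=te,
                qcov=(qe - qs) / qlen[qid],
                tcov=(te - ts) / tlen[tid],
            )
            if res.passes(params):
                out.append(res)
    return out


_ENGINES = {"sw": _sw_hits, "phmmer": _phmmer_hits}


def pairwise_hits(queries: Proteome, targets: Proteome,
                  params: ScoringParams | None = None, engine: str = "sw"):
    """All query→target alignments passing the E-value/coverage filters."""
    params = params or ScoringParams()
    try:
        fn = _ENGINES[engine]
    except KeyError:
        raise ConfigurationError(f"unknown homology engine {engine!r}") from None
    return fn(queries, targets, params)


def _best_per_query(hits):
    """Highest-bit-score hit per query; ties go to the smallest target id."""
    best: dict = {}
    for h in hits:
        cur = best.get(h.query_id)
        if (
            cur is None
            or h.bits > cur.bits
            or (h.bits == cur.bits and h.target_id < cur.target_id)
        ):
            best[h.query_id] = h
    return best


def search_best_hits(queries: Proteome, targets: Proteome,
                     params: ScoringParams | None = None, engine: str = "sw"):
    """Best filtered hit per query gene, or None when nothing passes.

    Returns an ordered dict (query gene order) of gene id →
    :class:`AlignmentResult` or None.
    """
    params = params or ScoringParams()
    best = _best_per_query(pairwise_hits(queries, targets, params, engine))
    return {q.id: best.get(q.id) for q in queries}


def build_bitscore_matrix(anchor: Proteome, strains, params: ScoringParams | None = None,
                          engine: str = "sw") -> pd.DataFrame:
    """Anchor-gene × strain matrix of best filtered bit scores (0 = no hit).

    Rows follow the anchor proteome's gene order; one column per strain in
    the given order. Passing the anchor strain itself yields its self-score
    column.
    """
    params = params or ScoringParams()
    strains = list(strains)
    ids = [p.strain for p in strains]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate strain ids in bit-score matrix input")
    mat = pd.DataFrame(0.0, index=anchor.ids, columns=ids)
    for (gid, strain), res in best_hits_per_strain(anchor, strains, params, engine).items():
        mat.at[gid, strain] = res.bits
    mat.index.name = "gene"
    return mat


def best_hits_per_strain(anchor: Proteome, strains, params: ScoringParams | None = None,
                         engine: str = "sw") -> dict:
    """Best filtered hit of each anchor gene in each strain.

    One search against the pooled targets (each query is processed once),
    split per target strain afterwards. Returns {(gene id, strain id):
    AlignmentResult}; absent keys mean no hit passed the filters.
    """
    params = params or ScoringParams()
    strains = list(strains)
    strain_of = {rec.id: p.strain for p in strains for rec in p}
    if len(strain_of) != sum(len(p) for p in strains):
        raise DataError("duplicate gene ids across strains")
    pooled = Proteome("__pooled__", [rec for p in strains for rec in p])
    best: dict = {}
    for h in pairwise_hits(anchor, pooled, params, engine):
        key = (h.query_id, strain_of[h.target_id])
        cur = best.get(key)
        if (
            cur is None
            or h.bits > cur.bits
            or (h.bits == cur.bits and h.target_id < cur.target_id)
        ):
            best[key] = h
    return best


def reciprocal_best_hits(p1: Proteome, p2: Proteome,
                         params: ScoringParams | None = None,
                         engine: str = "sw") -> set:
    """Gene-id pairs (a, b) that are mutual best filtered hits."""
    params = params or ScoringParams()
    fwd = _best_per_query(pairwise_hits(p1, p2, params, engine))
    rev = _best_per_query(pairwise_hits(p2, p1, params, engine))
    pairs = set()
    for a, hit in fwd.items():
        if hit is None:
            continue
        back = rev.get(hit.target_id)
        if back is not None and back.target_id == a:
            pairs.add((a, hit.target_id))
    return pairs


def all_hits(proteomes, params: ScoringParams | None = None, engine: str = "sw"):
    """All filtered gene→gene hits among a set of proteomes (self included).

    The backbone of ortholog clustering: includes intra-strain pairs (for
    in-paralogs) and each gene's self hit (its self bit score).
    """
    params = params or ScoringParams()
    proteomes = list(proteomes)
    records = [rec for p in proteomes for rec in p]
    combined = Proteome("__all__", records)
    return pairwise_hits(combined, combined, params, engine)


def hits_to_frame(hits) -> pd.DataFrame:
    """Tabulate alignment results (one row per hit) for TSV output."""
    return pd.DataFrame(
        [
            {
                "query": h.query_id, "target": h.target_id, "raw": h.raw,
                "bits": h.bits, "evalue": h.evalue,
                "qstart": h.qstart, "qend": h.qend,
                "tstart": h.tstart, "tend": h.tend,
                "qcov": h.qcov, "tcov": h.tcov,
            }
            for h in hits
        ],
        columns=["query", "target", "raw", "bits", "evalue",
                 "qstart", "qend", "tstart", "tend", "qcov", "tcov"],
    )
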