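"""Ortholog family clustering and pan/core-genome partitioning.

Families are connected components of a homology graph whose edges are (a)
all inter-strain reciprocal best hits and (b) any filtered hit pair (intra-
or inter-strain) whose bit score reaches half the smaller of the two genes'
self scores. Intra-strain edges let in-paralogs co-cluster; the single-copy
filter later removes such families, which is what the concatenated core
phylogeny needs. Genes without any qualifying edge become singleton
families.
"""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .errors import ConfigurationError, DataError
from .homology import ScoringParams, all_hits

__all__ = [
    "OrthologFamilySet",
    "PanCoreProfile",
    "cluster_families",
    "pan_core_counts",
    "single_copy_core",
    "core_percentages",
]


class OrthologFamilySet:
    """Partition of all input genes into families, grouped by strain."""

    def __init__(self, families: dict, strain_of: dict):
        # families: family id -> {strain -> [gene ids]}
        self.families = families
        self.strain_of = dict(strain_of)
        members = [g for fam in families.values() for genes in fam.values() for g in genes]
        if len(members) != len(set(members)):
            raise DataError("families do not partition the gene universe (duplicates)")
        if len(members) != len(self.strain_of):
            raise DataError("families do not cover the gene universe")
        if any(not fam for fam in families.values()):
            raise DataError("empty family")

    def __len__(self) -> int:
        return len(self.families)

    @property
    def strains(self) -> list:
        return sorted(set(self.strain_of.values()))

    def copy_counts(self, family_id: str) -> dict:
        return {s: len(g) for s, g in self.families[family_id].items()}

    def strains_of(self, family_id: str) -> set:
        return set(self.families[family_id])

    def presence(self) -> pd.DataFrame:
        """Family × strain table of copy counts."""
        strains = self.strains
        rows = {
            fid: [len(fam.get(s, ())) for s in strains]
            for fid, fam in self.families.items()
        }
        df = pd.DataFrame.from_dict(rows, orient="index", columns=strains)
        df.index.name = "family_id"
        return df.sort_index()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (fid, strain, gene)
            for fid, fam in sorted(self.families.items())
            for strain in sorted(fam)
            for gene in sorted(fam[strain])
        ]
        return pd.DataFrame(rows, columns=["family_id", "strain", "gene_id"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OrthologFamilySet":
        families: dict = {}
        strain_of: dict = {}
        for fid, strain, gene in df[["family_id", "strain", "gene_id"]].itertuples(index=False):
            families.setdefault(fid, {}).setdefault(strain, []).append(gene)
            strain_of[gene] = strain
        return cls(families, strain_of)


@dataclass
class PanCoreProfile:
    """Cumulative pan/core family counts along a genome addition order."""

    genomes: list
    pan: list
    core: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"genome": self.genomes, "pan": self.pan, "core": self.core})


def cluster_families(proteomes, params: ScoringParams | None = None,
                     engine: str = "sw") -> OrthologFamilySet:
    """Cluster genes of two or more proteomes into ortholog families."""
    proteomes = list(proteomes)
    if len(proteomes) < 2:
        raise ConfigurationError("clustering needs at least two proteomes")
    params = params or ScoringParams()
    strain_of = {}
    for p in proteomes:
        for rec in p:
            if rec.id in strain_of:
                raise DataError(f"duplicate gene id {rec.id!r} across proteomes")
            strain_of[rec.id] = p.strain

    hits = all_hits(proteomes, params, engine)
    self_bits = {h.query_id: h.bits for h in hits if h.query_id == h.target_id}

    graph = nx.Graph()
    graph.add_nodes_from(strain_of)

    # score-threshold edges (intra- and inter-strain)
    for h in hits:
        if h.query_id == h.target_id:
            continue
        floor = 0.5 * min(
            self_bits.get(h.query_id, float("inf")),
            self_bits.get(h.target_id, float("inf")),
        )
        if h.bits >= floor:
            graph.add_edge(h.query_id, h.target_id)

    # reciprocal-best-hit edges per ordered strain pair
    best: dict = {}  # (query gene, target strain) -> best hit
    for h in hits:
        tstrain = strain_of[h.target_id]
        if strain_of[h.query_id] == tstrain:
            continue
        key = (h.query_id, tstrain)
        cur = best.get(key)
        if (
            cur is None
            or h.bits > cur.bits
            or (h.bits == cur.bits and h.target_id < cur.target_id)
        ):
            best[key] = h
    for (q, tstrain), h in best.items():
        back = best.get((h.target_id, strain_of[q]))
        if back is not None and back.target_id == q:
            graph.add_edge(q, h.target_id)

    comps = sorted(nx.connected_components(graph), key=min)
    families = {}
    for k, comp in enumerate(comps):
        fam: dict = {}
        for gene in sorted(comp):
            fam.setdefault(strain_of[gene], []).append(gene)
        families[f"OG{k + 1:06d}"] = fam
    return OrthologFamilySet(families, strain_of)


def pan_core_counts(families: OrthologFamilySet, genome_order) -> PanCoreProfile:
    """Cumulative pan (seen in >=1 added genome) and core (seen in all added
    genomes) family counts after each genome addition."""
    genome_order = list(genome_order)
    known = set(families.strains)
    unknown = [g for g in genome_order if g not in known]
    if unknown:
        raise DataError(f"unknown strain(s) in genome order: {unknown}")
    fam_strains = {fid: families.strains_of(fid) for fid in families.families}
    pan, core = [], []
    added: set = set()
    for g in genome_order:
        added.add(g)
        pan.append(sum(1 for s in fam_strains.values() if s & added))
        core.append(sum(1 for s in fam_strains.values() if added <= s))
    return PanCoreProfile(genome_order, pan, core)


def single_copy_core(families: OrthologFamilySet, strains) -> list:
    """Family ids with exactly one member in every listed strain."""
    strains = list(strains)
    if not strains:
        raise ConfigurationError("strain list must be non-empty")
    out = []
    for fid in sorted(families.families):
        counts = families.copy_counts(fid)
        if all(counts.get(s, 0) == 1 for s in strains):
            out.append(fid)
    return out


def core_percentages(core_size: int, cds_counts) -> tuple:
    """Core-genome share of whole genomes: (min %, max %), one decimal.

    min% divides by the largest CDS count, max% by the smallest, matching
    how a core of fixed size occupies the largest/smallest genome.
    """
    counts = list(cds_counts)
    if core_size < 0:
        raise ConfigurationError("core size must be non-negative")
    if not counts or any(c < 1 for c in counts):
        raise DataError("all CDS counts must be >= 1")
    from .phylo import round_half_away

    return (
        round_half_away(100.0 * core_size / max(counts), 1),
        round_half_away(100.0 * core_size / min(counts), 1),
    )
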