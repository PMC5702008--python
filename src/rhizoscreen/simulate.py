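"""Group-structured synthetic proteomes with a planted conserved island.

The generator emulates the statistical structure the conservation screen
assumes: one focal *Rhizobium*-like anchor strain plus three strain groups
(ACiM, nonACiM, nonACiR), gene families evolving along a fixed two-genus
guide tree (*Mesorhizobium* clade = ACiM + nonACiM; *Rhizobium* clade =
focal + nonACiR), and a contiguous block of "island" families shared only
between the focal strain and the ACiM group at low divergence — the
symbiosis-island signal the screen is designed to detect. This reproduces
the tension the screen exploits: the focal strain groups with *Rhizobium*
in the core phylogeny but with ACiM at the island genes.

Sequence evolution is i.i.d. per-site replacement on the 20-letter protein
alphabet (a Jukes–Cantor-like model, no indels by default; an optional
per-copy indel rate exercises the center-star alignment path). Divergence
parameters are expected replacement events per site along a branch;
observed p-distances between strains are slightly smaller because of
multiple hits.

Randomness: one PRNG stream per strain plus one global stream, all spawned
deterministically from the master seed, so outputs are bit-identical for a
fixed seed regardless of strain insertion order.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .proteome import AMINO_ACIDS, GroupAssignment, ProteinRecord, Proteome

__all__ = ["SimConfig", "SyntheticDataset", "generate_dataset",
           "mutate_sequence", "emit_genome_summary"]

_N_AA = 20
_AA_ARR = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
_AA_INDEX = np.full(128, -1, dtype=np.int8)
for _i, _c in enumerate(AMINO_ACIDS):
    _AA_INDEX[ord(_c)] = _i


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the original 21-strain design: 1 focal strain plus
    6 ACiM / 8 nonACiM / 6 nonACiR strains, 1000 gene families of roughly
    120 residues, a planted island of 20 families at low divergence
    (d ≈ 0.02, the nodO-like ~96–99% similarity regime), within-genus
    background divergence 0.25 and between-genus divergence 0.45.
    """

    n_per_group: tuple = (6, 8, 6)  # ACiM, nonACiM, nonACiR
    n_families: int = 1000
    island_size: int = 20
    family_length_range: tuple = (100, 140)
    d_within_island: float = 0.02
    d_background: float = 0.25
    d_between_genus: float = 0.45
    accessory_fraction: float = 0.05
    indel_rate: float = 0.0
    n_scaffolds: int = 5
    seed: int = 0

    def validate(self) -> None:
        if len(self.n_per_group) != 3 or any(n < 2 for n in self.n_per_group):
            raise ConfigurationError(
                "n_per_group must give >=2 strains for each of ACiM/nonACiM/nonACiR"
            )
        if not (0 <= self.island_size < self.n_families):
            raise ConfigurationError("island_size must satisfy 0 <= island_size < n_families")
        for name in ("d_within_island", "d_background", "d_between_genus"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1), got {v}")
        if not (self.d_within_island < self.d_background <= self.d_between_genus
                or self.d_within_island == self.d_background <= self.d_between_genus):
            raise ConfigurationError(
                "divergences must satisfy d_within_island <= d_background <= d_between_genus"
            )
        if not (0.0 <= self.accessory_fraction <= 1.0):
            raise ConfigurationError("accessory_fraction must lie in [0, 1]")
        if not (0.0 <= self.indel_rate <= 1.0):
            raise ConfigurationError("indel_rate must lie in [0, 1]")
        lo, hi = self.family_length_range
        if lo < 10 or hi < lo:
            raise ConfigurationError("family_length_range must satisfy 10 <= min <= max")
        if self.n_scaffolds < 1 or self.n_scaffolds > self.n_families:
            raise ConfigurationError("n_scaffolds must lie in [1, n_families]")
        if self.island_size and self.island_size > self.n_families // self.n_scaffolds:
            raise ConfigurationError("island_size must fit within a single scaffold")

    @property
    def strain_names(self) -> list:
        names = ["focal"]
        for label, n in zip(("ACiM", "nonACiM", "nonACiR"), self.n_per_group):
            names += [f"{label}-{i + 1:02d}" for i in range(n)]
        return names

    @property
    def group_of(self) -> dict:
        out = {"focal": "FOCAL"}
        for label, n in zip(("ACiM", "nonACiM", "nonACiR"), self.n_per_group):
            for i in range(n):
                out[f"{label}-{i + 1:02d}"] = label
        return out


def mutate_sequence(seq: str, d: float, rng) -> str:
    """Replace each site independently with probability ``d`` by one of the
    other 19 residues (uniformly). ``d`` must lie in [0, 1)."""
    if not (0.0 <= d < 1.0):
        raise ValueError(f"substitution probability d must lie in [0, 1), got {d}")
    if not seq:
        raise ValueError("empty sequence")
    codes = _AA_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = seq[int(np.argmax(codes < 0))]
        raise ValueError(f"unknown residue {bad!r} in sequence")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    return _decode(_mutate_codes(codes.astype(np.int8), d, rng))


def _mutate_codes(codes: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    if d == 0.0:
        return out
    mask = rng.random(codes.size) < d
    k = int(mask.sum())
    if k:
        out[mask] = (out[mask] + rng.integers(1, _N_AA, size=k)) % _N_AA
    return out


def _decode(codes: np.ndarray) -> str:
    return _AA_ARR[codes.astype(np.intp)].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Guide tree


class _Node:
    __slots__ = ("name", "children", "length")

    def __init__(self, name=None, children=(), length=0.0):
        self.name = name
        self.children = list(children)
        self.length = length

    def newick(self) -> str:
        def fmt(node):
            if not node.children:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}):{node.length:.6f}"

        inner = ",".join(fmt(c) for c in self.children)
        return f"({inner});"


def _ultrametric_subtree(strains, height, rng) -> _Node:
    """Random ultrametric binary subtree: all tips `height` below the root."""
    if len(strains) == 1:
        return _Node(name=strains[0], length=height)
    perm = [strains[i] for i in rng.permutation(len(strains))]
    cut = int(rng.integers(1, len(strains)))
    node = _Node()
    for part in (sorted(perm[:cut]), sorted(perm[cut:])):
        child_h = float(height * rng.uniform(0.4, 0.75)) if len(part) > 1 else 0.0
        child = _ultrametric_subtree(part, child_h, rng)
        child.length = height - child_h if len(part) > 1 else height
        node.children.append(child)
    return node


def _build_guide_tree(config: SimConfig, rng) -> _Node:
    """Two-clade genus topology with ultrametric within-clade subtrees.

    Root-to-tip length within a clade is d_background/2 so that within-genus
    strain pairs diverge by about d_background; the two clade stems add
    (d_between_genus − d_background)/2 each, so between-genus pairs diverge
    by about d_between_genus.
    """
    half_bg = config.d_background / 2.0
    stem = (config.d_between_genus - config.d_background) / 2.0
    meso = [s for s, g in config.group_of.items() if g in ("ACiM", "nonACiM")]
    rhizo = [s for s, g in config.group_of.items() if g in ("FOCAL", "nonACiR")]
    root = _Node()
    for clade in (sorted(meso), sorted(rhizo)):
        sub = _ultrametric_subtree(clade, half_bg, rng)
        sub.length = stem
        root.children.append(sub)
    return root


# ---------------------------------------------------------------------------
# Dataset


@dataclass
class SyntheticDataset:
    """A complete synthetic study: proteomes, metadata tables and the truth."""

    config: SimConfig
    proteomes: dict
    groups: GroupAssignment
    gene_order: pd.DataFrame       # strain, scaffold, index, gene_id
    genome_summary: pd.DataFrame   # strain, group, size_mb, gc_pct, cds
    truth_families: pd.DataFrame   # family_id, strain, gene_id
    island_families: list          # family ids, contiguous in focal order
    tree_newick: str

    @property
    def focal(self) -> str:
        return self.groups.focal

    @property
    def family_of(self) -> dict:
        return dict(zip(self.truth_families["gene_id"], self.truth_families["family_id"]))

    @property
    def island_genes_focal(self) -> list:
        """Focal gene ids of the planted island families, in gene order."""
        fam = set(self.island_families)
        inv = self.truth_families
        rows = inv[(inv["strain"] == self.focal) & (inv["family_id"].isin(fam))]
        return sorted(rows["gene_id"])

    def write(self, outdir) -> None:
        from . import io as rio
        import os

        os.makedirs(os.path.join(outdir, "proteomes"), exist_ok=True)
        for strain, prot in self.proteomes.items():
            rio.write_fasta(prot, os.path.join(outdir, "proteomes", f"{strain}.faa"))
        rio.write_tsv(
            pd.DataFrame(
                [(s, g) for s, g in self.groups], columns=["strain", "group"]
            ),
            os.path.join(outdir, "groups.tsv"),
        )
        rio.write_tsv(self.gene_order, os.path.join(outdir, "gene_order.tsv"))
        rio.write_tsv(self.genome_summary, os.path.join(outdir, "genome_summary.tsv"))
        rio.write_tsv(self.truth_families, os.path.join(outdir, "truth_families.tsv"))
        rio.write_tsv(
            pd.DataFrame({"family_id": self.island_families}),
            os.path.join(outdir, "truth_islands.tsv"),
        )
        with open(os.path.join(outdir, "truth_tree.nwk"), "w") as fh:
            fh.write(self.tree_newick + "\n")


def _family_id(idx: int) -> str:
    return f"fam{idx:05d}"


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Simulate proteomes, gene orders, summary tables and truth tables.

    The planted island is a contiguous block of ``island_size`` families in
    the focal strain's gene order, present in the focal strain and every
    ACiM strain at divergence ``d_within_island`` and absent elsewhere.
    When ``d_within_island == d_background`` there is no planted signal: the
    flagged families are generated exactly like ordinary families (the
    screen's null/control scenario).
    """
    config.validate()
    strains = config.strain_names
    group_of = config.group_of
    planted = config.island_size > 0 and config.d_within_island < config.d_background

    master = np.random.SeedSequence(config.seed)
    children = master.spawn(1 + len(strains))
    rng_global = np.random.default_rng(children[0])
    strain_rng = {s: np.random.default_rng(c) for s, c in zip(strains, children[1:])}

    # Family scaffold layout along the focal gene order (contiguous chunks).
    nf = config.n_families
    base, extra = divmod(nf, config.n_scaffolds)
    scaffold_sizes = [base + (1 if i < extra else 0) for i in range(config.n_scaffolds)]
    scaffold_starts = np.concatenate([[0], np.cumsum(scaffold_sizes)])[:-1]
    scaffold_of_family = np.repeat(np.arange(config.n_scaffolds), scaffold_sizes)

    # Island block: contiguous inside one scaffold of the focal gene order.
    island = []
    if config.island_size > 0:
        eligible = [i for i, sz in enumerate(scaffold_sizes) if sz >= config.island_size]
        scaf = int(eligible[int(rng_global.integers(0, len(eligible)))])
        lo = int(scaffold_starts[scaf])
        start = lo + int(
            rng_global.integers(0, scaffold_sizes[scaf] - config.island_size + 1)
        )
        island = list(range(start, start + config.island_size))
    island_set = set(island)

    # Family lengths and root ancestor sequences (one concatenated array).
    lo, hi = config.family_length_range
    lengths = rng_global.integers(lo, hi + 1, size=nf)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    total = int(offsets[-1])
    root_seq = rng_global.integers(0, _N_AA, size=total).astype(np.int8)

    tree = _build_guide_tree(config, rng_global)

    # Evolve the concatenated proteome down the guide tree. Internal edges
    # consume the global stream; each pendant edge consumes its strain's own
    # stream (first draw of that stream).
    leaf_seqs: dict = {}

    def descend(node: _Node, parent: np.ndarray) -> None:
        for child in node.children:
            if child.children:
                seq = _mutate_codes(parent, child.length, rng_global)
                descend(child, seq)
            else:
                leaf_seqs[child.name] = _mutate_codes(
                    parent, child.length, strain_rng[child.name]
                )

    descend(tree, root_seq)

    # Planted island: ACiM copies re-derived from the focal copy.
    if planted:
        focal_seq = leaf_seqs["focal"]
        for s in strains:
            if group_of[s] != "ACiM":
                continue
            rng = strain_rng[s]
            seq = leaf_seqs[s]
            for f in island:
                sl = slice(offsets[f], offsets[f + 1])
                seq[sl] = _mutate_codes(focal_seq[sl], config.d_within_island, rng)

    # Presence: focal keeps everything; ordinary families survive accessory
    # loss per strain; planted island families are ACiM-private.
    presence: dict = {}
    for s in strains:
        if s == "focal":
            presence[s] = np.ones(nf, dtype=bool)
            continue
        keep = strain_rng[s].random(nf) >= config.accessory_fraction
        if planted:
            idx = np.array(island, dtype=int)
            keep[idx] = group_of[s] == "ACiM"
        presence[s] = keep

    # Assemble proteomes and gene orders.
    proteomes: dict = {}
    order_rows = []
    fam_rows = []
    gc_model: dict = {}
    for s in strains:
        rng = strain_rng[s]
        fams = np.flatnonzero(presence[s])
        if s == "focal":
            fams_ordered = fams  # family order == focal gene order
        else:
            fams_ordered = fams[rng.permutation(fams.size)]
        records = []
        n_genes = fams_ordered.size
        n_scaf = min(config.n_scaffolds, n_genes)
        b, e = divmod(n_genes, n_scaf)
        sizes = [b + (1 if i < e else 0) for i in range(n_scaf)]
        bounds = np.concatenate([[0], np.cumsum(sizes)])
        for pos, f in enumerate(fams_ordered):
            gid = f"{s}|g{pos:05d}"
            seq = leaf_seqs[s][offsets[f]:offsets[f + 1]]
            text = _decode(seq)
            if config.indel_rate > 0.0 and rng.random() < config.indel_rate:
                cut = int(rng.integers(0, len(text) - 3))
                width = int(rng.integers(1, 4))
                text = text[:cut] + text[cut + width:]
            fam = _family_id(int(f))
            records.append(ProteinRecord(gid, text, description=fam))
            if s == "focal":
                scaf = int(scaffold_of_family[f])
            else:
                scaf = int(np.searchsorted(bounds, pos, side="right") - 1)
            order_rows.append((s, f"scaffold{scaf + 1:02d}", pos, gid))
            fam_rows.append((fam, s, gid))
        proteomes[s] = Proteome(s, records)
        gc_model[s] = float(np.round(rng.uniform(58.0, 64.0), 1))

    groups = GroupAssignment({s: group_of[s] for s in strains})
    gene_order = pd.DataFrame(order_rows, columns=["strain", "scaffold", "index", "gene_id"])
    truth_families = pd.DataFrame(fam_rows, columns=["family_id", "strain", "gene_id"])
    truth_families = truth_families.sort_values(
        ["family_id", "strain", "gene_id"]
    ).reset_index(drop=True)

    dataset = SyntheticDataset(
        config=config,
        proteomes=proteomes,
        groups=groups,
        gene_order=gene_order,
        genome_summary=pd.DataFrame(),
        truth_families=truth_families,
        island_families=[_family_id(f) for f in island],
        tree_newick=tree.newick(),
    )
    dataset.genome_summary = emit_genome_summary(dataset, gc_model)
    return dataset


def emit_genome_summary(dataset: SyntheticDataset, gc_model: dict | None = None) -> pd.DataFrame:
    """One summary row per strain: coding size (Mb), GC mol% and CDS count.

    The simulator carries no nucleotide sequences, so genome size is the
    coding length (3·(residues+1) bases per CDS) and GC is an assigned
    per-strain model value.
    """
    rows = []
    for strain, prot in dataset.proteomes.items():
        coding_bases = sum(3 * (len(rec) + 1) for rec in prot)
        if gc_model is not None:
            gc = gc_model[strain]
        else:
            gc = float(dataset.genome_summary.set_index("strain").at[strain, "gc_pct"])
        rows.append(
            (
                strain,
                dataset.groups.label(strain),
                round(coding_bases / 1e6, 4),
                gc,
                len(prot),
            )
        )
    return pd.DataFrame(rows, columns=["strain", "group", "size_mb", "gc_pct", "cds"])
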