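"""Parameter-recovery experiments on synthetic data.

These helpers run the full inference on generated datasets and score it
against the generator's truth tables: screen sensitivity/precision for the
planted island families, island-detection coverage, FDR behaviour under the
no-signal control, and topology recovery of the neighbor-joining tree built
from the single-copy-core supermatrix.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from .homology import ScoringParams, build_bitscore_matrix
from .phylo import (align_family, concatenate, distance_matrix,
                    neighbor_joining, read_newick, robinson_foulds)
from .screen import detect_islands, select_conserved
from .simulate import SimConfig, SyntheticDataset, generate_dataset

__all__ = ["ScreenOutcome", "run_screen_scenario", "run_tree_recovery"]


@dataclass(frozen=True)
class ScreenOutcome:
    """Truth-scored result of one synthetic screen run."""

    seed: int
    n_tested: int
    n_selected: int
    sensitivity: float
    precision: float
    island_coverage: float   # planted genes inside the best-matching island
    islands_at_plant: int    # islands overlapping the planted block


def run_screen_scenario(
    seed: int,
    config: SimConfig | None = None,
    no_signal: bool = False,
    engine: str = "phmmer",
    q_threshold: float = 0.001,
    max_gap: int = 1,
    min_size: int = 3,
) -> ScreenOutcome:
    """Generate a dataset, run the screen, and score it against the truth.

    ``no_signal`` raises the island divergence to the background level,
    removing the planted signal (the false-positive control).
    """
    config = config or SimConfig()
    config = dataclasses.replace(config, seed=seed)
    if no_signal:
        config = dataclasses.replace(config, d_within_island=config.d_background)
    ds = generate_dataset(config)

    anchor = ds.proteomes[ds.focal]
    strains = [ds.proteomes[s] for s in sorted(ds.groups.non_focal)]
    matrix = build_bitscore_matrix(anchor, strains, ScoringParams(), engine=engine)
    records = select_conserved(matrix, ds.groups, q_threshold)

    selected = set(records.loc[records["selected"], "gene"])
    truth = set(ds.island_genes_focal)
    tp = len(selected & truth)
    sensitivity = tp / len(truth) if truth else float("nan")
    precision = tp / len(selected) if selected else 0.0

    focal_order = ds.gene_order[ds.gene_order["strain"] == ds.focal]
    islands = detect_islands(selected, focal_order, max_gap=max_gap, min_size=min_size)
    overlapping = [isl for isl in islands if set(isl.genes) & truth]
    coverage = max(
        (len(set(isl.genes) & truth) / len(truth) for isl in overlapping),
        default=0.0,
    ) if truth else float("nan")

    return ScreenOutcome(
        seed=seed,
        n_tested=int(records["tested"].sum()),
        n_selected=len(selected),
        sensitivity=sensitivity,
        precision=precision,
        island_coverage=coverage,
        islands_at_plant=len(overlapping),
    )


def _true_single_copy_core(ds: SyntheticDataset) -> list:
    """Family ids present exactly once in every strain, from the truth table."""
    taxa = sorted(ds.proteomes)
    counts = (
        ds.truth_families.groupby(["family_id", "strain"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=taxa, fill_value=0)
    )
    return counts.index[(counts == 1).all(axis=1)].tolist()


def run_tree_recovery(seed: int, config: SimConfig | None = None) -> int:
    """RF distance between the NJ tree of the single-copy-core supermatrix
    and the generating topology (0 = exact recovery).

    The supermatrix uses the generator's true family partition, isolating
    the alignment → p-distance → NJ chain from clustering.
    """
    config = dataclasses.replace(config or SimConfig(), seed=seed)
    ds = generate_dataset(config)
    taxa = sorted(ds.proteomes)
    gene_seq = {r.id: r.seq for s in taxa for r in ds.proteomes[s]}
    scc = set(_true_single_copy_core(ds))
    members = ds.truth_families[ds.truth_families["family_id"].isin(scc)]
    alignments = [
        align_family({row.strain: gene_seq[row.gene_id] for row in grp.itertuples()})
        for _, grp in members.groupby("family_id")
    ]
    supermatrix = concatenate(alignments, taxa)
    tree = neighbor_joining(distance_matrix(supermatrix))
    return robinson_foulds(tree, read_newick(ds.tree_newick))
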