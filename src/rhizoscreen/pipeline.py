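"""Pipeline orchestration: simulate → homology → pangenome → screen → phylo → report.

Each stage reads its inputs from, and writes its outputs to, the working
directory, so stages can be run separately or chained with ``all``. A stage
invoked before its prerequisites exist fails with an error naming the stage
to run first. All outputs are plain text (TSV / FASTA / Newick) written
atomically; given the same inputs and seed, reruns are byte-identical.
"""
from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import io as rio
from .errors import ConfigurationError, PrerequisiteError
from .homology import ScoringParams, best_hits_per_strain, hits_to_frame
from .pangenome import cluster_families, pan_core_counts, single_copy_core
from .phylo import (align_family, concatenate, distance_matrix,
                    neighbor_joining, similarity_ranges, write_newick)
from .screen import detect_islands, islands_to_frame, select_conserved
from .simulate import SimConfig, generate_dataset
from .stats_report import general_features_report

logger = logging.getLogger("rhizoscreen")

STAGES = ("simulate", "homology", "pangenome", "screen", "phylo", "report")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; serializable to/from YAML."""

    outdir: str = "rhizoscreen_out"
    engine: str = "sw"              # "sw" (exact DP) or "phmmer" (pyhmmer)
    seed: int | None = None          # overrides simulate.seed when given
    log_level: str = "INFO"
    scoring: ScoringParams = field(default_factory=ScoringParams)
    simulate: SimConfig = field(default_factory=SimConfig)
    q_threshold: float = 0.001
    max_gap: int = 1
    min_size: int = 3

    def to_dict(self) -> dict:
        return {
            "outdir": self.outdir,
            "engine": self.engine,
            "seed": self.seed,
            "log_level": self.log_level,
            "scoring": dataclasses.asdict(self.scoring),
            "simulate": dataclasses.asdict(self.simulate),
            "screen": {
                "q_threshold": self.q_threshold,
                "max_gap": self.max_gap,
                "min_size": self.min_size,
            },
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        screen = d.pop("screen", {}) or {}
        scoring = d.pop("scoring", {}) or {}
        sim = d.pop("simulate", {}) or {}
        try:
            if "n_per_group" in sim:
                sim["n_per_group"] = tuple(sim["n_per_group"])
            if "family_length_range" in sim:
                sim["family_length_range"] = tuple(sim["family_length_range"])
            return cls(
                scoring=ScoringParams(**scoring),
                simulate=SimConfig(**sim),
                **screen,
                **d,
            )
        except TypeError as exc:
            raise ConfigurationError(f"invalid configuration: {exc}") from exc

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def path(self, *parts) -> str:
        return os.path.join(self.outdir, *parts)


def _require(config: PipelineConfig, stage: str, relpath: str, run_first: str) -> str:
    p = config.path(relpath)
    if not os.path.exists(p):
        raise PrerequisiteError(stage, relpath, run_first)
    return p


def _load_proteomes(config: PipelineConfig, stage: str) -> dict:
    pdir = _require(config, stage, "proteomes", "simulate")
    out = {}
    for name in sorted(os.listdir(pdir)):
        if name.endswith((".faa", ".fasta", ".fa")):
            prot = rio.read_proteome(os.path.join(pdir, name))
            out[prot.strain] = prot
    if not out:
        raise PrerequisiteError(stage, "proteomes/*.faa", "simulate")
    return out


def stage_simulate(config: PipelineConfig) -> None:
    sim = config.simulate
    if config.seed is not None:
        sim = dataclasses.replace(sim, seed=config.seed)
    logger.info("simulate: %s", sim)
    dataset = generate_dataset(sim)
    dataset.write(config.outdir)


def stage_homology(config: PipelineConfig) -> None:
    groups = rio.read_groups(_require(config, "homology", "groups.tsv", "simulate"))
    proteomes = _load_proteomes(config, "homology")
    anchor = proteomes[groups.focal]
    strains = [anchor] + [proteomes[s] for s in sorted(groups.non_focal)]
    logger.info("homology: %d anchors vs %d strains (engine=%s)",
                len(anchor), len(strains), config.engine)
    matrix = pd.DataFrame(0.0, index=anchor.ids, columns=[p.strain for p in strains])
    best = []
    per_strain = best_hits_per_strain(anchor, strains, config.scoring, config.engine)
    for (gid, strain), res in per_strain.items():
        matrix.at[gid, strain] = res.bits
        best.append(res)
    best.sort(key=lambda h: (h.query_id, h.target_id))
    matrix.index.name = "gene"
    rio.write_matrix_tsv(matrix, config.path("bitscore_matrix.tsv"))
    rio.write_tsv(hits_to_frame(best), config.path("hits.tsv"))


def stage_pangenome(config: PipelineConfig) -> None:
    proteomes = _load_proteomes(config, "pangenome")
    logger.info("pangenome: clustering %d proteomes (engine=%s)",
                len(proteomes), config.engine)
    families = cluster_families(proteomes.values(), config.scoring, config.engine)
    rio.write_tsv(families.to_frame(), config.path("families.tsv"))
    order = sorted(proteomes)
    rio.write_tsv(pan_core_counts(families, order).to_frame(),
                  config.path("pan_core_curve.tsv"))
    scc = single_copy_core(families, order)
    with _atomic(config.path("single_copy_core.txt")) as fh:
        fh.write("\n".join(scc) + ("\n" if scc else ""))


def stage_screen(config: PipelineConfig) -> None:
    matrix = rio.read_matrix_tsv(
        _require(config, "screen", "bitscore_matrix.tsv", "homology")
    )
    groups = rio.read_groups(_require(config, "screen", "groups.tsv", "simulate"))
    gene_order = rio.read_gene_order(
        _require(config, "screen", "gene_order.tsv", "simulate")
    )
    records = select_conserved(matrix, groups, config.q_threshold)
    rio.write_tsv(records, config.path("screen.tsv"))
    selected = records.loc[records["selected"], "gene"]
    focal_order = gene_order[gene_order["strain"] == groups.focal]
    islands = detect_islands(selected, focal_order, config.max_gap, config.min_size)
    rio.write_tsv(islands_to_frame(islands), config.path("islands.tsv"))
    logger.info("screen: %d/%d genes selected, %d islands",
                len(selected), len(records), len(islands))


def stage_phylo(config: PipelineConfig) -> None:
    fam_path = _require(config, "phylo", "families.tsv", "pangenome")
    groups = rio.read_groups(_require(config, "phylo", "groups.tsv", "simulate"))
    proteomes = _load_proteomes(config, "phylo")
    from .pangenome import OrthologFamilySet

    families = OrthologFamilySet.from_frame(rio.read_tsv(fam_path, dtype=str))
    taxa = sorted(proteomes)
    scc = single_copy_core(families, taxa)
    if not scc:
        raise ConfigurationError("no single-copy core families; cannot build supermatrix")
    alignments = []
    for fid in scc:
        members = {
            strain: proteomes[strain][genes[0]].seq
            for strain, genes in families.families[fid].items()
        }
        alignments.append(align_family(members, config.scoring))
    supermatrix = concatenate(alignments, taxa)
    dm = distance_matrix(supermatrix)
    dm.to_data_frame().to_csv(config.path("distances.tsv"), sep="\t",
                              float_format=rio.FLOAT_FORMAT)
    tree = neighbor_joining(dm)
    write_newick(tree, config.path("core_tree.nwk"))
    rows = []
    for other in ("ACiM", "nonACiM", "nonACiR"):
        lo, hi = similarity_ranges(dm, groups, ("FOCAL", other))
        rows.append((f"FOCAL_vs_{other}", lo, hi))
    rio.write_tsv(pd.DataFrame(rows, columns=["pair", "min_pct", "max_pct"]),
                  config.path("similarity_ranges.tsv"))
    logger.info("phylo: %d single-copy core families, %d aligned columns",
                len(scc), len(next(iter(supermatrix.values()))))


def stage_report(config: PipelineConfig) -> None:
    summary = rio.read_genome_summary(
        _require(config, "report", "genome_summary.tsv", "simulate")
    )
    rio.write_tsv(general_features_report(summary), config.path("report.tsv"))


_STAGE_FN = {
    "simulate": stage_simulate,
    "homology": stage_homology,
    "pangenome": stage_pangenome,
    "screen": stage_screen,
    "phylo": stage_phylo,
    "report": stage_report,
}


def run_pipeline(config: PipelineConfig, stages=("all",)) -> None:
    """Run the requested stages in canonical order."""
    wanted = list(stages)
    if "all" in wanted:
        wanted = list(STAGES)
    unknown = [s for s in wanted if s not in STAGES]
    if unknown:
        raise ConfigurationError(f"unknown stage(s) {unknown}; choose from {STAGES}")
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    os.makedirs(config.outdir, exist_ok=True)
    logger.info("run: stages=%s outdir=%s engine=%s seed=%s",
                wanted, config.outdir, config.engine, config.seed)
    for stage in STAGES:
        if stage in wanted:
            _STAGE_FN[stage](config)


class _atomic:
    """Write to a temp file, then rename into place."""

    def __init__(self, path):
        self.path = str(path)
        self.tmp = self.path + ".tmp"

    def __enter__(self):
        self.fh = open(self.tmp, "w", encoding="utf-8")
        return self.fh

    def __exit__(self, exc_type, exc, tb):
        self.fh.close()
        if exc_type is None:
            os.replace(self.tmp, self.path)
        else:
            os.unlink(self.tmp)
        return False
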