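"""Core domain containers: protein records, per-strain proteomes, group labels.

A proteome is a strain's ordered protein-coding gene set. Order matters: the
focal (anchor) strain's gene order defines the rows of the bit-score matrix
and the coordinate system for island detection. Gene ids follow the
``<strain>|g<index>`` convention with 0-based indices.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError, DataError

#: The 20 canonical amino acids. ``X`` is tolerated by the aligner (scored 0).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Strain group labels used throughout the screen. FOCAL is the anchor strain
#: (*Rhizobium*-like); ACiM the AC-originating *Mesorhizobium* group; the two
#: non-AC groups are split by genus.
GROUP_LABELS = ("FOCAL", "ACiM", "nonACiM", "nonACiR")

_CANONICAL = {lbl.lower().replace("-", "").replace("_", ""): lbl for lbl in GROUP_LABELS}


def normalize_group_label(label: str) -> str:
    """Map case/punctuation variants ('acim', 'non-ACiM') to canonical labels."""
    key = "".join(ch for ch in label.lower() if ch.isalnum())
    try:
        return _CANONICAL[key]
    except KeyError:
        raise DataError(
            f"unknown group label {label!r}; expected one of {GROUP_LABELS}"
        ) from None


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein sequence with its gene id and free-text description."""

    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


class Proteome:
    """Ordered collection of :class:`ProteinRecord` for one strain."""

    def __init__(self, strain: str, records):
        self.strain = strain
        self.records = list(records)
        if not self.records:
            raise DataError(f"proteome of strain {strain!r} is empty")
        self._by_id = {}
        for rec in self.records:
            if rec.id in self._by_id:
                raise DataError(f"duplicate gene id {rec.id!r} in strain {strain!r}")
            self._by_id[rec.id] = rec

    @property
    def ids(self):
        return [rec.id for rec in self.records]

    def __getitem__(self, gene_id: str) -> ProteinRecord:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __repr__(self) -> str:
        return f"Proteome({self.strain!r}, n={len(self)})"


@dataclass
class GroupAssignment:
    """Strain → group label mapping with the screen's design constraints.

    Exactly one FOCAL strain, and every non-focal group needs at least two
    strains so the per-gene one-way ANOVA has within-group degrees of freedom.
    """

    mapping: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mapping = {s: normalize_group_label(g) for s, g in self.mapping.items()}
        focal = self.strains("FOCAL")
        if len(focal) != 1:
            raise ConfigurationError(
                f"group assignment must contain exactly one FOCAL strain, found {len(focal)}"
            )
        for lbl in ("ACiM", "nonACiM", "nonACiR"):
            if len(self.strains(lbl)) < 2:
                raise ConfigurationError(
                    f"group {lbl} has {len(self.strains(lbl))} strains; "
                    "ANOVA needs at least 2 per group"
                )

    @property
    def focal(self) -> str:
        return self.strains("FOCAL")[0]

    def strains(self, label: str) -> list:
        return [s for s, g in self.mapping.items() if g == label]

    @property
    def non_focal(self) -> list:
        return [s for s, g in self.mapping.items() if g != "FOCAL"]

    def label(self, strain: str) -> str:
        return self.mapping[strain]

    def __iter__(self):
        return iter(self.mapping.items())
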