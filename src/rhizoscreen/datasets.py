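"""Bundled reference tables.

``load_study_genome_summary`` returns the published genome summaries of the
23 strains of the original comparative study (21 rhizobia plus two
outgroups): strain, group label (FOCAL / ACiM / nonACiM / nonACiR /
OUTGROUP), genome size in Mb, GC mol%, and CDS count. The values are
transcribed from the public genome reports (NCBI BioSamples).
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from . import io as rio

__all__ = ["load_study_genome_summary"]


def load_study_genome_summary() -> pd.DataFrame:
    path = resources.files("rhizoscreen").joinpath("data/genome_summary.tsv")
    with resources.as_file(path) as p:
        return rio.read_genome_summary(p)
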