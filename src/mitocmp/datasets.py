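"""Bundled annotation tables for the two *Thaparocleidus* mitogenomes.

The tables carry the published per-gene coordinates, codons, anticodons and
orthologue identities for *T. asoti* (MN151340, 16,074 bp) and *T. varicus*
(MN151339, 14,088 bp).  They contain no nucleotide sequence; all derived
columns (size, intergenic nucleotides) are recomputed from the coordinates
by :func:`mitocmp.genome_model.build_organization_table`.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .genome_model import MitogenomeRecord, read_annotation_tsv

_DATA = resources.files(__package__) / "data"


def _bundled(name: str) -> Path:
    with resources.as_file(_DATA / name) as p:
        return Path(p)


def thaparocleidus_asoti() -> MitogenomeRecord:
    """Annotated record of the *T. asoti* mitogenome (coordinates only)."""
    return read_annotation_tsv(_bundled("thaparocleidus_asoti.tsv"))


def thaparocleidus_varicus() -> MitogenomeRecord:
    """Annotated record of the *T. varicus* mitogenome (coordinates only)."""
    return read_annotation_tsv(_bundled("thaparocleidus_varicus.tsv"))


def printed_table(species: str) -> pd.DataFrame:
    """The published organization table, as printed (blank cells = NaN).

    ``species`` is ``"asoti"`` or ``"varicus"``.  Useful for checking that
    recomputed size/intergenic columns reproduce the published ones.
    """
    name = f"thaparocleidus_{species}.tsv"
    return pd.read_csv(_bundled(name), sep="\t", comment="#")
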