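"""Data model and I/O for annotated circular mitochondrial genomes.

Flatworm mitogenomes carry a fixed complement of 36 genes (12 protein-coding
genes, *atp8* being absent; 22 tRNAs with the two leucine and two serine
isoacceptors distinguished; and the two rRNAs), typically all on one strand.
This module holds the annotated-record types, rebuilds the per-gene
organization table (size and intergenic nucleotides recomputed from
coordinates alone), and extracts large non-coding regions.

Coordinates are 1-based and fully closed throughout the public surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

# ---------------------------------------------------------------------------
# Controlled vocabulary and errors
# ---------------------------------------------------------------------------

PCG_LABELS = (
    "cox1", "cox2", "cox3", "cytb",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
    "atp6",
)

TRNA_LABELS = tuple(
    "trn" + aa
    for aa in (
        "A", "C", "D", "E", "F", "G", "H", "I", "K",
        "L1", "L2", "M", "N", "P", "Q", "R",
        "S1", "S2", "T", "V", "W", "Y",
    )
)

RRNA_LABELS = ("rrnL", "rrnS")

#: The standard 36-gene flatworm mitochondrial complement.
STANDARD_GENE_SET = frozenset(PCG_LABELS) | frozenset(TRNA_LABELS) | frozenset(RRNA_LABELS)


class MitocmpError(Exception):
    """Base class for package errors."""


class CoordinateError(MitocmpError):
    """A genomic coordinate falls outside the genome or is inconsistent."""


class ParseError(MitocmpError):
    """An input file could not be parsed; the message names the offending line."""


class AnnotationError(MitocmpError):
    """A record's feature set violates an annotation invariant."""


def gene_category(name: str) -> str:
    """Return ``PCG``/``tRNA``/``rRNA`` for a controlled gene label."""
    if name in PCG_LABELS:
        return "PCG"
    if name in TRNA_LABELS:
        return "tRNA"
    if name in RRNA_LABELS:
        return "rRNA"
    raise AnnotationError(f"unknown gene label: {name!r}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene on a circular mitogenome.

    ``start``/``end`` are 1-based inclusive.  A feature may wrap the origin,
    in which case ``start > end`` and ``wraps`` is set.  Protein-coding genes
    carry start/stop codons (the stop may be abbreviated, ``"T--"`` or
    ``"TA-"``, completed to TAA by transcript polyadenylation); tRNAs carry
    anticodons; rRNAs carry neither.
    """

    name: str
    start: int
    end: int
    strand: str = "+"
    anticodon: str | None = None
    start_codon: str | None = None
    stop_codon: str | None = None
    wraps: bool = False

    def __post_init__(self) -> None:
        gene_category(self.name)  # validates the label
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.name}: strand must be '+' or '-'")
        if self.start > self.end and not self.wraps:
            raise CoordinateError(
                f"{self.name}: start {self.start} > end {self.end} on a "
                "non-wrapping feature"
            )

    @property
    def category(self) -> str:
        return gene_category(self.name)

    def length(self, genome_length: int) -> int:
        return gene_length(self.start, self.end, genome_length, circular=True)


@dataclass
class MitogenomeRecord:
    """Annotated circular mitogenome: ordered features plus optional sequence."""

    id: str
    length: int
    features: list[GeneFeature]
    circular: bool = True
    sequence: str | None = None
    organism: str | None = None

    def __post_init__(self) -> None:
        if self.sequence is not None and len(self.sequence) != self.length:
            raise AnnotationError(
                f"{self.id}: sequence length {len(self.sequence)} != declared "
                f"length {self.length}"
            )
        seen: set[str] = set()
        for f in self.features:
            if not (1 <= f.start <= self.length and 1 <= f.end <= self.length):
                raise CoordinateError(
                    f"{self.id}/{f.name}: coordinates ({f.start}, {f.end}) outside "
                    f"[1, {self.length}]"
                )
            if f.name in seen:
                raise AnnotationError(f"{self.id}: duplicate feature {f.name!r}")
            seen.add(f.name)
        strands = {f.strand for f in self.features}
        if len(strands) > 1:
            warnings.warn(
                f"{self.id}: features on both strands; flatworm mitogenomes are "
                "expected to be single-strand",
                stacklevel=2,
            )
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise AnnotationError(f"{self.id}: no feature {name!r}")

    def gene_sequence(self, name: str) -> str:
        """Extract a feature's nucleotide sequence (wrap-aware, strand-aware)."""
        if self.sequence is None:
            raise AnnotationError(f"{self.id}: record has no sequence")
        f = self.feature(name)
        if f.wraps:
            seq = self.sequence[f.start - 1:] + self.sequence[: f.end]
        else:
            seq = self.sequence[f.start - 1: f.end]
        if f.strand == "-":
            seq = reverse_complement(seq)
        return seq


@dataclass(frozen=True)
class OrganizationRow:
    """One line of the per-gene organization table."""

    gene: str
    start: int
    end: int
    size: int
    intergenic_nucleotides: int
    start_codon: str | None = None
    stop_codon: str | None = None
    anticodon: str | None = None
    identity_pct: float | None = None


@dataclass(frozen=True)
class NonCodingRegion:
    """A maximal unannotated span of at least the extraction threshold."""

    label: str
    start: int
    end: int
    size: int
    upstream_gene: str
    downstream_gene: str
    sequence: str | None = None


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Annotation arithmetic
# ---------------------------------------------------------------------------

def gene_length(start: int, end: int, genome_length: int, circular: bool = True) -> int:
    """Length in bp of a feature on a (possibly circular) genome.

    For a wrapping feature (``start > end``, circular genome) the length is
    the count of circular positions ``start..genome_length, 1..end``.
    """
    if not (1 <= start <= genome_length and 1 <= end <= genome_length):
        raise CoordinateError(
            f"coordinates ({start}, {end}) outside [1, {genome_length}]"
        )
    if end >= start:
        return end - start + 1
    if not circular:
        raise CoordinateError(
            f"start {start} > end {end} on a linear genome"
        )
    return (genome_length - start + 1) + end


def intergenic_nucleotides(prev_end: int, next_start: int, genome_length: int) -> int:
    """Bases between two circularly adjacent features; negative means overlap.

    Returns ``next_start - prev_end - 1``.  For the origin-spanning pair (the
    last feature followed by the first) the raw difference would be close to
    ``-genome_length``; any raw value below ``-genome_length/2`` is therefore
    interpreted as the wrap and shifted by one genome length.  Genuine
    overlaps between neighbours are short, so they keep their negative sign.
    """
    raw = next_start - prev_end - 1
    if raw < -genome_length / 2:
        raw += genome_length
    return raw


def _circular_rank(record: MitogenomeRecord) -> list[GeneFeature]:
    """Features in genomic order starting at cox1 (or the first feature)."""
    feats = record.features
    if not feats:
        raise AnnotationError(f"{record.id}: record has no features")
    start_idx = 0
    for i, f in enumerate(feats):
        if f.name == "cox1":
            start_idx = i
            break
    return feats[start_idx:] + feats[:start_idx]


def build_organization_table(record: MitogenomeRecord) -> list[OrganizationRow]:
    """Recompute the per-gene organization table from coordinates alone.

    One row per feature in genomic order starting at cox1.  The first row's
    intergenic value is the circular-closure gap after the preceding feature
    (the span between the last gene and cox1 across the origin).
    """
    feats = _circular_rank(record)
    rows: list[OrganizationRow] = []
    for i, f in enumerate(feats):
        prev = feats[i - 1]  # circular: i == 0 pairs with the last feature
        rows.append(
            OrganizationRow(
                gene=f.name,
                start=f.start,
                end=f.end,
                size=f.length(record.length),
                intergenic_nucleotides=intergenic_nucleotides(
                    prev.end, f.start, record.length
                ),
                start_codon=f.start_codon,
                stop_codon=f.stop_codon,
                anticodon=f.anticodon,
            )
        )
    return rows


def extract_ncrs(
    record: MitogenomeRecord, threshold: int = 200
) -> list[NonCodingRegion]:
    """Maximal unannotated circular spans of at least ``threshold`` bp.

    Regions are labelled NCR1, NCR2, ... by circular position starting after
    cox1; in the *Thaparocleidus* arrangement this places NCR1 between nad5
    and trnK and NCR2 between trnG and cox3.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    if not record.features:
        raise AnnotationError(f"{record.id}: record is not annotated")
    L = record.length
    covered = bytearray(L)
    for f in record.features:
        if f.wraps:
            for p in range(f.start - 1, L):
                covered[p] = 1
            for p in range(f.end):
                covered[p] = 1
        else:
            for p in range(f.start - 1, f.end):
                covered[p] = 1
    # walk the circle starting just after cox1's start so NCR numbering
    # follows circular position downstream of cox1
    origin = _circular_rank(record)[0].start - 1
    runs: list[tuple[int, int]] = []  # 0-based circular (start_offset, length)
    i = 0
    while i < L:
        if covered[(origin + i) % L]:
            i += 1
            continue
        j = i
        while j < L and not covered[(origin + j) % L]:
            j += 1
        runs.append((i, j - i))
        i = j
    end_lookup = {}
    start_lookup = {}
    for f in record.features:
        end_lookup.setdefault(f.end % L, f.name)      # position after f.end
        start_lookup.setdefault((f.start - 1) % L, f.name)
    ncrs: list[NonCodingRegion] = []
    for off, size in runs:
        if size < threshold:
            continue
        s0 = (origin + off) % L            # 0-based first uncovered position
        e0 = (origin + off + size - 1) % L  # 0-based last uncovered position
        upstream = end_lookup.get(s0, "?")
        downstream = start_lookup.get((e0 + 1) % L, "?")
        seq = None
        if record.sequence is not None:
            if s0 <= e0:
                seq = record.sequence[s0: e0 + 1]
            else:
                seq = record.sequence[s0:] + record.sequence[: e0 + 1]
        ncrs.append(
            NonCodingRegion(
                label=f"NCR{len(ncrs) + 1}",
                start=s0 + 1,
                end=e0 + 1,
                size=size,
                upstream_gene=upstream,
                downstream_gene=downstream,
                sequence=seq,
            )
        )
    return ncrs


# ---------------------------------------------------------------------------
# I/O — annotation TSV (+ optional FASTA) and GenBank flat file
# ---------------------------------------------------------------------------

_TSV_COLUMNS = (
    "gene", "start", "end", "size", "intergenic",
    "start_codon", "stop_codon", "anticodon", "identity_pct",
)


def read_annotation_tsv(path: str | Path, fasta: str | Path | None = None) -> MitogenomeRecord:
    """Read a record from an annotation TSV (organization-table layout).

    Metadata lines ``# key: value`` declare ``id``, ``length``, ``circular``
    and optionally ``organism``.  Columns ``gene``, ``start`` and ``end`` are
    required; codon/anticodon columns are optional and derived columns
    (size, intergenic, identity) are ignored on input.  A FASTA file may
    supply the nucleotide sequence.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    header: list[str] | None = None
    features: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip().lower()] = val.strip()
                continue
            cells = line.split("\t")
            if header is None:
                header = [c.strip() for c in cells]
                for req in ("gene", "start", "end"):
                    if req not in header:
                        raise ParseError(
                            f"{path}:{lineno}: missing required column {req!r}"
                        )
                continue
            row = dict(zip(header, cells))
            try:
                name = row["gene"].strip()
                start = int(row["start"])
                end = int(row["end"])
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed row: {line!r}") from exc
            try:
                features.append(
                    GeneFeature(
                        name=name,
                        start=start,
                        end=end,
                        strand=row.get("strand", "+").strip() or "+",
                        anticodon=row.get("anticodon", "").strip() or None,
                        start_codon=row.get("start_codon", "").strip() or None,
                        stop_codon=row.get("stop_codon", "").strip() or None,
                        wraps=start > end,
                    )
                )
            except MitocmpError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if not features:
        raise AnnotationError(f"{path}: annotation file declares no features")
    sequence = None
    if fasta is not None:
        from Bio import SeqIO

        seqrec = next(SeqIO.parse(str(fasta), "fasta"))
        sequence = str(seqrec.seq).upper()
    if "length" in meta:
        length = int(meta["length"])
    elif sequence is not None:
        length = len(sequence)
    else:
        length = max(f.end for f in features)
    return MitogenomeRecord(
        id=meta.get("id", path.stem),
        length=length,
        features=features,
        circular=meta.get("circular", "true").lower() in ("true", "yes", "1"),
        sequence=sequence,
        organism=meta.get("organism"),
    )


def write_annotation_tsv(record: MitogenomeRecord, path: str | Path) -> None:
    """Write a record as an annotation TSV mirroring the organization table."""
    rows = build_organization_table(record)
    with open(path, "w") as fh:
        fh.write(f"# id: {record.id}\n")
        if record.organism:
            fh.write(f"# organism: {record.organism}\n")
        fh.write(f"# length: {record.length}\n")
        fh.write(f"# circular: {'true' if record.circular else 'false'}\n")
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.gene,
                        str(r.start),
                        str(r.end),
                        str(r.size),
                        str(r.intergenic_nucleotides),
                        r.start_codon or "",
                        r.stop_codon or "",
                        r.anticodon or "",
                        "" if r.identity_pct is None else f"{r.identity_pct:.2f}",
                    ]
                )
                + "\n"
            )


def organization_table_frame(record: MitogenomeRecord):
    """Organization table as a pandas DataFrame (reporting layer)."""
    import pandas as pd

    rows = build_organization_table(record)
    return pd.DataFrame(
        {
            "Gene": [r.gene for r in rows],
            "From": [r.start for r in rows],
            "To": [r.end for r in rows],
            "Size": [r.size for r in rows],
            "Intergenic Nucleotides": [r.intergenic_nucleotides for r in rows],
            "Start Codon": [r.start_codon or "" for r in rows],
            "Stop Codon": [r.stop_codon or "" for r in rows],
            "Anti-codon": [r.anticodon or "" for r in rows],
        }
    )


_GB_TYPE = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}
_GB_TYPE_INV = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}


def write_genbank(record: MitogenomeRecord, path: str | Path) -> None:
    """Write an annotated record as a GenBank flat file (sequence required)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, CompoundLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    if record.sequence is None:
        raise AnnotationError(f"{record.id}: GenBank output requires a sequence")
    seqrec = SeqRecord(
        Seq(record.sequence),
        id=record.id,
        name=record.id[:16],
        description=record.organism or "",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.circular else "linear",
        },
    )
    for f in record.features:
        strand = 1 if f.strand == "+" else -1
        if f.wraps:
            loc = CompoundLocation(
                [
                    FeatureLocation(f.start - 1, record.length, strand),
                    FeatureLocation(0, f.end, strand),
                ]
            )
        else:
            loc = FeatureLocation(f.start - 1, f.end, strand)
        quals: dict[str, list[str]] = {"gene": [f.name]}
        if f.anticodon:
            quals["note"] = [f"anticodon:{f.anticodon}"]
        if f.start_codon:
            quals["start_codon"] = [f.start_codon]
        if f.stop_codon:
            quals["stop_codon"] = [f.stop_codon]
        if f.category == "PCG":
            quals["transl_table"] = ["9"]
        seqrec.features.append(SeqFeature(loc, type=_GB_TYPE[f.category], qualifiers=quals))
    SeqIO.write([seqrec], str(path), "genbank")


def read_genbank(path: str | Path) -> MitogenomeRecord:
    """Read an annotated record from a GenBank flat file."""
    from Bio import SeqIO

    seqrec = next(SeqIO.parse(str(path), "genbank"))
    features: list[GeneFeature] = []
    for sf in seqrec.features:
        if sf.type not in _GB_TYPE_INV:
            continue
        name = (sf.qualifiers.get("gene") or [None])[0]
        if name is None:
            raise ParseError(f"{path}: feature {sf.type} lacks a /gene qualifier")
        parts = sf.location.parts
        if len(parts) > 1:
            start = int(parts[0].start) + 1
            end = int(parts[-1].end)
            wraps = True
        else:
            start = int(sf.location.start) + 1
            end = int(sf.location.end)
            wraps = False
        anticodon = None
        for note in sf.qualifiers.get("note", []):
            if note.startswith("anticodon:"):
                anticodon = note.split(":", 1)[1]
        try:
            features.append(
                GeneFeature(
                    name=name,
                    start=start,
                    end=end,
                    strand="+" if (sf.location.strand or 1) >= 0 else "-",
                    anticodon=anticodon,
                    start_codon=(sf.qualifiers.get("start_codon") or [None])[0],
                    stop_codon=(sf.qualifiers.get("stop_codon") or [None])[0],
                    wraps=wraps,
                )
            )
        except MitocmpError as exc:
            raise ParseError(f"{path}: {name}: {exc}") from exc
    if not features:
        raise AnnotationError(f"{path}: GenBank record has no gene features")
    return MitogenomeRecord(
        id=seqrec.id,
        length=len(seqrec.seq),
        features=features,
        circular=seqrec.annotations.get("topology", "circular") == "circular",
        sequence=str(seqrec.seq).upper(),
        organism=seqrec.description or None,
    )


def read_record(path: str | Path, format: str | None = None,
                fasta: str | Path | None = None) -> MitogenomeRecord:
    """Read a record, sniffing GenBank vs annotation-TSV from the suffix."""
    path = Path(path)
    if format is None:
        format = "genbank" if path.suffix.lower() in (".gb", ".gbk", ".genbank") else "tsv"
    if format == "genbank":
        return read_genbank(path)
    if format == "tsv":
        return read_annotation_tsv(path, fasta=fasta)
    raise ValueError(f"unknown format {format!r}")
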