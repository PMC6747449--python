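"""Nucleotide composition, strand skews, codon-position statistics and RSCU.

Skews are the classic strand-asymmetry statistics

    AT skew = (A - T) / (A + T),    GC skew = (G - C) / (G + C)

computed on base counts of the annotated (plus) strand.  Codon usage follows
the echinoderm/flatworm mitochondrial genetic code (translation table 9:
AAA = Asn, AGA/AGG = Ser, TGA = Trp, ATA = Ile; stops TAA/TAG), with the
six-fold leucine and serine families split into the two isoacceptor
sub-families (Leu1 = CTN, Leu2 = TTR, Ser1 = AGN, Ser2 = TCN) so that RSCU
is normalized within what a single tRNA actually reads.

All statistics are kept at full precision; rounding to the customary one
decimal (percentages) and three decimals (skews) happens only in the
reporting helpers.  N positions (unsequenced gaps) are excluded from every
denominator.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome_model import MitocmpError, MitogenomeRecord, extract_ncrs

# ---------------------------------------------------------------------------
# Genetic code 9 and codon families
# ---------------------------------------------------------------------------

_BASES = "TCAG"

#: Amino-acid assignment of the flatworm mitochondrial code (table 9).
GENETIC_CODE_9: dict[str, str] = {}


def _build_code_9() -> None:
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[9]
    for codon, aa in table.forward_table.items():
        GENETIC_CODE_9[codon] = aa
    for codon in table.stop_codons:
        GENETIC_CODE_9[codon] = "*"


_build_code_9()

STOP_CODONS_9 = tuple(c for c, aa in GENETIC_CODE_9.items() if aa == "*")

#: Codon-family label per codon: amino acid, with Leu/Ser split by isoacceptor.
CODON_FAMILY_9: dict[str, str] = {}
for _codon, _aa in GENETIC_CODE_9.items():
    if _aa == "*":
        continue
    if _aa == "L":
        CODON_FAMILY_9[_codon] = "Leu1" if _codon.startswith("CT") else "Leu2"
    elif _aa == "S":
        CODON_FAMILY_9[_codon] = "Ser1" if _codon.startswith("AG") else "Ser2"
    else:
        CODON_FAMILY_9[_codon] = _aa

FAMILY_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _fam in sorted(CODON_FAMILY_9.items()):
    FAMILY_CODONS.setdefault(_fam, ())
    FAMILY_CODONS[_fam] = FAMILY_CODONS[_fam] + (_codon,)

CANONICAL_STARTS = ("ATG", "GTG", "TTG", "ATT")
ABBREVIATED_STOPS = ("T--", "TA-")


# ---------------------------------------------------------------------------
# Composition profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompositionProfile:
    """Base percentages, AT/GC/GT content and skews for one genomic element."""

    label: str
    size: int
    pct_t: float
    pct_c: float
    pct_a: float
    pct_g: float
    at_content: float
    gc_content: float
    gt_content: float
    at_skew: float | None
    gc_skew: float | None


def skew(x: float, y: float) -> float | None:
    """(x - y)/(x + y) on counts or percentages; ``None`` when x + y == 0."""
    if x + y == 0:
        return None
    return (x - y) / (x + y)


def composition_profile(seq: str, label: str = "") -> CompositionProfile:
    """Composition and skews of a sequence; N positions are skipped."""
    if not seq:
        raise MitocmpError("composition_profile: empty sequence")
    counts = Counter(seq.upper())
    bad = set(counts) - set("ACGTN")
    if bad:
        raise MitocmpError(f"composition_profile: non-nucleotide characters {bad}")
    a, c, g, t = counts["A"], counts["C"], counts["G"], counts["T"]
    n = a + c + g + t
    if n == 0:
        raise MitocmpError("composition_profile: sequence is all N")
    return CompositionProfile(
        label=label,
        size=len(seq),
        pct_t=100 * t / n,
        pct_c=100 * c / n,
        pct_a=100 * a / n,
        pct_g=100 * g / n,
        at_content=100 * (a + t) / n,
        gc_content=100 * (g + c) / n,
        gt_content=100 * (g + t) / n,
        at_skew=skew(a, t),
        gc_skew=skew(g, c),
    )


def _trim_to_frame(seq: str) -> str:
    """Drop a trailing incomplete codon (abbreviated stop) if present."""
    return seq[: len(seq) - len(seq) % 3]


def codon_position_profiles(pcg_seqs: Sequence[str]) -> tuple[CompositionProfile, ...]:
    """Composition at the 1st/2nd/3rd codon position of concatenated PCGs."""
    if not pcg_seqs:
        raise MitocmpError("codon_position_profiles: no sequences given")
    pos = ["", "", ""]
    for s in pcg_seqs:
        s = _trim_to_frame(s.upper())
        for k in range(3):
            pos[k] += s[k::3]
    return tuple(
        composition_profile(pos[k], label=f"{k + 1}st codon position" if k == 0
                            else f"{k + 1}nd codon position" if k == 1
                            else "3rd codon position")
        for k in range(3)
    )


# ---------------------------------------------------------------------------
# Codon usage / RSCU
# ---------------------------------------------------------------------------

@dataclass
class CodonUsageTable:
    """Codon counts, RSCU and codon-family proportions under genetic code 9.

    RSCU(c) = count(c) * |family(c)| / sum of counts over family(c); a family
    with zero total count has undefined (None) RSCU for all of its codons.
    Family proportions are over total counted codons and sum to 1.
    """

    counts: dict[str, int]
    rscu: dict[str, float | None]
    family_totals: dict[str, int]
    family_proportions: dict[str, float]

    def frame(self) -> pd.DataFrame:
        rows = []
        for fam, codons in FAMILY_CODONS.items():
            for c in codons:
                rows.append(
                    {
                        "family": fam,
                        "codon": c,
                        "count": self.counts.get(c, 0),
                        "rscu": self.rscu[c],
                    }
                )
        return pd.DataFrame(rows)


def count_codons(pcg_seqs: Sequence[str]) -> Counter[str]:
    """Count in-frame codons, dropping incomplete trailing codons, stop
    codons and any codon containing an ambiguous base."""
    counts: Counter[str] = Counter()
    for s in pcg_seqs:
        s = _trim_to_frame(s.upper())
        for i in range(0, len(s), 3):
            codon = s[i: i + 3]
            if codon in STOP_CODONS_9 or set(codon) - set("ACGT"):
                continue
            counts[codon] += 1
    return counts


def rscu(pcg_seqs: Sequence[str]) -> CodonUsageTable:
    """Relative synonymous codon usage of coding sequences (genetic code 9)."""
    if not pcg_seqs:
        raise MitocmpError("rscu: no sequences given")
    counts = count_codons(pcg_seqs)
    family_totals = {fam: sum(counts.get(c, 0) for c in codons)
                     for fam, codons in FAMILY_CODONS.items()}
    total = sum(family_totals.values())
    values: dict[str, float | None] = {}
    for fam, codons in FAMILY_CODONS.items():
        ftot = family_totals[fam]
        for c in codons:
            values[c] = None if ftot == 0 else counts.get(c, 0) * len(codons) / ftot
    proportions = {fam: (family_totals[fam] / total if total else 0.0)
                   for fam in FAMILY_CODONS}
    return CodonUsageTable(
        counts=dict(counts),
        rscu=values,
        family_totals=family_totals,
        family_proportions=proportions,
    )


@dataclass(frozen=True)
class StartStop:
    start_codon: str
    stop_codon: str
    start_canonical: bool
    stop_canonical: bool


def start_stop_codons(pcg_seq: str) -> StartStop:
    """First codon and (possibly abbreviated) trailing stop of a PCG.

    A length of 1 (mod 3) ending in T reports the abbreviated stop ``T--``;
    a length of 2 (mod 3) ending in TA reports ``TA-``.  Starts outside
    ATG/GTG/TTG/ATT are flagged non-canonical.
    """
    seq = pcg_seq.upper()
    if len(seq) < 6:
        raise MitocmpError("start_stop_codons: sequence shorter than 6 nt")
    start = seq[:3]
    rem = len(seq) % 3
    if rem == 0:
        stop = seq[-3:]
        stop_ok = stop in STOP_CODONS_9
    elif rem == 1:
        tail = seq[-1]
        stop = tail + "--"
        stop_ok = tail == "T"
    else:
        tail = seq[-2:]
        stop = tail + "-"
        stop_ok = tail == "TA"
    return StartStop(
        start_codon=start,
        stop_codon=stop,
        start_canonical=start in CANONICAL_STARTS,
        stop_canonical=stop_ok,
    )


# ---------------------------------------------------------------------------
# Reporting layer
# ---------------------------------------------------------------------------

def _round(x: float | None, nd: int) -> float | None:
    return None if x is None else round(x, nd)


def profile_row(p: CompositionProfile) -> dict:
    """One composition-table row, with the customary rounding applied."""
    return {
        "Regions": p.label,
        "Size (bp)": p.size,
        "T(U)": _round(p.pct_t, 1),
        "C": _round(p.pct_c, 1),
        "A": _round(p.pct_a, 1),
        "G": _round(p.pct_g, 1),
        "AT(%)": _round(p.at_content, 1),
        "GC(%)": _round(p.gc_content, 1),
        "GT(%)": _round(p.gt_content, 1),
        "AT Skew": _round(p.at_skew, 3),
        "GC Skew": _round(p.gc_skew, 3),
    }


def composition_table(record: MitogenomeRecord) -> pd.DataFrame:
    """Composition/skew table over the standard elements of one record.

    Rows: concatenated PCGs, the three codon positions, each PCG, each rRNA,
    pooled rRNAs, pooled tRNAs and the full genome.  Requires a sequence.
    """
    from .genome_model import PCG_LABELS, RRNA_LABELS, TRNA_LABELS

    if record.sequence is None:
        raise MitocmpError(f"{record.id}: composition table requires a sequence")
    present = {f.name for f in record.features}
    pcgs = [g for g in PCG_LABELS if g in present]
    pcg_seqs = [record.gene_sequence(g) for g in pcgs]
    rows = []
    if pcg_seqs:
        rows.append(profile_row(composition_profile("".join(pcg_seqs), "PCGs")))
        for p in codon_position_profiles(pcg_seqs):
            rows.append(profile_row(p))
        for g, s in zip(pcgs, pcg_seqs):
            rows.append(profile_row(composition_profile(s, g)))
    for g in RRNA_LABELS:
        if g in present:
            rows.append(profile_row(composition_profile(record.gene_sequence(g), g)))
    rrna = "".join(record.gene_sequence(g) for g in RRNA_LABELS if g in present)
    if rrna:
        rows.append(profile_row(composition_profile(rrna, "rRNAs")))
    trna = "".join(record.gene_sequence(g) for g in TRNA_LABELS if g in present)
    if trna:
        rows.append(profile_row(composition_profile(trna, "tRNAs")))
    rows.append(profile_row(composition_profile(record.sequence, "Full genome")))
    return pd.DataFrame(rows)
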