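"""Synthetic flatworm-style mitogenome generator with declared ground truth.

Generates complete 36-gene circular mitogenomes (12 PCGs under genetic code
9, 22 tRNAs, 2 rRNAs, no atp8) whose every downstream observable is known
by construction: gene coordinates, start/stop codons, codon-position base
composition, and the tandem-repeat arrays planted inside the large
non-coding regions (unit length, copy number, per-unit substitutions and
deletions, truncated final copies).

The bundled presets emulate the two *Thaparocleidus* arrangements: the
``thaparocleidus`` preset uses the published gene order with T. varicus
gene sizes and codons and plants the 166 bp x ~3 and 48 bp x ~5 repeat
regimes in its two NCRs; ``thaparocleidus-asoti`` uses T. asoti sizes
(including the abbreviated cox2 stop) and the 132 bp and 63 bp regimes.
``ancestral-neodermatan`` provides the conserved flatworm arrangement with
the rRNAs between cox1 and cox2, for non-identical gene-order comparisons.

Everything is driven by one seeded generator: equal seeds give
byte-identical records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .genome_model import (
    GeneFeature,
    MitocmpError,
    MitogenomeRecord,
    PCG_LABELS,
    RRNA_LABELS,
    TRNA_LABELS,
    gene_category,
)
from .gene_order import GeneOrder


class SpecError(MitocmpError):
    """A synthetic-genome spec is internally infeasible."""


# ---------------------------------------------------------------------------
# Plans and spec
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatPlan:
    """A planted tandem array: unit length, copies, deviations, truncation.

    ``substitutions`` are (unit index, 1-based position, base or "" for a
    random different base); ``deletions`` are (unit index, position).  The
    truncated extra copy, when ``truncated_final_length`` > 0, is unit index
    ``copies + 1``.
    """

    period: int
    copies: int
    unit: str | None = None
    substitutions: tuple[tuple[int, int, str], ...] = ()
    deletions: tuple[tuple[int, int], ...] = ()
    truncated_final_length: int = 0

    def planted_copy_number(self) -> float:
        frac = self.truncated_final_length / self.period
        return self.copies + frac


@dataclass(frozen=True)
class NCRPlan:
    """A non-coding region: placement, total size, optional repeat array."""

    upstream: str
    downstream: str
    size: int
    repeat: RepeatPlan | None = None
    n_gap_length: int = 0  # central N-run emulating an unsequenced stretch


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    seed: int
    gene_order: GeneOrder
    pcg_lengths: Mapping[str, int]
    start_codons: Mapping[str, str]
    stop_codons: Mapping[str, str]  # TAA/TAG or abbreviated T--/TA-
    ncr_plans: tuple[NCRPlan, ...]
    codon_position_freqs: tuple[Mapping[str, float], ...]  # 3 dicts over TCAG
    background_freqs: Mapping[str, float]
    trna_length_range: tuple[int, int] = (57, 69)
    rrn_lengths: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"rrnL": (934, 940), "rrnS": (722, 733)}
    )
    spacer_range: tuple[int, int] = (0, 5)
    record_id: str = "synthetic"
    circular: bool = True


@dataclass
class PlantedRepeat:
    """Realized coordinates of one planted array (1-based, genome frame)."""

    ncr_label: str
    period: int
    copy_number: float
    start: int
    end: int
    unit_starts: list[int]
    unit: str
    substitutions: tuple[tuple[int, int, str], ...]
    deletions: tuple[tuple[int, int], ...]
    truncated_final_length: int


@dataclass
class GroundTruth:
    """The spec echoed plus everything realized during generation."""

    spec: SyntheticGenomeSpec
    ncr_coords: dict[str, tuple[int, int]]
    repeats: list[PlantedRepeat]
    effective_codon_position_freqs: tuple[dict[str, float], ...]
    pcg_internal_codons: dict[str, int]


# ---------------------------------------------------------------------------
# Default study-condition parameters
# ---------------------------------------------------------------------------

#: Codon-position base frequencies (T. varicus PCG values): the strong
#: position-2 T preference gives the characteristic negative AT skew.
DEFAULT_CODON_POSITION_FREQS = (
    {"T": 0.423, "C": 0.072, "A": 0.305, "G": 0.200},
    {"T": 0.502, "C": 0.120, "A": 0.204, "G": 0.174},
    {"T": 0.558, "C": 0.035, "A": 0.296, "G": 0.111},
)

#: Whole-genome base frequencies used for tRNA/rRNA/non-coding sequence.
DEFAULT_BACKGROUND_FREQS = {"T": 0.468, "C": 0.076, "A": 0.301, "G": 0.155}

ANTICODONS = {
    "trnA": "TGC", "trnC": "GCA", "trnD": "GTC", "trnE": "TTC", "trnF": "GAA",
    "trnG": "TCC", "trnH": "GTG", "trnI": "GAT", "trnK": "CTT", "trnL1": "TAG",
    "trnL2": "TAA", "trnM": "CAT", "trnN": "GTT", "trnP": "TGG", "trnQ": "TTG",
    "trnR": "TCG", "trnS1": "GCT", "trnS2": "TGA", "trnT": "TGT", "trnV": "TAC",
    "trnW": "TCA", "trnY": "GTA",
}

#: Published gene order of the two Thaparocleidus species (genomic order
#: from cox1), shared by both mitogenomes.
THAPAROCLEIDUS_GENE_ORDER = GeneOrder(
    labels=(
        "cox1", "trnC", "cox2", "nad6", "trnL1", "trnS2", "trnL2", "trnR",
        "nad5", "trnK", "trnT", "trnW", "trnY", "trnS1", "rrnL", "rrnS",
        "trnE", "trnG", "cox3", "trnH", "cytb", "nad4L", "nad4", "trnQ",
        "trnF", "trnM", "atp6", "nad2", "trnV", "trnA", "trnD", "nad1",
        "trnN", "trnP", "trnI", "nad3",
    ),
    orientations=("+",) * 36,
)

#: Conserved flatworm arrangement with the rRNAs between cox1 and cox2.
ANCESTRAL_NEODERMATAN_GENE_ORDER = GeneOrder(
    labels=(
        "cox1", "trnT", "rrnL", "trnC", "rrnS", "cox2", "trnE", "nad6",
        "trnY", "trnL1", "trnS2", "trnL2", "trnR", "nad5", "trnG", "cox3",
        "trnH", "cytb", "nad4L", "nad4", "trnQ", "trnF", "trnM", "atp6",
        "nad2", "trnV", "trnA", "trnD", "nad1", "trnN", "trnP", "trnI",
        "trnK", "nad3", "trnS1", "trnW",
    ),
    orientations=("+",) * 36,
)

_VARICUS_PCG_LENGTHS = {
    "cox1": 1557, "cox2": 627, "nad6": 447, "nad5": 1566, "cox3": 672,
    "cytb": 1077, "nad4L": 252, "nad4": 1218, "atp6": 513, "nad2": 828,
    "nad1": 900, "nad3": 363,
}
_VARICUS_STARTS = {
    "cox1": "ATT", "cox2": "GTG", "nad6": "ATG", "nad5": "ATG", "cox3": "ATG",
    "cytb": "ATG", "nad4L": "ATG", "nad4": "TTG", "atp6": "ATG", "nad2": "ATG",
    "nad1": "GTG", "nad3": "ATG",
}
_VARICUS_STOPS = {
    "cox1": "TAG", "cox2": "TAA", "nad6": "TAG", "nad5": "TAA", "cox3": "TAA",
    "cytb": "TAA", "nad4L": "TAG", "nad4": "TAA", "atp6": "TAA", "nad2": "TAA",
    "nad1": "TAA", "nad3": "TAA",
}
_ASOTI_PCG_LENGTHS = {
    "cox1": 1554, "cox2": 625, "nad6": 447, "nad5": 1572, "cox3": 672,
    "cytb": 1077, "nad4L": 252, "nad4": 1245, "atp6": 510, "nad2": 822,
    "nad1": 900, "nad3": 363,
}
_ASOTI_STARTS = {
    "cox1": "ATG", "cox2": "ATG", "nad6": "GTG", "nad5": "ATG", "cox3": "ATG",
    "cytb": "ATG", "nad4L": "ATG", "nad4": "ATG", "atp6": "ATG", "nad2": "ATG",
    "nad1": "ATG", "nad3": "ATG",
}
_ASOTI_STOPS = {
    "cox1": "TAG", "cox2": "T--", "nad6": "TAA", "nad5": "TAA", "cox3": "TAA",
    "cytb": "TAA", "nad4L": "TAG", "nad4": "TAG", "atp6": "TAG", "nad2": "TAA",
    "nad1": "TAA", "nad3": "TAA",
}

#: The four described repeat regimes: (period, full copies, deviations).
REPEAT_REGIMES = {
    "asoti-ncr1": RepeatPlan(period=132, copies=23),
    "asoti-ncr2": RepeatPlan(period=63, copies=11,
                             substitutions=((1, 10, ""),)),
    "varicus-ncr1": RepeatPlan(period=166, copies=2,
                               truncated_final_length=53,
                               substitutions=((3, 7, ""), (3, 8, ""), (3, 40, ""))),
    "varicus-ncr2": RepeatPlan(period=48, copies=4,
                               truncated_final_length=13,
                               substitutions=((5, 3, "C"),),
                               deletions=((5, 5),)),
}


def preset_spec(name: str, seed: int) -> SyntheticGenomeSpec:
    """A ready-made generator spec; names: ``thaparocleidus``,
    ``thaparocleidus-asoti``, ``ancestral-neodermatan``."""
    if name == "thaparocleidus":
        return SyntheticGenomeSpec(
            seed=seed,
            gene_order=THAPAROCLEIDUS_GENE_ORDER,
            pcg_lengths=_VARICUS_PCG_LENGTHS,
            start_codons=_VARICUS_STARTS,
            stop_codons=_VARICUS_STOPS,
            ncr_plans=(
                NCRPlan("nad5", "trnK", 478, REPEAT_REGIMES["varicus-ncr1"]),
                NCRPlan("trnG", "cox3", 416, REPEAT_REGIMES["varicus-ncr2"]),
            ),
            codon_position_freqs=DEFAULT_CODON_POSITION_FREQS,
            background_freqs=DEFAULT_BACKGROUND_FREQS,
            record_id="synthetic-varicus",
        )
    if name == "thaparocleidus-asoti":
        return SyntheticGenomeSpec(
            seed=seed,
            gene_order=THAPAROCLEIDUS_GENE_ORDER,
            pcg_lengths=_ASOTI_PCG_LENGTHS,
            start_codons=_ASOTI_STARTS,
            stop_codons=_ASOTI_STOPS,
            ncr_plans=(
                NCRPlan("nad5", "trnK", 2020,
                        RepeatPlan(period=132, copies=13)),
                NCRPlan("trnG", "cox3", 792, REPEAT_REGIMES["asoti-ncr2"]),
            ),
            codon_position_freqs=DEFAULT_CODON_POSITION_FREQS,
            background_freqs=DEFAULT_BACKGROUND_FREQS,
            record_id="synthetic-asoti",
        )
    if name == "ancestral-neodermatan":
        return SyntheticGenomeSpec(
            seed=seed,
            gene_order=ANCESTRAL_NEODERMATAN_GENE_ORDER,
            pcg_lengths=_VARICUS_PCG_LENGTHS,
            start_codons=_VARICUS_STARTS,
            stop_codons=_VARICUS_STOPS,
            ncr_plans=(
                NCRPlan("nad5", "trnG", 478, REPEAT_REGIMES["varicus-ncr1"]),
            ),
            codon_position_freqs=DEFAULT_CODON_POSITION_FREQS,
            background_freqs=DEFAULT_BACKGROUND_FREQS,
            record_id="synthetic-ancestral",
        )
    raise SpecError(f"unknown preset {name!r}")


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _norm(freqs: Mapping[str, float]) -> dict[str, float]:
    tot = sum(freqs.values())
    if tot <= 0:
        raise SpecError("base frequencies must sum to a positive value")
    return {b: freqs.get(b, 0.0) / tot for b in "TCAG"}


def _sample_bases(rng: np.random.Generator, freqs: Mapping[str, float], n: int) -> str:
    f = _norm(freqs)
    bases = np.array(list("TCAG"))
    probs = np.array([f[b] for b in "TCAG"])
    return "".join(rng.choice(bases, size=n, p=probs)) if n else ""


def effective_position_freqs(
    codon_position_freqs: Sequence[Mapping[str, float]],
) -> tuple[dict[str, float], ...]:
    """Per-position base frequencies after internal-stop avoidance.

    Internal TAA/TAG codons are avoided by resampling position 3 from the
    renormalized {T, C} whenever positions 1-2 read TA; positions 1 and 2
    keep their nominal frequencies, position 3 shifts by the closed form
    below.
    """
    f1, f2, f3 = (_norm(f) for f in codon_position_freqs)
    p_ta = f1["T"] * f2["A"]
    purines = f3["A"] + f3["G"]
    pyr = f3["T"] + f3["C"]
    eff3 = {}
    for b in "TCAG":
        if b in ("A", "G"):
            eff3[b] = f3[b] * (1 - p_ta)
        else:
            eff3[b] = f3[b] + p_ta * purines * (f3[b] / pyr if pyr else 0.0)
    return (f1, f2, eff3)


def _sample_pcg(
    rng: np.random.Generator,
    length: int,
    start_codon: str,
    stop_codon: str,
    freqs: Sequence[Mapping[str, float]],
) -> str:
    f1, f2, f3 = (_norm(f) for f in freqs)
    abbreviated = stop_codon.endswith("-")
    stop_len = 3 - stop_codon.count("-")
    if (length - stop_len) % 3 != 0:
        raise SpecError(
            f"PCG length {length} incompatible with stop {stop_codon!r}"
        )
    ncodons = (length - stop_len) // 3 - 1  # minus the start codon
    if ncodons < 1:
        raise SpecError(f"PCG length {length} too short")
    b = np.array(list("TCAG"))
    c1 = rng.choice(b, size=ncodons, p=[f1[x] for x in "TCAG"])
    c2 = rng.choice(b, size=ncodons, p=[f2[x] for x in "TCAG"])
    c3 = rng.choice(b, size=ncodons, p=[f3[x] for x in "TCAG"])
    # avoid internal stops: TA. codons get position 3 from renormalized {T,C}
    ta = (c1 == "T") & (c2 == "A") & np.isin(c3, ("A", "G"))
    if ta.any():
        pyr = f3["T"] + f3["C"]
        if pyr <= 0:
            raise SpecError("position-3 frequencies leave no stop-free codon")
        c3[ta] = rng.choice(
            np.array(["T", "C"]), size=int(ta.sum()), p=[f3["T"] / pyr, f3["C"] / pyr]
        )
    body = "".join(np.char.add(np.char.add(c1, c2), c3))
    return start_codon + body + stop_codon.replace("-", "")


def render_repeat_array(plan: RepeatPlan, rng: np.random.Generator,
                        background: Mapping[str, float] | None = None) -> tuple[str, RepeatPlan]:
    """Render a repeat plan to sequence; returns (array, plan-with-unit)."""
    if plan.copies < 2:
        raise SpecError("a tandem array needs at least 2 full copies")
    bg = background or DEFAULT_BACKGROUND_FREQS
    unit = plan.unit or _sample_bases(rng, bg, plan.period)
    if len(unit) != plan.period:
        raise SpecError("unit length != declared period")
    units = [list(unit) for _ in range(plan.copies)]
    if plan.truncated_final_length:
        if not (0 < plan.truncated_final_length < plan.period):
            raise SpecError("truncated final length must be in (0, period)")
        units.append(list(unit[: plan.truncated_final_length]))
    for u, pos, base in plan.substitutions:
        if not (1 <= u <= len(units) and 1 <= pos <= len(units[u - 1])):
            raise SpecError(f"substitution ({u}, {pos}) outside the array")
        old = units[u - 1][pos - 1]
        if not base:
            base = str(rng.choice([b for b in "ACGT" if b != old]))
        units[u - 1][pos - 1] = base
    for u, pos in sorted(plan.deletions, reverse=True):
        if not (1 <= u <= len(units) and 1 <= pos <= len(units[u - 1])):
            raise SpecError(f"deletion ({u}, {pos}) outside the array")
        del units[u - 1][pos - 1]
    return "".join("".join(u) for u in units), replace(plan, unit=unit)


def _render_ncr(
    plan: NCRPlan, label: str, rng: np.random.Generator,
    background: Mapping[str, float],
) -> tuple[str, PlantedRepeat | None, int]:
    """Returns (ncr sequence, planted repeat with NCR-local coords, offset)."""
    if plan.repeat is None:
        return _sample_bases(rng, background, plan.size), None, 0
    array, rplan = render_repeat_array(plan.repeat, rng, background)
    if len(array) > plan.size:
        raise SpecError(
            f"{label}: repeat array ({len(array)} bp) larger than NCR ({plan.size} bp)"
        )
    front = (plan.size - len(array)) // 2
    back = plan.size - len(array) - front
    seq = _sample_bases(rng, background, front) + array + _sample_bases(
        rng, background, back
    )
    if plan.n_gap_length:
        if plan.n_gap_length >= plan.size:
            raise SpecError(f"{label}: N-gap exceeds the NCR")
        mid = plan.size // 2
        lo = max(0, mid - plan.n_gap_length // 2)
        seq = seq[:lo] + "N" * plan.n_gap_length + seq[lo + plan.n_gap_length:]
    planted = PlantedRepeat(
        ncr_label=label,
        period=rplan.period,
        copy_number=rplan.planted_copy_number(),
        start=front + 1,
        end=front + len(array),
        unit_starts=[front + 1 + k * rplan.period for k in range(rplan.copies)],
        unit=rplan.unit or "",
        substitutions=rplan.substitutions,
        deletions=rplan.deletions,
        truncated_final_length=rplan.truncated_final_length,
    )
    return seq, planted, front


def generate(spec: SyntheticGenomeSpec) -> tuple[MitogenomeRecord, GroundTruth]:
    """Render a spec to an annotated record plus realized ground truth."""
    rng = np.random.default_rng(spec.seed)
    order = spec.gene_order
    if len(order) != len(set(order.labels)):
        raise SpecError("gene order has duplicate labels")
    ncr_after = {p.upstream: p for p in spec.ncr_plans}
    for p in spec.ncr_plans:
        if p.downstream not in order.labels or p.upstream not in order.labels:
            raise SpecError(f"NCR plan references absent gene {p!r}")
        i = order.labels.index(p.upstream)
        if order.labels[(i + 1) % len(order)] != p.downstream:
            raise SpecError(
                f"NCR plan {p.upstream}->{p.downstream} does not match the gene order"
            )
    parts: list[str] = []
    features: list[GeneFeature] = []
    ncr_coords: dict[str, tuple[int, int]] = {}
    planted: list[PlantedRepeat] = []
    pcg_codons: dict[str, int] = {}
    pos = 0  # 0-based length so far
    labels = order.linearized_at("cox1") if "cox1" in order.labels else order.labels
    for g in labels:
        cat = gene_category(g)
        if cat == "PCG":
            if g not in spec.pcg_lengths:
                raise SpecError(f"no length declared for PCG {g}")
            seq = _sample_pcg(
                rng,
                spec.pcg_lengths[g],
                spec.start_codons.get(g, "ATG"),
                spec.stop_codons.get(g, "TAA"),
                spec.codon_position_freqs,
            )
            pcg_codons[g] = (len(seq) - len(seq) % 3) // 3
            feat = GeneFeature(
                name=g, start=pos + 1, end=pos + len(seq),
                start_codon=spec.start_codons.get(g, "ATG"),
                stop_codon=spec.stop_codons.get(g, "TAA"),
            )
        elif cat == "tRNA":
            lo, hi = spec.trna_length_range
            n = int(rng.integers(lo, hi + 1))
            seq = _sample_bases(rng, spec.background_freqs, n)
            feat = GeneFeature(name=g, start=pos + 1, end=pos + n,
                               anticodon=ANTICODONS[g])
        else:
            lo, hi = spec.rrn_lengths[g]
            n = int(rng.integers(lo, hi + 1))
            seq = _sample_bases(rng, spec.background_freqs, n)
            feat = GeneFeature(name=g, start=pos + 1, end=pos + n)
        parts.append(seq)
        features.append(feat)
        pos += len(seq)
        if g in ncr_after:
            plan = ncr_after[g]
            label = f"NCR{len(ncr_coords) + 1}"
            nseq, prep, _off = _render_ncr(plan, label, rng, spec.background_freqs)
            ncr_coords[label] = (pos + 1, pos + len(nseq))
            if prep is not None:
                prep.start += pos
                prep.end += pos
                prep.unit_starts = [s + pos for s in prep.unit_starts]
                planted.append(prep)
            parts.append(nseq)
            pos += len(nseq)
        else:
            lo, hi = spec.spacer_range
            n = int(rng.integers(lo, hi + 1))
            parts.append(_sample_bases(rng, spec.background_freqs, n))
            pos += n
    sequence = "".join(parts)
    record = MitogenomeRecord(
        id=spec.record_id,
        length=len(sequence),
        features=features,
        circular=spec.circular,
        sequence=sequence,
        organism="synthetic flatworm mitogenome",
    )
    truth = GroundTruth(
        spec=spec,
        ncr_coords=ncr_coords,
        repeats=planted,
        effective_codon_position_freqs=effective_position_freqs(
            spec.codon_position_freqs
        ),
        pcg_internal_codons=pcg_codons,
    )
    return record, truth


# ---------------------------------------------------------------------------
# Gene-order perturbation machinery
# ---------------------------------------------------------------------------

def perturb_gene_order(
    order: GeneOrder,
    op: str,
    seed: int,
    block_start: int | None = None,
    block_length: int | None = None,
    insert_at: int | None = None,
) -> GeneOrder:
    """Apply one block transposition or reversal to a gene order.

    The block is drawn from ``seed`` unless given explicitly.  A block of
    length 0 or of the whole order is rejected as degenerate.
    """
    n = len(order)
    rng = np.random.default_rng(seed)
    if op not in ("transposition", "reversal"):
        raise MitocmpError(f"unknown operation {op!r}")
    if block_length is None:
        block_length = int(rng.integers(1, n - 1))
    if not (0 < block_length < n):
        raise MitocmpError(f"degenerate block length {block_length}")
    if block_start is None:
        block_start = int(rng.integers(0, n))
    labels = list(order.labels)
    ori = list(order.orientations or ("+",) * n)
    idx = [(block_start + k) % n for k in range(block_length)]
    if op == "reversal":
        sub_l = [labels[i] for i in idx][::-1]
        sub_o = [("-" if ori[i] == "+" else "+") for i in idx][::-1]
        for i, l, o in zip(idx, sub_l, sub_o):
            labels[i], ori[i] = l, o
        return GeneOrder(tuple(labels), tuple(ori))
    # transposition: remove the block, reinsert at a different junction
    block_l = [labels[i] for i in idx]
    block_o = [ori[i] for i in idx]
    rest = [(labels[i], ori[i]) for i in range(n) if i not in set(idx)]
    if insert_at is None:
        insert_at = int(rng.integers(1, len(rest)))
    insert_at %= max(len(rest), 1)
    new = rest[:insert_at] + list(zip(block_l, block_o)) + rest[insert_at:]
    out = GeneOrder(tuple(l for l, _ in new), tuple(o for _, o in new))
    if out == order:
        # the sampled junction reproduced the input; shift by one
        insert_at = (insert_at % (len(rest) - 1)) + 1
        new = rest[:insert_at] + list(zip(block_l, block_o)) + rest[insert_at:]
        out = GeneOrder(tuple(l for l, _ in new), tuple(o for _, o in new))
    return out
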