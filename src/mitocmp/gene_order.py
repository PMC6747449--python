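"""Circular gene orders and pairwise common-interval similarity.

A common interval of two gene orders is a set of genes that is contiguous in
both.  The similarity score used here counts, for the two circular orders
linearized at a shared cut gene, every common interval of size 2..n-2 once
per relative orientation (an unsigned interval matches both ways, so each
counts twice), and takes the maximum over cut genes.  On identical orders of
n genes every window of size 2..n-2 is common, giving

    f(n) = 2 * (n(n-1)/2 - 3) = n(n-1) - 6,

i.e. the published identity anchor of 1254 for the 36-gene flatworm
complement.  The score is symmetric, invariant under rotation of either
order and under simultaneous relabeling of both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_model import (
    STANDARD_GENE_SET,
    AnnotationError,
    MitocmpError,
    MitogenomeRecord,
    _circular_rank,
)

IDENTITY_SCORE_36 = 36 * 35 - 6  # = 1254, self-score of any 36-gene order


@dataclass(frozen=True)
class GeneOrder:
    """A circular (optionally signed) permutation of gene labels.

    Equality and hashing are rotation-invariant: two orders compare equal
    when one is a rotation of the other with matching orientations.
    """

    labels: tuple[str, ...]
    orientations: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            dupes = {l for l in self.labels if self.labels.count(l) > 1}
            raise AnnotationError(f"duplicate gene labels in order: {sorted(dupes)}")
        if self.orientations is not None and len(self.orientations) != len(self.labels):
            raise AnnotationError("orientations length != labels length")

    def __len__(self) -> int:
        return len(self.labels)

    def _canonical(self) -> tuple:
        i = self.labels.index(min(self.labels))
        labels = self.labels[i:] + self.labels[:i]
        ori = self.orientations or ("+",) * len(self.labels)
        ori = ori[i:] + ori[:i]
        return (labels, ori)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneOrder):
            return NotImplemented
        return self._canonical() == other._canonical()

    def __hash__(self) -> int:
        return hash(self._canonical())

    def rotated(self, k: int) -> "GeneOrder":
        k %= len(self.labels)
        ori = self.orientations
        return GeneOrder(
            labels=self.labels[k:] + self.labels[:k],
            orientations=None if ori is None else ori[k:] + ori[:k],
        )

    def linearized_at(self, gene: str) -> tuple[str, ...]:
        return self.rotated(self.labels.index(gene)).labels

    @classmethod
    def from_text(cls, text: str) -> "GeneOrder":
        """Parse ``a,b,-c,...`` (``-`` prefix marks reverse strand)."""
        labels, ori = [], []
        for tok in text.replace("\n", ",").split(","):
            tok = tok.strip()
            if not tok:
                continue
            if tok.startswith("-"):
                labels.append(tok[1:])
                ori.append("-")
            else:
                labels.append(tok)
                ori.append("+")
        return cls(tuple(labels), tuple(ori))

    def to_text(self) -> str:
        ori = self.orientations or ("+",) * len(self.labels)
        return ",".join(
            (l if o == "+" else "-" + l) for l, o in zip(self.labels, ori)
        )


def extract_gene_order(record: MitogenomeRecord, require_standard: bool = True) -> GeneOrder:
    """Gene order of a record in circular genomic order starting at cox1."""
    present = [f.name for f in record.features]
    if require_standard:
        missing = STANDARD_GENE_SET - set(present)
        if missing:
            raise AnnotationError(
                f"{record.id}: missing genes {sorted(missing)}"
            )
    feats = _circular_rank(record)
    return GeneOrder(
        labels=tuple(f.name for f in feats),
        orientations=tuple(f.strand for f in feats),
    )


def _interval_count_linear(a: Sequence[str], b: Sequence[str]) -> int:
    """Number of subsets of size 2..n-2 contiguous in both linear orders.

    Uses the permutation characterization: mapping b through a's positions
    gives a permutation pi; a window [i..j] of a is a common interval iff
    max(pi[i..j]) - min(pi[i..j]) == j - i.
    """
    n = len(a)
    pos_b = {g: i for i, g in enumerate(b)}
    pi = [pos_b[g] for g in a]
    count = 0
    for i in range(n):
        mn = mx = pi[i]
        for j in range(i + 1, n):
            v = pi[j]
            if v < mn:
                mn = v
            elif v > mx:
                mx = v
            size = j - i + 1
            if size > n - 2:
                break
            if mx - mn == j - i:
                count += 1
    return count


def _signed_interval_count(a: GeneOrder, b: GeneOrder, g: str) -> int:
    """Count common intervals once per strand-respecting match direction."""
    la = a.linearized_at(g)
    lb = b.linearized_at(g)
    oa = (a.rotated(a.labels.index(g)).orientations or ("+",) * len(la))
    ob = (b.rotated(b.labels.index(g)).orientations or ("+",) * len(lb))
    n = len(la)
    pos_b = {x: i for i, x in enumerate(lb)}
    pi = [pos_b[x] for x in la]
    flip = {"+": "-", "-": "+"}
    count = 0
    for i in range(n):
        mn = mx = pi[i]
        for j in range(i + 1, n):
            v = pi[j]
            mn, mx = min(mn, v), max(mx, v)
            if j - i + 1 > n - 2:
                break
            if mx - mn != j - i:
                continue
            seg_a = [(la[k], oa[k]) for k in range(i, j + 1)]
            seg_b = [(lb[k], ob[k]) for k in range(mn, mx + 1)]
            if seg_a == seg_b:
                count += 1
            if [(x, flip[o]) for x, o in reversed(seg_a)] == seg_b:
                count += 1
    return count


def common_interval_score(a: GeneOrder, b: GeneOrder, signed: bool = False) -> int:
    """Common-interval similarity of two circular gene orders.

    Counts gene sets of size 2..n-2 contiguous in both orders after
    linearizing at a shared cut gene, once per match orientation, maximized
    over cut genes.  Unsigned (the default, appropriate for these
    single-strand mitogenomes) every common interval matches both ways and
    counts twice, so identical n-gene orders score n(n-1)-6; any
    difference scores strictly less.  With ``signed=True`` an interval
    counts only in the directions where gene strands agree (forward) or
    are jointly flipped (reverse).
    """
    if set(a.labels) != set(b.labels):
        raise MitocmpError(
            "gene orders carry different label sets: "
            f"{sorted(set(a.labels) ^ set(b.labels))}"
        )
    n = len(a)
    if n < 4:
        raise MitocmpError("common_interval_score requires at least 4 genes")
    best = 0
    for g in a.labels:
        if signed:
            best = max(best, _signed_interval_count(a, b, g))
        else:
            best = max(
                best,
                2 * _interval_count_linear(a.linearized_at(g), b.linearized_at(g)),
            )
    return best


def identity_score(n: int) -> int:
    """Self-score of an n-gene order under this counting convention."""
    return n * (n - 1) - 6


@dataclass
class SimilarityMatrix:
    """Pairwise common-interval scores with presentational shading tiers."""

    taxa: tuple[str, ...]
    scores: np.ndarray
    tiers: np.ndarray  # 0 (most similar) .. 3 (least), quartiles off-diagonal

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=list(self.taxa), columns=list(self.taxa))


def similarity_matrix(
    orders: Sequence[GeneOrder], taxa: Sequence[str] | None = None
) -> SimilarityMatrix:
    """Full pairwise common-interval matrix over a set of gene orders."""
    if len(orders) < 2:
        raise MitocmpError("similarity_matrix requires at least 2 orders")
    if taxa is None:
        taxa = tuple(f"order{i + 1}" for i in range(len(orders)))
    if len(set(taxa)) != len(taxa):
        raise MitocmpError("duplicate taxon labels")
    m = len(orders)
    scores = np.zeros((m, m), dtype=int)
    for i in range(m):
        scores[i, i] = common_interval_score(orders[i], orders[i])
        for j in range(i + 1, m):
            s = common_interval_score(orders[i], orders[j])
            scores[i, j] = scores[j, i] = s
    off = scores[~np.eye(m, dtype=bool)]
    qs = np.quantile(off, [0.25, 0.5, 0.75]) if off.size else np.zeros(3)
    tiers = np.digitize(-scores, -qs[::-1])  # higher score -> lower tier
    np.fill_diagonal(tiers, 0)
    return SimilarityMatrix(taxa=tuple(taxa), scores=scores, tiers=tiers)
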