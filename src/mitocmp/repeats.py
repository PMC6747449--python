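"""Tandem-repeat detection in non-coding regions and hairpin prediction.

The control-region candidates of flatworm mitogenomes carry highly
repetitive regions: head-to-tail copies of a unit tens to hundreds of bp
long, occasionally with point substitutions, a deletion, or a truncated
final copy.  The detector here seeds candidate periods with exact
self-matches at lag p, grows arrays unit by unit requiring at least 90%
per-unit identity, and calls a fractional final copy by prefix alignment.
Among overlapping candidate arrays the longest wins, with ties broken
toward the shortest period (so a p-periodic array is not reported at 2p).

Hairpin (stem-loop) prediction uses a deliberately simple nearest-neighbour
energy model: a stacked pair contributes -2.0 (G:C), -1.5 (A:T) or
-1.0 (G:T wobble) kcal/mol, each hairpin loop costs +3.0, helices are
perfect (no bulges), and the minimum-energy set of non-crossing helices is
found by dynamic programming.  The estimates rank structures; they are not
calibrated thermodynamic free energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genome_model import MitocmpError

# ---------------------------------------------------------------------------
# Tandem repeats
# ---------------------------------------------------------------------------

SEED_LENGTH = 8  # minimum exact self-match run used to seed a candidate period


@dataclass(frozen=True)
class Deviation:
    """One departure of a repeat unit from the consensus."""

    unit: int        # 1-based unit index within the array
    position: int    # 1-based position within the unit
    kind: str        # "substitution" | "deletion" | "insertion"
    observed: str = ""


@dataclass
class TandemRepeatCall:
    """A detected tandem array (1-based, inclusive coordinates)."""

    start: int
    end: int
    period: int
    copy_number: float
    unit_starts: list[int]
    partial_length: int
    consensus_unit: str
    deviations: list[Deviation]

    @property
    def full_copies(self) -> int:
        return len(self.unit_starts) - (1 if self.partial_length else 0)


def consensus_unit(units: Sequence[str]) -> str:
    """Per-column majority base over equal-length aligned units.

    Ties are broken toward the first unit's base.
    """
    if not units:
        raise MitocmpError("consensus_unit: no units given")
    L = len(units[0])
    if any(len(u) != L for u in units):
        raise MitocmpError("consensus_unit: units differ in length")
    out = []
    for col in range(L):
        tally: dict[str, int] = {}
        for u in units:
            b = u[col]
            tally[b] = tally.get(b, 0) + 1
        best = max(tally.values())
        first = units[0][col]
        if tally[first] == best:
            out.append(first)
        else:
            out.append(max(sorted(tally), key=lambda b: tally[b]))
    return "".join(out)


def _partial_copy(unit: str, tail: str, max_mismatch_frac: float) -> tuple[int, int]:
    """Longest unit prefix present (within an edit budget) at the tail start.

    The truncated final copy of an array is the longest prefix ``unit[:i]``
    whose edit distance to some prefix of ``tail`` stays within
    ``max(2, floor(max_mismatch_frac * i))`` edits.  Returns
    (unit_prefix_len, tail_len_consumed); (0, 0) when no prefix of at least
    SEED_LENGTH qualifies.  The tight budget keeps the call from drifting
    into flanking sequence, which in AT-rich mitogenomes matches a unit
    surprisingly often by chance.
    """
    n, m = len(unit), len(tail)
    prev = list(range(m + 1))
    best = (0, 0, 0)
    abort_at = max(2, int(max_mismatch_frac * n))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        dm, jm = n + m, 0
        for j in range(1, m + 1):
            hit = unit[i - 1] == tail[j - 1] and unit[i - 1] != "N"
            cur[j] = min(prev[j - 1] + (0 if hit else 1), prev[j] + 1, cur[j - 1] + 1)
            # the copy must end on a matched base, not on trailing edits
            if hit and cur[j] == prev[j - 1] and cur[j] < dm:
                dm, jm = cur[j], j
        if i >= SEED_LENGTH and dm <= max(2, int(max_mismatch_frac * i)):
            # prefer long prefixes but not at the price of extra edits
            if i - 3 * dm > best[0] - 3 * best[2]:
                best = (i, jm, dm)
        if min(cur) > abort_at:
            break
        prev = cur
    return best[:2]


def _unit_deviations(unit: str, ref: str, index: int) -> list[Deviation]:
    """Deviations of one realized unit against a reference, via edlib."""
    if unit == ref:
        return []
    import edlib

    res = edlib.align(unit, ref, task="path", mode="NW")
    devs: list[Deviation] = []
    qpos = rpos = 0  # 0-based cursors in unit (query) and ref (target)
    for length, op in _cigar_ops(res["cigar"]):
        if op == "=":
            qpos += length
            rpos += length
        elif op == "X":
            for k in range(length):
                devs.append(
                    Deviation(index, rpos + k + 1, "substitution", unit[qpos + k])
                )
            qpos += length
            rpos += length
        elif op == "D":  # present in ref, absent from unit
            for k in range(length):
                devs.append(Deviation(index, rpos + k + 1, "deletion"))
            rpos += length
        elif op == "I":  # extra base in unit
            for k in range(length):
                devs.append(
                    Deviation(index, min(rpos, len(ref) - 1) + 1, "insertion",
                              unit[qpos + k])
                )
            qpos += length
    return devs


def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def detect_tandem_repeats(
    seq: str,
    min_period: int = 10,
    max_mismatch_frac: float = 0.1,
    max_period: int | None = None,
) -> list[TandemRepeatCall]:
    """Find maximal tandem arrays in a sequence.

    An array needs at least two copies whose unit-against-next identity is
    at least ``1 - max_mismatch_frac``; a truncated final copy is reported
    as a fractional copy.  N positions never match.
    """
    seq = seq.upper()
    L = len(seq)
    if L < 2 * min_period:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_n = arr == ord("N")
    if max_period is None:
        max_period = L // 2
    candidates: list[TandemRepeatCall] = []
    found: list[tuple[int, int, int]] = []  # (start0, end0, period)
    for p in range(min_period, max_period + 1):
        m = (arr[:-p] == arr[p:]) & ~is_n[:-p] & ~is_n[p:]
        if not m.any():
            continue
        # periods scan ascending, so an exact multiple of an already-found
        # period is a harmonic of it; skip seeds inside that array's span
        skip = [(s, e) for s, e, q in found if p % q == 0]
        calls = _arrays_for_period(seq, m, p, max_mismatch_frac, skip)
        for c in calls:
            found.append((c.start - 1, c.end - 1, c.period))
        candidates.extend(calls)
    # resolve overlaps: most full-copy coverage first, then smallest period,
    # so a p-periodic array is preferred over its 2p harmonic (whose last
    # odd copy only survives as a fractional unit)
    candidates.sort(
        key=lambda c: (-(c.full_copies * c.period), c.period, c.start)
    )
    kept: list[TandemRepeatCall] = []
    for c in candidates:
        if all(c.end < k.start or c.start > k.end for k in kept):
            kept.append(c)
    kept.sort(key=lambda c: c.start)
    return kept


def _arrays_for_period(
    seq: str, m: np.ndarray, p: int, max_mismatch_frac: float,
    skip: Sequence[tuple[int, int]] = (),
) -> list[TandemRepeatCall]:
    """Grow unit-aligned arrays of period ``p`` from exact seed runs."""
    thr = 1.0 - max_mismatch_frac
    # seed runs of >= SEED_LENGTH consecutive matches at lag p
    idx = np.flatnonzero(m)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate(([0], breaks + 1))
    run_ends = np.concatenate((breaks, [idx.size - 1]))
    calls: list[TandemRepeatCall] = []
    claimed: list[tuple[int, int]] = []  # i-ranges already inside an array
    for rs, re_ in zip(run_starts, run_ends):
        a = int(idx[rs])
        if idx[re_] - a + 1 < SEED_LENGTH:
            continue
        if any(lo <= a <= hi for lo, hi in claimed):
            continue
        if any(lo <= a <= hi for lo, hi in skip):
            continue
        # block j covers lags [a + j*p, a + (j+1)*p); require identity >= thr
        def block_ok(j: int) -> bool:
            lo, hi = a + j * p, a + (j + 1) * p
            if lo < 0 or hi > m.size:
                return False
            return float(m[lo:hi].mean()) >= thr
        if not block_ok(0):
            continue
        jlo = 0
        while block_ok(jlo - 1):
            jlo -= 1
        jhi = 0
        while block_ok(jhi + 1):
            jhi += 1
        x = a + jlo * p                  # first unit start (0-based)
        nblocks = jhi - jlo + 1
        full = nblocks + 1               # matched blocks link full+1 units
        span_end = x + full * p          # 0-based exclusive end of full units
        units = [seq[x + k * p: x + (k + 1) * p] for k in range(full)]
        cons = consensus_unit(units) if full > 1 else units[0]
        # fractional final copy
        tail = seq[span_end: span_end + p - 1]
        plen = tlen = 0
        if tail:
            plen, tlen = _partial_copy(cons, tail, max_mismatch_frac)
        devs: list[Deviation] = []
        for k, u in enumerate(units, start=1):
            devs.extend(_unit_deviations(u, cons, k))
        unit_starts = [x + k * p + 1 for k in range(full)]
        if plen:
            devs.extend(
                _unit_deviations(seq[span_end: span_end + tlen], cons[:plen], full + 1)
            )
            unit_starts.append(span_end + 1)
        calls.append(
            TandemRepeatCall(
                start=x + 1,
                end=span_end + tlen,
                period=p,
                copy_number=full + plen / p,
                unit_starts=unit_starts,
                partial_length=plen,
                consensus_unit=cons,
                deviations=devs,
            )
        )
        claimed.append((x, span_end - p))
    return calls


# ---------------------------------------------------------------------------
# Hairpin (stem-loop) folding
# ---------------------------------------------------------------------------

STACK_ENERGY = {
    frozenset(("G", "C")): -2.0,
    frozenset(("A", "T")): -1.5,
    frozenset(("G", "T")): -1.0,
}
LOOP_PENALTY = 3.0
MIN_LOOP = 3


def _pair_energy(a: str, b: str) -> float | None:
    return STACK_ENERGY.get(frozenset((a, b)))


@dataclass
class HairpinStructure:
    """A non-crossing set of base pairs decomposed into perfect helices."""

    sequence: str
    pairs: list[tuple[int, int]]          # 0-based (i, j), i < j
    stems: list[list[tuple[int, int]]]    # one pair-list per helix
    stem_loop_count: int
    dG_estimate: float

    @property
    def dot_bracket(self) -> str:
        s = ["."] * len(self.sequence)
        for i, j in self.pairs:
            s[i], s[j] = "(", ")"
        return "".join(s)


def fold_hairpins(seq: str) -> HairpinStructure:
    """Minimum-energy arrangement of perfect stem-loops on one strand.

    Watson-Crick and G:T wobble pairs only; no pseudoknots, no bulges.
    dG_estimate is 0 exactly when no pairing is worth forming.
    """
    seq = seq.upper()
    if set(seq) - set("ACGTN"):
        raise MitocmpError(
            f"fold_hairpins: non-nucleotide characters {set(seq) - set('ACGTN')}"
        )
    n = len(seq)
    INF = float("inf")
    # V[i][j]: energy of a perfect helix whose outermost pair is (i, j)
    V = [[INF] * n for _ in range(n)]
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            e = _pair_energy(seq[i], seq[j])
            if e is None:
                continue
            best = LOOP_PENALTY  # close a hairpin loop here
            inner = V[i + 1][j - 1] if j - i >= MIN_LOOP + 3 else INF
            if inner < INF:
                best = min(best, inner + e)  # stack on the inner pair
            V[i][j] = best
    # tile [0..j] with non-overlapping helices; empty prefix costs 0
    best = [0.0] * (n + 1)  # best[k]: energy of prefix of length k
    choice: list[tuple[int, int] | None] = [None] * (n + 1)
    for k in range(1, n + 1):
        best[k] = best[k - 1]
        j = k - 1
        for i in range(0, j - MIN_LOOP):
            if V[i][j] < INF:
                cand = best[i] + V[i][j]
                if cand < best[k]:
                    best[k] = cand
                    choice[k] = (i, j)
    # traceback
    stems: list[list[tuple[int, int]]] = []
    k = n
    while k > 0:
        if choice[k] is None:
            k -= 1
            continue
        i, j = choice[k]
        helix: list[tuple[int, int]] = []
        while True:
            helix.append((i, j))
            e = _pair_energy(seq[i], seq[j])
            inner = V[i + 1][j - 1] if j - i >= MIN_LOOP + 3 else INF
            if inner < INF and abs(V[i][j] - (inner + e)) < 1e-9 and V[i][j] != LOOP_PENALTY:
                i, j = i + 1, j - 1
            else:
                break
        stems.append(helix)
        k = choice[k][0]
    stems.reverse()
    pairs = sorted(p for s in stems for p in s)
    return HairpinStructure(
        sequence=seq,
        pairs=pairs,
        stems=stems,
        stem_loop_count=len(stems),
        dG_estimate=best[n],
    )
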