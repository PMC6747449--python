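"""Independent oracles shared by the unit and acceptance tests.

These deliberately re-derive quantities by brute force (subset enumeration,
exhaustive structure search) so they stay independent of the package's
optimized code paths.
"""

from itertools import combinations


def brute_force_common_interval_score(a, b):
    """Count common intervals by enumerating every gene subset.

    Mirrors the scoring convention from first principles: for each shared
    cut gene, linearize both circular orders at it, count subsets of size
    2..n-2 occupying consecutive positions in both, twice each (one per
    relative orientation of the unsigned match), and take the maximum over
    cut genes.  Exponential in n; usable for n <= ~12.
    """
    la, lb = tuple(a.labels), tuple(b.labels)
    n = len(la)
    assert set(la) == set(lb)
    best = 0
    for g in la:
        xa = _linearize(la, g)
        xb = _linearize(lb, g)
        count = 0
        for size in range(2, n - 1):
            for subset in combinations(range(n), size):
                genes = {xa[i] for i in subset}
                if _contiguous(xa, genes) and _contiguous(xb, genes):
                    count += 1
        best = max(best, 2 * count)
    return best


def _linearize(labels, gene):
    i = labels.index(gene)
    return labels[i:] + labels[:i]


def _contiguous(order, genes):
    pos = sorted(i for i, g in enumerate(order) if g in genes)
    return pos[-1] - pos[0] + 1 == len(pos)


PAIR_ENERGY = {
    frozenset(("G", "C")): -2.0,
    frozenset(("A", "T")): -1.5,
    frozenset(("G", "T")): -1.0,
}


def brute_force_min_energy(seq, min_loop=3, loop_penalty=3.0):
    """Exhaustive search over sets of non-overlapping perfect helices.

    A helix is a run of pairs (i, j), (i+1, j-1), ... closing a loop of at
    least ``min_loop`` unpaired bases; the innermost pair costs the loop
    penalty and every stacked pair contributes its pair energy.  Returns
    the minimum total energy (0 for the empty structure).  Exponential;
    usable for sequences up to ~30 nt.
    """
    n = len(seq)
    helices = []  # (span set, energy)
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            # grow a perfect helix outermost pair (i, j) inward
            pairs = []
            x, y = i, j
            while y - x > min_loop and frozenset((seq[x], seq[y])) in PAIR_ENERGY:
                pairs.append((x, y))
                x += 1
                y -= 1
            for depth in range(1, len(pairs) + 1):
                used = pairs[:depth]
                energy = loop_penalty + sum(
                    PAIR_ENERGY[frozenset((seq[x], seq[y]))]
                    for x, y in used[:-1]  # innermost pair: loop only
                )
                span = frozenset(range(used[0][0], used[0][1] + 1))
                helices.append((span, energy))

    best = 0.0

    def rec(idx, occupied, energy):
        nonlocal best
        best = min(best, energy)
        for k in range(idx, len(helices)):
            span, e = helices[k]
            if not (span & occupied):
                rec(k + 1, occupied | span, energy + e)

    rec(0, frozenset(), 0.0)
    return best
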