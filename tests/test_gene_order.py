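import random

import numpy as np
import pytest

import mitocmp as m
from helpers import brute_force_common_interval_score
from mitocmp.gene_order import GeneOrder, identity_score
from mitocmp.genome_model import AnnotationError, MitocmpError
from mitocmp.synthetic_data import THAPAROCLEIDUS_GENE_ORDER, perturb_gene_order


def toy_order(n, seed=None):
    labels = [f"g{i}" for i in range(n)]
    if seed is not None:
        random.Random(seed).shuffle(labels)
    return GeneOrder(tuple(labels))


def test_extract_gene_order_starts_at_cox1(varicus_record):
    order = m.extract_gene_order(varicus_record)
    assert order.labels[:10] == (
        "cox1", "trnC", "cox2", "nad6", "trnL1", "trnS2", "trnL2", "trnR",
        "nad5", "trnK",
    )
    assert len(order) == 36


def test_gene_orders_of_both_taxa_identical(varicus_record, asoti_record):
    assert m.extract_gene_order(varicus_record) == m.extract_gene_order(asoti_record)
    assert m.extract_gene_order(varicus_record) == THAPAROCLEIDUS_GENE_ORDER


def test_rotation_invariant_equality():
    o = toy_order(8, seed=1)
    assert o == o.rotated(3)
    assert hash(o) == hash(o.rotated(5))
    assert o != toy_order(8, seed=2)


def test_missing_gene_named_in_error(varicus_record):
    from mitocmp.genome_model import MitogenomeRecord

    rec = MitogenomeRecord(
        id="partial", length=varicus_record.length,
        features=[f for f in varicus_record.features if f.name != "nad3"],
    )
    with pytest.raises(AnnotationError, match="nad3"):
        m.extract_gene_order(rec)


def test_identity_anchor_on_36_genes(varicus_record):
    order = m.extract_gene_order(varicus_record)
    assert m.common_interval_score(order, order) == 1254
    assert identity_score(36) == 1254


@pytest.mark.parametrize("n", range(4, 11))
def test_self_score_closed_form_and_oracle(n):
    o = toy_order(n, seed=n)
    assert m.common_interval_score(o, o) == identity_score(n)
    assert brute_force_common_interval_score(o, o) == identity_score(n)


@pytest.mark.parametrize("n", range(4, 11))
def test_score_matches_brute_force_enumeration(n):
    """The optimized interval count equals exhaustive subset enumeration."""
    rng = random.Random(100 + n)
    for trial in range(4):
        a = toy_order(n)
        labels = list(a.labels)
        rng.shuffle(labels)
        b = GeneOrder(tuple(labels))
        assert m.common_interval_score(a, b) == brute_force_common_interval_score(a, b)


def test_score_symmetric_and_rotation_invariant():
    a = toy_order(12, seed=3)
    b = toy_order(12, seed=4)
    s = m.common_interval_score(a, b)
    assert s == m.common_interval_score(b, a)
    assert s == m.common_interval_score(a.rotated(7), b.rotated(2))


def test_relabeling_invariance():
    a = toy_order(9, seed=5)
    b = toy_order(9, seed=6)
    mapping = {g: f"x{i}" for i, g in enumerate(sorted(a.labels))}
    ra = GeneOrder(tuple(mapping[g] for g in a.labels))
    rb = GeneOrder(tuple(mapping[g] for g in b.labels))
    assert m.common_interval_score(a, b) == m.common_interval_score(ra, rb)


def test_self_score_is_strict_maximum():
    a = THAPAROCLEIDUS_GENE_ORDER
    for seed in range(8):
        b = perturb_gene_order(a, "transposition", seed=seed)
        if b == a:
            continue
        assert m.common_interval_score(a, b) < 1254
    assert m.common_interval_score(a, a.rotated(11)) == 1254


def test_transposition_strictly_decreases_score_small_n_oracle():
    for n in (6, 8):
        a = toy_order(n, seed=n)
        for seed in range(3):
            b = perturb_gene_order(a, "transposition", seed=seed)
            if b == a:
                continue
            s = m.common_interval_score(a, b)
            assert s == brute_force_common_interval_score(a, b)
            assert s < identity_score(n)


def test_label_set_mismatch_rejected():
    with pytest.raises(MitocmpError):
        m.common_interval_score(toy_order(5), GeneOrder(("a", "b", "c", "d", "e")))


def test_similarity_matrix_identical_pair(varicus_record):
    order = m.extract_gene_order(varicus_record)
    mat = m.similarity_matrix([order, order], taxa=["a", "b"])
    assert (mat.scores == 1254).all()


def test_similarity_matrix_structure_and_permutation():
    a = toy_order(10, seed=1)
    b = perturb_gene_order(a, "transposition", seed=0)
    c = toy_order(10, seed=9)
    mat = m.similarity_matrix([a, b, c], taxa=["a", "b", "c"])
    assert (mat.scores == mat.scores.T).all()
    assert np.diag(mat.scores).tolist() == [identity_score(10)] * 3
    # two near-identical orders share the maximal off-diagonal entry
    off = mat.scores.copy()
    np.fill_diagonal(off, -1)
    assert off.max() == mat.scores[0, 1]
    # permuting input order permutes rows/columns
    mat2 = m.similarity_matrix([c, a, b], taxa=["c", "a", "b"])
    perm = [2, 0, 1]
    assert (mat2.scores == mat.scores[np.ix_(perm, perm)]).all()


def test_similarity_matrix_rejects_duplicate_taxa():
    a = toy_order(6)
    with pytest.raises(MitocmpError):
        m.similarity_matrix([a, a], taxa=["t", "t"])


def test_signed_mode_counts_strand_respecting_directions():
    """Co-oriented identical orders match forward only in signed mode
    (half the unsigned score); a jointly reversed+flipped block still
    matches in the reverse direction."""
    o = toy_order(8, seed=2)
    assert m.common_interval_score(o, o, signed=True) == identity_score(8) // 2
    rev = GeneOrder(tuple(reversed(o.labels)), ("-",) * 8)
    # every window avoiding the cut gene matches in the reverse direction:
    # sum of sizes 2..n-2 over a length n-1 segment
    assert m.common_interval_score(o, rev, signed=True) == sum(range(2, 7))
    assert m.common_interval_score(o, rev) == 2 * sum(range(2, 7))  # unsigned


def test_order_text_roundtrip():
    o = GeneOrder(("cox1", "trnA", "nad3"), ("+", "-", "+"))
    assert GeneOrder.from_text(o.to_text()) == o
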