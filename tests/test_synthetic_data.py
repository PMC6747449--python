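import numpy as np
import pytest

import mitocmp as m
from mitocmp import composition as comp
from mitocmp import synthetic_data as syn


def test_generation_is_deterministic():
    spec = syn.preset_spec("thaparocleidus", 3)
    rec1, _ = syn.generate(spec)
    rec2, _ = syn.generate(spec)
    assert rec1.sequence == rec2.sequence
    assert rec1.features == rec2.features
    rec3, _ = syn.generate(syn.preset_spec("thaparocleidus", 4))
    assert rec3.sequence != rec1.sequence


def test_preset_order_and_identity_anchor(synthetic_pair):
    (rec, _), _ = synthetic_pair
    order = m.extract_gene_order(rec)
    assert order == syn.THAPAROCLEIDUS_GENE_ORDER
    assert m.common_interval_score(order, order) == 1254


def test_record_has_standard_complement_and_codons(synthetic_pair):
    (rec, truth), _ = synthetic_pair
    assert {f.name for f in rec.features} == m.STANDARD_GENE_SET
    for f in rec.features:
        if f.category != "PCG":
            continue
        seq = rec.gene_sequence(f.name)
        ss = comp.start_stop_codons(seq)
        assert ss.start_codon == truth.spec.start_codons[f.name]
        assert ss.stop_codon == truth.spec.stop_codons[f.name]
        # no internal stops under the flatworm code
        body = seq[: len(seq) - len(seq) % 3]
        internal = [body[i: i + 3] for i in range(3, len(body) - 3, 3)]
        assert not set(internal) & set(comp.STOP_CODONS_9)


def test_planted_ncrs_and_repeats_are_recovered(synthetic_pair):
    (rec, truth), _ = synthetic_pair
    ncrs = m.extract_ncrs(rec)
    assert {n.label: (n.start, n.end) for n in ncrs} == truth.ncr_coords
    by_label = {n.label: n for n in ncrs}
    for planted in truth.repeats:
        calls = m.detect_tandem_repeats(by_label[planted.ncr_label].sequence)
        assert any(
            c.period == planted.period
            and abs(c.copy_number - planted.copy_number) <= 0.5
            for c in calls
        ), planted.ncr_label


def test_codon_position_frequencies_recovered_within_3se(synthetic_pair):
    """Internal-codon composition matches the generator's declared
    effective frequencies to within multinomial sampling noise."""
    (rec, truth), _ = synthetic_pair
    internal = []
    for f in rec.features:
        if f.category == "PCG":
            s = rec.gene_sequence(f.name)
            internal.append(s[3: len(s) - 3 - len(s) % 3])
    profs = comp.codon_position_profiles(internal)
    n = sum(len(s) for s in internal) // 3
    for k, prof in enumerate(profs):
        eff = truth.effective_codon_position_freqs[k]
        got = {"T": prof.pct_t, "C": prof.pct_c, "A": prof.pct_a, "G": prof.pct_g}
        for b in "TCAG":
            se = (eff[b] * (1 - eff[b]) / n) ** 0.5
            assert abs(got[b] / 100 - eff[b]) <= 3 * se, (k, b)


def test_position2_at_skew_strongly_negative(synthetic_pair):
    (rec, _), _ = synthetic_pair
    pcgs = [rec.gene_sequence(f.name) for f in rec.features if f.category == "PCG"]
    p1, p2, p3 = comp.codon_position_profiles(pcgs)
    assert p2.at_skew < -0.3
    assert p2.at_skew < p1.at_skew and p2.at_skew < p3.at_skew


def test_asoti_preset_features():
    rec, truth = syn.generate(syn.preset_spec("thaparocleidus-asoti", 1))
    cox2 = rec.gene_sequence("cox2")
    assert comp.start_stop_codons(cox2).stop_codon == "T--"
    sizes = {n.label: n.size for n in m.extract_ncrs(rec)}
    assert sizes == {"NCR1": 2020, "NCR2": 792}


def test_ancestral_preset_scores_below_identity():
    rec, _ = syn.generate(syn.preset_spec("ancestral-neodermatan", 1))
    order = m.extract_gene_order(rec)
    assert order != syn.THAPAROCLEIDUS_GENE_ORDER
    s = m.common_interval_score(order, syn.THAPAROCLEIDUS_GENE_ORDER)
    assert s < 1254


def test_infeasible_repeat_plan_rejected():
    spec = syn.preset_spec("thaparocleidus", 1)
    big = syn.NCRPlan("nad5", "trnK", 100, syn.RepeatPlan(period=60, copies=5))
    bad = syn.SyntheticGenomeSpec(
        **{**spec.__dict__, "ncr_plans": (big, spec.ncr_plans[1])}
    )
    with pytest.raises(syn.SpecError):
        syn.generate(bad)


def test_ncr_plan_must_match_gene_order():
    spec = syn.preset_spec("thaparocleidus", 1)
    misplaced = syn.NCRPlan("cox1", "nad3", 300, None)
    bad = syn.SyntheticGenomeSpec(**{**spec.__dict__, "ncr_plans": (misplaced,)})
    with pytest.raises(syn.SpecError):
        syn.generate(bad)


def test_perturb_rejects_degenerate_blocks():
    o = syn.THAPAROCLEIDUS_GENE_ORDER
    with pytest.raises(m.MitocmpError):
        syn.perturb_gene_order(o, "transposition", seed=0, block_length=0)
    with pytest.raises(m.MitocmpError):
        syn.perturb_gene_order(o, "reversal", seed=0, block_length=36)


def test_perturbation_changes_order_and_reversal_is_involution():
    o = syn.THAPAROCLEIDUS_GENE_ORDER
    for seed in range(5):
        t = syn.perturb_gene_order(o, "transposition", seed=seed)
        assert t != o
        assert set(t.labels) == set(o.labels)
        r = syn.perturb_gene_order(o, "reversal", seed=seed)
        rr = syn.perturb_gene_order(r, "reversal", seed=seed)
        assert rr == o


def test_transposition_lowers_common_interval_score():
    o = syn.THAPAROCLEIDUS_GENE_ORDER
    for seed in range(5):
        t = syn.perturb_gene_order(o, "transposition", seed=seed)
        assert m.common_interval_score(o, t) < 1254


def test_generated_record_roundtrips(tmp_path, synthetic_pair):
    from mitocmp.genome_model import read_annotation_tsv, write_annotation_tsv

    (rec, _), _ = synthetic_pair
    write_annotation_tsv(rec, tmp_path / "r.tsv")
    (tmp_path / "r.fasta").write_text(f">{rec.id}\n{rec.sequence}\n")
    back = read_annotation_tsv(tmp_path / "r.tsv", fasta=tmp_path / "r.fasta")
    assert back.sequence == rec.sequence
    assert m.build_organization_table(back) == m.build_organization_table(rec)


def test_n_gap_plan_inserts_n_run():
    spec = syn.preset_spec("thaparocleidus-asoti", 2)
    plans = list(spec.ncr_plans)
    plans[0] = syn.NCRPlan(plans[0].upstream, plans[0].downstream,
                           plans[0].size, plans[0].repeat, n_gap_length=300)
    spec2 = syn.SyntheticGenomeSpec(**{**spec.__dict__, "ncr_plans": tuple(plans)})
    rec, truth = syn.generate(spec2)
    s, e = truth.ncr_coords["NCR1"]
    ncr_seq = rec.sequence[s - 1: e]
    assert ncr_seq.count("N") == 300
    # composition statistics skip the unsequenced positions
    prof = comp.composition_profile(ncr_seq)
    assert prof.pct_a + prof.pct_c + prof.pct_g + prof.pct_t == pytest.approx(100)
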