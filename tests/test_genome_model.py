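import pytest

import mitocmp as m
from mitocmp import datasets
from mitocmp.genome_model import (
    AnnotationError,
    CoordinateError,
    GeneFeature,
    MitogenomeRecord,
    ParseError,
    read_annotation_tsv,
    write_annotation_tsv,
)


def brute_circular_length(start, end, L):
    pos = start
    n = 1
    while pos != end:
        pos = pos % L + 1
        n += 1
    return n


@pytest.mark.parametrize(
    "start,end,L,expected",
    [
        (2966, 4537, 16074, 1572),  # a long PCG
        (5, 5, 100, 1),             # single base
        (95, 4, 100, 10),           # wraps the origin
        (1, 100, 100, 100),
    ],
)
def test_gene_length(start, end, L, expected):
    assert m.gene_length(start, end, L) == expected
    assert m.gene_length(start, end, L) == brute_circular_length(start, end, L)


def test_gene_length_rejects_out_of_range():
    with pytest.raises(CoordinateError):
        m.gene_length(0, 5, 100)
    with pytest.raises(CoordinateError):
        m.gene_length(5, 101, 100)


@pytest.mark.parametrize(
    "prev_end,next_start,L,expected",
    [
        (11520, 11608, 16074, 87),    # the nad4L-nad4 gap
        (10150, 10131, 16074, -20),   # overlap
        (10, 11, 100, 0),             # abutting
        (16058, 1, 16074, 16),        # circular closure across the origin
    ],
)
def test_intergenic_nucleotides(prev_end, next_start, L, expected):
    assert m.intergenic_nucleotides(prev_end, next_start, L) == expected


@pytest.mark.parametrize("species", ["asoti", "varicus"])
def test_organization_table_matches_published_columns(species, request):
    """Size and intergenic columns recomputed from From/To reproduce the
    published table exactly; the blank first-row cell is the circular
    closure gap."""
    rec = request.getfixturevalue(f"{species}_record")
    printed = datasets.printed_table(species)
    rows = m.build_organization_table(rec)
    assert len(rows) == 36
    by_gene = {r.gene: r for r in rows}
    for _, p in printed.iterrows():
        r = by_gene[p["gene"]]
        assert r.size == p["size"], p["gene"]
        if p["gene"] == "cox1":
            continue  # printed blank: the closure gap is checked below
        expected = 0 if p.isna()["intergenic"] else int(p["intergenic"])
        assert r.intergenic_nucleotides == expected, p["gene"]
    closure = {"asoti": 16, "varicus": 15}[species]
    assert by_gene["cox1"].intergenic_nucleotides == closure


@pytest.mark.parametrize("species", ["asoti", "varicus"])
def test_circular_length_conservation(species, request):
    rec = request.getfixturevalue(f"{species}_record")
    rows = m.build_organization_table(rec)
    total = sum(r.size for r in rows) + sum(r.intergenic_nucleotides for r in rows)
    assert total == rec.length


def test_single_gene_record():
    rec = MitogenomeRecord(
        id="x", length=1000, features=[GeneFeature("cox1", 101, 700)]
    )
    rows = m.build_organization_table(rec)
    assert len(rows) == 1
    assert rows[0].size == 600
    assert rows[0].intergenic_nucleotides == 1000 - 600


def test_duplicate_feature_rejected():
    with pytest.raises(AnnotationError, match="duplicate"):
        MitogenomeRecord(
            id="x", length=100,
            features=[GeneFeature("cox1", 1, 10), GeneFeature("cox1", 20, 30)],
        )


def test_extract_ncrs_published_regions(asoti_record, varicus_record):
    v = m.extract_ncrs(varicus_record)
    assert [(n.label, n.size, n.upstream_gene, n.downstream_gene) for n in v] == [
        ("NCR1", 478, "nad5", "trnK"),
        ("NCR2", 416, "trnG", "cox3"),
    ]
    a = m.extract_ncrs(asoti_record)
    assert [(n.label, n.size) for n in a] == [("NCR1", 2020), ("NCR2", 792)]
    assert (a[0].upstream_gene, a[0].downstream_gene) == ("nad5", "trnK")
    assert (a[1].upstream_gene, a[1].downstream_gene) == ("trnG", "cox3")


def test_extract_ncrs_dense_record_and_threshold_monotonicity(varicus_record):
    dense = MitogenomeRecord(
        id="d", length=20,
        features=[GeneFeature("cox1", 1, 10), GeneFeature("cox2", 11, 20)],
    )
    assert m.extract_ncrs(dense) == []
    at200 = {(n.start, n.end) for n in m.extract_ncrs(varicus_record, 200)}
    for t in (150, 100, 37, 10):
        lower = {(n.start, n.end) for n in m.extract_ncrs(varicus_record, t)}
        assert at200 <= lower


def test_ncrs_never_overlap_features(asoti_record):
    feats = [(f.start, f.end) for f in asoti_record.features]
    for n in m.extract_ncrs(asoti_record, 10):
        for s, e in feats:
            assert n.end < s or n.start > e


def test_extract_ncrs_requires_annotation():
    rec = MitogenomeRecord(id="e", length=500, features=[])
    with pytest.raises(AnnotationError):
        m.extract_ncrs(rec)


def test_tsv_roundtrip(tmp_path, synthetic_pair):
    (rec, _), _ = synthetic_pair
    path = tmp_path / "rec.tsv"
    write_annotation_tsv(rec, path)
    back = read_annotation_tsv(path)
    assert m.build_organization_table(back) == m.build_organization_table(rec)
    assert {f.name: (f.start, f.end) for f in back.features} == {
        f.name: (f.start, f.end) for f in rec.features
    }


def test_genbank_roundtrip(tmp_path, synthetic_pair):
    (rec, _), _ = synthetic_pair
    path = tmp_path / "rec.gb"
    m.write_genbank(rec, path)
    back = m.read_record(path)
    assert back.sequence == rec.sequence
    assert [
        (f.name, f.start, f.end, f.anticodon, f.start_codon, f.stop_codon)
        for f in back.features
    ] == [
        (f.name, f.start, f.end, f.anticodon, f.start_codon, f.stop_codon)
        for f in rec.features
    ]


def test_parse_errors_name_the_line(tmp_path):
    bad = tmp_path / "bad.tsv"
    bad.write_text("# length: 100\ngene\tstart\tend\nnotagene\t1\t50\n")
    with pytest.raises(ParseError, match="bad.tsv:3"):
        read_annotation_tsv(bad)
    empty = tmp_path / "empty.tsv"
    empty.write_text("# length: 100\ngene\tstart\tend\n")
    with pytest.raises(AnnotationError, match="no features"):
        read_annotation_tsv(empty)


def test_wrapping_feature_length_and_sequence():
    seq = "ACGT" * 25
    rec = MitogenomeRecord(
        id="w", length=100, sequence=seq,
        features=[GeneFeature("cox1", 95, 4, wraps=True)],
    )
    assert rec.features[0].length(100) == 10
    assert rec.gene_sequence("cox1") == seq[94:] + seq[:4]


def test_mixed_strand_warns_not_errors():
    with pytest.warns(UserWarning, match="both strands"):
        MitogenomeRecord(
            id="x", length=100,
            features=[GeneFeature("cox1", 1, 10), GeneFeature("cox2", 20, 30, strand="-")],
        )
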