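"""Core data model: I/O round trips, extraction, circular rotation."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastkit.genome_model import (
    FeatureAnnotation,
    GenomeRecord,
    ParseError,
    Part,
    extract_feature_sequence,
    read_fasta,
    read_genbank,
    reverse_complement,
    rotate_circular,
    write_genbank,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


@settings(derandomize=True)
@given(dna)
def test_reverse_complement_involution(s):
    assert reverse_complement(reverse_complement(s)) == s


def test_read_genbank_minimal(minimal_gb_path):
    rec = read_genbank(minimal_gb_path)
    assert rec.length == 120
    assert rec.circular
    cds = rec.features_of_kind("CDS")
    assert len(cds) == 1
    assert cds[0].parts == [Part(10, 100, "+")]
    assert cds[0].name == "demo"


def test_read_genbank_missing_file(tmp_path):
    with pytest.raises(ParseError):
        read_genbank(tmp_path / "nope.gb")


def test_read_genbank_complement_join(tmp_path, minimal_gb_path):
    text = minimal_gb_path.read_text().replace(
        "CDS             11..100",
        "CDS             complement(join(11..40,61..100))")
    p = tmp_path / "join.gb"
    p.write_text(text)
    rec = read_genbank(p)
    cds = rec.features_of_kind("CDS")[0]
    # biological order on the minus strand: high-coordinate exon first
    assert cds.parts == [Part(60, 100, "-"), Part(10, 40, "-")]
    expected = reverse_complement(rec.seq[10:40] + rec.seq[60:100])
    assert extract_feature_sequence(rec, cds) == expected


def test_genbank_round_trip(record, tmp_path):
    path = tmp_path / "out.gb"
    write_genbank(record, path)
    back = read_genbank(path)
    assert back.seq == record.seq
    assert len(back.features) == len(record.features)
    for a, b in zip(record.sorted_features(), back.sorted_features()):
        assert (a.kind, a.name, a.parts, a.split_links) == \
            (b.kind, b.name, b.parts, b.split_links)


@pytest.mark.parametrize("text,expected", [
    (">x\nacgt\n", [("x", "ACGT")]),
    (">w\nACGT\nACGT\nAC\n", [("w", "ACGTACGTAC")]),
    (">u\nacgu\n", [("u", "ACGT")]),  # U normalized to T
])
def test_read_fasta_valid(tmp_path, text, expected):
    p = tmp_path / "in.fasta"
    p.write_text(text)
    assert read_fasta(p) == expected


@pytest.mark.parametrize("text", [
    "",  # empty file
    ">a\nACGT\n>a\nACGT\n",  # duplicate ids
    ">z\nAC-GT\n",  # non-IUPAC character
])
def test_read_fasta_invalid(tmp_path, text):
    p = tmp_path / "bad.fasta"
    p.write_text(text)
    with pytest.raises(ParseError):
        read_fasta(p)


def test_extract_plus_and_minus_parts():
    rec = GenomeRecord(id="r", seq="AACGTTAA", features=[])
    plus = FeatureAnnotation("gene", "g", [Part(2, 6, "+")])
    minus = FeatureAnnotation("gene", "g", [Part(2, 6, "-")])
    assert extract_feature_sequence(rec, plus) == "CGTT"
    assert extract_feature_sequence(rec, minus) == "AACG"


def test_extract_rejects_out_of_range():
    rec = GenomeRecord(id="r", seq="ACGT", features=[])
    bad = FeatureAnnotation("gene", "g", [Part(2, 9, "+")])
    with pytest.raises(ValueError):
        extract_feature_sequence(rec, bad)


def test_rotate_identity_and_inverse(record):
    assert rotate_circular(record, 0) is record
    k = 12345 % record.length
    back = rotate_circular(rotate_circular(record, k), record.length - k)
    assert back.seq == record.seq
    for a, b in zip(record.features, back.features):
        assert a.parts == b.parts and a.split_links == b.split_links


def test_rotate_out_of_range(record):
    with pytest.raises(ValueError):
        rotate_circular(record, record.length)
    with pytest.raises(ValueError):
        rotate_circular(record, -1)


def test_extraction_invariant_under_rotation(record):
    """Every feature's spliced sequence survives >=100 random rotations,
    including rotations that split features across the origin."""
    baseline = [extract_feature_sequence(record, f) for f in record.features]
    rng = random.Random(1)
    for _ in range(100):
        rot = rotate_circular(record, rng.randrange(record.length))
        for want, f in zip(baseline, rot.features):
            assert extract_feature_sequence(rot, f) == want


def test_origin_spanning_feature_round_trips(record, tmp_path):
    """A rotation that splits a gene across the origin still writes valid
    GenBank and reads back identically."""
    gene = record.genes()[0]
    mid = gene.leftmost + 5
    rot = rotate_circular(record, mid)
    split = [f for f in rot.features if f.split_links]
    assert split, "rotation should have split at least one feature"
    path = tmp_path / "rot.gb"
    write_genbank(rot, path)
    back = read_genbank(path)
    for a, b in zip(rot.sorted_features(), back.sorted_features()):
        assert (a.kind, a.name, a.parts, a.split_links) == \
            (b.kind, b.name, b.parts, b.split_links)
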