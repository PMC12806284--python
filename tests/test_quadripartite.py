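"""Quadripartite structure detection and sequence normalization."""

import random

import pytest

from oracles import brute_lsrs
from plastkit.genome_model import (
    PlastkitError,
    reverse_complement,
    reverse_complement_record,
    rotate_circular,
)
from plastkit.quadripartite import (
    StructureNotFound,
    adjust_sequence,
    classify_regions,
    find_inverted_repeats,
)
from plastkit.synthetic import PlastomeSpec, generate_synthetic_plastome


def test_detects_planted_boundaries(record, ledger):
    structure = find_inverted_repeats(record.seq)
    found = {r.name: (r.start, r.length) for r in structure.regions()}
    assert found == ledger.regions
    assert structure.ir_length == ledger.regions["IRb"][1]


def test_ir_identity_bit_exact(record):
    s = find_inverted_repeats(record.seq)
    assert s.ira.sequence(record.seq) == \
        reverse_complement(s.irb.sequence(record.seq))


def test_detection_invariant_under_rotation(record):
    base = find_inverted_repeats(record.seq).region_lengths()
    rng = random.Random(2)
    offsets = [rng.randrange(record.length) for _ in range(20)]
    for off in offsets:
        rot = rotate_circular(record, off)
        s = find_inverted_repeats(rot.seq)
        assert s.region_lengths() == base
        assert s.ira.sequence(rot.seq) == \
            reverse_complement(s.irb.sequence(rot.seq))


def test_no_ir_returns_none():
    rng = random.Random(3)
    seq = "".join(rng.choices("ACGT", k=50000))
    assert find_inverted_repeats(seq, seed_length=1000) is None


def test_too_short_sequence_raises():
    with pytest.raises(PlastkitError):
        find_inverted_repeats("ACGT" * 100, seed_length=1000)


def test_oracle_equivalence_small_scale():
    """On a ~4.4 kb genome with seed 20, the reported IR equals the
    maximal palindromic pair of an exhaustive match-matrix oracle."""
    rng = random.Random(4)
    lsc = "".join(rng.choices("ACGT", k=2800))
    ir = "".join(rng.choices("ACGT", k=320))
    ssc = "".join(rng.choices("ACGT", k=900))
    seq = lsc + ir + ssc + reverse_complement(ir)
    structure = find_inverted_repeats(seq, seed_length=20)
    assert structure is not None
    want = brute_lsrs(seq, 20, types=("palindromic",))
    top = max(want, key=lambda h: h[1])
    assert (structure.ir_length, structure.irb.start, structure.ira.start) \
        == (top[1], top[2], top[3])
    assert structure.region_lengths() == {
        "LSC": 2800, "IRb": 320, "SSC": 900, "IRa": 320}


def test_classify_canonical_orientation(record):
    s = find_inverted_repeats(record.seq)
    report = classify_regions(s, record)
    assert report.starts_at_lsc
    assert report.ssc_forward
    assert set(report.region_gc) == {"LSC", "IRb", "SSC", "IRa"}


def test_classify_rotated_into_ir(record):
    s0 = find_inverted_repeats(record.seq)
    rot = rotate_circular(record, s0.irb.start + 10)
    s = find_inverted_repeats(rot.seq)
    assert not classify_regions(s, rot).starts_at_lsc


def test_adjust_lsc_identity_on_canonical(record):
    assert adjust_sequence(record, "LSC").seq == record.seq


def test_adjust_lsc_restores_rotation(record):
    rot = rotate_circular(record, 23456 % record.length)
    assert adjust_sequence(rot, "LSC").seq == record.seq


def test_adjust_rp_involution(record):
    """RP applied to a reverse-complemented genome recovers the LSC-mode
    sequence; applying RP twice equals one LSC adjustment."""
    rc = reverse_complement_record(record)
    assert adjust_sequence(rc, "RP").seq == record.seq
    twice = adjust_sequence(adjust_sequence(record, "RP"), "RP")
    assert twice.seq == adjust_sequence(record, "LSC").seq


def test_adjust_ssc_restores_flipped_fixture(record):
    from plastkit.quadripartite import _flip_ssc, _ssc_forward

    s = find_inverted_repeats(record.seq)
    flipped = _flip_ssc(record, s)
    s2 = find_inverted_repeats(flipped.seq)
    assert not _ssc_forward(flipped, s2)
    assert adjust_sequence(flipped, "SSC").seq == record.seq


def test_adjust_is_idempotent_across_orientations(record):
    rng = random.Random(5)
    for _ in range(10):
        rot = rotate_circular(record, rng.randrange(record.length))
        if rng.random() < 0.5:
            rot = reverse_complement_record(rot)
        adj = adjust_sequence(rot, "LSC")
        if adj.seq != record.seq:
            # a reverse-complemented genome needs RP mode
            adj = adjust_sequence(rot, "RP")
        assert adj.seq == record.seq
        again = adjust_sequence(adj, "LSC")
        assert again.seq == adj.seq
        s = find_inverted_repeats(adj.seq)
        assert s.region_lengths() == \
            find_inverted_repeats(record.seq).region_lengths()


def test_adjust_without_structure_raises():
    rng = random.Random(6)
    from plastkit.genome_model import GenomeRecord

    rec = GenomeRecord(id="r", seq="".join(rng.choices("ACGT", k=8000)))
    with pytest.raises(StructureNotFound):
        adjust_sequence(rec, "LSC", seed_length=500)


def test_seed_guarantee_at_exact_seed_length():
    """A planted exact IR with arms equal to the 1000 bp seed is always
    found, across seeds and rotations."""
    for seed in (0, 1):
        rec, ledger = generate_synthetic_plastome(
            PlastomeSpec(seed=seed, irb_len=1000))
        s = find_inverted_repeats(rec.seq, seed_length=1000)
        assert s is not None and s.ir_length == 1000
        rot = rotate_circular(rec, 4321)
        s2 = find_inverted_repeats(rot.seq, seed_length=1000)
        assert s2 is not None and s2.ir_length == 1000
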