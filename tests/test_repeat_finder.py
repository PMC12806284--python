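"""SSR and long-repeat detection: thresholds, canonicalization, oracles."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_lsrs, brute_ssrs
from plastkit.genome_model import complement, reverse_complement
from plastkit.repeat_finder import (
    DEFAULT_SSR_THRESHOLDS,
    MotifPeriodError,
    canonical_motif,
    find_lsrs,
    find_ssrs,
    locate_context,
)


@pytest.mark.parametrize("motif,expected", [
    ("TTA", "AAT"),
    ("A", "A"),
    ("G", "C"),  # reverse complement equivalence for mononucleotides
    ("AG", "AG"),
    ("CT", "AG"),
    ("GAA", "AAG"),
])
def test_canonical_motif(motif, expected):
    assert canonical_motif(motif) == expected


@pytest.mark.parametrize("motif", ["ATAT", "AA", "ACGACG"])
def test_canonical_motif_rejects_periodic(motif):
    with pytest.raises(MotifPeriodError):
        canonical_motif(motif)


@settings(derandomize=True)
@given(st.text(alphabet="ACGT", min_size=1, max_size=6))
def test_canonical_motif_class_invariance(motif):
    """All rotations and the reverse complement share one canonical form."""
    try:
        canon = canonical_motif(motif)
    except MotifPeriodError:
        return
    for i in range(len(motif)):
        assert canonical_motif(motif[i:] + motif[:i]) == canon
    assert canonical_motif(reverse_complement(motif)) == canon


@pytest.mark.parametrize("unit,threshold", sorted(
    DEFAULT_SSR_THRESHOLDS.items()))
def test_threshold_ladder(unit, threshold):
    """The minimum unit count that yields a hit is exactly the ladder
    value 10/6/5/4/4/4 for unit lengths 1..6."""
    motifs = {1: "A", 2: "AT", 3: "AAG", 4: "AATT", 5: "AACCT", 6: "AACGCT"}
    motif = motifs[unit]
    below = "GC" + motif * (threshold - 1) + "GG"
    at = "GC" + motif * threshold + "GG"
    assert find_ssrs(below) == []
    hits = find_ssrs(at)
    assert len(hits) == 1
    assert hits[0].count == threshold
    assert hits[0].motif == canonical_motif(motif)


def test_period_rule_no_double_reporting():
    seq = "GC" + "AT" * 6 + "GG"
    hits = find_ssrs(seq)
    assert len(hits) == 1
    assert (hits[0].unit_length, hits[0].count) == (2, 6)


def test_n_breaks_runs():
    assert find_ssrs("C" * 5 + "N" + "C" * 5) == []
    assert len(find_ssrs("C" * 10 + "N" + "C" * 10)) == 2


def test_ssr_oracle_equivalence():
    """Hit sets equal the exhaustive brute-force scanner on seeded random
    5-kb sequences."""
    rng = random.Random(7)
    for _ in range(20):
        seq = "".join(rng.choices("ACGT", k=5000))
        got = {(h.motif, h.count, h.start, h.end) for h in find_ssrs(seq)}
        assert got == brute_ssrs(seq, DEFAULT_SSR_THRESHOLDS)


def test_ssr_strand_symmetry(record):
    fwd = find_ssrs(record.seq)
    rev = find_ssrs(reverse_complement(record.seq))
    assert sorted((h.motif, h.count) for h in fwd) == \
        sorted((h.motif, h.count) for h in rev)


def test_ssr_self_verification_and_maximality(record):
    """Every hit re-extracted from the genome is an exact tandem
    repetition of its motif class, and adding one more unit on either
    side breaks the repetition."""
    n = record.length
    for h in find_ssrs(record.seq):
        u, segment = h.unit_length, record.seq[h.start:h.end]
        unit = segment[:u]
        assert segment == unit * h.count
        assert canonical_motif(unit) == h.motif
        left = record.seq[h.start - u:h.start] if h.start >= u else None
        right = record.seq[h.end:h.end + u] if h.end + u <= n else None
        if left is not None:
            assert record.seq[h.start - u:h.end] != unit * (h.count + 1)
        if right is not None:
            assert record.seq[h.start:h.end + u] != unit * (h.count + 1)


def test_ssrs_match_generator_truth(record, ledger):
    got = {(h.motif, h.count, h.start, h.end) for h in find_ssrs(record.seq)}
    assert got == ledger.ssr_tuples()


def test_ssr_contexts_match_ledger(record, ledger):
    hits = find_ssrs(record.seq, record=record)
    got = {(h.start, h.context, h.context_name) for h in hits}
    want = {(s["start"], s["context"], s["context_name"])
            for s in ledger.ssrs}
    assert got == want


def test_locate_context_priorities(record, ledger):
    for s in ledger.ssrs:
        ctx, name = locate_context((s["start"], s["end"]), record)
        assert (ctx, name) == (s["context"], s["context_name"])


# ---------------------------------------------------------------------------
# long repeats


def test_planted_forward_pair(record, ledger):
    hits = find_lsrs(record.seq, min_arm=30)
    forward = [h for h in hits if h.type == "forward"]
    planted = next(r for r in ledger.lsrs if r["type"] == "forward")
    assert len(forward) == 1
    h = forward[0]
    assert (h.arm_length, h.start1, h.start2) == \
        (planted["arm_length"], planted["start1"], planted["start2"])
    assert record.seq[h.start1:h.end1] == record.seq[h.start2:h.end2]


def test_top_palindromic_hit_is_the_ir(record, ledger):
    hits = find_lsrs(record.seq, min_arm=30)
    pal = max((h for h in hits if h.type == "palindromic"),
              key=lambda h: h.arm_length)
    assert (pal.start1, pal.start2) == \
        (ledger.regions["IRb"][0], ledger.regions["IRa"][0])
    assert pal.arm_length == ledger.regions["IRb"][1]


def test_lsr_oracle_equivalence():
    """Hit sets equal the match-matrix oracle on sequences with planted
    repeats of all four types, at reduced arm length."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    for rep in range(5):
        rng = random.Random(200 + rep)
        base = "".join(rng.choices("ACGT", k=1800))
        seg = "".join(rng.choices("ACGT", k=25))
        seq = (base[:300] + seg + base[300:700] + seg +
               base[700:1000] + reverse_complement(seg) +
               base[1000:1300] + seg[::-1] +
               base[1300:1600] + "".join(comp[c] for c in seg) + base[1600:])
        got = {(h.type, h.arm_length, h.start1, h.start2)
               for h in find_lsrs(seq, min_arm=12)}
        assert got == brute_lsrs(seq, 12)


def test_lsr_self_verification(record):
    for h in find_lsrs(record.seq, min_arm=30):
        arm1 = record.seq[h.start1:h.end1]
        arm2 = record.seq[h.start2:h.end2]
        if h.type == "forward":
            assert arm1 == arm2
        elif h.type == "palindromic":
            assert arm1 == reverse_complement(arm2)
        elif h.type == "reverse":
            assert arm1 == arm2[::-1]
        else:
            assert arm1 == complement(arm2)


def test_lsr_arm_contexts(record, ledger):
    hits = find_lsrs(record.seq, min_arm=30, record=record)
    fwd = next(h for h in hits if h.type == "forward")
    planted = next(r for r in ledger.lsrs if r["type"] == "forward")
    assert fwd.context1 == tuple(planted["context1"])
    assert fwd.context2 == tuple(planted["context2"])


def test_lsr_rejects_short_sequence():
    with pytest.raises(ValueError):
        find_lsrs("ACGT", min_arm=30)
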