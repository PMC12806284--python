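"""Quadripartite LSC/IRb/SSC/IRa structure detection and normalization.

Plastomes typically carry two large inverted repeats (IRa/IRb) separating
a large and a small single-copy region.  Because assemblies linearize the
circle at arbitrary positions, region detection must work on circular
coordinates.  Detection is seed-and-extend: every circular
``seed_length``-mer of the sequence is indexed by rolling hash, matched
against the reverse-complement windows, and each verified pair is
extended base-by-base (exact match) outward until the inverted-repeat
identity breaks or the arms would collide.  Because the index covers all
window positions, an inverted repeat with arms of at least
``seed_length`` is guaranteed to be found at any rotation.
"""

from __future__ import annotations

from dataclasses import dataclass

from plastkit.genome_model import (
    GenomeRecord,
    LogicalPart,
    PlastkitError,
    _rebuild_feature,
    circular_slice,
    complement,
    reverse_complement,
    reverse_complement_record,
    rotate_circular,
)

__all__ = [
    "QuadripartiteStructure",
    "RegionReport",
    "StructureNotFound",
    "find_inverted_repeats",
    "classify_regions",
    "adjust_sequence",
]

REGION_NAMES = ("LSC", "IRb", "SSC", "IRa")

DEFAULT_SEED_LENGTH = 1000


class StructureNotFound(PlastkitError):
    """No quadripartite structure could be detected on a sequence."""


@dataclass(frozen=True)
class Region:
    """A named region on the circle: start plus length (end may wrap)."""

    name: str
    start: int
    length: int
    genome_length: int

    @property
    def end(self) -> int:
        """Half-open end, modulo genome length (may be < start on wrap)."""
        return (self.start + self.length) % self.genome_length

    def sequence(self, seq: str) -> str:
        return circular_slice(seq, self.start, self.length)

    def contains(self, pos: int) -> bool:
        return (pos - self.start) % self.genome_length < self.length


@dataclass(frozen=True)
class QuadripartiteStructure:
    """The four plastome regions in cyclic order LSC → IRb → SSC → IRa."""

    lsc: Region
    irb: Region
    ssc: Region
    ira: Region
    seed_length: int

    @property
    def ir_length(self) -> int:
        return self.irb.length

    @property
    def genome_length(self) -> int:
        return self.lsc.genome_length

    def regions(self) -> tuple[Region, Region, Region, Region]:
        return (self.lsc, self.irb, self.ssc, self.ira)

    def region_lengths(self) -> dict[str, int]:
        return {r.name: r.length for r in self.regions()}

    def validate(self, seq: str) -> None:
        """Assert the structural invariants against the sequence."""
        n = self.genome_length
        if sum(r.length for r in self.regions()) != n:
            raise PlastkitError("regions do not tile the circle")
        for a, b in zip(self.regions(), self.regions()[1:] + (self.lsc,)):
            if (a.start + a.length) % n != b.start:
                raise PlastkitError(f"{a.name} and {b.name} are not adjacent")
        if self.ira.sequence(seq) != reverse_complement(self.irb.sequence(seq)):
            raise PlastkitError("IRa is not the reverse complement of IRb")
        if self.lsc.length < self.ssc.length:
            raise PlastkitError("LSC shorter than SSC")


def _extend_pair(seq: str, i: int, j: int, k: int) -> tuple[int, int, int]:
    """Maximally extend a seed pair where ``circ(i, k) == revcomp(circ(j, k))``.

    Returns (arm1_start, arm2_start, arm_length).  Extension preserves the
    invariant and stops at a mismatch, an N, or when the arms would meet.
    """
    n = len(seq)
    a1, a2, length = i, j, k

    # rightward for arm1 pairs with leftward for arm2
    while True:
        gap = (a2 - (a1 + length)) % n
        if gap < 2:
            break
        x = seq[(a1 + length) % n]
        y = seq[(a2 - 1) % n]
        if x == "N" or y == "N" or x != complement(y):
            break
        a2 = (a2 - 1) % n
        length += 1
    # leftward for arm1 pairs with rightward for arm2
    while True:
        gap = (a1 - (a2 + length)) % n
        if gap < 2:
            break
        x = seq[(a1 - 1) % n]
        y = seq[(a2 + length) % n]
        if x == "N" or y == "N" or x != complement(y):
            break
        a1 = (a1 - 1) % n
        length += 1
    return a1, a2, length


def _window_in_arm(w: int, k: int, arm_start: int, arm_len: int, n: int) -> bool:
    off = (w - arm_start) % n
    return off + k <= arm_len


def _pair_covered(i: int, j: int, k: int,
                  hits: list[tuple[int, int, int]], n: int) -> bool:
    """Is the seed pair (i, j) already explained by a found arm pair?"""
    for a1, a2, length in hits:
        for b1, b2 in ((a1, a2), (a2, a1)):
            if _window_in_arm(i, k, b1, length, n) and \
               _window_in_arm(j, k, b2, length, n):
                t = (i - b1) % n
                expect_j = (b2 + length - k - t) % n
                if j == expect_j:
                    return True
    return False


_MOD = (1 << 61) - 1
_HASH_BASE = 1315423911 % _MOD
_BASE_VALUES = {"A": 1, "C": 2, "G": 3, "T": 4}


def _window_hashes(s: str, k: int) -> list[int | None]:
    """Rolling hash of every circular k-window of ``s``; ``None`` marks
    windows containing a character outside ACGT (they never match)."""
    n = len(s)
    ext = s + s[: k - 1]
    vals = [_BASE_VALUES.get(c) for c in ext]
    pw = pow(_HASH_BASE, k - 1, _MOD)
    h = 0
    bad = 0
    for t in range(k):
        v = vals[t]
        h = (h * _HASH_BASE + (v or 0)) % _MOD
        bad += v is None
    out: list[int | None] = [None] * n
    for i in range(n):
        out[i] = None if bad else h
        if i == n - 1:
            break
        v_out, v_in = vals[i], vals[i + k]
        h = ((h - (v_out or 0) * pw) * _HASH_BASE + (v_in or 0)) % _MOD
        bad += (v_in is None) - (v_out is None)
    return out


def find_inverted_repeats(seq: str,
                          seed_length: int = DEFAULT_SEED_LENGTH,
                          ) -> QuadripartiteStructure | None:
    """Detect the quadripartite structure of a circular plastome sequence.

    Returns ``None`` when no inverted repeat with arms of at least
    ``seed_length`` exists (IR-lacking plastomes).  Raises
    :class:`PlastkitError` for sequences shorter than ``2 * seed_length``
    or when the best arms leave no single-copy region between them.
    """
    seq = seq.upper()
    n = len(seq)
    k = seed_length
    if n <= 2 * k:
        raise PlastkitError(
            f"sequence length {n} must exceed twice the seed length {k}")

    rc = reverse_complement(seq)
    h_seq = _window_hashes(seq, k)
    h_rc = _window_hashes(rc, k)
    index: dict[int, list[int]] = {}
    for i, h in enumerate(h_seq):
        if h is not None:
            index.setdefault(h, []).append(i)

    hits: list[tuple[int, int, int]] = []
    for p, h in enumerate(h_rc):
        if h is None:
            continue
        for i0 in index.get(h, ()):
            # rc window p equals the reverse complement of seq window j0
            j0 = (n - p - k) % n
            # skip degenerate self-overlapping windows
            if (j0 - i0) % n < k or (i0 - j0) % n < k:
                continue
            if _pair_covered(i0, j0, k, hits, n):
                continue
            if circular_slice(seq, i0, k) != \
                    reverse_complement(circular_slice(seq, j0, k)):
                continue  # hash collision
            a1, a2, length = _extend_pair(seq, i0, j0, k)
            key = min((a1, a2), (a2, a1))
            if (key[0], key[1], length) not in hits:
                hits.append((key[0], key[1], length))

    if not hits:
        return None

    def arm_distance(h: tuple[int, int, int]) -> int:
        a1, a2, length = h
        m1 = (a1 + length // 2) % n
        m2 = (a2 + length // 2) % n
        d = (m2 - m1) % n
        return min(d, n - d)

    best_len = max(h[2] for h in hits)
    candidates = [h for h in hits if h[2] == best_len]
    a1, a2, length = max(candidates, key=arm_distance)

    gap1 = (a2 - (a1 + length)) % n  # clockwise from arm1 end to arm2 start
    gap2 = (a1 - (a2 + length)) % n
    if gap1 == 0 or gap2 == 0:
        raise PlastkitError(
            "inverted-repeat arms leave no single-copy region (degenerate)")

    # label: LSC is the longer single-copy span, IRb follows the LSC
    if gap2 >= gap1:
        lsc_start, lsc_len = (a2 + length) % n, gap2
        irb_start, irb_len = a1, length
        ssc_start, ssc_len = (a1 + length) % n, gap1
        ira_start = a2
    else:
        lsc_start, lsc_len = (a1 + length) % n, gap1
        irb_start, irb_len = a2, length
        ssc_start, ssc_len = (a2 + length) % n, gap2
        ira_start = a1

    struct = QuadripartiteStructure(
        lsc=Region("LSC", lsc_start, lsc_len, n),
        irb=Region("IRb", irb_start, irb_len, n),
        ssc=Region("SSC", ssc_start, ssc_len, n),
        ira=Region("IRa", ira_start, length, n),
        seed_length=k,
    )
    struct.validate(seq)
    return struct


# ---------------------------------------------------------------------------
# classification and adjustment


@dataclass(frozen=True)
class RegionReport:
    """Orientation summary of one record against its detected structure."""

    record_id: str
    starts_at_lsc: bool
    ssc_forward: bool
    region_lengths: dict[str, int]
    region_gc: dict[str, float]


def _ssc_forward(record: GenomeRecord,
                 structure: QuadripartiteStructure) -> bool:
    """SSC orientation convention: ndhF (or the majority of SSC genes)
    lies on the minus strand when the SSC is 'forward'."""
    ssc = structure.ssc
    ssc_genes = [
        f for f in record.genes()
        if ssc.contains(f.leftmost)
    ]
    for f in ssc_genes:
        if f.name == "ndhF":
            return f.strand == "-"
    if ssc_genes:
        minus = sum(1 for f in ssc_genes if f.strand == "-")
        return minus * 2 >= len(ssc_genes)
    return True  # no annotation inside the SSC: orientation undeterminable


def classify_regions(structure: QuadripartiteStructure,
                     record: GenomeRecord) -> RegionReport:
    """Report whether the record starts at the LSC, whether its SSC is in
    the forward orientation, and per-region length and GC."""
    return RegionReport(
        record_id=record.id,
        starts_at_lsc=structure.lsc.start == 0,
        ssc_forward=_ssc_forward(record, structure),
        region_lengths=structure.region_lengths(),
        region_gc={
            r.name: record.gc_fraction(r.start, r.length)
            for r in structure.regions()
        },
    )


def _flip_ssc(record: GenomeRecord,
              structure: QuadripartiteStructure) -> GenomeRecord:
    """Reverse-complement the SSC span in place, remapping features inside."""
    s = structure.ssc.start
    e = s + structure.ssc.length
    if e > record.length:
        raise PlastkitError("SSC spans the origin; rotate to LSC start first")
    seq = record.seq[:s] + reverse_complement(record.seq[s:e]) + record.seq[e:]
    feats = []
    for f in record.features:
        logical = f.logical_parts()
        inside = [s <= lp.start and lp.start + lp.length <= e for lp in logical]
        if not any(inside):
            feats.append(f)
            continue
        if not all(inside):
            raise PlastkitError(
                f"feature {f.name!r} straddles the SSC boundary; cannot flip")
        mapped = [
            LogicalPart(s + e - (lp.start + lp.length), lp.length,
                        "-" if lp.strand == "+" else "+")
            for lp in logical
        ]
        feats.append(_rebuild_feature(f, mapped, record.length))
    return GenomeRecord(id=record.id, seq=seq, circular=record.circular,
                        features=feats)


def adjust_sequence(record: GenomeRecord, mode: str = "LSC",
                    seed_length: int = DEFAULT_SEED_LENGTH) -> GenomeRecord:
    """Normalize a plastome's linearization.

    mode ``LSC``: rotate so the LSC starts at position 0.
    mode ``SSC``: as LSC, additionally reverse-complementing the SSC span
    in place when it is not in the forward orientation.
    mode ``RP``: reverse-complement the whole genome, then rotate so the
    LSC starts at position 0.
    """
    if mode not in ("LSC", "SSC", "RP"):
        raise ValueError(f"unknown adjustment mode {mode!r}")
    structure = find_inverted_repeats(record.seq, seed_length)
    if structure is None:
        raise StructureNotFound(
            "no quadripartite structure detected; for raw FASTA input "
            "without an inverted repeat there is nothing to adjust")

    if mode == "RP":
        rec = reverse_complement_record(record)
        structure = find_inverted_repeats(rec.seq, seed_length)
        assert structure is not None
        return rotate_circular(rec, structure.lsc.start)

    rec = rotate_circular(record, structure.lsc.start)
    if mode == "SSC":
        structure = find_inverted_repeats(rec.seq, seed_length)
        assert structure is not None
        if not _ssc_forward(rec, structure):
            rec = _flip_ssc(rec, structure)
    return rec
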