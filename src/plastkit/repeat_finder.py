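"""Microsatellite (SSR) and long sequence repeat (LSR) detection.

SSRs are perfect tandem repeats of a 1-6 bp motif.  Minimum repeat counts
follow the MISA-style unit ladder: 10 units for mononucleotides, 6 for
dinucleotides, 5 for trinucleotides, and 4 for tetra-, penta- and
hexanucleotides.  Thresholds are counted in repeat UNITS, not base pairs
(so the mononucleotide minimum is 10 bp and the hexanucleotide minimum is
24 bp).  Motifs are reported in canonical form: the lexicographically
smallest rotation of the motif or of its reverse complement, which makes
detection strand-symmetric.

LSRs are dispersed exact repeat pairs of four types — forward (identical),
palindromic (reverse complement), reverse, and complement — found by
seed-and-extend with the seed equal to the minimum arm length.  Arms are
kept disjoint: extension stops when the arms would overlap, so "maximal"
means maximal subject to non-overlap.

Each hit can be localized to its genomic context (exon, intron, or
intergenic spacer) against an annotated record.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from plastkit.genome_model import (
    GenomeRecord,
    complement,
    reverse_complement,
)

__all__ = [
    "SSRHit",
    "LSRHit",
    "DEFAULT_SSR_THRESHOLDS",
    "LSR_TYPES",
    "canonical_motif",
    "find_ssrs",
    "find_lsrs",
    "locate_context",
    "annotate_contexts",
]

DEFAULT_SSR_THRESHOLDS: dict[int, int] = {1: 10, 2: 6, 3: 5, 4: 4, 5: 4, 6: 4}

LSR_TYPES = ("forward", "palindromic", "reverse", "complement")

DEFAULT_LSR_MIN_ARM = 30


@dataclass(frozen=True)
class SSRHit:
    """A maximal perfect microsatellite: ``seq[start:end]`` is ``count``
    tandem copies of (a rotation/complement of) the canonical ``motif``."""

    motif: str
    unit_length: int
    count: int
    start: int
    end: int
    context: str | None = None  # "exon" | "intron" | "IGS"
    context_name: str | None = None

    def __post_init__(self) -> None:
        if self.end - self.start != self.unit_length * self.count:
            raise ValueError("SSR interval is not a whole number of units")


@dataclass(frozen=True)
class LSRHit:
    """A maximal exact repeat pair with two arms of equal length."""

    type: str
    arm_length: int
    start1: int
    start2: int
    context1: tuple[str, str] | None = None
    context2: tuple[str, str] | None = None

    @property
    def end1(self) -> int:
        return self.start1 + self.arm_length

    @property
    def end2(self) -> int:
        return self.start2 + self.arm_length


class MotifPeriodError(ValueError):
    """Motif is a whole-number repetition of a shorter unit."""


def smallest_period(s: str) -> int:
    """Smallest p such that s is a whole-number repetition of s[:p]."""
    n = len(s)
    for p in range(1, n + 1):
        if n % p == 0 and s == s[:p] * (n // p):
            return p
    return n  # unreachable


def canonical_motif(motif: str) -> str:
    """Canonical representative of a motif under rotation and reverse
    complement: the lexicographically smallest candidate.

    Raises :class:`MotifPeriodError` for motifs that are repetitions of a
    shorter unit (they belong to the shorter unit's class).
    """
    if not 1 <= len(motif) <= 6:
        raise ValueError(f"motif length {len(motif)} outside 1..6")
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    if smallest_period(motif) < len(motif):
        raise MotifPeriodError(
            f"motif {motif!r} has period {smallest_period(motif)}")
    rc = reverse_complement(motif)
    candidates = [motif[i:] + motif[:i] for i in range(len(motif))]
    candidates += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(candidates)


def find_ssrs(seq: str,
              thresholds: dict[int, int] | None = None,
              record: GenomeRecord | None = None) -> list[SSRHit]:
    """All maximal perfect SSRs with unit length 1-6 meeting the unit-count
    thresholds.  N never matches, so no repeat crosses an N.

    A run whose motif has a smaller period is reported only under the
    smaller period's class.  Hits are left-anchored within their maximal
    per-base run and truncated to whole units.  If ``record`` is given,
    each hit is annotated with its genomic context.
    """
    thresholds = dict(DEFAULT_SSR_THRESHOLDS if thresholds is None else thresholds)
    seq = seq.upper()
    n = len(seq)
    hits: list[SSRHit] = []
    for u, min_units in sorted(thresholds.items()):
        if u < 1 or min_units < 2:
            raise ValueError("unit length >= 1 and min units >= 2 required")
        # walk left-maximal runs of the per-base relation seq[j] == seq[j-u]
        s = 0
        while s + u <= n:
            j = s + u
            while j < n and seq[j] != "N" and seq[j] == seq[j - u]:
                j += 1
            count = (j - s) // u
            if count >= min_units:
                motif = seq[s:s + u]
                if "N" not in motif and smallest_period(motif) == u:
                    hits.append(SSRHit(
                        motif=canonical_motif(motif),
                        unit_length=u,
                        count=count,
                        start=s,
                        end=s + count * u,
                    ))
            # next left-maximal start: the per-base relation fails at j
            s = max(s + 1, j - u + 1)
    hits.sort(key=lambda h: (h.start, h.unit_length))
    if record is not None:
        hits = [
            replace(h, context=ctx, context_name=name)
            for h in hits
            for ctx, name in [locate_context((h.start, h.end), record)]
        ]
    return hits


# ---------------------------------------------------------------------------
# genomic context


def locate_context(interval: tuple[int, int],
                   record: GenomeRecord) -> tuple[str, str]:
    """Classify an interval's midpoint as exon, intron, or IGS.

    Priority is exon > intron > IGS when annotations overlap.  Exon parts
    are taken from CDS/tRNA/rRNA features (their joined parts are the
    exons); a gene's overall span minus its exons is intron.  The IGS is
    named "a-b" after the flanking genes in genomic order.
    """
    mid = (interval[0] + interval[1]) // 2
    n = record.length

    exonic = record.features_of_kind("CDS") + \
        record.features_of_kind("tRNA") + record.features_of_kind("rRNA")
    for f in exonic:
        for lp in f.logical_parts():
            if (mid - lp.start) % n < lp.length:
                return "exon", f.name
    genes = record.genes()
    for f in genes:
        s, e = f.span(n)
        if (mid - s) % n < e - s:
            return "intron", f.name
    # IGS: flanking genes in genomic order around the midpoint
    if not genes:
        return "IGS", ""
    before = min(genes, key=lambda f: (mid - f.span(n)[1]) % n)
    after = min(genes, key=lambda f: (f.span(n)[0] - mid) % n)
    return "IGS", f"{before.name}-{after.name}"


def annotate_contexts(hits: list[LSRHit],
                      record: GenomeRecord) -> list[LSRHit]:
    """Attach context labels to both arms of each LSR hit."""
    return [
        replace(
            h,
            context1=locate_context((h.start1, h.end1), record),
            context2=locate_context((h.start2, h.end2), record),
        )
        for h in hits
    ]


# ---------------------------------------------------------------------------
# long sequence repeats


def _transform(window: str, lsr_type: str) -> str:
    if lsr_type == "forward":
        return window
    if lsr_type == "palindromic":
        return reverse_complement(window)
    if lsr_type == "reverse":
        return window[::-1]
    if lsr_type == "complement":
        return complement(window)
    raise ValueError(f"unknown LSR type {lsr_type!r}")


def _relation_holds(seq: str, lsr_type: str, i: int, j: int, length: int) -> bool:
    a = seq[i:i + length]
    b = seq[j:j + length]
    if "N" in a or "N" in b:
        return False
    return a == _transform(b, lsr_type)


def _extend_lsr(seq: str, lsr_type: str, i: int, j: int,
                k: int) -> tuple[int, int, int]:
    """Maximally extend a seed pair (arm1 at i, arm2 at j, i < j or i <= j),
    keeping the arms disjoint.  Arm-to-arm base pairing depends on type:
    forward/complement arms run parallel, palindromic/reverse antiparallel.
    """
    n = len(seq)
    a1, a2, length = i, j, k
    parallel = lsr_type in ("forward", "complement")
    eq = (lambda x, y: x != "N" and x == y) if lsr_type in ("forward", "reverse") \
        else (lambda x, y: x != "N" and x == complement(y))

    if parallel:
        # left of arm1 pairs with left of arm2; right with right
        while a1 > 0 and a2 > 0 and a1 + length <= a2 - 1 and \
                eq(seq[a1 - 1], seq[a2 - 1]):
            a1 -= 1
            a2 -= 1
            length += 1
        while a2 + length < n and a1 + length < a2 and \
                eq(seq[a1 + length], seq[a2 + length]):
            length += 1
    else:
        # left of arm1 pairs with right of arm2; right of arm1 with left of arm2
        while a1 > 0 and a2 + length < n and a1 + length <= a2 and \
                eq(seq[a1 - 1], seq[a2 + length]):
            a1 -= 1
            length += 1
        while a2 > 0 and a1 + length <= a2 - 2 and \
                eq(seq[a1 + length], seq[a2 - 1]):
            a2 -= 1
            length += 1
    return a1, a2, length


def _lsr_covered(i: int, j: int, k: int, lsr_type: str,
                 found: list[LSRHit]) -> bool:
    parallel = lsr_type in ("forward", "complement")
    for h in found:
        if h.type != lsr_type:
            continue
        if h.start1 <= i and i + k <= h.end1 and \
                h.start2 <= j and j + k <= h.end2:
            t = i - h.start1
            expect = h.start2 + t if parallel else h.end2 - k - t
            if j == expect:
                return True
    return False


def find_lsrs(seq: str,
              min_arm: int = DEFAULT_LSR_MIN_ARM,
              types: tuple[str, ...] = LSR_TYPES,
              record: GenomeRecord | None = None) -> list[LSRHit]:
    """All maximal exact repeat pairs with arms of at least ``min_arm`` bp.

    Coordinates are linear (the sequence as given); arms never overlap.
    Self-trivial forward matches of a segment with itself are excluded.
    If ``record`` is given, both arms are context-annotated.
    """
    seq = seq.upper()
    n = len(seq)
    k = min_arm
    if n < 2 * k:
        raise ValueError(f"sequence length {n} shorter than 2*min_arm {2 * k}")
    for t in types:
        if t not in LSR_TYPES:
            raise ValueError(f"unknown LSR type {t!r}")

    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        w = seq[i:i + k]
        if "N" not in w:
            index.setdefault(w, []).append(i)

    found: list[LSRHit] = []
    seen: set[tuple[str, int, int, int]] = set()
    for lsr_type in types:
        for i in range(n - k + 1):
            w = seq[i:i + k]
            if "N" in w:
                continue
            for j in index.get(_transform(w, lsr_type), ()):
                # seed means seq[i:i+k] == transform(seq[j:j+k])
                if j < i + k:  # keep arm1 strictly left of (or self) arm2
                    continue
                if _lsr_covered(i, j, k, lsr_type, found):
                    continue
                a1, a2, length = _extend_lsr(seq, lsr_type, i, j, k)
                key = (lsr_type, a1, a2, length)
                if key not in seen:
                    seen.add(key)
                    found.append(LSRHit(lsr_type, length, a1, a2))
    found.sort(key=lambda h: (LSR_TYPES.index(h.type), h.start1, h.start2))
    if record is not None:
        found = annotate_contexts(found, record)
    return found
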