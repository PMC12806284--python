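"""Core plastome data model and GenBank/FASTA I/O.

Coordinates are 0-based, half-open throughout the package; GenBank's
1-based inclusive convention is converted at the I/O boundary.  Plastomes
are circular by default, so a feature part may span the origin; such a
part is stored split into two in-range intervals linked into one logical
part (see :class:`FeatureAnnotation.split_links`).

Parts are kept in biological (5'→3') order, the same convention Biopython
uses for ``join``/``complement`` locations, so extracting a feature's
sequence is a uniform per-part concatenation with minus-strand parts
reverse-complemented individually.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "PlastkitError",
    "ParseError",
    "Part",
    "FeatureAnnotation",
    "GenomeRecord",
    "CheckFinding",
    "reverse_complement",
    "complement",
    "circular_slice",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "extract_feature_sequence",
    "rotate_circular",
    "reverse_complement_record",
]

FEATURE_KINDS = ("gene", "CDS", "tRNA", "rRNA", "exon", "intron", "misc")

# IUPAC nucleotide alphabet; everything outside {A,C,G,T} is treated as N
# by the analysis modules, but accepted on read.
IUPAC_DNA = set("ACGTNRYSWKMBDHV")

_COMP = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                      "TGCANYRSWMKVHDBtgcanyrswmkvhdb")


class PlastkitError(Exception):
    """Base class for errors raised by plastkit."""


class ParseError(PlastkitError):
    """A file could not be parsed."""


def complement(seq: str) -> str:
    """Complement of a DNA string (IUPAC-aware; case preserved)."""
    return seq.translate(_COMP)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP)[::-1]


def circular_slice(seq: str, start: int, length: int) -> str:
    """Slice ``length`` bases starting at ``start``, wrapping past the end."""
    n = len(seq)
    if not 0 <= start < n:
        raise ValueError(f"start {start} outside [0, {n})")
    if length < 0 or length > n:
        raise ValueError(f"slice length {length} outside [0, {n}]")
    end = start + length
    if end <= n:
        return seq[start:end]
    return seq[start:] + seq[: end - n]


class Part(NamedTuple):
    """One in-range interval of a feature: 0-based half-open, stranded."""

    start: int
    end: int
    strand: str  # "+" or "-"


class LogicalPart(NamedTuple):
    """A biological part (exon) on the circle; ``start + length`` may wrap."""

    start: int
    length: int
    strand: str


@dataclass
class FeatureAnnotation:
    """A gene/CDS/tRNA/rRNA/... annotation with one or more stranded parts.

    ``split_links`` holds indices ``i`` such that ``parts[i]`` and
    ``parts[i+1]`` are the two halves of a single origin-spanning logical
    part.  Parts are in biological order: for a minus-strand wrap the
    low-coordinate half comes first (it is the 5' half on that strand).
    """

    kind: str
    name: str
    parts: list[Part]
    qualifiers: dict[str, str] = field(default_factory=dict)
    split_links: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not self.parts:
            raise ValueError("feature must have at least one part")
        self.parts = [Part(*p) for p in self.parts]

    @property
    def leftmost(self) -> int:
        return min(p.start for p in self.parts)

    @property
    def strand(self) -> str:
        return self.parts[0].strand

    def logical_parts(self) -> list[LogicalPart]:
        """Merge split halves back into origin-spanning logical parts."""
        out: list[LogicalPart] = []
        i = 0
        while i < len(self.parts):
            p = self.parts[i]
            if i in self.split_links:
                q = self.parts[i + 1]
                length = (p.end - p.start) + (q.end - q.start)
                # genomic start of the wrap is the high-coordinate half
                start = p.start if p.start > q.start else q.start
                out.append(LogicalPart(start, length, p.strand))
                i += 2
            else:
                out.append(LogicalPart(p.start, p.end - p.start, p.strand))
                i += 1
        return out

    @property
    def n_exons(self) -> int:
        return len(self.logical_parts())

    def span(self, genome_length: int) -> tuple[int, int]:
        """Outer (start, end) of the feature; end may exceed genome length
        for origin-spanning features (interpret modulo the length)."""
        lps = self.logical_parts()
        if len(lps) == 1:
            lp = lps[0]
            return lp.start, lp.start + lp.length
        starts = [lp.start for lp in lps]
        ends = [lp.start + lp.length for lp in lps]
        if max(ends) <= genome_length:
            return min(starts), max(ends)
        # at least one part wraps: report span anchored at the wrap start
        return min(starts), max(ends)


@dataclass
class GenomeRecord:
    """One annotated (usually circular) genome."""

    id: str
    seq: str
    circular: bool = True
    features: list[FeatureAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("empty sequence")
        self.seq = self.seq.upper()

    @property
    def length(self) -> int:
        return len(self.seq)

    def sorted_features(self) -> list[FeatureAnnotation]:
        """Features in ascending order of leftmost coordinate."""
        return sorted(self.features, key=lambda f: (f.leftmost, f.kind, f.name))

    def genes(self) -> list[FeatureAnnotation]:
        return [f for f in self.sorted_features() if f.kind == "gene"]

    def features_of_kind(self, kind: str) -> list[FeatureAnnotation]:
        return [f for f in self.sorted_features() if f.kind == kind]

    def feature_by_name(self, kind: str, name: str) -> FeatureAnnotation | None:
        for f in self.features:
            if f.kind == kind and f.name == name:
                return f
        return None

    def gc_fraction(self, start: int | None = None, length: int | None = None) -> float:
        s = self.seq if start is None else circular_slice(self.seq, start, length)
        gc = s.count("G") + s.count("C")
        return gc / len(s) if s else 0.0


CHECK_CATEGORIES = (
    "non_atg_start",
    "missing_stop",
    "internal_stop",
    "length_not_multiple_of_3",
    "duplicate_name",
    "parse_warning",
)


@dataclass(frozen=True)
class CheckFinding:
    """One annotation-QC finding for a feature of a record."""

    record_id: str
    gene: str
    category: str
    detail: str
    severity: str = "warning"  # "warning" | "error"

    def __post_init__(self) -> None:
        if self.category not in CHECK_CATEGORIES:
            raise ValueError(f"unknown finding category {self.category!r}")
        if self.severity not in ("warning", "error"):
            raise ValueError(f"unknown severity {self.severity!r}")


# ---------------------------------------------------------------------------
# conversions between our parts model and Biopython locations


def _parts_from_location(location, genome_length: int) -> tuple[list[Part], frozenset[int]]:
    raw = [
        (int(p.start), int(p.end), "-" if p.strand == -1 else "+")
        for p in location.parts
    ]
    parts: list[Part] = []
    links: set[int] = set()
    i = 0
    while i < len(raw):
        s, e, st = raw[i]
        if i + 1 < len(raw):
            s2, e2, st2 = raw[i + 1]
            if st2 == st:
                plus_wrap = st == "+" and e == genome_length and s2 == 0 and s > 0
                minus_wrap = st == "-" and s == 0 and e2 == genome_length and s2 > 0
                if plus_wrap or minus_wrap:
                    links.add(len(parts))
                    parts.append(Part(s, e, st))
                    parts.append(Part(s2, e2, st))
                    i += 2
                    continue
        if not 0 <= s < e <= genome_length:
            raise ParseError(f"feature interval [{s}, {e}) outside genome of "
                             f"length {genome_length}")
        parts.append(Part(s, e, st))
        i += 1
    return parts, frozenset(links)


def _location_from_feature(feat: FeatureAnnotation, genome_length: int):
    locs = []
    i = 0
    while i < len(feat.parts):
        p = feat.parts[i]
        strand = -1 if p.strand == "-" else 1
        if i in feat.split_links:
            q = feat.parts[i + 1]
            locs.append(SimpleLocation(p.start, p.end, strand))
            locs.append(SimpleLocation(q.start, q.end, strand))
            i += 2
        else:
            locs.append(SimpleLocation(p.start, p.end, strand))
            i += 1
    if len(locs) == 1:
        return locs[0]
    return CompoundLocation(locs)


# ---------------------------------------------------------------------------
# readers / writers


def _record_from_seqrecord(rec: SeqRecord) -> GenomeRecord:
    seq = str(rec.seq).upper()
    if not seq:
        raise ParseError(f"record {rec.id!r} has an empty sequence")
    bad = set(seq) - IUPAC_DNA
    if bad:
        raise ParseError(f"record {rec.id!r} contains non-IUPAC characters: "
                         f"{sorted(bad)}")
    topology = rec.annotations.get("topology", "circular")
    features: list[FeatureAnnotation] = []
    for f in rec.features:
        if f.type == "source":
            continue
        kind = f.type if f.type in FEATURE_KINDS else "misc"
        quals = {k: v[0] if isinstance(v, list) and v else str(v)
                 for k, v in f.qualifiers.items()}
        name = quals.get("gene", quals.get("locus_tag", "")).strip()
        parts, links = _parts_from_location(f.location, len(seq))
        features.append(FeatureAnnotation(kind=kind, name=name, parts=parts,
                                          qualifiers=quals, split_links=links))
    return GenomeRecord(id=rec.id, seq=seq, circular=(topology != "linear"),
                        features=features)


def read_genbank(path: str | os.PathLike) -> GenomeRecord:
    """Read a single-record GenBank flat file into a :class:`GenomeRecord`.

    All gene/CDS/tRNA/rRNA features are captured; other feature types are
    kept with kind ``misc``.  The sequence is uppercased and origin-spanning
    ``join`` locations are normalized into linked split parts.
    """
    try:
        rec = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # biopython raises assorted ValueError subtypes
        raise ParseError(f"cannot parse GenBank file {path}: {exc}") from exc
    return _record_from_seqrecord(rec)


def read_genbank_dir(path: str | os.PathLike) -> list[GenomeRecord]:
    """Read every ``*.gb``/``*.gbk``/``*.genbank`` file in a directory,
    sorted by file name."""
    names = sorted(
        n for n in os.listdir(path)
        if n.lower().endswith((".gb", ".gbk", ".genbank", ".gbf"))
    )
    if not names:
        raise ParseError(f"no GenBank files found in {path}")
    return [read_genbank(os.path.join(path, n)) for n in names]


def to_seqrecord(record: GenomeRecord) -> SeqRecord:
    """Convert to a Biopython SeqRecord (for writing)."""
    rec = SeqRecord(
        Seq(record.seq),
        id=record.id,
        name=record.id[:16].replace(" ", "_"),
        description=record.id,
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.circular else "linear",
        },
    )
    rec.features.append(
        SeqFeature(SimpleLocation(0, record.length, 1), type="source")
    )
    for f in record.sorted_features():
        quals = dict(f.qualifiers)
        if f.name and "gene" not in quals:
            quals["gene"] = f.name
        rec.features.append(
            SeqFeature(
                _location_from_feature(f, record.length),
                type=f.kind,
                qualifiers={k: [v] for k, v in quals.items()},
            )
        )
    return rec


def write_genbank(record: GenomeRecord, path: str | os.PathLike) -> None:
    SeqIO.write(to_seqrecord(record), str(path), "genbank")


def genbank_text(record: GenomeRecord) -> str:
    from io import StringIO

    buf = StringIO()
    SeqIO.write(to_seqrecord(record), buf, "genbank")
    return buf.getvalue()


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]``.

    The full header line (after ``>``) is used as the id.  Sequences are
    uppercased and U is normalized to T; characters outside the IUPAC
    nucleotide alphabet are rejected, as are duplicate ids and empty files.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"no FASTA records in {path}")
    out: list[tuple[str, str]] = []
    seen: dict[str, int] = {}
    for rec in records:
        rid = rec.description
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - IUPAC_DNA
        if bad:
            raise ParseError(
                f"record {rid!r} contains non-IUPAC characters: {sorted(bad)}"
            )
        seen[rid] = seen.get(rid, 0) + 1
        out.append((rid, seq))
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ParseError(f"duplicate FASTA ids: {dups}")
    return out


def write_fasta(entries: Iterable[tuple[str, str]],
                path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(fasta_text(entries, width=width))


def fasta_text(entries: Iterable[tuple[str, str]], width: int = 70) -> str:
    lines = []
    for rid, seq in entries:
        lines.append(f">{rid}")
        for i in range(0, len(seq), width):
            lines.append(seq[i:i + width])
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# sequence extraction and circular-coordinate operations


def extract_feature_sequence(record: GenomeRecord,
                             feature: FeatureAnnotation) -> str:
    """Spliced, strand-resolved sequence of a feature.

    Parts are concatenated in their stored (biological) order with
    minus-strand parts reverse-complemented; origin-spanning logical parts
    yield the contiguous circular subsequence.
    """
    chunks = []
    for p in feature.parts:
        if not (0 <= p.start < p.end <= record.length):
            raise ValueError(
                f"part [{p.start}, {p.end}) outside genome of length "
                f"{record.length}"
            )
        s = record.seq[p.start:p.end]
        chunks.append(reverse_complement(s) if p.strand == "-" else s)
    return "".join(chunks)


def _split_logical(lp: LogicalPart, genome_length: int) -> tuple[list[Part], bool]:
    """Render a logical part as stored parts (split if it wraps)."""
    s, n, st = lp
    if s + n <= genome_length:
        return [Part(s, s + n, st)], False
    hi = Part(s, genome_length, st)
    lo = Part(0, s + n - genome_length, st)
    # biological order: '+' reads hi then lo; '-' reads lo then hi
    return ([hi, lo] if st == "+" else [lo, hi]), True


def _rebuild_feature(feat: FeatureAnnotation, logical: list[LogicalPart],
                     genome_length: int) -> FeatureAnnotation:
    parts: list[Part] = []
    links: set[int] = set()
    for lp in logical:
        rendered, wrapped = _split_logical(lp, genome_length)
        if wrapped:
            links.add(len(parts))
        parts.extend(rendered)
    return replace(feat, parts=parts, split_links=frozenset(links))


def rotate_circular(record: GenomeRecord, offset: int) -> GenomeRecord:
    """Rotate a circular genome so position ``offset`` becomes position 0.

    Feature coordinates are shifted modulo the genome length; features that
    come to span the origin are stored split, and previously split features
    that no longer wrap are merged back.  Rotating by 0 is the identity.
    """
    n = record.length
    if not 0 <= offset < n:
        raise ValueError(f"offset {offset} outside [0, {n})")
    if offset == 0:
        return record
    if not record.circular:
        raise ValueError("cannot rotate a linear record")
    seq = record.seq[offset:] + record.seq[:offset]
    feats = []
    for f in record.features:
        logical = [LogicalPart((lp.start - offset) % n, lp.length, lp.strand)
                   for lp in f.logical_parts()]
        feats.append(_rebuild_feature(f, logical, n))
    return GenomeRecord(id=record.id, seq=seq, circular=True, features=feats)


def reverse_complement_record(record: GenomeRecord) -> GenomeRecord:
    """Reverse-complement the whole genome, remapping all features."""
    n = record.length
    feats = []
    for f in record.features:
        logical = []
        for lp in reversed(f.logical_parts()):
            new_start = (n - (lp.start + lp.length)) % n
            new_strand = "-" if lp.strand == "+" else "+"
            logical.append(LogicalPart(new_start, lp.length, new_strand))
        feats.append(_rebuild_feature(f, logical, n))
    return GenomeRecord(id=record.id, seq=reverse_complement(record.seq),
                        circular=record.circular, features=feats)
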