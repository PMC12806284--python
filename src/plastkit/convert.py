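"""GenBank → tbl / FASTA / mVISTA format conversion.

``to_tbl`` emits the NCBI 5-column feature table used for GenBank
submissions: 1-based inclusive coordinates, start/stop reversed on the
minus strand, the feature key on the first interval line, continuation
lines for joined intervals, and tab-indented qualifier lines.

``to_mvista`` emits the plain-text annotation dialect consumed by the
mVISTA comparative-genomics viewer: one stranded header line per gene
followed by per-exon lines; tRNA/rRNA exons are labeled ``utr`` since
mVISTA has no RNA class.  Output is byte-stable across runs.
"""

from __future__ import annotations

import warnings

from plastkit.genome_model import FeatureAnnotation, GenomeRecord, fasta_text

__all__ = ["to_tbl", "to_mvista", "to_fasta"]

# qualifiers emitted in tbl output, in this order, then any others except
# the bulky translation
TBL_QUALIFIER_ORDER = ("gene", "product", "codon_start", "transl_table")


def _tbl_intervals(feat: FeatureAnnotation) -> list[tuple[int, int]]:
    """1-based inclusive (start, stop) pairs in biological order; start >
    stop on the minus strand.  Origin-split halves stay as separate
    intervals (tbl has no circular syntax)."""
    out = []
    for p in feat.parts:
        if p.strand == "-":
            out.append((p.end, p.start + 1))
        else:
            out.append((p.start + 1, p.end))
    return out


def to_tbl(record: GenomeRecord) -> str:
    lines = [f">Feature {record.id}"]
    for feat in record.sorted_features():
        ivals = _tbl_intervals(feat)
        s, e = ivals[0]
        lines.append(f"{s}\t{e}\t{feat.kind}")
        for s, e in ivals[1:]:
            lines.append(f"{s}\t{e}")
        quals = dict(feat.qualifiers)
        if feat.name and "gene" not in quals:
            quals["gene"] = feat.name
        quals.pop("translation", None)
        for key in TBL_QUALIFIER_ORDER:
            if key in quals:
                lines.append(f"\t\t\t{key}\t{quals.pop(key)}")
        for key in sorted(quals):
            lines.append(f"\t\t\t{key}\t{quals[key]}")
    return "\n".join(lines) + "\n"


def to_mvista(record: GenomeRecord) -> str:
    """mVISTA annotation: per gene a ``start end strand name`` header and
    one ``start end exon|utr`` line per exon, in genomic order."""
    genes = record.genes()
    if not genes:
        warnings.warn(f"record {record.id!r} has no gene features; "
                      "mVISTA output is empty")
        return ""
    lines = []
    for g in genes:
        s, e = g.span(record.length)
        marker = ">" if g.strand == "+" else "<"
        lines.append(f"{s + 1} {e} {marker} {g.name}")
        exon_feat = None
        for kind, label in (("CDS", "exon"), ("tRNA", "utr"), ("rRNA", "utr")):
            f = record.feature_by_name(kind, g.name)
            if f is not None:
                exon_feat = (f, label)
                break
        feat, label = exon_feat if exon_feat else (g, "exon")
        for lp in sorted(feat.logical_parts(), key=lambda lp: lp.start):
            lines.append(f"{lp.start + 1} {lp.start + lp.length} {label}")
    return "\n".join(lines) + "\n"


def to_fasta(record: GenomeRecord, width: int = 70) -> str:
    """FASTA text: ``>`` plus the record id (spaces preserved) and the
    sequence wrapped at ``width`` columns."""
    return fasta_text([(record.id, record.seq)], width=width)
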