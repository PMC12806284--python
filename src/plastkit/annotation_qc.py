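"""Annotation quality control and genome statistics.

``check_record`` examines every CDS for start/stop codon problems and
frame errors; ``compare_annotations`` diffs two annotation sets by gene
name; ``summarize_genome`` produces gene/exon/GC statistics, the numbers
a curator checks first after annotating a new plastome.

Stop codons follow translation table 11 (bacterial/plastid).  A non-ATG
start is reported as a warning rather than an error because chloroplast
genes with RNA-edited GTG/ACG starts are legitimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from plastkit.genome_model import (
    CheckFinding,
    FeatureAnnotation,
    GenomeRecord,
    extract_feature_sequence,
)

__all__ = [
    "GenomeStats",
    "AnnotationDiff",
    "STOP_CODONS",
    "check_record",
    "compare_annotations",
    "summarize_genome",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}  # translation table 11


def _codons(seq: str) -> list[str]:
    return [seq[i:i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]


def check_record(record: GenomeRecord) -> list[CheckFinding]:
    """Integrity findings for every CDS of a record.

    For each CDS (spliced, strand-resolved): ``non_atg_start`` if the
    first codon is not ATG (warning), ``missing_stop`` if the final codon
    is not a stop, ``internal_stop`` for any in-frame stop before the
    final codon, ``length_not_multiple_of_3`` for frame errors, and
    ``duplicate_name`` when a gene name is annotated with more than two
    CDS copies (two copies are the expected IR duplication).
    """
    findings: list[CheckFinding] = []
    cds = record.features_of_kind("CDS")
    if not cds:
        return [CheckFinding(record.id, "", "parse_warning",
                             "record has no CDS features", "warning")]
    for f in cds:
        seq = extract_feature_sequence(record, f)
        name = f.name or "<unnamed>"
        if len(seq) % 3 != 0:
            findings.append(CheckFinding(
                record.id, name, "length_not_multiple_of_3",
                f"spliced length {len(seq)} is not a multiple of 3", "error"))
        codons = _codons(seq)
        if not codons:
            continue
        if codons[0] != "ATG":
            findings.append(CheckFinding(
                record.id, name, "non_atg_start",
                f"first codon is {codons[0]}", "warning"))
        if codons[-1] not in STOP_CODONS:
            findings.append(CheckFinding(
                record.id, name, "missing_stop",
                f"final codon is {codons[-1]}", "error"))
        internal = [i for i, c in enumerate(codons[:-1]) if c in STOP_CODONS]
        if internal:
            findings.append(CheckFinding(
                record.id, name, "internal_stop",
                f"in-frame stop at codon(s) {internal}", "error"))
    counts: dict[str, int] = {}
    for f in cds:
        counts[f.name] = counts.get(f.name, 0) + 1
    for name, c in sorted(counts.items()):
        if c > 2:
            findings.append(CheckFinding(
                record.id, name, "duplicate_name",
                f"gene annotated with {c} CDS copies", "warning"))
    return findings


@dataclass(frozen=True)
class AnnotationDiff:
    """Gene-name set differences between a query and a reference record."""

    query_only: frozenset[str]
    reference_only: frozenset[str]
    differing: tuple[tuple[str, str, str, str], ...]
    # (gene, field, query value, reference value)


def compare_annotations(query: GenomeRecord,
                        reference: GenomeRecord) -> AnnotationDiff:
    """Diff two records by gene name; shared genes are additionally
    compared on exon-part count and strand."""

    def gene_map(rec: GenomeRecord) -> dict[str, FeatureAnnotation]:
        return {f.name: f for f in rec.genes() if f.name}

    q, r = gene_map(query), gene_map(reference)
    differing: list[tuple[str, str, str, str]] = []
    for name in sorted(set(q) & set(r)):
        qf, rf = q[name], r[name]
        if qf.n_exons != rf.n_exons:
            differing.append((name, "part_count",
                              str(qf.n_exons), str(rf.n_exons)))
        if qf.strand != rf.strand:
            differing.append((name, "strand", qf.strand, rf.strand))
    return AnnotationDiff(
        query_only=frozenset(set(q) - set(r)),
        reference_only=frozenset(set(r) - set(q)),
        differing=tuple(differing),
    )


@dataclass
class GenomeStats:
    """Headline statistics of one annotated plastome."""

    record_id: str
    total_genes: int
    unique_genes: int
    class_counts: dict[str, int]  # protein_coding / tRNA / rRNA / other
    exon_counts: dict[str, int]  # gene name -> exon count (max over copies)
    intron_counts: dict[str, int]
    gc_overall: float
    gc_by_region: dict[str, float] = field(default_factory=dict)

    def to_tsv(self) -> str:
        lines = [
            f"record\t{self.record_id}",
            f"total_genes\t{self.total_genes}",
            f"unique_genes\t{self.unique_genes}",
        ]
        for cls, n in sorted(self.class_counts.items()):
            lines.append(f"genes_{cls}\t{n}")
        lines.append(f"gc_overall\t{self.gc_overall:.4f}")
        for region, gc in self.gc_by_region.items():
            lines.append(f"gc_{region}\t{gc:.4f}")
        multi = {g: e for g, e in sorted(self.exon_counts.items()) if e > 1}
        for g, e in multi.items():
            lines.append(f"exons\t{g}\t{e}\t{self.intron_counts[g]}")
        return "\n".join(lines) + "\n"


def _exon_feature_for(record: GenomeRecord,
                      gene: FeatureAnnotation) -> FeatureAnnotation:
    """The feature carrying a gene's exon structure: its CDS/tRNA/rRNA of
    the same name, else the gene feature itself."""
    for kind in ("CDS", "tRNA", "rRNA"):
        f = record.feature_by_name(kind, gene.name)
        if f is not None:
            return f
    return gene


def summarize_genome(record: GenomeRecord,
                     structure=None) -> GenomeStats:
    """Gene counts by class, per-gene exon/intron counts, and GC content
    (per quadripartite region when ``structure`` is given).

    IR-duplicated genes (same name annotated twice) count once in the
    unique-gene tally.
    """
    genes = record.genes()
    cds_names = {f.name for f in record.features_of_kind("CDS")}
    trna_names = {f.name for f in record.features_of_kind("tRNA")}
    rrna_names = {f.name for f in record.features_of_kind("rRNA")}
    class_counts = {"protein_coding": 0, "tRNA": 0, "rRNA": 0, "other": 0}
    for g in genes:
        if g.name in cds_names:
            class_counts["protein_coding"] += 1
        elif g.name in trna_names:
            class_counts["tRNA"] += 1
        elif g.name in rrna_names:
            class_counts["rRNA"] += 1
        else:
            class_counts["other"] += 1
    exon_counts: dict[str, int] = {}
    for g in genes:
        n = _exon_feature_for(record, g).n_exons
        exon_counts[g.name] = max(exon_counts.get(g.name, 0), n)
    intron_counts = {g: max(0, e - 1) for g, e in exon_counts.items()}
    gc_by_region: dict[str, float] = {}
    if structure is not None:
        gc_by_region = {
            r.name: record.gc_fraction(r.start, r.length)
            for r in structure.regions()
        }
    return GenomeStats(
        record_id=record.id,
        total_genes=len(genes),
        unique_genes=len({g.name for g in genes}),
        class_counts=class_counts,
        exon_counts=exon_counts,
        intron_counts=intron_counts,
        gc_overall=record.gc_fraction(),
        gc_by_region=gc_by_region,
    )
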