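"""Shared-CDS extraction and supermatrix construction for phylogenomics.

Genes present single-copy in every input genome are collected into
per-gene sequence sets (nucleotide CDS or table-11 translations); after
external alignment the per-gene alignments are concatenated in
alphabetical gene order into a supermatrix with a RAxML-style partition
table.  IR-duplicated genes with identical copies deduplicate silently;
copies that differ drop the gene with a warning, keeping the matrix
valid.  Alignment, model selection and tree inference are delegated to
external programs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio.Seq import Seq

from plastkit.genome_model import (
    GenomeRecord,
    PlastkitError,
    extract_feature_sequence,
    fasta_text,
)
from plastkit.quadripartite import adjust_sequence

__all__ = [
    "GeneMatrixSet",
    "Supermatrix",
    "extract_shared_cds",
    "concatenate_matrix",
    "merge_whole_genomes",
]


def translate_cds(seq: str) -> str:
    """Table-11 translation with the terminal stop trimmed."""
    prot = str(Seq(seq).translate(table=11))
    return prot[:-1] if prot.endswith("*") else prot


@dataclass
class GeneMatrixSet:
    """Per-gene sequences across records: gene -> [(record id, seq), ...],
    one entry per input record, in input order."""

    genes: dict[str, list[tuple[str, str]]]
    molecule: str  # "CDS" | "protein"

    def gene_names(self) -> list[str]:
        return sorted(self.genes)


def _cds_by_name(record: GenomeRecord) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for f in record.features_of_kind("CDS"):
        if f.name:
            out.setdefault(f.name, []).append(
                extract_feature_sequence(record, f))
    return out


def _has_internal_stop(seq: str) -> bool:
    prot = str(Seq(seq[: len(seq) - len(seq) % 3]).translate(table=11))
    return "*" in prot[:-1]


def extract_shared_cds(records: list[GenomeRecord],
                       molecule: str = "CDS") -> GeneMatrixSet:
    """Genes with exactly one distinct CDS sequence in every record.

    In ``protein`` mode sequences are table-11 translations (terminal stop
    trimmed); a gene with an internal stop in any record is dropped from
    protein mode with a warning.
    """
    if molecule not in ("CDS", "protein"):
        raise ValueError(f"unknown molecule {molecule!r}")
    if len(records) < 2:
        raise PlastkitError("need at least 2 records")
    maps = [_cds_by_name(rec) for rec in records]
    shared = set(maps[0])
    for m in maps[1:]:
        shared &= set(m)
    genes: dict[str, list[tuple[str, str]]] = {}
    for name in sorted(shared):
        rows: list[tuple[str, str]] = []
        ok = True
        for rec, m in zip(records, maps):
            distinct = set(m[name])
            if len(distinct) != 1:
                warnings.warn(
                    f"gene {name!r}: divergent copies in record "
                    f"{rec.id!r}; dropped")
                ok = False
                break
            rows.append((rec.id, m[name][0]))
        if not ok:
            continue
        if molecule == "protein":
            if any(_has_internal_stop(s) for _, s in rows):
                warnings.warn(
                    f"gene {name!r}: internal stop codon; dropped from "
                    "protein mode")
                continue
            rows = [(rid, translate_cds(s)) for rid, s in rows]
        genes[name] = rows
    if not genes:
        raise PlastkitError("no shared single-copy CDS across records")
    return GeneMatrixSet(genes=genes, molecule=molecule)


@dataclass
class Supermatrix:
    """Concatenated aligned genes with a 1-based inclusive partition table."""

    rows: list[tuple[str, str]]  # (record id, concatenated sequence)
    partitions: list[tuple[str, int, int]]  # (gene, first col, last col)

    def to_fasta(self) -> str:
        return fasta_text(self.rows)

    def to_phylip(self) -> str:
        """Relaxed PHYLIP: names of any length, space-separated."""
        n = len(self.rows)
        length = len(self.rows[0][1]) if self.rows else 0
        width = max(len(rid) for rid, _ in self.rows) + 2
        lines = [f" {n} {length}"]
        for rid, seq in self.rows:
            lines.append(f"{rid.ljust(width)}{seq}")
        return "\n".join(lines) + "\n"

    def partition_text(self, datatype: str = "DNA") -> str:
        """RAxML-style partition file."""
        return "".join(
            f"{datatype}, {gene} = {a}-{b}\n"
            for gene, a, b in self.partitions
        )

    def split(self) -> dict[str, list[tuple[str, str]]]:
        """Recover each gene alignment from the partition table."""
        out: dict[str, list[tuple[str, str]]] = {}
        for gene, a, b in self.partitions:
            out[gene] = [(rid, seq[a - 1:b]) for rid, seq in self.rows]
        return out


def concatenate_matrix(aligned: dict[str, list[tuple[str, str]]],
                       ) -> Supermatrix:
    """Concatenate per-gene alignments (gene -> [(id, aligned seq), ...])
    in alphabetical gene order.

    Every gene must cover the same id set; rows within a gene must be
    equal length.  Output is deterministic: alphabetical genes, ids in
    the order of the first gene's alignment.
    """
    if not aligned:
        raise PlastkitError("no gene alignments given")
    gene_names = sorted(aligned)
    id_order = [rid for rid, _ in aligned[gene_names[0]]]
    id_set = set(id_order)
    for g in gene_names:
        ids = {rid for rid, _ in aligned[g]}
        if ids != id_set:
            raise PlastkitError(
                f"gene {g!r} id set {sorted(ids)} does not match "
                f"{sorted(id_set)}")
        if len({len(s) for _, s in aligned[g]}) != 1:
            raise PlastkitError(f"gene {g!r} rows differ in length")
    parts: dict[str, list[str]] = {rid: [] for rid in id_order}
    partitions: list[tuple[str, int, int]] = []
    col = 1
    for g in gene_names:
        seqs = dict(aligned[g])
        glen = len(next(iter(seqs.values())))
        for rid in id_order:
            parts[rid].append(seqs[rid])
        partitions.append((g, col, col + glen - 1))
        col += glen
    rows = [(rid, "".join(parts[rid])) for rid in id_order]
    return Supermatrix(rows=rows, partitions=partitions)


def merge_whole_genomes(records: list[GenomeRecord],
                        adjust: bool = True,
                        seed_length: int = 1000) -> str:
    """Multi-FASTA of complete genomes, each first normalized to canonical
    (LSC-first) orientation when its structure is detectable."""
    if len(records) < 2:
        raise PlastkitError("need at least 2 records")
    ids = [r.id for r in records]
    dups = sorted({i for i in ids if ids.count(i) > 1})
    if dups:
        raise PlastkitError(f"duplicate record ids: {dups}")
    entries = []
    for rec in records:
        if adjust:
            from plastkit.quadripartite import StructureNotFound
            try:
                rec = adjust_sequence(rec, "LSC", seed_length=seed_length)
            except StructureNotFound:
                pass
        entries.append((rec.id, rec.seq))
    return fasta_text(entries)
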