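"""Relative synonymous codon usage (RSCU).

RSCU for a codon c in a synonym family F is the observed count divided by
the count expected if all members of F were used equally:

    RSCU(c) = x_c / ( (sum over c' in F of x_c') / |F| )

so every family's RSCU values sum to its size |F| whenever the family was
observed at all.  Codons are pooled over a filtered CDS set: sequences
shorter than ``min_length``, out of frame, not starting with ATG, or
duplicating an already-seen gene name (the IR copy) are excluded before
counting; the terminal stop codon of each retained CDS is trimmed.  Stop
codons are excluded from the table; single-codon families (Met/Trp under
translation table 11) are included with RSCU trivially 1.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from Bio.Data.CodonTable import unambiguous_dna_by_id

from plastkit.genome_model import (
    GenomeRecord,
    PlastkitError,
    extract_feature_sequence,
)

__all__ = ["RSCURow", "RSCUTable", "collect_cds_for_rscu", "compute_rscu"]

DEFAULT_MIN_CDS_LENGTH = 300


@dataclass(frozen=True)
class RSCURow:
    codon: str
    amino_acid: str
    family_size: int
    count: int
    rscu: float
    family_unobserved: bool = False


@dataclass
class RSCUTable:
    """Per-codon counts and RSCU values for one pooled CDS set."""

    rows: list[RSCURow]
    n_cds: int
    table_id: int = 11

    def by_codon(self) -> dict[str, RSCURow]:
        return {r.codon: r for r in self.rows}

    def family_sums(self) -> dict[str, float]:
        sums: dict[str, float] = {}
        for r in self.rows:
            sums[r.amino_acid] = sums.get(r.amino_acid, 0.0) + r.rscu
        return sums

    def to_tsv(self) -> str:
        lines = ["codon\tamino_acid\tcount\trscu"]
        for r in sorted(self.rows, key=lambda r: (r.amino_acid, r.codon)):
            lines.append(f"{r.codon}\t{r.amino_acid}\t{r.count}\t{r.rscu:.4f}")
        return "\n".join(lines) + "\n"


def collect_cds_for_rscu(record: GenomeRecord,
                         min_length: int = DEFAULT_MIN_CDS_LENGTH,
                         ) -> list[str]:
    """Spliced, strand-resolved CDS passing the RSCU filters.

    Drops CDS shorter than ``min_length`` bp, with length not a multiple
    of 3, not starting with ATG, or repeating a gene name already kept
    (the first occurrence wins).  Raises if nothing survives, reporting
    why each candidate was dropped.
    """
    kept: list[str] = []
    seen: set[str] = set()
    dropped: list[str] = []
    cds = record.features_of_kind("CDS")
    if not cds:
        raise PlastkitError(f"record {record.id!r} has no CDS features")
    for f in cds:
        seq = extract_feature_sequence(record, f)
        name = f.name or "<unnamed>"
        if name in seen:
            dropped.append(f"{name}: duplicate gene name")
            continue
        if len(seq) < min_length:
            dropped.append(f"{name}: length {len(seq)} < {min_length}")
            continue
        if len(seq) % 3 != 0:
            dropped.append(f"{name}: length {len(seq)} not a multiple of 3")
            continue
        if not seq.startswith("ATG"):
            dropped.append(f"{name}: does not start with ATG")
            continue
        seen.add(name)
        kept.append(seq)
    if not kept:
        raise PlastkitError(
            "no CDS passed the RSCU filters:\n  " + "\n  ".join(dropped))
    return kept


def _synonym_families(table_id: int) -> dict[str, list[str]]:
    table = unambiguous_dna_by_id[table_id]
    fam: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        fam.setdefault(aa, []).append(codon)
    return fam


def compute_rscu(cds_set: list[str], table_id: int = 11) -> RSCUTable:
    """Pool codons over a CDS set and compute RSCU per codon.

    Each sequence must be a multiple of 3 long; the final codon is trimmed
    when it is a stop.  Families never observed get RSCU 0 with the
    ``family_unobserved`` flag set.
    """
    table = unambiguous_dna_by_id[table_id]
    stops = set(table.stop_codons)
    counts: Counter[str] = Counter()
    for seq in cds_set:
        seq = seq.upper()
        if len(seq) % 3 != 0:
            raise PlastkitError(
                f"CDS length {len(seq)} is not a multiple of 3")
        codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
        if codons and codons[-1] in stops:
            codons = codons[:-1]
        counts.update(c for c in codons if set(c) <= set("ACGT"))
    rows: list[RSCURow] = []
    for aa, codons in sorted(_synonym_families(table_id).items()):
        k = len(codons)
        total = sum(counts.get(c, 0) for c in codons)
        for c in sorted(codons):
            x = counts.get(c, 0)
            if total == 0:
                rows.append(RSCURow(c, aa, k, 0, 0.0, family_unobserved=True))
            else:
                rows.append(RSCURow(c, aa, k, x, x * k / total))
    return RSCUTable(rows=rows, n_cds=len(cds_set), table_id=table_id)
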