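"""Nucleotide diversity (π) per gene and intergenic spacer.

π is the Nei–Li per-site diversity of an alignment: the mean proportion
of differing sites over all sequence pairs,

    π = Σ_{i<j} d_ij / ( C(n, 2) · L' )

where d_ij counts differing columns between rows i and j and L' is the
number of columns retained after complete deletion (any column containing
a gap or N is excluded entirely, the DnaSP default; pairwise deletion is
available via a flag).

The batch pipeline extracts every shared single-copy gene and IGS region
across a set of annotated genomes, aligns each region via an external
command template (the package never implements multiple alignment), and
reports π per region ordered by its genomic location on the first record
in canonical (LSC-first) orientation.
"""

from __future__ import annotations

import os
import subprocess
import tempfile
from dataclasses import dataclass

import numpy as np

from plastkit.genome_model import (
    FeatureAnnotation,
    GenomeRecord,
    PlastkitError,
    extract_feature_sequence,
    read_fasta,
    write_fasta,
)
from plastkit.quadripartite import StructureNotFound, adjust_sequence

__all__ = [
    "RegionSequence",
    "PiResult",
    "extract_regions",
    "collect_shared_regions",
    "compute_pi",
    "pi_pipeline",
    "pi_from_aligned_dir",
    "write_pi_tsv",
]


@dataclass(frozen=True)
class RegionSequence:
    """A named gene or intergenic-spacer subsequence of one genome."""

    name: str
    kind: str  # "gene" | "IGS"
    start: int
    end: int  # end may exceed genome length for origin-wrapping regions
    seq: str
    record_id: str

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class PiResult:
    name: str
    kind: str
    n: int
    alignment_length: int
    variable_sites: int
    pi: float
    midpoint: int | None = None


def _gene_spans(record: GenomeRecord) -> list[tuple[FeatureAnnotation, int, int]]:
    out = []
    for g in record.genes():
        s, e = g.span(record.length)
        out.append((g, s, e))
    out.sort(key=lambda t: (t[1], t[2]))
    return out


def extract_regions(record: GenomeRecord) -> list[RegionSequence]:
    """One region per gene (spliced, strand-resolved) plus one per
    non-empty gap between consecutive gene spans in circular order.

    IGS regions are named "geneA-geneB" after the flanking genes in
    genomic order; overlapping genes produce no IGS between them.
    """
    spans = _gene_spans(record)
    if len(spans) < 2:
        raise PlastkitError(
            f"record {record.id!r} has fewer than 2 annotated genes")
    n = record.length
    regions: list[RegionSequence] = []
    for g, s, e in spans:
        regions.append(RegionSequence(
            name=g.name, kind="gene", start=s, end=e,
            seq=extract_feature_sequence(record, g), record_id=record.id))
    # gaps between consecutive spans, circularly; a gene wholly inside the
    # previous one never opens a gap (track the running rightmost end)
    frontier = spans[0][2]
    prev_name = spans[0][0].name
    for g, s, e in spans[1:]:
        if s > frontier:
            regions.append(RegionSequence(
                name=f"{prev_name}-{g.name}", kind="IGS",
                start=frontier, end=s,
                seq=record.seq[frontier:s], record_id=record.id))
        if e > frontier:
            frontier = e
            prev_name = g.name
    # wrap-around gap from the last frontier to the first gene
    first_g, first_s, _ = spans[0]
    wrap_len = (first_s - frontier) % n
    if record.circular and wrap_len > 0 and frontier <= n:
        gap_start = frontier % n
        seq = (record.seq[gap_start:] + record.seq[:first_s]
               if gap_start + wrap_len > n
               else record.seq[gap_start:gap_start + wrap_len])
        regions.append(RegionSequence(
            name=f"{prev_name}-{first_g.name}", kind="IGS",
            start=frontier, end=frontier + wrap_len,
            seq=seq, record_id=record.id))
    return regions


def collect_shared_regions(records: list[GenomeRecord],
                           ) -> dict[str, list[RegionSequence]]:
    """Regions present exactly once in every record (shared single-copy),
    keyed by region name, values in input record order.

    Regions duplicated within any record (IR copies) are excluded, as are
    regions missing from any record.
    """
    if len(records) < 2:
        raise PlastkitError("need at least 2 records")
    per_record = []
    for rec in records:
        regions = extract_regions(rec)
        by_name: dict[str, list[RegionSequence]] = {}
        for r in regions:
            by_name.setdefault(r.name, []).append(r)
        per_record.append(by_name)
    shared = set(per_record[0])
    for by_name in per_record[1:]:
        shared &= set(by_name)
    out: dict[str, list[RegionSequence]] = {}
    for name in sorted(shared):
        if all(len(by_name[name]) == 1 for by_name in per_record):
            out[name] = [by_name[name][0] for by_name in per_record]
    return out


def compute_pi(alignment: list[str], complete_deletion: bool = True,
               name: str = "", kind: str = "",
               midpoint: int | None = None) -> PiResult:
    """Nei–Li nucleotide diversity of an aligned set of sequences.

    With ``complete_deletion`` (default), any column containing a gap or
    N is excluded entirely before counting pairwise differences;
    otherwise sites are compared pairwise wherever both rows are ungapped.
    """
    n = len(alignment)
    if n < 2:
        raise PlastkitError("need at least 2 sequences")
    lengths = {len(s) for s in alignment}
    if len(lengths) != 1:
        raise PlastkitError(f"unequal row lengths: {sorted(lengths)}")
    arr = np.array([list(s.upper()) for s in alignment])
    missing = (arr == "-") | (arr == "N")
    n_pairs = n * (n - 1) // 2
    if complete_deletion:
        keep = ~missing.any(axis=0)
        sub = arr[:, keep]
        L = sub.shape[1]
        if L == 0:
            raise PlastkitError("no ungapped columns")
        diffs = 0
        for i in range(n):
            for j in range(i + 1, n):
                diffs += int((sub[i] != sub[j]).sum())
        pi = diffs / (n_pairs * L)
        variable = int((sub != sub[0]).any(axis=0).sum())
        aln_len = L
    else:
        total = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                ok = ~missing[i] & ~missing[j]
                li = int(ok.sum())
                if li == 0:
                    raise PlastkitError("no comparable sites for a pair")
                total += (arr[i][ok] != arr[j][ok]).sum() / li
        pi = total / n_pairs
        ok_any = ~missing.any(axis=0)
        variable = int((arr[:, ok_any] != arr[0, ok_any]).any(axis=0).sum())
        aln_len = arr.shape[1]
    return PiResult(name=name, kind=kind, n=n, alignment_length=aln_len,
                    variable_sites=variable, pi=float(pi), midpoint=midpoint)


def _run_aligner(template: str, in_path: str, out_path: str) -> None:
    cmd = template.format(**{"in": in_path, "out": out_path})
    proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
    if proc.returncode != 0:
        raise PlastkitError(
            f"aligner command failed ({proc.returncode}): {cmd}\n{proc.stderr}")


def pi_pipeline(records: list[GenomeRecord],
                aligner: str | None = None,
                out_dir: str | None = None,
                complete_deletion: bool = True) -> list[PiResult]:
    """Batch π over all shared single-copy gene and IGS regions.

    ``aligner`` is a shell command template with ``{in}`` and ``{out}``
    placeholders (e.g. ``"mafft --auto {in} > {out}"``).  When omitted,
    region sequences must already be equal-length (no-indel data or
    pre-aligned input).  Results are ordered by midpoint coordinate on the
    first record after LSC-mode adjustment; per-region FASTAs are written
    under ``out_dir`` when given.
    """
    if len(records) < 2:
        raise PlastkitError("need at least 2 records")
    try:
        ref = adjust_sequence(records[0], "LSC")
    except StructureNotFound:
        ref = records[0]
    ref_midpoints = {r.name: r.midpoint for r in extract_regions(ref)}
    shared = collect_shared_regions(records)
    if not shared:
        raise PlastkitError("no shared single-copy regions across records")
    region_dir = None
    if out_dir is not None:
        region_dir = os.path.join(out_dir, "regions")
        os.makedirs(region_dir, exist_ok=True)
    results: list[PiResult] = []
    kinds = {name: regs[0].kind for name, regs in shared.items()}
    with tempfile.TemporaryDirectory() as tmp:
        for name, regs in shared.items():
            entries = [(r.record_id, r.seq) for r in regs]
            safe = name.replace("/", "_")
            fasta_path = os.path.join(region_dir or tmp, f"{safe}.fasta")
            write_fasta(entries, fasta_path)
            if aligner is not None:
                aligned_path = os.path.join(tmp, f"{safe}.aln.fasta")
                _run_aligner(aligner, fasta_path, aligned_path)
                rows = [s for _, s in read_fasta(aligned_path)]
            else:
                rows = [s for _, s in entries]
                if len({len(s) for s in rows}) != 1:
                    raise PlastkitError(
                        f"region {name!r} sequences differ in length and no "
                        "aligner was given; pass an aligner command template "
                        "or pre-aligned input")
            results.append(compute_pi(
                rows, complete_deletion=complete_deletion, name=name,
                kind=kinds[name], midpoint=ref_midpoints.get(name)))
    results.sort(key=lambda r: (r.midpoint if r.midpoint is not None else -1))
    return results


def pi_from_aligned_dir(path: str,
                        complete_deletion: bool = True) -> list[PiResult]:
    """π per pre-aligned FASTA file in a directory (bypasses extraction)."""
    names = sorted(n for n in os.listdir(path)
                   if n.lower().endswith((".fa", ".fasta", ".aln", ".fas")))
    if not names:
        raise PlastkitError(f"no FASTA alignments found in {path}")
    results = []
    for fname in names:
        rows = [s for _, s in read_fasta(os.path.join(path, fname))]
        region = os.path.splitext(fname)[0]
        results.append(compute_pi(rows, complete_deletion=complete_deletion,
                                  name=region,
                                  kind="IGS" if "-" in region else "gene"))
    return results


def write_pi_tsv(results: list[PiResult], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("region\tkind\tn\taln_len\tvar_sites\tpi\tmidpoint\n")
        for r in results:
            mid = "" if r.midpoint is None else str(r.midpoint)
            fh.write(f"{r.name}\t{r.kind}\t{r.n}\t{r.alignment_length}\t"
                     f"{r.variable_sites}\t{r.pi:.6f}\t{mid}\n")
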