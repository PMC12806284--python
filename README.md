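# plastkit

A toolkit for comparative analysis of chloroplast genomes (plastomes):
annotation quality control, quadripartite-structure detection and
sequence normalization, batch nucleotide diversity, codon-usage bias,
microsatellite and long-repeat detection with genomic-context
localization, phylogenetic matrix preparation, and format conversion.
It is aimed at researchers assembling and comparing plastomes who need
one consistent, scriptable pipeline from annotated GenBank files to
publication-ready tables.

## The problem and the methods

Plastomes are circular molecules of ~120–170 kb with a canonical
quadripartite layout: a large single-copy region (LSC), inverted repeat
b (IRb), a small single-copy region (SSC), and inverted repeat a (IRa),
where IRa is the exact reverse complement of IRb. Assemblies linearize
the circle at arbitrary positions and orientations, so before any
comparative analysis the four regions must be located and the sequence
rotated into a canonical LSC-first orientation.

The core methods:

- **Quadripartite detection** — seed-and-extend inverted-repeat search
  on circular coordinates. Every *k*-mer (default *k* = 1000 bp) is
  indexed by rolling hash and matched against the reverse-complement
  windows; verified seed pairs are extended base-by-base under exact
  match until the identity breaks or the arms would collide. Any IR
  with arms ≥ *k* is guaranteed to be found at any rotation. Single-copy
  spans between the arms are labeled LSC (longer) and SSC (shorter).
- **Nucleotide diversity** — Nei–Li π per region:
  π = Σ_{i<j} d_ij / (C(n,2)·L′), where d_ij counts differing columns
  between rows *i* and *j* and L′ is the column count after complete
  deletion of gap/N columns. Shared single-copy gene and intergenic
  spacer (IGS) regions are extracted across all genomes, aligned by an
  external aligner (e.g. MAFFT), and reported ordered by genomic
  location.
- **RSCU** — relative synonymous codon usage,
  RSCU(c) = x_c · |F| / Σ_{c′∈F} x_{c′} for codon *c* in synonym family
  *F* (translation table 11), computed over CDS filtered by length,
  frame, ATG start, and IR-duplicate removal.
- **SSRs** — perfect microsatellites of unit length 1–6, with MISA-style
  minimum unit counts 10/6/5/4/4/4 (mono → hexa); motifs are canonical
  under rotation and reverse complement, and each hit is localized to
  exon, intron, or IGS.
- **LSRs** — dispersed exact repeat pairs of four types (forward,
  palindromic, reverse, complement) with arms ≥ 30 bp by default, found
  by seed-and-extend and localized the same way.
- **Phylogenetic preparation** — shared single-copy CDS (or table-11
  protein) sets across genomes, and concatenation of per-gene alignments
  into a supermatrix with a RAxML-style partition table.

A deterministic synthetic-plastome generator (with a machine-readable
truth ledger) provides fully verifiable inputs for all of the above; no
downloads are required anywhere in the package or its tests.

## Worked example

Generate a synthetic plastome and analyze it:

```bash
plastkit make-fixture --seed 42 -o fx
plastkit ir fx/synthplast1.gb
```

```
record	region	start	end	length
synthplast1	LSC	1	20000	20000
synthplast1	IRb	20001	22500	2500
synthplast1	SSC	22501	30500	8000
synthplast1	IRa	30501	33000	2500
# starts_at_LSC	True
# ssc_forward	True
```

The four regions tile the 33 kb circle exactly once; coordinates are
1-based inclusive, the genome already starts at the LSC, and the SSC is
in its forward orientation (the ndhF convention). Microsatellites with
their genomic context:

```bash
plastkit ssr fx/synthplast1.gb
```

```
motif	count	start	end	context	name
A	12	1020	1031	IGS	psbA-trnH-GUG
AT	7	2446	2459	IGS	matK-atpF
AAG	5	3069	3083	intron	atpF
AAG	5	24783	24797	exon	ndhF
AATT	5	26338	26357	IGS	ccsA-trnV-GAC
```

Each row is one maximal perfect repeat: e.g. `A 12` is a 12 bp poly-A in
the psbA–trnH spacer, and the `AAG 5` at 24783 lies inside the ndhF
coding sequence (the motif is reported canonically, so the genomic
CTT-repeat on the minus strand collapses to AAG). `plastkit info`
summarizes the annotation — this genome carries 11 gene features of
which 9 are unique (the rRNA and tRNA inside the IR are present twice):

```
total_genes	11
unique_genes	9
genes_protein_coding	6
genes_rRNA	2
genes_tRNA	3
gc_overall	0.5033
```

Other subcommands: `gbcheck` (CDS start/stop/frame findings, annotation
diff against a reference), `seq --mode LSC|SSC|RP` (orientation
normalization), `pi` (batch diversity over a directory), `rscu`, `lsr`,
`phy`/`phy-concat` (supermatrix), `merge`, and
`convert --to tbl|fasta|mvista`.

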