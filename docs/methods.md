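# Methods

This note documents the models, conventions and numerical choices behind
plastkit, what the synthetic data generator does and does not emulate,
and the known limitations.

## Coordinate model

All internal coordinates are 0-based half-open; GenBank's 1-based
inclusive convention (and the tbl writer's) is converted only at the I/O
boundary. Plastomes are circular by default (a GenBank `linear` topology
disables origin-spanning logic). A feature part that spans the origin is
stored split into two in-range intervals linked as one logical part;
parts are kept in biological 5'→3' order, matching Biopython's
convention for `join`/`complement` locations, so feature extraction is a
uniform per-part concatenation with minus-strand parts
reverse-complemented. Rotation and whole-genome reverse complement remap
every feature exactly; extraction is invariant under both (property
tested over ≥100 random rotations).

Gene identity is the `gene` qualifier, case-sensitive after whitespace
trimming; a CDS without one falls back to `locus_tag`. Ambiguity codes
other than N are accepted on read but treated as N by every analysis.

## Quadripartite structure detection

Detection is seed-and-extend on circular coordinates with an exact-match
extension (mismatch tolerance 0). Every circular window of
`seed_length` bp (default 1000) is hashed with a rolling polynomial hash
mod 2^61−1; windows of the reverse-complement strand are looked up in
that index, candidate pairs are verified by direct string comparison
(hash collisions are thereby harmless), and each verified pair is
extended outward base-by-base while the inverted-repeat identity holds
and the arms remain disjoint. Because all window positions are indexed
— rather than a sampled subset — an IR with arms ≥ `seed_length` is
found at any rotation; this full indexing was chosen precisely so that
the guarantee coincides with the advertised seed size. Windows
containing N never match, and extension stops at N.

Among maximal candidates the longest wins; ties are broken by the pair
whose arm midpoints are most distant on the circle. The two single-copy
gaps become LSC (longer) and SSC (shorter); IRb is the repeat that
follows the LSC clockwise. A detected structure always satisfies, by
construction and re-checked at run time: the four regions tile the
circle exactly once, and sequence(IRa) == revcomp(sequence(IRb))
bit-exactly. Sequences without an IR of at least seed length return
"no structure" rather than an arbitrary segmentation; arms that leave
no single-copy gap raise a degenerate-genome error.

"SSC forward" is operationalized as: ndhF (or, absent ndhF, the
majority of SSC genes) lies on the minus strand. This matches the
common deposition convention but is stated explicitly because the
orientation of the SSC is intrinsically arbitrary. Adjustment modes:
`LSC` rotates the LSC start to position 0; `SSC` additionally
reverse-complements the SSC span in place when it is not forward
(features wholly inside are remapped; a feature straddling the SSC
boundary raises rather than being silently corrupted); `RP`
reverse-complements the whole genome and then rotates to the LSC start.
Adjustment is idempotent and re-detection of an adjusted genome
reproduces the same region lengths.

## Nucleotide diversity

π is the Nei–Li per-site diversity: with complete deletion (default,
DnaSP's convention) every column containing a gap or N is removed, then
π = Σ_{i<j} d_ij / (C(n,2)·L′). Pairwise deletion is available via a
flag. L′ = 0 is an error, not a zero. The batch pipeline keeps only
regions present exactly once in every genome (IR-duplicated regions are
excluded to avoid double-weighting), aligns each region through a
user-supplied shell template — the package never implements multiple
alignment — and orders results by the region midpoint on the first
input genome after LSC-mode adjustment, giving one consistent
coordinate axis for by-location plots. When no aligner is given,
sequences must already be equal length (pre-aligned or indel-free
data); that bypass is exact, not approximate.

## Codon usage

RSCU uses translation table 11 (plastid). CDS are filtered before
pooling: minimum length 300 bp (a CodonW-community convention, exposed
as a flag), length divisible by 3, ATG start, and one copy per gene
name (first occurrence wins, removing IR duplicates). The terminal stop
is trimmed; stop codons are excluded from the table; single-codon
families (Met, Trp) appear with RSCU trivially 1; a family never
observed reports RSCU 0 with an explicit flag rather than NaN. The
invariant Σ RSCU over a nonzero family = family size holds to 1e-9 and
is asserted in the tests.

## Repeat detection

SSR thresholds are interpreted as repeat *units*, MISA-style: minimum
10/6/5/4/4/4 units for unit lengths 1–6 (so 10 bp for mononucleotides
and 24 bp for hexanucleotides). The base-pair reading would make the
hexanucleotide minimum 4 bp — less than one unit — which settles the
interpretation. A hit is the left-anchored whole-unit prefix of a
maximal per-base tandem run: runs with a trailing partial unit are
truncated to whole units, and a run whose motif has a smaller period is
reported only under the smaller period's class. Motifs are canonical:
lexicographically smallest among all rotations of the motif and of its
reverse complement, making detection strand-symmetric. N never matches,
so no repeat crosses an N. The scanner is verified against an
exhaustive brute-force enumeration (zero set difference on seeded
random sequences).

LSRs are exact repeat pairs of four types — forward (identical),
palindromic (reverse complement), reverse, complement — found by
indexing all `min_arm`-mers (default 30 bp, REPuter-comparable) and
extending seed pairs under the type's pairing geometry. Arms are kept
disjoint: extension stops before the arms would overlap, so "maximal"
means maximal subject to non-overlap; self-matches of a segment with
itself are excluded, and seeds inside an already-found pair are skipped
via the pair's diagonal invariant. Coordinates are linear (detection
runs on the genome as linearized); on a canonically oriented plastome
the top palindromic hit is the IR itself. Mismatched (hamming > 0)
repeats are out of scope.

Context localization takes the hit's midpoint: exon if it falls in any
CDS/tRNA/rRNA part, else intron if inside a gene's span, else IGS named
"a-b" after the flanking genes in genomic order (priority exon > intron
> IGS when annotations overlap).

## Annotation QC and statistics

Every CDS is checked spliced and strand-resolved: non-ATG start
(warning — RNA-edited GTG/ACG starts are legitimate and are reported,
not rejected), missing stop, internal in-frame stop, and length not
divisible by 3 (errors). Stop codons follow table 11. The annotation
diff is by exact gene name (so trnfM-CAU vs trnM-CAU shows up as one
entry in each only-set); shared genes are additionally compared on exon
count and strand. Genome statistics count IR-duplicated names once in
the unique tally and read exon structure from the CDS/tRNA/rRNA feature
carrying the join, with intron count = exon count − 1.

## Synthetic data

The generator assembles LSC + IRb + SSC + IRa with IRa = revcomp(IRb)
exactly, genes as valid ORFs (with introns, a minus-strand SSC, and
IR-duplicated rRNA/tRNA genes), planted SSRs in exon/intron/IGS
contexts, and one planted 40 bp forward repeat pair. Default region
sizes are 20 kb / 2.5 kb / 8 kb (a deliberately scaled-down plastome
that keeps every structural property while making exhaustive oracles
affordable); a `plastome-like` preset (84/25/17 kb) exercises realistic
scale. Background sequence is screened by rejection sampling (cap 1000
attempts, then a hard error) against thresholds one unit below the SSR
ladder and against ≥25 bp internal repeats, and every segment junction
carries fixed 6 bp caps that cannot seed a tandem run; region junctions
are arranged so the planted IR cannot extend past its boundaries. After
assembly the genome is re-scanned with the package's own detectors and
generation fails loudly on any discrepancy with the ledger, so a
returned fixture's ground truth is always verifiable by inspection.

The population emitter applies independent per-site substitutions at
per-region rates (≤ 0.2), with no indels, no rearrangement, no codon
model, and no linkage — so π tests are alignment-free and the expected
pairwise difference rate has the closed form 2p(1−p) + (2/3)p² for two
sequences independently mutated from a common reference at rate p.
Real plastomes differ in ways the generator does not emulate: indels
and microinversions, IR boundary shifts, heterogeneous base
composition, RNA-edited starts, and trans-spliced genes (rps12).
Passing tests therefore demonstrate algorithmic correctness on clean
inputs, not robustness to annotation pathology.

## Numerical and problem-size choices

Rolling hashes use base 1315423911 mod 2^61−1 with verification by
string comparison, so a collision can cost time but never correctness.
The acceptance script runs the π parameter recovery at n = 6, L = 2000,
50 replicates (3 Monte-Carlo standard errors), the SSR oracle on 50
random 5 kb sequences, and the LSR oracle on ~800 bp planted sequences
with arms reduced to 12 bp — sizes chosen so the exhaustive oracles
stay exact while the whole run completes in seconds; the test suite
additionally runs the 200-sequence SSR oracle sweep. The trans-spliced
rps12 case is intentionally unhandled: parts are stored in file order
and surface in QC rather than being reassembled by guesswork.
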