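"""Deterministic synthetic plastomes with a machine-readable truth ledger.

The generator assembles a circular genome as LSC + IRb + SSC + IRa with
IRa the exact reverse complement of IRb, realistic gene content (valid
ORFs, tRNA/rRNA genes, introns, IR-duplicated genes, a minus-strand SSC),
planted microsatellites in exon/intron/IGS contexts, and one planted
long-repeat pair.  Background sequence is screened by rejection sampling
so that no accidental repeat reaches the detection thresholds, and every
inter-segment junction carries short fixed caps that cannot seed a
tandem run; the assembled genome is then verified against the ledger
with the package's own detectors, and generation fails loudly rather
than emitting a fixture whose truth is wrong.

All randomness flows from one explicit seed; the same seed yields a
byte-identical genome.  No indels, rearrangements, or codon models are
simulated — the population emitter applies independent per-site point
substitutions only, which keeps alignment-free π testing valid.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field

from plastkit.genome_model import (
    FeatureAnnotation,
    GenomeRecord,
    Part,
    PlastkitError,
    reverse_complement,
)
from plastkit.quadripartite import find_inverted_repeats
from plastkit.repeat_finder import canonical_motif, find_lsrs, find_ssrs

__all__ = [
    "GeneratorError",
    "PlastomeSpec",
    "TruthLedger",
    "generate_synthetic_plastome",
    "generate_population",
    "write_fixture",
    "PRESETS",
]


class GeneratorError(PlastkitError):
    """The requested synthetic genome could not be realized."""


# screening thresholds one unit below the detection ladder, so junction
# effects cannot promote a background run to a reportable SSR
_STRICT = {1: 9, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}

_CAP_L = "ACGTCA"
_CAP_R = "AGTCAG"

_STOPS = ("TAA", "TAG", "TGA")
_SENSE = [a + b + c
          for a in "ACGT" for b in "ACGT" for c in "ACGT"
          if a + b + c not in _STOPS]

_MAX_ATTEMPTS = 1000


@dataclass(frozen=True)
class GenePlan:
    name: str
    kind: str  # CDS | tRNA | rRNA
    strand: str
    exon_lens: tuple[int, ...]
    intron_lens: tuple[int, ...] = ()
    # (motif, count, codon offset) planted into the coding sequence;
    # single-exon CDS only
    exon_ssr: tuple[str, int, int] | None = None
    # (motif, count, intron index) planted into an intron; '+' strand only
    intron_ssr: tuple[str, int, int] | None = None


@dataclass(frozen=True)
class PlastomeSpec:
    """Region sizes and a seed; gene and repeat plans are fixed per preset."""

    lsc_len: int = 20000
    irb_len: int = 2500
    ssc_len: int = 8000
    seed: int = 42
    record_id: str = "synthplast1"
    detection_seed_length: int = 1000

    def __post_init__(self) -> None:
        if min(self.lsc_len, self.irb_len, self.ssc_len) <= 0:
            raise GeneratorError("region sizes must be positive")
        if self.irb_len < self.detection_seed_length:
            raise GeneratorError(
                f"IR length {self.irb_len} below the detection seed length "
                f"{self.detection_seed_length}")


PRESETS: dict[str, dict[str, int]] = {
    "small": {"lsc_len": 20000, "irb_len": 2500, "ssc_len": 8000},
    "plastome-like": {"lsc_len": 84000, "irb_len": 25000, "ssc_len": 17000},
}


@dataclass
class TruthLedger:
    """Everything planted into a synthetic genome, verifiable by direct
    inspection of the emitted sequence."""

    seed: int
    genome_length: int
    regions: dict[str, tuple[int, int]]  # name -> (start, length)
    genes: list[dict]
    ssrs: list[dict]
    lsrs: list[dict]
    population_rates: dict[str, float] | None = None

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=list)

    def ssr_tuples(self) -> set[tuple[str, int, int, int]]:
        return {(s["motif"], s["count"], s["start"], s["end"])
                for s in self.ssrs}

    def lsr_tuples(self) -> set[tuple[str, int, int, int]]:
        return {(r["type"], r["arm_length"], r["start1"], r["start2"])
                for r in self.lsrs}


# ---------------------------------------------------------------------------
# screened building blocks


def _rand(rng: random.Random, n: int) -> str:
    return "".join(rng.choices("ACGT", k=n))


def _clean(seq: str, lsr_screen: bool = True) -> bool:
    if find_ssrs(seq, _STRICT):
        return False
    if lsr_screen and len(seq) >= 60 and find_lsrs(seq, min_arm=25):
        return False
    return True


def _screened_igs(rng: random.Random, n: int) -> str:
    if n < 16:
        raise GeneratorError(f"IGS length {n} too short (minimum 16)")
    for _ in range(_MAX_ATTEMPTS):
        s = _CAP_L + _rand(rng, n - 12) + _CAP_R
        if _clean(s):
            return s
    raise GeneratorError("could not screen an IGS segment")


def _screened_flex(rng: random.Random, n: int, chunk: int = 3000) -> str:
    parts = []
    while n > 0:
        take = min(chunk, n)
        if n - take < 16 and n - take > 0:
            take = n  # avoid a trailing sliver below the minimum
            if take > chunk + 16:
                take = n - 16
        parts.append(_screened_igs(rng, take))
        n -= take
    return "".join(parts)


def _segment_with_insert(rng: random.Random, total_len: int, insert: str,
                         expected_ssrs: list[tuple[str, int, int, int]],
                         ) -> tuple[str, int]:
    """A capped segment containing ``insert`` at a fixed offset, accepted
    only when the strict SSR scan reports exactly ``expected_ssrs``
    (positions relative to the insert start)."""
    body = total_len - 12 - len(insert)
    if body < 4:
        raise GeneratorError(f"segment of {total_len} too short for insert")
    left_len = body // 2
    right_len = body - left_len
    offset = 6 + left_len
    want = sorted((m, c, offset + s, offset + e)
                  for m, c, s, e in expected_ssrs)
    for _ in range(_MAX_ATTEMPTS):
        s = (_CAP_L + _rand(rng, left_len) + insert +
             _rand(rng, right_len) + _CAP_R)
        got = sorted((h.motif, h.count, h.start, h.end)
                     for h in find_ssrs(s, _STRICT))
        if got == want and (len(s) < 60 or
                            not find_lsrs(s, min_arm=25)):
            return s, offset
    raise GeneratorError("could not screen a segment with a planted insert")


def _screened_orf(rng: random.Random, length: int,
                  plant: tuple[str, int, int] | None = None,
                  ) -> tuple[str, int | None]:
    """A valid ORF (ATG ... TAA, no internal stop) of ``length`` bp,
    optionally carrying a planted in-frame SSR; returns (sequence,
    planted start within the ORF or None)."""
    if length % 3 != 0 or length < 9:
        raise GeneratorError(f"ORF length {length} invalid")
    n_codons = length // 3 - 2
    planted_start = None
    plant_codons: list[str] = []
    if plant is not None:
        motif, count, cod_off = plant
        if (len(motif) * count) % 3 != 0:
            raise GeneratorError("planted exon SSR must be in-frame")
        run = motif * count
        plant_codons = [run[i:i + 3] for i in range(0, len(run), 3)]
        if any(c in _STOPS for c in plant_codons):
            raise GeneratorError("planted exon SSR contains a stop codon")
        if cod_off + len(plant_codons) > n_codons:
            raise GeneratorError("planted exon SSR outside the ORF")
        planted_start = 3 + 3 * cod_off
    for _ in range(_MAX_ATTEMPTS):
        codons = rng.choices(_SENSE, k=n_codons - len(plant_codons))
        if plant is not None:
            codons = codons[:plant[2]] + plant_codons + codons[plant[2]:]
        s = "ATG" + "".join(codons) + "TAA"
        got = sorted((h.motif, h.count, h.start, h.end)
                     for h in find_ssrs(s, _STRICT))
        if plant is None:
            want = []
            flanks_ok = True
        else:
            motif, count, _ = plant
            u = len(motif)
            run_len = u * count
            want = [(canonical_motif(motif), count, planted_start,
                     planted_start + run_len)]
            # the per-base tandem relation must break exactly at the run
            # ends; otherwise the left-anchored hit shifts once the gene
            # is placed on the minus strand (anchoring flips with strand)
            lo, hi = planted_start, planted_start + run_len
            flanks_ok = (s[lo - 1] != s[lo - 1 + u] and
                         s[hi] != s[hi - u])
        if got == want and flanks_ok and \
                (len(s) < 60 or not find_lsrs(s, min_arm=25)):
            return s, planted_start
    raise GeneratorError("could not screen an ORF")


def _screened_rna(rng: random.Random, n: int) -> str:
    return _screened_igs(rng, n)


# ---------------------------------------------------------------------------
# layout plans (the "small" architecture, scaled by flex IGS padding)


def _lsc_plan() -> list:
    return [
        ("igs", 300),
        ("gene", GenePlan("psbA", "CDS", "+", (600,))),
        ("igs_ssr", 250, "A", 12, "psbA-trnH-GUG"),
        ("gene", GenePlan("trnH-GUG", "tRNA", "+", (72,))),
        ("igs", 200),
        ("gene", GenePlan("matK", "CDS", "-", (900,))),
        ("igs_ssr", 260, "AT", 7, "matK-atpF"),
        ("gene", GenePlan("atpF", "CDS", "+", (144, 555), (700,),
                          intron_ssr=("TTC", 5, 0))),
        ("igs_lsr", 262, 1, "atpF-clpP"),
        ("gene", GenePlan("clpP", "CDS", "+", (69, 291, 228), (500, 400))),
        ("igs_flex",),
    ]


def _irb_plan(irb_len: int) -> list:
    if irb_len < 2100:
        # slim layout for genomes with a short inverted repeat
        return [
            ("igs", 150),
            ("gene", GenePlan("trnV-GAC", "tRNA", "+", (72,))),
            ("igs_flex",),
        ]
    return [
        ("igs", 150),
        ("gene", GenePlan("rrn16", "rRNA", "+", (1490,))),
        ("igs", 120),
        ("gene", GenePlan("trnV-GAC", "tRNA", "+", (72,))),
        ("igs_flex",),
    ]


def _ssc_plan() -> list:
    return [
        ("igs", 200),
        ("gene", GenePlan("ndhF", "CDS", "-", (2220,),
                          exon_ssr=("AAG", 5, 40))),
        ("igs_lsr", 342, 2, "ndhF-ccsA"),
        ("gene", GenePlan("ccsA", "CDS", "-", (960,))),
        ("igs_ssr", 250, "AATT", 5, "ccsA-trnV-GAC"),
        ("igs_flex",),
    ]


def _gene_length(plan: GenePlan) -> int:
    return sum(plan.exon_lens) + sum(plan.intron_lens)


def _item_length(item) -> int:
    if item[0] in ("igs", "igs_ssr", "igs_lsr"):
        return item[1]
    if item[0] == "gene":
        return _gene_length(item[1])
    raise ValueError(item)


def _build_gene(rng: random.Random, plan: GenePlan,
                ) -> tuple[str, list[tuple[int, int]], tuple[int, int] | None,
                           tuple[int, int] | None]:
    """Returns (genomic segment, genomic exon intervals in biological
    order, planted exon SSR genomic interval, planted intron SSR genomic
    interval); intervals are relative to the segment start."""
    if len(plan.intron_lens) != len(plan.exon_lens) - 1:
        raise GeneratorError(
            f"gene {plan.name}: need one fewer intron than exons")
    seg_len = _gene_length(plan)
    exon_ssr_iv = None
    intron_ssr_iv = None

    if plan.kind == "CDS":
        coding_len = sum(plan.exon_lens)
        orf, orf_ssr_start = _screened_orf(rng, coding_len, plan.exon_ssr)
        if plan.exon_ssr is not None and len(plan.exon_lens) != 1:
            raise GeneratorError("planted exon SSR needs a single-exon gene")
        exon_seqs = []
        pos = 0
        for el in plan.exon_lens:
            exon_seqs.append(orf[pos:pos + el])
            pos += el
    else:
        exon_seqs = [_screened_rna(rng, el) for el in plan.exon_lens]
        orf_ssr_start = None

    introns: list[str] = []
    intron_local: list[int] = []  # transcript-coordinate offsets
    t_off = 0
    transcript_parts: list[str] = []
    exon_t_offsets: list[int] = []
    for i, ex in enumerate(exon_seqs):
        exon_t_offsets.append(t_off)
        transcript_parts.append(ex)
        t_off += len(ex)
        if i < len(plan.intron_lens):
            ilen = plan.intron_lens[i]
            if plan.intron_ssr is not None and plan.intron_ssr[2] == i:
                motif, count, _ = plan.intron_ssr
                intron, ins_off = _segment_with_insert(
                    rng, ilen, motif * count,
                    [(canonical_motif(motif), count, 0, len(motif) * count)])
                intron_local.append(t_off + ins_off)
            else:
                intron = _screened_igs(rng, ilen)
                intron_local.append(-1)
            introns.append(intron)
            transcript_parts.append(intron)
            t_off += ilen
    transcript = "".join(transcript_parts)
    assert len(transcript) == seg_len

    if plan.strand == "+":
        segment = transcript
        exon_ivs = [(o, o + el)
                    for o, el in zip(exon_t_offsets, plan.exon_lens)]
        if orf_ssr_start is not None:
            # single-exon CDS: coding position == segment position
            run = len(plan.exon_ssr[0]) * plan.exon_ssr[1]
            exon_ssr_iv = (orf_ssr_start, orf_ssr_start + run)
        if plan.intron_ssr is not None:
            idx = plan.intron_ssr[2]
            start = intron_local[idx]
            run = len(plan.intron_ssr[0]) * plan.intron_ssr[1]
            intron_ssr_iv = (start, start + run)
    else:
        if plan.intron_ssr is not None:
            raise GeneratorError("intron SSR planting supports '+' genes only")
        segment = reverse_complement(transcript)
        exon_ivs = [(seg_len - (o + el), seg_len - o)
                    for o, el in zip(exon_t_offsets, plan.exon_lens)]
        if orf_ssr_start is not None:
            run = len(plan.exon_ssr[0]) * plan.exon_ssr[1]
            exon_ssr_iv = (seg_len - (orf_ssr_start + run),
                           seg_len - orf_ssr_start)
    return segment, exon_ivs, exon_ssr_iv, intron_ssr_iv


def _mirror_feature(feat: FeatureAnnotation, b0: int, b1: int,
                    a0: int) -> FeatureAnnotation:
    """The IRa copy of an IRb feature: coordinates mirrored, strand
    flipped, biological part order preserved."""
    parts = [
        Part(a0 + (b1 - p.end), a0 + (b1 - p.start),
             "-" if p.strand == "+" else "+")
        for p in feat.parts
    ]
    return FeatureAnnotation(kind=feat.kind, name=feat.name, parts=parts,
                             qualifiers=dict(feat.qualifiers))


def _build_region(rng: random.Random, plan: list, target_len: int,
                  lsr_insert: str) -> tuple[str, list, list, list]:
    """Assemble one region.  Returns (sequence, features(local), planted
    SSRs(local), planted LSR arms(local)) with local coordinates."""
    fixed = sum(_item_length(it) for it in plan if it[0] != "igs_flex")
    flex = target_len - fixed
    if flex < 16:
        raise GeneratorError(
            f"region target {target_len} too small for its layout "
            f"(fixed content {fixed} bp)")
    chunks: list[str] = []
    features: list = []
    ssrs: list[dict] = []
    lsr_arms: list[tuple[int, int]] = []  # (copy index, local start)
    cursor = 0
    for item in plan:
        if item[0] == "igs":
            chunks.append(_screened_igs(rng, item[1]))
            cursor += item[1]
        elif item[0] == "igs_flex":
            chunks.append(_screened_flex(rng, flex))
            cursor += flex
        elif item[0] == "igs_ssr":
            _, length, motif, count, ctx_name = item
            canon = canonical_motif(motif)
            run = len(motif) * count
            seg, off = _segment_with_insert(
                rng, length, motif * count, [(canon, count, 0, run)])
            ssrs.append({"motif": canon, "unit_length": len(motif),
                         "count": count, "start": cursor + off,
                         "end": cursor + off + run,
                         "context": "IGS", "context_name": ctx_name})
            chunks.append(seg)
            cursor += length
        elif item[0] == "igs_lsr":
            _, length, copy_idx, ctx_name = item
            # fixed guard bases differ between the two copies so the
            # forward pair cannot extend past the planted arms
            guard = "A" if copy_idx == 1 else "C"
            seg, off = _segment_with_insert(
                rng, length, guard + lsr_insert + guard, [])
            lsr_arms.append((copy_idx, cursor + off + 1, ctx_name))
            chunks.append(seg)
            cursor += length
        elif item[0] == "gene":
            plan_g: GenePlan = item[1]
            seg, exon_ivs, exon_ssr_iv, intron_ssr_iv = _build_gene(rng, plan_g)
            glen = len(seg)
            parts = [Part(cursor + s, cursor + e, plan_g.strand)
                     for s, e in exon_ivs]
            span = (cursor, cursor + glen)
            features.append(("gene", plan_g, span, parts))
            if exon_ssr_iv is not None:
                motif, count, _ = plan_g.exon_ssr
                ssrs.append({"motif": canonical_motif(motif),
                             "unit_length": len(motif), "count": count,
                             "start": cursor + exon_ssr_iv[0],
                             "end": cursor + exon_ssr_iv[1],
                             "context": "exon", "context_name": plan_g.name})
            if intron_ssr_iv is not None:
                motif, count, _ = plan_g.intron_ssr
                ssrs.append({"motif": canonical_motif(motif),
                             "unit_length": len(motif), "count": count,
                             "start": cursor + intron_ssr_iv[0],
                             "end": cursor + intron_ssr_iv[1],
                             "context": "intron",
                             "context_name": plan_g.name})
            chunks.append(seg)
            cursor += glen
        else:
            raise ValueError(item)
    seq = "".join(chunks)
    assert len(seq) == target_len
    return seq, features, ssrs, lsr_arms


_KIND_QUALIFIERS = {"CDS": {"transl_table": "11"}, "tRNA": {}, "rRNA": {}}


def _emit_features(raw: list, offset: int) -> list[FeatureAnnotation]:
    out: list[FeatureAnnotation] = []
    for _, plan, span, parts in raw:
        g_parts = [Part(span[0] + offset, span[1] + offset, plan.strand)]
        out.append(FeatureAnnotation("gene", plan.name, g_parts,
                                     {"gene": plan.name}))
        shifted = [Part(p.start + offset, p.end + offset, p.strand)
                   for p in parts]
        quals = {"gene": plan.name, **_KIND_QUALIFIERS[plan.kind]}
        if plan.kind == "CDS":
            quals["product"] = f"{plan.name} protein"
        out.append(FeatureAnnotation(plan.kind, plan.name, shifted, quals))
    return out


def generate_synthetic_plastome(spec: PlastomeSpec | None = None,
                                ) -> tuple[GenomeRecord, TruthLedger]:
    """Build a synthetic quadripartite plastome and its truth ledger.

    The emitted genome is verified against the ledger with the package's
    own detectors (structure, SSRs, LSRs); any discrepancy raises
    :class:`GeneratorError` instead of returning a fixture whose ground
    truth is wrong.
    """
    spec = spec or PlastomeSpec()
    rng = random.Random(spec.seed)
    lsr_insert = None
    for _ in range(_MAX_ATTEMPTS):
        cand = _rand(rng, 40)
        if _clean(cand, lsr_screen=False):
            lsr_insert = cand
            break
    if lsr_insert is None:
        raise GeneratorError("could not screen the long-repeat arm")

    lsc, lsc_feats, lsc_ssrs, lsc_lsr = _build_region(
        rng, _lsc_plan(), spec.lsc_len, lsr_insert)
    irb, irb_feats, irb_ssrs, _ = _build_region(
        rng, _irb_plan(spec.irb_len), spec.irb_len, lsr_insert)
    ssc, ssc_feats, ssc_ssrs, ssc_lsr = _build_region(
        rng, _ssc_plan(), spec.ssc_len, lsr_insert)
    ira = reverse_complement(irb)

    lsc_off = 0
    irb_off = spec.lsc_len
    ssc_off = irb_off + spec.irb_len
    ira_off = ssc_off + spec.ssc_len
    genome = lsc + irb + ssc + ira
    n = len(genome)

    features = (_emit_features(lsc_feats, lsc_off) +
                _emit_features(irb_feats, irb_off) +
                _emit_features(ssc_feats, ssc_off))
    # IRa carries mirrored copies of every IRb feature
    ira_features = [
        _mirror_feature(f, irb_off, irb_off + spec.irb_len, ira_off)
        for f in _emit_features(irb_feats, irb_off)
    ]
    features += ira_features

    record = GenomeRecord(id=spec.record_id, seq=genome, circular=True,
                          features=features)

    ssrs = []
    for s, off in ((lsc_ssrs, lsc_off), (irb_ssrs, irb_off),
                   (ssc_ssrs, ssc_off)):
        for h in s:
            h = dict(h)
            h["start"] += off
            h["end"] += off
            ssrs.append(h)
    ssrs.sort(key=lambda h: h["start"])

    arm1 = next(t for t in lsc_lsr if t[0] == 1)
    arm2 = next(t for t in ssc_lsr if t[0] == 2)
    lsrs = [
        {"type": "forward", "arm_length": 40,
         "start1": lsc_off + arm1[1], "start2": ssc_off + arm2[1],
         "context1": ("IGS", arm1[2]), "context2": ("IGS", arm2[2])},
        {"type": "palindromic", "arm_length": spec.irb_len,
         "start1": irb_off, "start2": ira_off,
         "context1": None, "context2": None},
    ]

    genes = []
    for f in record.genes():
        exon_feat = next(
            (x for x in record.features
             if x.name == f.name and x.kind in ("CDS", "tRNA", "rRNA")
             and x.leftmost >= f.leftmost and
             max(p.end for p in x.parts) <= max(p.end for p in f.parts)),
            None)
        genes.append({
            "name": f.name,
            "kind": exon_feat.kind if exon_feat else "gene",
            "strand": f.strand,
            "span": list(f.span(n)),
            "n_exons": exon_feat.n_exons if exon_feat else f.n_exons,
        })

    ledger = TruthLedger(
        seed=spec.seed,
        genome_length=n,
        regions={"LSC": (lsc_off, spec.lsc_len),
                 "IRb": (irb_off, spec.irb_len),
                 "SSC": (ssc_off, spec.ssc_len),
                 "IRa": (ira_off, spec.irb_len)},
        genes=genes,
        ssrs=ssrs,
        lsrs=lsrs,
    )
    _verify(record, ledger, spec)
    return record, ledger


def _verify(record: GenomeRecord, ledger: TruthLedger,
            spec: PlastomeSpec) -> None:
    structure = find_inverted_repeats(record.seq,
                                      spec.detection_seed_length)
    if structure is None:
        raise GeneratorError("planted inverted repeat was not detected")
    found = {r.name: (r.start, r.length) for r in structure.regions()}
    if found != ledger.regions:
        raise GeneratorError(
            f"detected regions {found} differ from planted "
            f"{ledger.regions}")
    got_ssrs = {(h.motif, h.count, h.start, h.end)
                for h in find_ssrs(record.seq)}
    if got_ssrs != ledger.ssr_tuples():
        raise GeneratorError(
            f"SSR scan {sorted(got_ssrs)} differs from planted "
            f"{sorted(ledger.ssr_tuples())}")
    got_lsrs = {(h.type, h.arm_length, h.start1, h.start2)
                for h in find_lsrs(record.seq, min_arm=30)}
    if got_lsrs != ledger.lsr_tuples():
        raise GeneratorError(
            f"LSR scan {sorted(got_lsrs)} differs from planted "
            f"{sorted(ledger.lsr_tuples())}")


# ---------------------------------------------------------------------------
# population emission for diversity testing


def generate_population(base: GenomeRecord, n: int,
                        rates: dict[str, float] | float,
                        seed: int) -> list[GenomeRecord]:
    """``n`` descendants of ``base`` with independent per-site point
    substitutions, at a per-region rate when ``rates`` is keyed by region
    name (LSC/IRb/SSC/IRa) or a single genome-wide rate.  Annotations are
    carried over unchanged (no indels)."""
    if n < 2:
        raise PlastkitError("population size must be at least 2")
    if isinstance(rates, dict):
        rate_of = dict(rates)
        structure = find_inverted_repeats(base.seq)
        if structure is None:
            raise PlastkitError(
                "per-region rates need a detectable quadripartite structure")
        region_at = [None] * base.length
        for r in structure.regions():
            for off in range(r.length):
                region_at[(r.start + off) % base.length] = r.name
        site_rates = [rate_of.get(region_at[i], 0.0)
                      for i in range(base.length)]
    else:
        site_rates = [float(rates)] * base.length
    for r in set(site_rates):
        if not 0.0 <= r <= 0.2:
            raise PlastkitError(f"substitution rate {r} outside [0, 0.2]")
    rng = random.Random(seed)
    out = []
    others = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}
    for k in range(n):
        chars = list(base.seq)
        for i, rate in enumerate(site_rates):
            if rate > 0.0 and rng.random() < rate:
                if chars[i] in others:
                    chars[i] = rng.choice(others[chars[i]])
        out.append(GenomeRecord(
            id=f"{base.id}_{k}", seq="".join(chars), circular=base.circular,
            features=[f for f in base.features]))
    return out


def write_fixture(out_dir: str, spec: PlastomeSpec | None = None) -> None:
    """Write a synthetic plastome (GenBank) and its ledger (JSON)."""
    import os

    from plastkit.genome_model import write_genbank

    record, ledger = generate_synthetic_plastome(spec)
    os.makedirs(out_dir, exist_ok=True)
    write_genbank(record, os.path.join(out_dir, f"{record.id}.gb"))
    with open(os.path.join(out_dir, f"{record.id}.ledger.json"), "w") as fh:
        fh.write(ledger.to_json())
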