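"""Region extraction and Nei-Li nucleotide diversity."""

import math
import random

import pytest

from plastkit.diversity import (
    collect_shared_regions,
    compute_pi,
    extract_regions,
    pi_from_aligned_dir,
    pi_pipeline,
)
from plastkit.genome_model import (
    FeatureAnnotation,
    GenomeRecord,
    Part,
    PlastkitError,
    write_fasta,
)
from plastkit.synthetic import generate_population


def _two_gene_circle():
    feats = [
        FeatureAnnotation("gene", "a", [Part(0, 10, "+")]),
        FeatureAnnotation("gene", "b", [Part(20, 30, "+")]),
    ]
    return GenomeRecord(id="c", seq="ACGTACGTAC" * 4, features=feats)


def test_extract_regions_genes_and_both_gaps():
    regions = extract_regions(_two_gene_circle())
    by_name = {r.name: r for r in regions}
    assert set(by_name) == {"a", "b", "a-b", "b-a"}
    assert (by_name["a-b"].start, by_name["a-b"].end) == (10, 20)
    assert (by_name["b-a"].start, by_name["b-a"].end) == (30, 40)
    assert by_name["b-a"].seq == _two_gene_circle().seq[30:40]


def test_overlapping_genes_produce_no_igs():
    feats = [
        FeatureAnnotation("gene", "a", [Part(0, 15, "+")]),
        FeatureAnnotation("gene", "b", [Part(10, 30, "+")]),
    ]
    rec = GenomeRecord(id="c", seq="ACGTACGTAC" * 4, features=feats)
    names = {r.name for r in extract_regions(rec)}
    assert "a-b" not in names


def test_extract_regions_counts_match_generator(record, ledger):
    regions = extract_regions(record)
    gene_regions = [r for r in regions if r.kind == "gene"]
    assert len(gene_regions) == len(ledger.genes)
    # adjacent gene pairs with a gap each contribute one IGS
    igs = [r for r in regions if r.kind == "IGS"]
    assert len(igs) == len(ledger.genes)  # sequential layout: gap after each


def test_unannotated_record_raises():
    with pytest.raises(PlastkitError):
        extract_regions(GenomeRecord(id="x", seq="ACGT" * 100))


def test_collect_shared_identical_records(record):
    shared = collect_shared_regions([record, record])
    single_copy = {r.name for r in extract_regions(record)
                   if sum(x.name == r.name
                          for x in extract_regions(record)) == 1}
    assert set(shared) == single_copy
    for rows in shared.values():
        assert len(rows) == 2


def test_collect_shared_drops_missing_and_duplicated():
    def rec(rid, names):
        feats, pos = [], 0
        for name in names:
            feats.append(FeatureAnnotation(
                "gene", name, [Part(pos, pos + 10, "+")]))
            pos += 20
        return GenomeRecord(id=rid, seq="ACGTACGTAC" * 12, features=feats)

    r1 = rec("r1", ["a", "b", "c"])
    r2 = rec("r2", ["a", "c"])          # missing b
    r3 = rec("r3", ["a", "b", "c", "a"])  # duplicated a
    shared = collect_shared_regions([r1, r2, r3])
    assert "a" not in shared  # duplicated in r3
    assert "b" not in shared  # missing from r2
    assert "c" in shared


@pytest.mark.parametrize("rows,expected", [
    (["AAAA", "AAAT"], 0.25),
    (["AAAA", "AAAA", "AAAA"], 0.0),
    (["AAAA", "AAAT", "AATT"], (1 + 2 + 1) / (3 * 4)),
])
def test_compute_pi_hand_enumerated(rows, expected):
    assert compute_pi(rows).pi == pytest.approx(expected, abs=1e-12)


def test_compute_pi_errors():
    with pytest.raises(PlastkitError):
        compute_pi(["AAAA"])
    with pytest.raises(PlastkitError):
        compute_pi(["AAAA", "AAA"])
    with pytest.raises(PlastkitError):
        compute_pi(["A-", "-A"])  # every column gapped


def test_complete_deletion_ignores_gapped_columns():
    base = ["AAAA", "AAAT", "AATT"]
    gapped = ["AA-AA", "AA-AT", "AATTT"]  # one fully shared gap column? no:
    # insert a column that is gapped in at least one row -> excluded
    gapped = ["AA-AA", "AAAAT", "AAATT"]
    assert compute_pi(gapped).pi == pytest.approx(compute_pi(base).pi)


def test_pi_invariant_under_row_permutation():
    rows = ["ACGTAC", "ACGTAT", "ACCTAT", "AGGTAC"]
    rng = random.Random(8)
    base = compute_pi(rows).pi
    for _ in range(5):
        shuffled = rows[:]
        rng.shuffle(shuffled)
        assert compute_pi(shuffled).pi == pytest.approx(base)


def test_parameter_recovery_bernoulli():
    """Mean pi over seeded replicates matches the expected pairwise
    difference rate of independent per-site substitutions, within 3
    Monte-Carlo standard errors (n=6, L=2000, 50 reps)."""
    L, n, reps = 2000, 6, 50
    for p in (0.01, 0.05):
        expected = 2 * p * (1 - p) + (2 / 3) * p * p
        rng = random.Random(int(p * 1000))
        pis = []
        for _ in range(reps):
            ref = rng.choices("ACGT", k=L)
            rows = []
            for _ in range(n):
                chars = list(ref)
                for i in range(L):
                    if rng.random() < p:
                        chars[i] = rng.choice(
                            [c for c in "ACGT" if c != chars[i]])
                rows.append("".join(chars))
            pis.append(compute_pi(rows).pi)
        mean = sum(pis) / reps
        sd = math.sqrt(sum((x - mean) ** 2 for x in pis) / (reps - 1))
        se = sd / math.sqrt(reps)
        assert abs(mean - expected) < 3 * se + 1e-9, (p, mean, expected, se)


def test_pipeline_identical_genomes_all_zero(record):
    results = pi_pipeline([record, record])
    assert results
    assert all(r.pi == 0.0 for r in results)
    mids = [r.midpoint for r in results]
    assert mids == sorted(mids)


def test_pipeline_per_region_rates(record):
    """Regions in the high-rate compartment show higher pi than in the
    near-zero compartment."""
    pop = generate_population(
        record, 4, {"LSC": 0.02, "IRb": 0.0, "SSC": 0.0, "IRa": 0.0},
        seed=9)
    results = pi_pipeline(pop)
    by_name = {r.name: r for r in results}
    assert by_name["psbA"].pi > 0.005  # LSC gene mutated
    assert by_name["ndhF"].pi == 0.0   # SSC gene untouched


def test_pipeline_prealigned_bypass(tmp_path, record):
    pop = generate_population(record, 3, 0.01, seed=10)
    shared_rows = {}
    from plastkit.diversity import collect_shared_regions

    shared = collect_shared_regions(pop)
    for name, regs in list(shared.items())[:5]:
        fname = tmp_path / f"{name}.fasta"
        write_fasta([(r.record_id, r.seq) for r in regs], fname)
        shared_rows[name] = [r.seq for r in regs]
    results = pi_from_aligned_dir(str(tmp_path))
    for r in results:
        assert r.pi == pytest.approx(compute_pi(shared_rows[r.name]).pi)


def test_population_rate_zero_gives_identical_genomes(record):
    pop = generate_population(record, 3, 0.0, seed=11)
    assert all(p.seq == record.seq for p in pop)
    assert pi_pipeline(pop) and all(r.pi == 0.0 for r in pi_pipeline(pop))


def test_population_determinism(record):
    a = generate_population(record, 3, 0.01, seed=12)
    b = generate_population(record, 3, 0.01, seed=12)
    assert [x.seq for x in a] == [x.seq for x in b]


def test_population_rate_out_of_range(record):
    with pytest.raises(PlastkitError):
        generate_population(record, 3, 0.5, seed=13)


def test_pipeline_with_external_aligner(tmp_path, record):
    """mafft round trip on a small population (no indels, so alignment is
    the identity and results match the aligner-free path)."""
    import shutil

    if shutil.which("mafft") is None:
        pytest.skip("mafft not on PATH")
    pop = generate_population(record, 3, 0.005, seed=14)
    direct = {r.name: r.pi for r in pi_pipeline(pop)}
    aligned = {r.name: r.pi
               for r in pi_pipeline(pop, aligner="mafft --auto {in} > {out} 2>/dev/null")}
    for name in list(direct)[:10]:
        assert aligned[name] == pytest.approx(direct[name], abs=1e-9)
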