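"""Generator contracts: determinism, planted-event bookkeeping, closure."""

import numpy as np
import pytest

from congener import synthdata as sd
from congener._seq import encode, revcomp


def _cfg(**kw):
    base = dict(genome_length=100_000, n_chromosomes=2, seed=3)
    base.update(kw)
    return sd.SimConfig(**base)


class TestReference:
    def test_same_seed_is_byte_identical(self):
        a = sd.simulate_reference(_cfg())
        b = sd.simulate_reference(_cfg())
        assert [r.sequence for r in a] == [r.sequence for r in b]

    def test_gc_fraction_within_binomial_interval(self):
        # 99 % binomial interval at n=10^6, p=0.5 is +- ~0.0013; the spec'd
        # +-0.005 band is looser still
        cfg = sd.SimConfig(genome_length=1_000_000, n_chromosomes=1,
                           gc_fraction=0.5, seed=11)
        (rec,) = sd.simulate_reference(cfg)
        codes = encode(rec.sequence)
        gc = np.mean((codes == 1) | (codes == 2))
        assert abs(gc - 0.5) < 0.005

    def test_chromosome_naming(self):
        recs = sd.simulate_reference(_cfg(n_chromosomes=3, genome_length=30_000))
        assert [r.id for r in recs] == ["chr1", "chr2", "chr3"]


class TestDivergence:
    def test_null_rates_give_identical_genome(self):
        ref = sd.simulate_reference(_cfg())
        der, truth = sd.diverge_genome(ref, _cfg(snp_rate=0, indel_rate=0))
        assert [r.sequence for r in der] == [r.sequence for r in ref]
        assert truth.variants == [] and truth.rearrangements == []

    def test_snc_count_binomial_interval(self):
        # 1 Mb at rate 0.01 -> 10,000 +- 300 (99 % interval ~ +-256)
        cfg = sd.SimConfig(genome_length=1_000_000, n_chromosomes=1,
                           snp_rate=0.01, indel_rate=0.0, seed=19)
        ref = sd.simulate_reference(cfg)
        _, truth = sd.diverge_genome(ref, cfg)
        assert abs(len(truth.snc_keys()) - 10_000) <= 300

    def test_translocations_recorded_with_min_length(self):
        cfg = sd.SimConfig(genome_length=1_000_000, n_chromosomes=4,
                           snp_rate=0.001, indel_rate=0.0,
                           n_translocations=5, translocation_min_len=25_000,
                           seed=23)
        ref = sd.simulate_reference(cfg)
        der, truth = sd.diverge_genome(ref, cfg)
        assert len(truth.rearrangements) == 5
        for ev in truth.rearrangements:
            assert ev.src_chrom != ev.dest_chrom
            assert ev.src_end - ev.src_start >= 25_000
        # total sequence is conserved by cut-and-paste
        assert sum(len(r.sequence) for r in der) == sum(len(r.sequence) for r in ref)

    @pytest.mark.parametrize("seed", [3, 7, 31])
    def test_truth_closure_reproduces_derived_genome(self, seed):
        """Replaying the TruthSet against the reference must reproduce the
        derived genome byte for byte, including with translocations."""
        cfg = sd.SimConfig(genome_length=800_000, n_chromosomes=4,
                           snp_rate=0.01, indel_rate=0.001,
                           n_translocations=2, translocation_min_len=25_000,
                           seed=seed)
        ref = sd.simulate_reference(cfg)
        der, truth = sd.diverge_genome(ref, cfg)
        rebuilt = sd.apply_truth(ref, truth)
        assert [r.sequence for r in rebuilt] == [r.sequence for r in der]

    def test_variant_reference_alleles_match_reference_genome(self):
        cfg = _cfg(snp_rate=0.005, indel_rate=0.0005)
        ref = sd.simulate_reference(cfg)
        seqs = {r.id: r.sequence for r in ref}
        _, truth = sd.diverge_genome(ref, cfg)
        for v in truth.variants:
            assert seqs[v.chrom][v.pos : v.pos + len(v.ref)] == v.ref


class TestTEs:
    def test_zero_divergence_copy_equals_consensus(self, random_seq):
        cons = random_seq(500, seed=1)
        fam = sd.TEFamily("fam", cons, copies=3, divergences=[0.0, 0.0, 0.0])
        genome = sd.simulate_reference(_cfg())
        out, truth = sd.plant_tes(genome, _cfg(te_families=(fam,)))
        seqs = {r.id: r.sequence for r in out}
        assert len(truth.te_copies) == 3
        for c in truth.te_copies:
            assert seqs[c.chrom][c.start : c.end] == cons

    def test_divergence_draw_mutates_expected_fraction(self, random_seq):
        # d=10 % on 1000 bp: ~100 mutated sites, ~2/3 transitions
        cons = random_seq(1000, seed=2)
        rng = np.random.default_rng(5)
        tis = tvs = 0
        for _ in range(20):
            copy = sd.mutate_to_divergence(cons, 0.10, rng)
            for a, b in zip(cons, copy):
                if a != b:
                    if (a in "AG") == (b in "AG"):
                        tis += 1
                    else:
                        tvs += 1
        n = tis + tvs
        assert abs(n - 2000) <= 10  # round(0.1*1000) per copy, exact by design
        assert abs(tis / n - 2 / 3) < 0.04  # 99 % multinomial interval

    def test_zero_copies_family_absent(self):
        fam = sd.TEFamily("fam", "ACGTACGT", copies=0, divergences=[])
        genome = sd.simulate_reference(_cfg())
        _, truth = sd.plant_tes(genome, _cfg(te_families=(fam,)))
        assert truth.te_copies == []


class TestReads:
    def test_pair_count_arithmetic(self):
        genome = sd.simulate_reference(
            sd.SimConfig(genome_length=1_000_000, n_chromosomes=1, seed=1)
        )
        rs = sd.simulate_pairs(
            genome, [sd.LibrarySpec("f", 300, 30, "FR", 30.0)], read_length=100,
            seed=1,
        )[0]
        assert rs.n_pairs == 150_000  # 30 * 1e6 / (2 * 100)

    def test_error_free_reads_are_genome_substrings(self, small_genome):
        rs = sd.simulate_pairs(
            small_genome, [sd.LibrarySpec("f", 300, 30, "FR", 1.0)], seed=2
        )[0]
        text = "|".join(r.sequence for r in small_genome)
        for i in range(0, rs.n_pairs, max(rs.n_pairs // 50, 1)):
            r1 = rs.read_strings(1)[i]
            r2 = rs.read_strings(2)[i]
            assert r1 in text
            assert revcomp(r2) in text  # FR: mate 2 is reverse-complemented

    def test_rf_pairs_read_outward(self, small_genome):
        rs = sd.simulate_pairs(
            small_genome, [sd.LibrarySpec("mp", 3000, 100, "RF", 1.0)], seed=2
        )[0]
        text = "|".join(r.sequence for r in small_genome)
        r1 = rs.read_strings(1)[0]
        r2 = rs.read_strings(2)[0]
        assert revcomp(r1) in text and r2 in text

    def test_insert_mean_recovered_from_alignments(self):
        """Observed inserts of mapped pairs average to the drawn mean
        (CLT bound: 30/sqrt(20000) ~ 0.2, asserted at +-1)."""
        from congener import assist, chromo

        genome = sd.simulate_reference(
            sd.SimConfig(genome_length=1_000_000, n_chromosomes=1, seed=6)
        )
        lib = sd.LibrarySpec("f", 300, 30, "FR", 4.0)
        rs = sd.simulate_pairs(genome, [lib], seed=6)[0]
        mapping = chromo.map_reads([rs], chromo.GenomeIndex(genome))
        (table,) = assist.pair_table(mapping)
        inserts = table.insert[(table.orientation == "FR") & (table.insert > 0)]
        assert len(inserts) > 15_000
        assert abs(inserts.mean() - 300) < 1.0

    def test_fastq_round_trip(self, small_genome, tmp_path):
        rs = sd.simulate_pairs(
            small_genome, [sd.LibrarySpec("f", 300, 30, "FR", 0.5)], seed=3
        )[0]
        rs.to_fastq(tmp_path / "r1.fq", tmp_path / "r2.fq")
        from congener.core_io import read_sequences

        back = read_sequences(tmp_path / "r1.fq", "FASTQ")
        assert len(back) == rs.n_pairs
        assert back[0].sequence == rs.read_strings(1)[0]


class TestScaffolding:
    def test_zero_gaps_identity(self, small_genome):
        scaf, truth = sd.fragment_scaffolds(small_genome, 0, seed=1)
        assert [r.sequence for r in scaf] == [r.sequence for r in small_genome]
        assert truth.gap_fills == []

    def test_gap_lengths_and_truth_reinsertion(self, small_genome):
        scaf, truth = sd.fragment_scaffolds(
            small_genome, 8, gap_len_range=(20, 500), seed=2
        )
        assert len(truth.gap_fills) == 8
        seqs = {r.id: r.sequence for r in scaf}
        rebuilt = {r.id: list(r.sequence) for r in scaf}
        for g in truth.gap_fills:
            assert 20 <= g.end - g.start <= 500
            assert set(seqs[g.scaffold][g.start : g.end]) == {"N"}
            rebuilt[g.scaffold][g.start : g.end] = g.fill
        originals = {r.id: r.sequence for r in small_genome}
        for cid, chars in rebuilt.items():
            assert "".join(chars) == originals[cid]

    def test_infeasible_spacing_raises(self):
        genome = sd.simulate_reference(
            sd.SimConfig(genome_length=10_000, n_chromosomes=1, seed=1)
        )
        with pytest.raises(ValueError):
            sd.fragment_scaffolds(genome, 50, seed=1)

    def test_shred_genome_covers_genome_and_flags_strand(self, small_genome):
        pieces, origins = sd.shred_genome(small_genome, 10_000, seed=4)
        total = sum(len(p.sequence) for p in pieces)
        assert total == sum(len(r.sequence) for r in small_genome)
        originals = {r.id: r.sequence for r in small_genome}
        for p, o in zip(pieces, origins):
            src = originals[o.chrom][o.start : o.end]
            assert p.sequence == (src if o.strand == "+" else revcomp(src))


def test_config_validation():
    with pytest.raises(ValueError):
        sd.SimConfig(snp_rate=1.5)
    with pytest.raises(ValueError):
        sd.SimConfig(genome_length=100_000, n_translocations=1,
                     translocation_min_len=25_000)
    with pytest.raises(ValueError):
        sd.LibrarySpec("x", 300, 30, "XX", 1.0)


def test_config_from_yaml(tmp_path):
    p = tmp_path / "sim.yaml"
    p.write_text(
        "genome_length: 50000\nn_chromosomes: 2\nseed: 9\n"
        "libraries:\n - {name: f, insert_mean: 300, insert_sd: 30.0, "
        "orientation: FR, coverage: 10.0}\n"
    )
    cfg = sd.SimConfig.from_yaml(p)
    assert cfg.genome_length == 50_000
    assert cfg.libraries[0].name == "f" and cfg.libraries[0].coverage == 10.0
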