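"""Variant calling thresholds and effect classification."""

import numpy as np
import pytest
from Bio.Seq import Seq
from scipy.stats import binom

from congener import varcall
from congener.core_io import GeneModel, SeqRecord
from congener.varcall import Variant


def _variant(chrom, pos, ref, alt, vtype="SNC"):
    return Variant(chrom, pos, ref, alt, vtype, 30, 30, 1e-9)


def _pileup_single(ref_base, counts_by_base, depth_pad=0):
    """A one-column pileup embedded in a tiny genome."""
    from congener.chromo import GenomeIndex

    seq = "ACGT" * 10
    pos = 17
    seq = seq[:pos] + ref_base + seq[pos + 1 :]
    idx = GenomeIndex([SeqRecord("chr1", seq, tier="chromosome")])
    counts = np.zeros((len(idx.codes), 4), dtype=np.int32)
    for base, n in counts_by_base.items():
        counts[pos, "ACGT".index(base)] = n
    return varcall.Pileup(idx, counts), pos


class TestCalling:
    def test_below_minimum_coverage_not_called(self):
        pu, _ = _pileup_single("A", {"T": 2})
        assert varcall.call_variants(pu) == []

    def test_unanimous_deep_alt_called_with_tiny_p(self):
        pu, pos = _pileup_single("A", {"T": 10})
        (v,) = varcall.call_variants(pu)
        assert (v.pos, v.ref, v.alt) == (pos, "A", "T")
        # closed form: p = 0.01^10
        assert v.p_value == pytest.approx(1e-20, rel=1e-6)

    def test_low_fraction_alt_rejected_despite_p(self):
        # depth 10, alt 1: tail p = 1 - 0.99^10 ~ 0.096 < 0.1 but fraction 0.1 < 0.2
        pu, _ = _pileup_single("A", {"A": 9, "T": 1})
        assert varcall.call_variants(pu) == []
        assert binom.sf(0, 10, 0.01) == pytest.approx(1 - 0.99**10)

    def test_p_value_monotone_in_alt_depth(self):
        pvals = []
        for alt in range(6, 31, 4):
            pu, _ = _pileup_single("A", {"A": 30 - alt, "T": alt})
            calls = varcall.call_variants(pu)
            if calls:
                pvals.append(calls[0].p_value)
        assert pvals == sorted(pvals, reverse=True)
        assert len(pvals) >= 5

    def test_most_frequent_non_reference_allele_reported(self):
        pu, _ = _pileup_single("A", {"A": 5, "T": 20, "G": 3})
        (v,) = varcall.call_variants(pu)
        assert v.alt == "T" and v.alt_depth == 20 and v.depth == 28


class TestClassifier:
    def test_stop_gained_from_gln_codon(self, toy_gene_genome):
        genome, model = toy_gene_genome
        seq = genome[0].sequence
        # plant CAA (Gln) at codon 2 then mutate C->T giving TAA
        s = seq[:1043] + "CAA" + seq[1046:]
        genome = [SeqRecord("chr1", s, tier="chromosome")]
        anns = varcall.classify_effects(
            [_variant("chr1", 1043, "C", "T")], [model], genome
        )
        assert [a.category for a in anns] == ["stop_gained"]
        assert anns[0].impact == "high"

    def test_synonymous_ala_codon(self, toy_gene_genome):
        genome, model = toy_gene_genome
        seq = genome[0].sequence
        s = seq[:1043] + "GCC" + seq[1046:]
        genome = [SeqRecord("chr1", s, tier="chromosome")]
        anns = varcall.classify_effects(
            [_variant("chr1", 1045, "C", "G")], [model], genome
        )
        assert [(a.category, a.impact) for a in anns] == [
            ("synonymous_coding", "low")
        ]

    def test_downstream_window(self, toy_gene_genome):
        genome, model = toy_gene_genome
        pos = 1500 + 2300  # 2.3 kb past transcript end, + strand
        ref = genome[0].sequence[pos]
        alt = "A" if ref != "A" else "C"
        anns = varcall.classify_effects(
            [_variant("chr1", pos, ref, alt)], [model], genome
        )
        assert [(a.category, a.impact) for a in anns] == [("downstream", "modifier")]

    def test_intergenic_outside_all_windows(self, toy_gene_genome):
        genome, model = toy_gene_genome
        # upstream window ends 5 kb before the gene; position 0..? use far end
        genome2 = [SeqRecord("chr1", genome[0].sequence * 3, tier="chromosome")]
        pos = 11_000
        ref = genome2[0].sequence[pos]
        alt = "A" if ref != "A" else "C"
        anns = varcall.classify_effects(
            [_variant("chr1", pos, ref, alt)], [model], genome2
        )
        assert [a.category for a in anns] == ["intergenic"]

    def test_splice_site_and_intron(self, toy_gene_genome):
        genome, model = toy_gene_genome
        seq = genome[0].sequence
        for pos, want in [(1101, "splice_site"), (1200, "intron")]:
            ref = seq[pos]
            alt = "A" if ref != "A" else "C"
            anns = varcall.classify_effects(
                [_variant("chr1", pos, ref, alt)], [model], genome
            )
            assert [a.category for a in anns] == [want], pos

    def test_utr_assignment_respects_strand(self, toy_gene_genome):
        genome, model = toy_gene_genome
        seq = genome[0].sequence
        ref5 = seq[1010]
        anns = varcall.classify_effects(
            [_variant("chr1", 1010, ref5, "A" if ref5 != "A" else "C")],
            [model], genome,
        )
        assert [a.category for a in anns] == ["utr5"]
        ref3 = seq[1450]
        anns = varcall.classify_effects(
            [_variant("chr1", 1450, ref3, "A" if ref3 != "A" else "C")],
            [model], genome,
        )
        assert [a.category for a in anns] == ["utr3"]

    def test_frame_shift_vs_codon_indel(self, toy_gene_genome):
        genome, model = toy_gene_genome
        seq = genome[0].sequence
        v_fs = Variant("chr1", 1050, seq[1050 : 1052], seq[1050], "InDel", 30, 30, 1e-9)
        v_ci = Variant("chr1", 1050, seq[1050 : 1054], seq[1050], "InDel", 30, 30, 1e-9)
        anns = varcall.classify_effects([v_fs, v_ci], [model], genome)
        cats = [a.category for a in anns]
        assert cats == ["frame_shift", "codon_indel"]
        assert [a.impact for a in anns] == ["high", "moderate"]

    def test_exon_deleted(self, toy_gene_genome):
        genome, model = toy_gene_genome
        seq = genome[0].sequence
        ref = seq[995 : 1105]  # removes exon1 [1000,1100) entirely
        v = Variant("chr1", 995, ref, ref[0], "InDel", 30, 30, 1e-9)
        anns = varcall.classify_effects([v], [model], genome)
        assert "exon_deleted" in [a.category for a in anns]

    def test_chromosome_scale_deletion_high_impact(self, toy_gene_genome):
        genome, model = toy_gene_genome
        seq = genome[0].sequence
        ref = seq[2000:2100]  # 100 bp of a 4 kb chromosome: > 1 %
        v = Variant("chr1", 2000, ref, ref[0], "InDel", 30, 30, 1e-9)
        anns = varcall.classify_effects([v], [model], genome)
        assert anns[0].category == "chromosome_large_deletion"
        assert anns[0].impact == "high"

    def test_reference_mismatch_is_error(self, toy_gene_genome):
        genome, model = toy_gene_genome
        ref = genome[0].sequence[1200]
        wrong = "A" if ref != "A" else "C"
        with pytest.raises(ValueError, match="mismatch"):
            varcall.classify_effects(
                [_variant("chr1", 1200, wrong, ref)], [model], genome
            )

    def test_exhaustive_cds_snc_agrees_with_translation_oracle(
        self, toy_gene_genome
    ):
        """Classify every possible SNC at every CDS position and compare
        with a direct whole-protein translation oracle."""
        genome, model = toy_gene_genome
        seq = genome[0].sequence
        cds_pos = [p for a, b in model.cds for p in range(a, b)]
        cds_seq = "".join(seq[a:b] for a, b in model.cds)
        prot_ref = str(Seq(cds_seq).translate())
        clf = varcall.EffectClassifier([model], genome)
        checked = 0
        for i, p in enumerate(cds_pos):
            for alt in "ACGT":
                if alt == seq[p]:
                    continue
                alt_cds = cds_seq[:i] + alt + cds_seq[i + 1 :]
                prot_alt = str(Seq(alt_cds).translate())
                ci = i // 3
                aa_r, aa_a = prot_ref[ci], prot_alt[ci]
                if ci == 0 and aa_r == "M" and aa_a != "M":
                    want = "start_lost"
                elif aa_r != "*" and aa_a == "*":
                    want = "stop_gained"
                elif aa_r == "*" and aa_a != "*":
                    want = "stop_lost"
                elif aa_r == aa_a:
                    want = "synonymous_coding"
                else:
                    want = "non_synonymous_coding"
                (ann,) = clf.classify(_variant("chr1", p, seq[p], alt))
                assert ann.category == want, (p, alt)
                checked += 1
        assert checked == 3 * len(cds_pos)

    def test_minus_strand_gene_translation(self, random_seq):
        """A minus-strand CDS classifies via the reverse complement."""
        from congener._seq import revcomp

        cds_fwd = "ATG" + "GCTTGG" * 8 + "TAA"  # 54 bp clean ORF
        flank_l = random_seq(500, seed=21)
        flank_r = random_seq(500, seed=22)
        chrom = flank_l + revcomp(cds_fwd) + flank_r
        genome = [SeqRecord("chr1", chrom, tier="chromosome")]
        model = GeneModel(
            "g", "t", "chr1", "-",
            exons=[(500, 500 + len(cds_fwd))],
            cds=[(500, 500 + len(cds_fwd))],
        )
        # mutate the genome base corresponding to the start codon's A
        p = 500 + len(cds_fwd) - 1  # genome base pairing with cds position 0
        ref = chrom[p]  # this is complement of 'A' = 'T'
        assert ref == "T"
        (ann,) = varcall.classify_effects(
            [_variant("chr1", p, "T", "G")], [model], genome
        )
        assert ann.category == "start_lost"


class TestSummaries:
    def test_single_annotation_is_100_percent(self):
        ann = varcall.EffectAnnotation(("c", 1, "A", "T"), "t1", "g1",
                                       "intron", "modifier")
        s = varcall.summarize_effects([ann])
        assert s.percentages == {"intron": 100.0} and s.total == 1

    def test_counts_conserved_and_percentages_sum(self):
        rng = np.random.default_rng(0)
        cats = list(varcall.CATEGORIES)
        anns = [
            varcall.EffectAnnotation(("c", i, "A", "T"), None, None,
                                     cats[rng.integers(len(cats))], "modifier")
            for i in range(5000)
        ]
        s = varcall.summarize_effects(anns)
        assert sum(s.counts.values()) == 5000
        assert abs(sum(s.percentages.values()) - 100.0) <= 0.05

    def test_accepts_count_mapping(self):
        s = varcall.summarize_effects({"intron": 3, "exon": 1})
        assert s.percentages == {"intron": 75.0, "exon": 25.0}


class TestDensityAndPartition:
    def test_density_normalization(self):
        variants = [_variant("chr1", i, "A", "T") for i in range(3000)]
        (t,) = varcall.density_track(variants, {"chr1": 150_000})
        assert t.counts[0] == 3000 and t.normalized[0] == 1.0
        assert len(t.counts) == 2  # trailing partial bin kept

    def test_density_empty_and_half(self):
        (t,) = varcall.density_track([], {"chr1": 100_000})
        assert t.normalized[0] == 0.0
        variants = [_variant("chr1", i, "A", "T") for i in range(1500)]
        (t,) = varcall.density_track(variants, {"chr1": 100_000})
        assert t.normalized[0] == 0.5

    def test_partition_three_cases(self):
        shared = _variant("chr1", 10, "A", "T")
        only_b = _variant("chr1", 20, "C", "G")
        diff_b = _variant("chr1", 30, "G", "A")
        diff_c = _variant("chr1", 30, "G", "C")
        parts = varcall.partition_species(
            [shared, only_b, diff_b], [shared, diff_c]
        )
        assert parts["shared"] == {shared.key}
        assert parts["only_b"] == {only_b.key, diff_b.key}
        assert parts["only_c"] == {diff_c.key}


class TestRate:
    def test_rate_arithmetic(self):
        assert varcall.polymorphism_rate(100, 6_900)[0] == 69

    def test_zero_variants_is_error(self):
        with pytest.raises(ValueError):
            varcall.polymorphism_rate(0, 100)
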