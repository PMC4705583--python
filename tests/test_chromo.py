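"""Anchor mapping, placement, statistics, rearrangements, orthologs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from congener import chromo
from congener._seq import encode, revcomp
from congener.core_io import SeqRecord


def _seqrec(name, s, tier="scaffold"):
    return SeqRecord(name, s, tier=tier)


class TestAnchorMap:
    def test_self_match_single_cluster_full_identity(self, random_seq):
        s = random_seq(10_000, seed=1)
        ref = [_seqrec("chr1", s, "chromosome")]
        clusters = chromo.anchor_map([_seqrec("q", s)], ref)
        plus = [c for c in clusters if c.strand == "+"]
        assert len(plus) == 1
        c = plus[0]
        assert c.total_match >= 0.99 * 10_000
        assert c.mean_identity == 1.0
        assert c.target_id == "chr1"

    def test_short_match_below_min_cluster_discarded(self, random_seq):
        ref_seq = random_seq(20_000, seed=2)
        ref = [_seqrec("chr1", ref_seq, "chromosome")]
        # a 300 bp exact match embedded in otherwise unrelated sequence
        q = random_seq(2_000, seed=3) + ref_seq[5_000:5_300] + random_seq(2_000, seed=4)
        clusters = chromo.anchor_map([_seqrec("q", q)], ref)
        assert clusters == []  # 300 < min_cluster 400

    def test_two_nearby_matches_chain_and_survive(self, random_seq):
        ref_seq = random_seq(20_000, seed=5)
        ref = [_seqrec("chr1", ref_seq, "chromosome")]
        # two 300 bp exact blocks separated by 450 unrelated bp on both sides
        q = (
            ref_seq[4_000:4_300]
            + random_seq(450, seed=6)
            + ref_seq[4_750:5_050]
        )
        clusters = chromo.anchor_map([_seqrec("q", q)], ref)
        assert len(clusters) == 1
        assert clusters[0].total_match >= 600 * 0.95

    def test_minus_strand_query_found(self, random_seq):
        s = random_seq(5_000, seed=7)
        ref = [_seqrec("chr1", s, "chromosome")]
        clusters = chromo.anchor_map([_seqrec("q", revcomp(s[1000:3000]))], ref)
        assert len(clusters) == 1
        assert clusters[0].strand == "-"
        assert abs(clusters[0].target_start - 1000) < 25

    def test_empty_query_set_rejected(self):
        with pytest.raises(ValueError):
            chromo.anchor_map([], [])


class TestPlacement:
    def _clusters(self, spec):
        return [
            chromo.AnchorCluster("s1", chrom, 0, bp, 1000, 1000 + bp, strand, bp, 1.0)
            for chrom, bp, strand in spec
        ]

    def test_majority_chromosome_wins(self):
        cls = self._clusters([("chr2", 30_000, "+"), ("chr7", 2_000, "+")])
        placements, _ = chromo.place_scaffolds(cls, [_seqrec("s1", "A" * 100)])
        assert placements[0].status == "placed"
        assert placements[0].chromosome == "chr2"

    def test_no_clusters_unplaced(self):
        placements, agp = chromo.place_scaffolds([], [_seqrec("s1", "A" * 100)])
        assert placements[0].status == "unplaced"
        assert agp == []

    def test_minority_minus_strand_orientation(self):
        cls = self._clusters([("chr1", 4_000, "-"), ("chr1", 2_500, "+")])
        placements, _ = chromo.place_scaffolds(cls, [_seqrec("s1", "A" * 100)])
        assert placements[0].orientation == "-"

    def test_close_tie_becomes_unplaced(self):
        cls = self._clusters([("chr1", 10_000, "+"), ("chr2", 9_500, "+")])
        placements, _ = chromo.place_scaffolds(cls, [_seqrec("s1", "A" * 100)])
        assert placements[0].status == "unplaced"

    def test_agp_gaps_between_ordered_scaffolds(self):
        cls = [
            chromo.AnchorCluster("s1", "chr1", 0, 500, 10_000, 10_500, "+", 500, 1.0),
            chromo.AnchorCluster("s2", "chr1", 0, 500, 50_000, 50_500, "+", 500, 1.0),
        ]
        scaffolds = [_seqrec("s1", "A" * 600), _seqrec("s2", "C" * 700)]
        _, agp = chromo.place_scaffolds(cls, scaffolds)
        assert [r.component_type for r in agp] == ["W", "N", "W"]
        assert agp[0].component_id == "s1"  # ordered by target coordinate
        assert agp[1].gap_length == 100


class TestAssemblyStats:
    def _stats_oracle(self, lengths):
        lengths = sorted(lengths, reverse=True)
        total, acc = sum(lengths), 0
        for l in lengths:
            acc += l
            if 2 * acc >= total:
                return l

    @pytest.mark.parametrize(
        "lengths,expected", [([300, 200, 100], 300), ([5, 4, 3, 2, 1], 4)]
    )
    def test_n50_examples(self, lengths, expected):
        recs = [_seqrec(f"s{i}", "A" * l) for i, l in enumerate(lengths)]
        s = chromo.assembly_stats(recs, "contig")
        assert s.n50 == expected == self._stats_oracle(lengths)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.integers(1, 500), min_size=1, max_size=30))
    def test_n50_matches_bruteforce(self, lengths):
        recs = [_seqrec(f"s{i}", "A" * l) for i, l in enumerate(lengths)]
        assert chromo.assembly_stats(recs, "contig").n50 == self._stats_oracle(lengths)

    def test_gc_excludes_n(self):
        s = chromo.assembly_stats([_seqrec("s", "ATGC")], "contig")
        assert s.gc_percent == 50.0
        s2 = chromo.assembly_stats([_seqrec("s", "ATGCNNNN")], "contig")
        assert s2.gc_percent == 50.0

    def test_empty_assembly_rejected(self):
        with pytest.raises(ValueError):
            chromo.assembly_stats([], "contig")


class TestInterchromosomal:
    def _cluster(self, contig, chrom, q0, q1):
        bp = q1 - q0
        return chromo.AnchorCluster(contig, chrom, q0, q1, 0, bp, "+", bp, 1.0)

    def test_both_spans_over_threshold_yield_event(self):
        cls = [
            self._cluster("c1", "chr1", 0, 25_000),
            self._cluster("c1", "chr2", 25_000, 47_000),
        ]
        events = chromo.detect_interchromosomal(cls)
        assert len(events) == 1
        e = events[0]
        assert {e.chrom_a, e.chrom_b} == {"chr1", "chr2"}
        assert abs(e.breakpoint - 25_000) < 100

    def test_one_small_span_is_not_an_event(self):
        cls = [
            self._cluster("c1", "chr1", 0, 25_000),
            self._cluster("c1", "chr2", 25_000, 30_000),
        ]
        assert chromo.detect_interchromosomal(cls) == []

    def test_single_chromosome_contig_is_not_an_event(self):
        cls = [self._cluster("c1", "chr1", 0, 50_000)]
        assert chromo.detect_interchromosomal(cls) == []


class TestReciprocalBest:
    def test_mutual_best_pairs(self):
        ab = [("g1", "h1", 100.0), ("g1", "h2", 50.0)]
        ba = [("h1", "g1", 95.0), ("h2", "g2", 40.0)]
        pairs = chromo.reciprocal_best(ab, ba)
        assert [(p.query_gene, p.ref_gene) for p in pairs] == [("g1", "h1")]

    def test_non_mutual_is_dropped(self):
        ab = [("g1", "h1", 100.0)]
        ba = [("h1", "g2", 95.0)]
        assert chromo.reciprocal_best(ab, ba) == []

    def test_tied_top_scores_disqualify_exhaustively(self):
        """Enumerate a 3x3 toy score table: only strict mutual bests pair."""
        genes = ["g1", "g2", "g3"]
        homs = ["h1", "h2", "h3"]
        # g1 ties h1/h2; g2 and g3 have unique bests
        ab = [
            ("g1", "h1", 9.0), ("g1", "h2", 9.0), ("g1", "h3", 1.0),
            ("g2", "h2", 8.0), ("g2", "h1", 2.0), ("g2", "h3", 1.0),
            ("g3", "h3", 7.0), ("g3", "h1", 1.0), ("g3", "h2", 1.0),
        ]
        ba = [
            ("h1", "g1", 9.0), ("h1", "g2", 1.0), ("h1", "g3", 1.0),
            ("h2", "g2", 8.0), ("h2", "g1", 3.0), ("h2", "g3", 1.0),
            ("h3", "g3", 7.0), ("h3", "g1", 1.0), ("h3", "g2", 1.0),
        ]
        pairs = chromo.reciprocal_best(ab, ba)
        assert [(p.query_gene, p.ref_gene) for p in pairs] == [
            ("g2", "h2"), ("g3", "h3")
        ]


class TestDotplot:
    def test_rows_sorted_and_midpoints(self):
        pairs = [
            chromo.OrthologPair("g2", "h2", 1.0),
            chromo.OrthologPair("g1", "h1", 1.0),
        ]
        qc = {"g1": ("q13", 100, 200), "g2": ("q13", 400, 500)}
        rc = {"h1": ("r13", 1000, 1100), "h2": ("r3", 50, 60)}
        rows, skipped = chromo.dotplot_table(pairs, qc, rc)
        assert skipped == 0
        assert rows == [("q13", 150, "r13", 1050), ("q13", 450, "r3", 55)]

    def test_empty_and_missing_coordinates(self):
        rows, skipped = chromo.dotplot_table([], {}, {})
        assert rows == [] and skipped == 0
        pairs = [chromo.OrthologPair("g1", "h1", 1.0)]
        rows, skipped = chromo.dotplot_table(pairs, {}, {})
        assert rows == [] and skipped == 1

    def test_translocated_block_appears_off_diagonal(self, random_seq):
        """Planted gene-block move shows up as an off-diagonal cluster."""
        pairs = [chromo.OrthologPair(f"g{i}", f"h{i}", 1.0) for i in range(10)]
        qc = {f"g{i}": ("q1", 1000 * i, 1000 * i + 100) for i in range(10)}
        rc = {f"h{i}": ("r1", 1000 * i, 1000 * i + 100) for i in range(7)}
        rc.update({f"h{i}": ("r5", 1000 * i, 1000 * i + 100) for i in range(7, 10)})
        rows, _ = chromo.dotplot_table(pairs, qc, rc)
        off = [r for r in rows if r[2] == "r5"]
        assert len(off) == 3


class TestReadMapper:
    def test_exact_reads_map_to_their_origin(self, small_genome):
        from congener import synthdata as sd

        rs = sd.simulate_pairs(
            small_genome, [sd.LibrarySpec("f", 300, 30, "FR", 2.0)], seed=5
        )[0]
        idx = chromo.GenomeIndex(small_genome)
        mp = chromo.map_reads([rs], idx)
        assert mp.mapped.mean() > 0.99
        # mapped reads really match the reference at their position
        for i in np.flatnonzero(mp.mapped)[:200]:
            if mp.cigars[i] is None:
                win = idx.codes[mp.gstart[i] : mp.gstart[i] + mp.read_length]
                assert np.array_equal(win, mp.oriented_read(i))

    def test_clip_cigar_anchors_and_soft_clips(self):
        got = chromo._clip_cigar("3X50=2X30=5X", anchor=12)
        assert got is not None
        cigar, pre_t, matched, edits = got
        assert cigar == "3S82M5S"
        assert pre_t == 3 and matched == 82 and edits == 2

    def test_clip_cigar_without_anchor_rejects(self):
        assert chromo._clip_cigar("5=1X5=1X5=", anchor=12) is None
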