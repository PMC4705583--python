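"""Whole-pipeline recovery benchmarks on synthetic truth.

Each function regenerates its scenario from a seed, runs the relevant
pipeline end to end and scores the result against the planted truth.
The scenario shapes follow the sequencing design the toolkit models:
2 Mb genomes across 4 chromosomes, tiered 30x/17x/5x error-free paired
libraries with 100 bp reads, ~1 point change per 100 bp and short InDels
at a tenth of that rate.
"""

from __future__ import annotations

import math

import numpy as np

from . import assist, chromo, synthdata as sd, telandscape, varcall

__all__ = [
    "gap_fill_benchmark",
    "variant_recovery_benchmark",
    "rearrangement_benchmark",
    "placement_benchmark",
    "kimura_benchmark",
]


def gap_fill_benchmark(
    seed: int = 1,
    genome_length: int = 2_000_000,
    n_chromosomes: int = 4,
    n_gaps: int = 100,
    gap_len_range: tuple[int, int] = (20, 500),
) -> dict:
    """Plant N-run gaps, rebuild their content from tiered mate pairs.

    Returns the fraction of gaps reaching ``filled`` status and the
    fraction of fills that equal the removed sequence byte for byte.
    """
    cfg = sd.SimConfig(genome_length=genome_length, n_chromosomes=n_chromosomes,
                       seed=seed)
    genome = sd.simulate_reference(cfg)
    scaffolds, truth = sd.fragment_scaffolds(genome, n_gaps, gap_len_range,
                                             seed=seed)
    readsets = sd.simulate_pairs(genome, sd.DEFAULT_LIBRARIES, seed=seed)
    index = chromo.GenomeIndex(scaffolds)
    mapping = chromo.map_reads(readsets, index)
    tables = assist.pair_table(mapping)
    models = [assist.build_insert_model(t) for t in tables]
    keeps = [assist.filter_pairs(t, m) for t, m in zip(tables, models)]
    bridges = assist.find_bridges(scaffolds, mapping, tables, models, keeps)
    results = assist.fill_all_gaps(scaffolds, mapping, tables, models, keeps,
                                   bridges)
    truth_fills = {(g.scaffold, g.gap_index): g.fill for g in truth.gap_fills}
    filled = [r for r in results if r.status == "filled"]
    exact = sum(
        r.fill == truth_fills[(r.scaffold, r.gap_index)] for r in filled
    )
    return {
        "n_gaps": n_gaps,
        "n_bridged": len(bridges),
        "n_filled": len(filled),
        "filled_pct": 100.0 * len(filled) / n_gaps,
        "exact_pct": 100.0 * exact / len(filled) if filled else 0.0,
    }


def variant_recovery_benchmark(
    seed: int = 1,
    genome_length: int = 2_000_000,
    n_chromosomes: int = 4,
    snp_rate: float = 0.01,
    indel_rate: float = 0.001,
    coverage: float = 30.0,
) -> dict:
    """Call SNCs from 30x error-free reads of a diverged genome against the
    reference and score against the planted truth."""
    cfg = sd.SimConfig(genome_length=genome_length, n_chromosomes=n_chromosomes,
                       snp_rate=snp_rate, indel_rate=indel_rate, seed=seed)
    reference = sd.simulate_reference(cfg)
    derived, truth = sd.diverge_genome(reference, cfg)
    readsets = sd.simulate_pairs(
        derived, [sd.LibrarySpec("frag300", 300, 30.0, "FR", coverage)],
        seed=seed,
    )
    index = chromo.GenomeIndex(reference)
    mapping = chromo.map_reads(readsets, index)
    pileup = varcall.build_pileup(mapping)
    variants = varcall.call_variants(pileup)
    called = {v.key for v in variants if v.type == "SNC"}
    truth_keys = truth.snc_keys()
    tp = len(called & truth_keys)
    rate_n, _ = varcall.polymorphism_rate(len(called), genome_length)
    truth_rate_n, _ = varcall.polymorphism_rate(len(truth_keys), genome_length)
    return {
        "n_truth_snc": len(truth_keys),
        "n_called_snc": len(called),
        "sensitivity_pct": 100.0 * tp / len(truth_keys),
        "precision_pct": 100.0 * tp / len(called) if called else 0.0,
        "rate_one_per_bp": rate_n,
        "truth_rate_one_per_bp": truth_rate_n,
    }


def rearrangement_benchmark(
    seed: int = 1,
    genome_length: int = 2_000_000,
    n_chromosomes: int = 4,
    n_translocations: int = 5,
    translocation_min_len: int = 25_000,
) -> dict:
    """Detect planted inter-chromosomal translocations with the 20 kb rule;
    a translocation-free control genome supplies the false-positive count.

    Contigs are cut so that every planted junction lies at least 25 kb
    inside a contig — the rule can only fire on a breakpoint-spanning
    contig, which is the regime it is defined for.
    """
    cfg = sd.SimConfig(
        genome_length=genome_length, n_chromosomes=n_chromosomes,
        snp_rate=0.01, indel_rate=0.0,
        n_translocations=n_translocations,
        translocation_min_len=translocation_min_len, seed=seed,
    )
    reference = sd.simulate_reference(cfg)
    derived, truth = sd.diverge_genome(reference, cfg)
    avoid = []
    for ev in truth.rearrangements:
        avoid.append((ev.dest_chrom, ev.derived_start))
        avoid.append((ev.dest_chrom, ev.derived_end))
    contigs, _origins = sd.shred_genome(
        derived, piece_len=120_000, seed=seed, avoid=avoid,
        margin=translocation_min_len, flip_fraction=0.3, tier="contig",
    )
    clusters = chromo.anchor_map(contigs, reference)
    events = chromo.detect_interchromosomal(clusters, min_span=20_000)
    # a planted translocation counts as detected when an event on a contig
    # overlapping its segment names its source chromosome (two same-source
    # segments inside one contig are covered by a single chromosome-pair
    # event, which is how the rule counts them)
    piece_span = {o.piece_id: o for o in _origins}
    detected = 0
    for ev in truth.rearrangements:
        hit = False
        for e in events:
            o = piece_span[e.contig]
            if o.chrom != ev.dest_chrom:
                continue
            if o.start < ev.derived_end and o.end > ev.derived_start:
                if ev.src_chrom in (e.chrom_a, e.chrom_b):
                    hit = True
                    break
        detected += hit

    cfg0 = sd.SimConfig(genome_length=genome_length,
                        n_chromosomes=n_chromosomes, snp_rate=0.01,
                        indel_rate=0.0, seed=seed + 1)
    ref0 = sd.simulate_reference(cfg0)
    der0, _ = sd.diverge_genome(ref0, cfg0)
    contigs0, _ = sd.shred_genome(der0, piece_len=120_000, seed=seed + 1,
                                  flip_fraction=0.3, tier="contig")
    control = chromo.detect_interchromosomal(
        chromo.anchor_map(contigs0, ref0), min_span=20_000
    )
    return {
        "n_planted": n_translocations,
        "n_detected": detected,
        "n_events": len(events),
        "control_false_positives": len(control),
    }


def placement_benchmark(
    seed: int = 1,
    genome_length: int = 2_000_000,
    n_chromosomes: int = 4,
    piece_len: int = 50_000,
) -> dict:
    """Shred a diverged genome into oriented scaffolds and place them back
    onto the reference chromosomes."""
    cfg = sd.SimConfig(genome_length=genome_length, n_chromosomes=n_chromosomes,
                       snp_rate=0.01, indel_rate=0.001, seed=seed)
    reference = sd.simulate_reference(cfg)
    derived, _ = sd.diverge_genome(reference, cfg)
    pieces, origins = sd.shred_genome(derived, piece_len=piece_len, seed=seed)
    clusters = chromo.anchor_map(pieces, reference)
    placements, _agp = chromo.place_scaffolds(clusters, pieces)
    origin = {o.piece_id: o for o in origins}
    placed = [p for p in placements if p.status == "placed"]
    correct = sum(
        1
        for p in placed
        if origin[p.scaffold].chrom == p.chromosome
        and origin[p.scaffold].strand == p.orientation
    )
    wrong_chrom = sum(
        1 for p in placed if origin[p.scaffold].chrom != p.chromosome
    )
    return {
        "n_scaffolds": len(pieces),
        "n_placed": len(placed),
        "correct_pct": 100.0 * correct / len(pieces),
        "wrong_chromosome": wrong_chrom,
    }


def kimura_benchmark(seed: int = 1, copy_len: int = 1_000, n_copies: int = 25) -> dict:
    """Numerical and statistical checks of the K2P age machinery.

    Reports the worst absolute deviation of :func:`kimura_distance` from a
    direct evaluation of the closed form over a (p, q) grid, and the worst
    relative error of median recovered K against the Jukes-Cantor-corrected
    truth for copies planted at 1/5/10/20 % divergence.
    """
    worst_formula = 0.0
    for p in np.linspace(0.0, 0.3, 16):
        for q in np.linspace(0.0, 0.3, 16):
            if 2 * p + q >= 1 or 2 * q >= 1:
                continue
            direct = -0.5 * math.log(1 - 2 * p - q) - 0.25 * math.log(1 - 2 * q)
            worst_formula = max(
                worst_formula,
                abs(telandscape.kimura_distance(float(p), float(q)) - direct),
            )
    rng = np.random.default_rng(seed)
    consensus = sd._seq.decode(rng.integers(0, 4, size=copy_len).astype(np.uint8))
    worst_rel = 0.0
    for d in (0.01, 0.05, 0.10, 0.20):
        ks = []
        for i in range(n_copies):
            crng = np.random.default_rng(seed + 37 * i + int(d * 1e4))
            copy = sd.mutate_to_divergence(consensus, d, crng)
            p, q, _ = telandscape.pq_from_alignment(copy, consensus)
            ks.append(telandscape.kimura_distance(p, q))
        jc = -0.75 * math.log(1 - 4 * d / 3)
        worst_rel = max(worst_rel, abs(float(np.median(ks)) - jc) / jc)
    return {
        "formula_max_abs_error": worst_formula,
        "recovery_max_rel_error": worst_rel,
    }
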