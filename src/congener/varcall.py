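"""Pileup variant calling and effect classification.

Single nucleotide changes (SNCs) and short InDels are called from read
pileups with the thresholds of the original comparative pipeline: minimum
coverage of three reads and a p-value cutoff of 0.1, where the p-value is
a one-sided binomial tail P(X >= alt_depth | n = depth, error_rate)
testing the alternate-allele count against the sequencing error rate, plus
a minimum alternate-allele fraction.  The sequenced lines are inbred, so
calls are substitution events between genomes, not genotypes.

Effects are classified against transcript models into the standard
annotation categories (synonymous/non-synonymous coding, stop/start
changes, splice sites, UTRs, introns, up/downstream, intergenic, InDel
categories) with the high-impact tier covering the protein-disrupting
events.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq
from intervaltree import IntervalTree
from scipy.stats import binom

from . import _seq
from .chromo import GenomeIndex, MappingResult, _iter_cigar
from .core_io import GeneModel, SeqRecord, VariantRecordOut

__all__ = [
    "Pileup",
    "Variant",
    "EffectAnnotation",
    "EffectSummary",
    "DensityTrack",
    "build_pileup",
    "call_variants",
    "classify_effects",
    "summarize_effects",
    "density_track",
    "partition_species",
    "polymorphism_rate",
    "HIGH_IMPACT",
]

CATEGORIES = (
    "downstream", "codon_indel", "exon", "intergenic", "intron",
    "non_synonymous_coding", "splice_site", "start_lost", "stop_gained",
    "stop_lost", "synonymous_coding", "upstream", "utr3", "utr5",
    "frame_shift", "exon_deleted", "chromosome_large_deletion",
)

HIGH_IMPACT = frozenset(
    {
        "frame_shift", "splice_site", "stop_gained", "stop_lost",
        "start_lost", "exon_deleted", "chromosome_large_deletion",
    }
)
_MODERATE = frozenset({"non_synonymous_coding", "codon_indel"})
_LOW = frozenset({"synonymous_coding"})


def impact_of(category: str) -> str:
    if category in HIGH_IMPACT:
        return "high"
    if category in _MODERATE:
        return "moderate"
    if category in _LOW:
        return "low"
    return "modifier"


@dataclass
class Variant:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    type: str  # "SNC" | "InDel"
    depth: int
    alt_depth: int
    p_value: float

    @property
    def alt_fraction(self) -> float:
        return self.alt_depth / self.depth if self.depth else 0.0

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    def to_record(self) -> VariantRecordOut:
        return VariantRecordOut(
            self.chrom, self.pos, self.ref, self.alt,
            self.depth, self.alt_depth, self.p_value,
        )


# ---------------------------------------------------------------------------
# pileup


@dataclass
class Pileup:
    """Base counts over the concatenated genome plus indel observations.

    ``counts`` has one row per global position and four columns (A,C,G,T);
    ``indels`` maps a global anchor position (the base before the event)
    to a Counter of observation strings ``+SEQ`` / ``-LEN``.
    """

    index: GenomeIndex
    counts: np.ndarray
    indels: dict[int, Counter] = field(default_factory=dict)


def build_pileup(
    mapping: MappingResult, chunk: int = 50_000, end_trim: int = 10
) -> Pileup:
    """Accumulate mapped reads into per-position base counts.

    Full-length ungapped matches go through a vectorized bincount path;
    reads with indel CIGARs are walked op by op and contribute their indel
    observations anchored VCF-style at the preceding reference base.

    ``end_trim`` bases at each end of every aligned read are excluded from
    the pileup: near an InDel the last few bases of an overhanging read
    systematically misalign, and untrimmed they fabricate consistent
    alternate alleles on columns that correct reads skip.
    """
    G = len(mapping.index.codes)
    counts = np.zeros((G, 4), dtype=np.int32)
    L = mapping.read_length
    t0, t1 = end_trim, L - end_trim
    if t1 <= t0:
        raise ValueError("end_trim leaves no read interior")
    plain = np.flatnonzero(
        mapping.mapped & np.array([c is None for c in mapping.cigars])
    )
    span = np.arange(t0, t1, dtype=np.int64)
    for lo in range(0, len(plain), chunk):
        sel = plain[lo : lo + chunk]
        rows = mapping.reads[sel]
        flip = mapping.strand[sel] == 1
        if flip.any():
            rows = rows.copy()
            rows[flip] = np.where(
                rows[flip, ::-1] >= 4, 4, 3 - rows[flip, ::-1]
            )
        rows = rows[:, t0:t1]
        pos = mapping.gstart[sel][:, None] + span
        ok = rows < 4
        flat = (pos * 4 + rows)[ok]
        if len(flat):
            bc = np.bincount(flat, minlength=4 * G)
            counts += bc.reshape(G, 4).astype(np.int32)
    indels: dict[int, Counter] = {}
    gapped = np.flatnonzero(
        mapping.mapped & np.array([c is not None for c in mapping.cigars])
    )
    for i in gapped:
        bases = mapping.oriented_read(i)
        t = int(mapping.gstart[i])
        q = 0
        for n, op in _iter_cigar(mapping.cigars[i]):
            if op in "M=X":
                qpos = np.arange(q, q + n)
                keep = (qpos >= t0) & (qpos < t1)
                seg = bases[q : q + n]
                okk = (seg < 4) & keep
                idx = (t + np.arange(n))[okk] * 4 + seg[okk]
                np.add.at(counts.ravel(), idx, 1)
                t += n
                q += n
            elif op == "I":
                if q >= t0 and q + n <= t1:
                    ins = _seq.decode(bases[q : q + n])
                    indels.setdefault(t - 1, Counter())[f"+{ins}"] += 1
                q += n
            elif op == "D":
                if t0 <= q < t1:
                    indels.setdefault(t - 1, Counter())[f"-{n}"] += 1
                t += n
            elif op == "S":
                q += n
    return Pileup(mapping.index, counts, indels)


# ---------------------------------------------------------------------------
# calling


def call_variants(
    pileup: Pileup,
    min_coverage: int = 3,
    p_cutoff: float = 0.1,
    error_rate: float = 0.01,
    min_alt_fraction: float = 0.2,
) -> list[Variant]:
    """Call SNCs and InDels from a pileup.

    A site is called when depth >= min_coverage, the most frequent
    non-reference allele reaches min_alt_fraction of the depth, and the
    one-sided binomial tail p-value against ``error_rate`` falls below
    ``p_cutoff``.  InDel observations are tested identically against the
    column depth at their anchor base.
    """
    index = pileup.index
    counts = pileup.counts
    G = len(index.codes)
    depth = counts.sum(axis=1)
    refc = index.codes
    valid = (refc < 4) & (depth >= min_coverage)
    pos_valid = np.flatnonzero(valid)
    sub = counts[pos_valid].copy()
    ref_sel = refc[pos_valid].astype(np.int64)
    ref_count = sub[np.arange(len(sub)), ref_sel]
    sub[np.arange(len(sub)), ref_sel] = -1
    alt_allele = sub.argmax(axis=1)
    alt_depth = sub[np.arange(len(sub)), alt_allele]
    d = depth[pos_valid]
    frac_ok = alt_depth >= np.maximum(min_alt_fraction * d, 1)
    cand = np.flatnonzero(frac_ok)
    pv = binom.sf(alt_depth[cand] - 1, d[cand], error_rate)
    keep = pv < p_cutoff
    variants: list[Variant] = []
    gpos = pos_valid[cand[keep]]
    ci, local = index.to_local(gpos)
    for g, c, p, a, ad, dd, pval in zip(
        gpos, ci, local, alt_allele[cand[keep]], alt_depth[cand[keep]],
        d[cand[keep]], pv[keep],
    ):
        variants.append(
            Variant(
                index.names[c], int(p),
                _seq.decode(np.array([refc[g]], dtype=np.uint8)),
                _seq.decode(np.array([a], dtype=np.uint8)),
                "SNC", int(dd), int(ad), float(pval),
            )
        )
    # InDels: observations at equivalent anchors are pooled after
    # left-normalization, then tested against the anchor-column depth
    pooled: dict[tuple, int] = {}
    for anchor, obs in pileup.indels.items():
        if refc[anchor] >= 4:
            continue
        ci_, lp = index.to_local(np.array([anchor]))
        cidx = int(ci_[0])
        chrom = index.names[cidx]
        lpos = int(lp[0])
        base0 = int(index.starts[cidx])
        chrom_at = lambda i: _seq.decode(
            np.array([index.codes[base0 + i]], dtype=np.uint8)
        )
        anchor_base = chrom_at(lpos)
        for key, ad in obs.items():
            if key.startswith("+"):
                ref, alt = anchor_base, anchor_base + key[1:]
            else:
                n = int(key[1:])
                deleted = _seq.decode(index.codes[anchor + 1 : anchor + 1 + n])
                ref, alt = anchor_base + deleted, anchor_base
            npos, nref, nalt = _seq.left_align_indel(chrom_at, lpos, ref, alt)
            k = (chrom, npos, nref, nalt, base0)
            pooled[k] = pooled.get(k, 0) + ad
    deletion_spans: list[tuple[str, int, int]] = []
    for (chrom, lpos, ref, alt, base0), ad in pooled.items():
        dd = int(depth[base0 + lpos])
        if dd < min_coverage or ad < max(min_alt_fraction * dd, 1):
            continue
        pval = float(binom.sf(ad - 1, dd, error_rate))
        if pval >= p_cutoff:
            continue
        variants.append(Variant(chrom, lpos, ref, alt, "InDel", dd, int(ad), pval))
        if len(ref) > len(alt):
            deletion_spans.append((chrom, lpos + 1, lpos + len(ref)))
    # an SNC cannot live inside a deleted interval: stray read tails that
    # pile up on deleted columns are artifacts, not calls
    if deletion_spans:
        spans_by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, a, b in deletion_spans:
            spans_by_chrom.setdefault(chrom, []).append((a, b))
        variants = [
            v
            for v in variants
            if v.type != "SNC"
            or not any(
                a <= v.pos < b for a, b in spans_by_chrom.get(v.chrom, ())
            )
        ]
    variants.sort(key=lambda v: (v.chrom, v.pos))
    return variants


# ---------------------------------------------------------------------------
# effect classification


@dataclass
class EffectAnnotation:
    variant_key: tuple
    transcript_id: str | None
    gene_id: str | None
    category: str
    impact: str


class EffectClassifier:
    """Classifies variants against a set of transcript models.

    One variant yields one annotation per nearby transcript (matching the
    convention that a polymorphism can have several effects in
    neighbouring genes); a variant outside every transcript and its
    up/downstream windows yields a single intergenic annotation.
    """

    def __init__(
        self,
        models: Sequence[GeneModel],
        genome: Sequence[SeqRecord],
        updown_window: int = 5000,
        splice_window: int = 2,
    ):
        self.updown = updown_window
        self.splice = splice_window
        self.genome = {r.id: r.sequence for r in genome}
        self.chrom_len = {r.id: len(r.sequence) for r in genome}
        self.trees: dict[str, IntervalTree] = {}
        self.models = list(models)
        for m in self.models:
            t = self.trees.setdefault(m.chrom, IntervalTree())
            t[max(m.start - updown_window, 0) : m.end + updown_window] = m
        self._cds_cache: dict[str, str] = {}

    def _cds_seq(self, m: GeneModel) -> str:
        if m.transcript_id not in self._cds_cache:
            seq = "".join(self.genome[m.chrom][a:b] for a, b in m.cds)
            if m.strand == "-":
                seq = _seq.revcomp(seq)
            self._cds_cache[m.transcript_id] = seq
        return self._cds_cache[m.transcript_id]

    def classify(self, variant: Variant) -> list[EffectAnnotation]:
        chrom_seq = self.genome.get(variant.chrom)
        if chrom_seq is None:
            raise ValueError(f"unknown chromosome {variant.chrom}")
        if chrom_seq[variant.pos : variant.pos + len(variant.ref)] != variant.ref:
            raise ValueError(
                f"reference mismatch at {variant.chrom}:{variant.pos + 1}: "
                f"expected {variant.ref!r}"
            )
        out: list[EffectAnnotation] = []
        tree = self.trees.get(variant.chrom)
        span_end = variant.pos + max(len(variant.ref), 1)
        hits = sorted(tree[variant.pos:span_end], key=lambda iv: iv.data.transcript_id) if tree else []
        # chromosome-scale deletion outranks per-transcript annotation
        del_len = len(variant.ref) - len(variant.alt)
        if del_len > 0 and del_len > 0.01 * self.chrom_len[variant.chrom]:
            out.append(
                EffectAnnotation(variant.key, None, None,
                                 "chromosome_large_deletion", "high")
            )
        for iv in hits:
            m: GeneModel = iv.data
            cat = self._classify_one(variant, m)
            if cat is not None:
                out.append(
                    EffectAnnotation(variant.key, m.transcript_id, m.gene_id,
                                     cat, impact_of(cat))
                )
        if not out:
            out.append(
                EffectAnnotation(variant.key, None, None, "intergenic",
                                 "modifier")
            )
        return out

    # -- helpers ---------------------------------------------------------

    def _classify_one(self, v: Variant, m: GeneModel) -> str | None:
        pos = v.pos
        if v.type == "InDel":
            return self._classify_indel(v, m)
        if pos < m.start:
            side = "upstream" if m.strand == "+" else "downstream"
            return side if pos >= m.start - self.updown else None
        if pos >= m.end:
            side = "downstream" if m.strand == "+" else "upstream"
            return side if pos < m.end + self.updown else None
        in_exon = any(a <= pos < b for a, b in m.exons)
        if not in_exon:
            near = min(
                min(abs(pos - a), abs(pos - (b - 1))) for a, b in m.exons
            )
            return "splice_site" if near <= self.splice else "intron"
        if not m.cds:
            return "exon"
        cds_lo, cds_hi = m.cds[0][0], m.cds[-1][1]
        in_cds = any(a <= pos < b for a, b in m.cds)
        if not in_cds:
            if pos < cds_lo:
                return "utr5" if m.strand == "+" else "utr3"
            if pos >= cds_hi:
                return "utr3" if m.strand == "+" else "utr5"
            return "exon"  # exonic gap inside the CDS span (unusual models)
        return self._coding_snc(v, m)

    def _coding_snc(self, v: Variant, m: GeneModel) -> str:
        # CDS-relative offset of the variant
        off = 0
        for a, b in m.cds:
            if a <= v.pos < b:
                off += v.pos - a
                break
            off += b - a
        cds = self._cds_seq(m)
        if m.strand == "-":
            off = len(cds) - 1 - off
            ref_base = _seq.revcomp(v.ref)
            alt_base = _seq.revcomp(v.alt)
        else:
            ref_base, alt_base = v.ref, v.alt
        ci = off // 3
        k = off % 3
        codon = cds[3 * ci : 3 * ci + 3]
        if len(codon) < 3:
            return "exon"
        if codon[k] != ref_base:
            raise ValueError(
                f"{m.transcript_id}: CDS/reference inconsistency at {v.chrom}:{v.pos + 1}"
            )
        alt_codon = codon[:k] + alt_base + codon[k + 1 :]
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq(alt_codon).translate())
        if ci == 0 and m.complete and aa_ref == "M" and aa_alt != "M":
            return "start_lost"
        if aa_ref != "*" and aa_alt == "*":
            return "stop_gained"
        if aa_ref == "*" and aa_alt != "*":
            return "stop_lost"
        return "synonymous_coding" if aa_ref == aa_alt else "non_synonymous_coding"

    def _classify_indel(self, v: Variant, m: GeneModel) -> str | None:
        # the changed interval excludes the anchor base
        lo = v.pos + 1
        hi = v.pos + len(v.ref) if len(v.ref) > 1 else v.pos + 1
        net = len(v.alt) - len(v.ref)
        if hi <= m.start or lo >= m.end:
            left = hi <= m.start
            if left and hi >= m.start - self.updown:
                return "upstream" if m.strand == "+" else "downstream"
            if not left and lo < m.end + self.updown:
                return "downstream" if m.strand == "+" else "upstream"
            return None
        if net < 0:
            for a, b in m.exons:
                if lo <= a and hi >= b:
                    return "exon_deleted"
        touches_cds = any(lo < b and hi > a for a, b in m.cds) or (
            net > 0 and any(a <= v.pos < b - 1 for a, b in m.cds)
        )
        if touches_cds:
            return "frame_shift" if net % 3 != 0 else "codon_indel"
        in_exon = any(lo < b and hi > a for a, b in m.exons) or (
            net > 0 and any(a <= v.pos < b - 1 for a, b in m.exons)
        )
        if in_exon:
            if not m.cds:
                return "exon"
            cds_lo, cds_hi = m.cds[0][0], m.cds[-1][1]
            if hi <= cds_lo:
                return "utr5" if m.strand == "+" else "utr3"
            if lo >= cds_hi:
                return "utr3" if m.strand == "+" else "utr5"
            return "exon"
        near = min(
            min(abs(p - a), abs(p - (b - 1)))
            for a, b in m.exons
            for p in (lo, hi - 1)
        )
        return "splice_site" if near <= self.splice else "intron"


def classify_effects(
    variants: Iterable[Variant],
    models: Sequence[GeneModel],
    genome: Sequence[SeqRecord],
    updown_window: int = 5000,
    splice_window: int = 2,
) -> list[EffectAnnotation]:
    clf = EffectClassifier(models, genome, updown_window, splice_window)
    out: list[EffectAnnotation] = []
    for v in variants:
        out.extend(clf.classify(v))
    return out


# ---------------------------------------------------------------------------
# summaries


@dataclass
class EffectSummary:
    counts: dict[str, int]
    percentages: dict[str, float]
    total: int


def summarize_effects(
    annotations: Iterable[EffectAnnotation] | Mapping[str, int],
) -> EffectSummary:
    """Per-category counts and percentages of total effects (2-dp rounding).

    Effects, not variants, are the counting unit: a variant annotated
    against three transcripts contributes three effects.  Accepts either a
    list of annotations or a ready category->count mapping.
    """
    if isinstance(annotations, Mapping):
        counts = {k: int(v) for k, v in annotations.items()}
    else:
        counts = Counter(a.category for a in annotations)
        counts = dict(counts)
    total = sum(counts.values())
    if total == 0:
        return EffectSummary({}, {}, 0)
    pct = {k: round(100.0 * v / total, 2) for k, v in counts.items()}
    return EffectSummary(counts, pct, total)


@dataclass
class DensityTrack:
    chrom: str
    bin_width: int
    counts: np.ndarray
    normalized: np.ndarray


def density_track(
    variants: Iterable[Variant],
    chrom_lengths: Mapping[str, int],
    bin_width: int = 100_000,
    normalizer: float = 3000.0,
) -> list[DensityTrack]:
    """SNC counts per fixed-width bin, normalized by a plotting constant.

    The trailing partial bin is kept; normalized values are not capped.
    """
    per: dict[str, list[int]] = {c: [] for c in chrom_lengths}
    for v in variants:
        per.setdefault(v.chrom, []).append(v.pos)
    out = []
    for chrom, length in chrom_lengths.items():
        nbins = max((length + bin_width - 1) // bin_width, 1)
        counts = np.zeros(nbins, dtype=np.int64)
        pos = np.asarray(per.get(chrom, []), dtype=np.int64)
        if len(pos):
            counts = np.bincount(pos // bin_width, minlength=nbins)
        out.append(
            DensityTrack(chrom, bin_width, counts, counts / normalizer)
        )
    return out


def partition_species(
    variants_b: Iterable[Variant], variants_c: Iterable[Variant]
) -> dict[str, set]:
    """Split two call sets against the same reference into shared/specific.

    Sharing requires the identical alternate allele at the identical site;
    the same site with different alt alleles lands in both specific sets.
    """
    kb = {v.key for v in variants_b}
    kc = {v.key for v in variants_c}
    return {
        "shared": kb & kc,
        "only_b": kb - kc,
        "only_c": kc - kb,
    }


def polymorphism_rate(n_variants: int, denominator_bp: int) -> tuple[int, float]:
    """Report '1 change per N bp'; returns (N, raw per-bp rate)."""
    if n_variants <= 0:
        raise ValueError("rate undefined for zero variants")
    return int(round(denominator_bp / n_variants)), n_variants / denominator_bp
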