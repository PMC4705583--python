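"""Transposable-element comparative statistics.

Covers the TE side of the comparative analysis: the 80 bp / 80 % identity
filter applied before counting, per-family genome coverage as per-position
unions, Kimura two-parameter (K2P) copy ages computed from the
transition/transversion proportions of copy-vs-consensus alignments, age
landscapes binned on a 0-50 K*100 axis, and genome-vs-transcriptome
representation ("spider") tables.

The K2P distance K = -1/2 ln(1-2p-q) - 1/4 ln(1-2q) uses the standard
assignment: p is the transition proportion (purine<->purine or
pyrimidine<->pyrimidine) and q the transversion proportion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_io import RepeatHit

__all__ = [
    "TEFilterParams",
    "FamilyCoverage",
    "KimuraRecord",
    "LandscapeBin",
    "SpiderRow",
    "filter_te_hits",
    "coverage_table",
    "kimura_distance",
    "pq_from_alignment",
    "landscape",
    "spider_table",
]

_PURINES = frozenset("AG")


@dataclass(frozen=True)
class TEFilterParams:
    min_length: int = 80
    min_identity: float = 80.0

    def __post_init__(self):
        if self.min_length < 0 or self.min_identity < 0:
            raise ValueError("filter thresholds must be non-negative")


def filter_te_hits(
    hits: Iterable[RepeatHit], params: TEFilterParams = TEFilterParams()
) -> list[RepeatHit]:
    """Drop hits strictly shorter than min_length or strictly below
    min_identity (identity = 100 - percent divergence); boundaries are
    inclusive."""
    return [
        h
        for h in hits
        if h.length >= params.min_length and h.identity >= params.min_identity
    ]


@dataclass
class FamilyCoverage:
    label: str
    covered_bp: int
    percent_of_genome: float
    copy_count: int


def _union_bp(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    intervals.sort()
    total = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)


def coverage_table(
    hits: Sequence[RepeatHit],
    genome_length: int,
    group: str = "class_family",
) -> dict[str, FamilyCoverage]:
    """Per-position union coverage per repeat group, plus a Total row.

    ``group`` selects the grouping key: ``class_family`` (Table-4 style
    rows such as DNA/hAT) or ``superfamily`` (the class before the slash).
    Positions covered by hits of several groups count once in the Total
    row; within that row, credit goes to whichever hit is longer, which
    does not change the union.
    """
    if group not in ("class_family", "superfamily"):
        raise ValueError("group must be class_family or superfamily")
    per: dict[str, list[tuple[int, int]]] = {}
    counts: dict[str, int] = {}
    everything: list[tuple[int, int]] = []
    # intervals are disambiguated per chromosome via large offsets
    chrom_offsets: dict[str, int] = {}
    next_off = 0
    for h in hits:
        if h.chrom not in chrom_offsets:
            chrom_offsets[h.chrom] = next_off
            next_off += 1 << 40  # larger than any plausible chromosome
        off = chrom_offsets[h.chrom]
        key = h.class_family if group == "class_family" else h.superfamily_class
        per.setdefault(key, []).append((off + h.start, off + h.end))
        counts[key] = counts.get(key, 0) + 1
        everything.append((off + h.start, off + h.end))
    out: dict[str, FamilyCoverage] = {}
    for key in sorted(per):
        bp = _union_bp(per[key])
        out[key] = FamilyCoverage(
            key, bp, 100.0 * bp / genome_length, counts[key]
        )
    tot = _union_bp(everything)
    out["Total"] = FamilyCoverage(
        "Total", tot, 100.0 * tot / genome_length, len(hits)
    )
    return out


@dataclass(frozen=True)
class KimuraRecord:
    p: float
    q: float
    K: float | None  # None when outside the K2P domain
    aligned_sites: int = 0

    @property
    def defined(self) -> bool:
        return self.K is not None


def kimura_distance(p: float, q: float) -> float:
    """K2P distance K = -1/2 ln(1-2p-q) - 1/4 ln(1-2q).

    Raises ValueError outside the domain (2p+q >= 1 or 2q >= 1); callers
    that prefer flagged records should use :func:`kimura_record`.
    """
    if p < 0 or q < 0:
        raise ValueError("p and q must be non-negative")
    if 2 * p + q >= 1 or 2 * q >= 1:
        raise ValueError("K undefined: 2p+q or 2q reaches 1")
    return -0.5 * math.log(1 - 2 * p - q) - 0.25 * math.log(1 - 2 * q)


def kimura_record(p: float, q: float, aligned_sites: int = 0) -> KimuraRecord:
    try:
        return KimuraRecord(p, q, kimura_distance(p, q), aligned_sites)
    except ValueError:
        return KimuraRecord(p, q, None, aligned_sites)


def pq_from_alignment(copy_seq: str, consensus_seq: str) -> tuple[float, float, int]:
    """Transition/transversion proportions from an aligned copy/consensus pair.

    The two strings must be equal length (gapped alignment); gap and N
    columns are excluded from the aligned-site count.
    """
    if len(copy_seq) != len(consensus_seq):
        raise ValueError("aligned sequences must have equal length")
    sites = ti = tv = 0
    for a, b in zip(copy_seq.upper(), consensus_seq.upper()):
        if a in "-.N" or b in "-.N":
            continue
        sites += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            ti += 1
        else:
            tv += 1
    if sites == 0:
        raise ValueError("no aligned sites")
    return ti / sites, tv / sites, sites


@dataclass
class LandscapeBin:
    k_low: int
    k_high: int
    covered_bp: dict[str, int]


def landscape(
    entries: Iterable[tuple[str, float, int]], k_max: int = 50
) -> tuple[list[LandscapeBin], dict[str, int]]:
    """Bin TE-covered bp by copy age.

    ``entries`` are (superfamily, K*100, covered_bp) triples — the axis is
    the K2P distance scaled by 100, binned at integer width over
    [0, k_max].  Returns the bins plus an overflow tally for K*100 > k_max.
    """
    bins = [LandscapeBin(i, i + 1, {}) for i in range(k_max)]
    overflow: dict[str, int] = {}
    for fam, k100, bp in entries:
        if k100 < 0:
            raise ValueError("negative K")
        if k100 > k_max:
            overflow[fam] = overflow.get(fam, 0) + bp
            continue
        # K*100 exactly == k_max joins the last bin ([49, 50] is closed)
        idx = min(int(k100), k_max - 1)
        b = bins[idx].covered_bp
        b[fam] = b.get(fam, 0) + bp
    return bins, overflow


@dataclass
class SpiderRow:
    superfamily: str
    genome_log10_pct: float | None
    transcriptome_log10_pct: float | None
    flag: str  # over | under | proportional | absent


def spider_table(
    genome_cov: Mapping[str, float],
    tx_cov: Mapping[str, float],
    ratio_threshold: float = 2.0,
) -> list[SpiderRow]:
    """Genome vs transcriptome representation per superfamily.

    Inputs map superfamily -> percent covered.  A superfamily is flagged
    ``over`` (``under``) when its transcriptome percent exceeds (falls
    below) the genome percent by at least ``ratio_threshold``-fold;
    zero on either side makes the log undefined and flags ``absent``.
    """
    rows = []
    for fam in sorted(set(genome_cov) | set(tx_cov)):
        g = float(genome_cov.get(fam, 0.0))
        t = float(tx_cov.get(fam, 0.0))
        if g <= 0.0 or t <= 0.0:
            rows.append(
                SpiderRow(
                    fam,
                    math.log10(g) if g > 0 else None,
                    math.log10(t) if t > 0 else None,
                    "absent",
                )
            )
            continue
        if t >= ratio_threshold * g:
            flag = "over"
        elif t <= g / ratio_threshold:
            flag = "under"
        else:
            flag = "proportional"
        rows.append(SpiderRow(fam, math.log10(g), math.log10(t), flag))
    return rows
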