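"""The assisted-assembly core.

Given a scaffolded assembly with N-run gaps and tiered paired-end
libraries aligned to it, this module

1. models each library's insert-size distribution from the alignments and
   keeps only pairs with the expected orientation and an insert inside the
   central 99 % interval of the dominant histogram mode,
2. finds consecutive contigs bridged by mate pairs that carry an exact
   30-mer anchor on each side of the gap,
3. performs bounded local de novo assembly inside each bridged gap by
   walking a 30-mer graph built only from filtered reads and reads mapped
   near contig ends, requiring a unique extension at every step,
4. detects cross-scaffold structural differences from pairs whose mates
   map to different scaffolds and joins mutually-best scaffold ends, and
5. merges the assisted assembly with an independent de novo assembly,
   appending de novo contigs that the assisted genome does not already
   cover.

Ambiguity is always an explicit failure status, never a guess: a gap walk
that meets a fork stops and reports it.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _seq
from .chromo import GenomeIndex, MappingResult, anchor_map
from .core_io import SeqRecord, find_gaps

__all__ = [
    "InsertSizeModel",
    "PairTable",
    "Bridge",
    "GapFillResult",
    "CrossLink",
    "MergeReport",
    "pair_table",
    "build_insert_model",
    "filter_pairs",
    "find_bridges",
    "KmerGraph",
    "collect_gap_reads",
    "fill_gap",
    "fill_all_gaps",
    "apply_gap_fills",
    "cross_links_from_mapping",
    "reorder_scaffolds",
    "merge_assemblies",
]


# ---------------------------------------------------------------------------
# pairs and insert models


@dataclass
class PairTable:
    """Per-pair geometry of one library's alignments.

    ``orientation`` holds "FR", "RF" or "NA" per pair (NA: unmapped mate,
    different targets, or same-strand mates); ``insert`` is the outer span
    (rightmost end minus leftmost start) where defined.
    """

    library_name: str
    expected_orientation: str
    insert_mean: int
    insert_sd: float
    rows1: np.ndarray
    rows2: np.ndarray
    both_mapped: np.ndarray
    same_target: np.ndarray
    orientation: np.ndarray
    insert: np.ndarray
    left_row: np.ndarray  # row index of the leftmost mate (or -1)


def pair_table(mapping: MappingResult) -> list[PairTable]:
    """Derive pair geometry for every library block of a mapping."""
    out = []
    idx = mapping.index
    ci_all, _ = idx.to_local(np.where(mapping.gstart >= 0, mapping.gstart, 0))
    for blk in mapping.pair_blocks:
        n = blk.n_pairs
        r1 = np.arange(blk.first1, blk.first1 + n)
        r2 = np.arange(blk.first2, blk.first2 + n)
        m1, m2 = mapping.mapped[r1], mapping.mapped[r2]
        both = m1 & m2
        same = both & (ci_all[r1] == ci_all[r2])
        s1, s2 = mapping.gstart[r1], mapping.gstart[r2]
        e1 = s1 + mapping.read_length
        e2 = s2 + mapping.read_length
        left_is_1 = s1 <= s2
        left = np.where(left_is_1, s1, s2)
        right = np.where(left_is_1, e2, e1)
        insert = np.where(same, right - left, -1)
        st1, st2 = mapping.strand[r1], mapping.strand[r2]
        left_strand = np.where(left_is_1, st1, st2)
        right_strand = np.where(left_is_1, st2, st1)
        orient = np.full(n, "NA", dtype="U2")
        fr = same & (left_strand == 0) & (right_strand == 1)
        rf = same & (left_strand == 1) & (right_strand == 0)
        orient[fr] = "FR"
        orient[rf] = "RF"
        out.append(
            PairTable(
                blk.library_name,
                blk.orientation,
                blk.insert_mean,
                blk.insert_sd,
                r1, r2, both, same, orient, insert,
                np.where(same, np.where(left_is_1, r1, r2), -1),
            )
        )
    return out


@dataclass
class InsertSizeModel:
    library_name: str
    histogram: dict[int, int]
    selected_range: tuple[int, int]
    expected_orientation: str
    mode: int

    def contains(self, insert: int) -> bool:
        return self.selected_range[0] <= insert <= self.selected_range[1]


def build_insert_model(
    table: PairTable, smooth_window: int = 10, central_mass: float = 0.99
) -> InsertSizeModel:
    """Histogram the observed inserts of properly oriented pairs and select
    the central 99 % interval of the dominant (10 bp-smoothed) mode.

    Pairs with the wrong orientation or mates on different targets are
    excluded from the histogram.  Fewer than 100 usable pairs is an error
    ("library underpowered").
    """
    use = table.orientation == table.expected_orientation
    inserts = table.insert[use]
    inserts = inserts[inserts > 0]
    if len(inserts) < 100:
        raise ValueError(f"library {table.library_name} underpowered: "
                         f"{len(inserts)} usable pairs (need >= 100)")
    hist = np.bincount(inserts)
    kernel = np.ones(smooth_window) / smooth_window
    smooth = np.convolve(hist, kernel, mode="same")
    peak = int(np.argmax(smooth))
    # dominant mode = contiguous region of non-zero smoothed mass around peak
    lo = peak
    while lo > 0 and smooth[lo - 1] > 0:
        lo -= 1
    hi = peak
    while hi < len(smooth) - 1 and smooth[hi + 1] > 0:
        hi += 1
    mass = hist[lo : hi + 1].astype(np.float64)
    cum = np.cumsum(mass)
    total = cum[-1]
    tail = (1.0 - central_mass) / 2.0
    lo_q = lo + int(np.searchsorted(cum, tail * total, side="left"))
    hi_q = lo + int(np.searchsorted(cum, (1.0 - tail) * total, side="left"))
    return InsertSizeModel(
        table.library_name,
        {int(i): int(c) for i, c in enumerate(hist) if c},
        (lo_q, hi_q),
        table.expected_orientation,
        peak,
    )


def filter_pairs(table: PairTable, model: InsertSizeModel) -> np.ndarray:
    """Boolean mask of retained pairs: correct orientation AND in-range insert."""
    orient_ok = table.orientation == model.expected_orientation
    lo, hi = model.selected_range
    insert_ok = (table.insert >= lo) & (table.insert <= hi)
    return orient_ok & insert_ok


# ---------------------------------------------------------------------------
# bridging


@dataclass
class Bridge:
    scaffold: str
    gap_index: int
    left_contig: str
    right_contig: str
    gap_start: int  # scaffold-local N-run interval
    gap_end: int
    supporting_pairs: int
    gap_estimate: int


def _longest_match_run(read: np.ndarray, ref: np.ndarray) -> int:
    n = min(len(read), len(ref))
    eq = read[:n] == ref[:n]
    bad = np.flatnonzero(~eq)
    if len(bad) == 0:
        return n
    return int(np.max(np.diff(np.concatenate([[-1], bad, [n]])) - 1))


def find_bridges(
    assembly: Sequence[SeqRecord],
    mapping: MappingResult,
    tables: Sequence[PairTable],
    models: Sequence[InsertSizeModel],
    keep_masks: Sequence[np.ndarray],
    k: int = 30,
    min_support: int = 3,
) -> list[Bridge]:
    """Find gaps bridged by filtered mate pairs with k-mer anchors.

    A pair supports the bridge across a gap when one mate lies entirely in
    the left flank with an exact match run of >= k bases, the other
    likewise in the right flank, the mates face each other across the gap,
    and the implied gap size is consistent with the library insert.
    """
    idx = mapping.index
    name_to_i = {n: i for i, n in enumerate(idx.names)}
    ends = mapping.gstart + mapping.read_length  # ungapped spans suffice here
    bridges: list[Bridge] = []
    order = np.argsort(mapping.gstart[mapping.mapped])
    mapped_rows = np.flatnonzero(mapping.mapped)[order]
    mapped_starts = mapping.gstart[mapped_rows]
    row_lib = np.full(mapping.n_reads, -1)
    row_pair = np.full(mapping.n_reads, -1)
    for li, t in enumerate(tables):
        row_lib[t.rows1] = li
        row_lib[t.rows2] = li
        row_pair[t.rows1] = np.arange(len(t.rows1))
        row_pair[t.rows2] = np.arange(len(t.rows2))
    for rec in assembly:
        gi = name_to_i[rec.id]
        base = int(idx.starts[gi])
        for g_idx, (gs, ge) in enumerate(find_gaps(rec.sequence)):
            g_lo, g_hi = base + gs, base + ge
            support = 0
            estimates = []
            max_w = max(m.selected_range[1] for m in models) + 1
            cand = mapped_rows[
                np.searchsorted(mapped_starts, g_lo - max_w):
                np.searchsorted(mapped_starts, g_lo)
            ]
            for r in cand:
                li = row_lib[r]
                if li < 0 or not keep_masks[li][row_pair[r]]:
                    continue
                t, m = tables[li], models[li]
                pi = row_pair[r]
                mate = t.rows2[pi] if r == t.rows1[pi] else t.rows1[pi]
                if not mapping.mapped[mate]:
                    continue
                # left mate fully in the left flank, mate fully right of gap
                if ends[r] > g_lo or mapping.gstart[mate] < g_hi:
                    continue
                if mapping.gstart[r] < base or ends[mate] > base + len(rec.sequence):
                    continue
                # anchors: exact >= k run against each flank
                lread = mapping.oriented_read(r)
                lref = idx.codes[mapping.gstart[r] : ends[r]]
                rread = mapping.oriented_read(mate)
                rref = idx.codes[mapping.gstart[mate] : ends[mate]]
                if (
                    _longest_match_run(lread, lref) < k
                    or _longest_match_run(rread, rref) < k
                ):
                    continue
                d_left = g_lo - int(mapping.gstart[r])
                d_right = int(ends[mate]) - g_hi
                # insert consistency: the observed span across the gap
                # (counting the N-run) must fall inside the library's
                # selected insert range -- a symmetric acceptance window,
                # so the gap estimate stays unbiased
                span = d_left + d_right + (g_hi - g_lo)
                if not (m.selected_range[0] <= span <= m.selected_range[1]):
                    continue
                support += 1
                estimates.append(m.mode - d_left - d_right)
            if support >= min_support:
                bridges.append(
                    Bridge(
                        rec.id, g_idx,
                        f"{rec.id}_ctg{g_idx + 1}", f"{rec.id}_ctg{g_idx + 2}",
                        gs, ge, support, int(np.median(estimates)),
                    )
                )
    return bridges


# ---------------------------------------------------------------------------
# gap filling


class KmerGraph:
    """Successor counts of k-mers from a pool of reads (both strands)."""

    def __init__(self, k: int = 30):
        self.k = k
        self.succ: dict[bytes, Counter] = defaultdict(Counter)

    def add_read(self, codes: np.ndarray) -> None:
        k = self.k
        for arr in (codes, _seq.revcomp_codes(codes)):
            s = _seq.decode(arr).encode()
            for i in range(len(s) - k):
                self.succ[s[i : i + k]][s[i + k]] += 1

    def unique_successor(self, kmer: bytes):
        c = self.succ.get(kmer)
        if not c:
            return None, 0
        if len(c) > 1:
            return None, len(c)
        ((b, _n),) = c.items()
        return b, 1


@dataclass
class GapFillResult:
    scaffold: str
    gap_index: int
    status: str  # filled | partial | unfilled_ambiguous | unfilled_too_long | unfilled_no_path
    fill: str
    iterations_used: int


def collect_gap_reads(
    mapping: MappingResult,
    tables: Sequence[PairTable],
    keep_masks: Sequence[np.ndarray],
    scaffold: str,
    gap_start: int,
    gap_end: int,
    flank_window: int = 1000,
) -> list[int]:
    """Admit reads to a gap's assembly index.

    Admitted: filtered-pair reads mapped within ``flank_window`` of the
    gap, plus unmapped reads whose mapped mate sits within the library's
    insert range of the gap (these carry the gap interior).
    """
    idx = mapping.index
    gi = idx.names.index(scaffold)
    g_lo = int(idx.starts[gi]) + gap_start
    g_hi = int(idx.starts[gi]) + gap_end
    L = mapping.read_length
    out: list[np.ndarray] = []
    for t, keep in zip(tables, keep_masks):
        w = int(t.insert_mean + 4 * t.insert_sd)
        for a_rows, b_rows in ((t.rows1, t.rows2), (t.rows2, t.rows1)):
            ma = mapping.mapped[a_rows]
            s = mapping.gstart[a_rows]
            near = ma & (s >= g_lo - flank_window) & (s + L <= g_hi + flank_window)
            out.append(a_rows[near & keep])
            rescue = ma & ~mapping.mapped[b_rows] & (s >= g_lo - w) & (s <= g_hi + w)
            out.append(b_rows[rescue])
    rows = np.unique(np.concatenate(out)) if out else np.empty(0, np.int64)
    return [int(r) for r in rows]


#: bases walked per "iteration" of the bounded gap walk; together with
#: max_iterations this caps the resources spent on any one gap.
ITERATION_CHUNK = 500


def fill_gap(
    bridge: Bridge,
    graph: KmerGraph,
    left_flank: str,
    right_flank: str,
    k: int = 30,
    max_gap: int = 5000,
    max_iterations: int = 10,
) -> GapFillResult:
    """Walk the k-mer graph from the left flank toward the right flank.

    ``left_flank`` / ``right_flank`` are the gap-adjacent contig sequences
    (at least k bases each).  The walk demands a unique successor at every
    step; a fork stops it with status ``unfilled_ambiguous``.  Extension
    is capped at min(max_gap, max_iterations * 500) bases.
    """
    if len(left_flank) < k or len(right_flank) < k:
        return GapFillResult(bridge.scaffold, bridge.gap_index,
                             "unfilled_no_path", "", 0)
    cur = left_flank[-k:].encode()
    target = right_flank[:k].encode()
    budget = min(max_gap, max_iterations * ITERATION_CHUNK)
    ext = bytearray()
    while True:
        if len(ext) >= k and bytes(cur) == target:
            fill = ext[:-k].decode()
            iters = max(1, -(-len(ext) // ITERATION_CHUNK))
            return GapFillResult(bridge.scaffold, bridge.gap_index,
                                 "filled", fill, iters)
        if len(ext) > budget + k:
            return GapFillResult(bridge.scaffold, bridge.gap_index,
                                 "unfilled_too_long", "", max_iterations)
        nxt, n = graph.unique_successor(bytes(cur))
        if nxt is None:
            iters = max(1, -(-len(ext) // ITERATION_CHUNK))
            if n > 1:
                return GapFillResult(bridge.scaffold, bridge.gap_index,
                                     "unfilled_ambiguous", "", iters)
            status = "partial" if len(ext) >= k else "unfilled_no_path"
            return GapFillResult(bridge.scaffold, bridge.gap_index,
                                 status, ext.decode(), iters)
        ext.append(nxt)
        cur = cur[1:] + bytes([nxt])


def fill_all_gaps(
    assembly: Sequence[SeqRecord],
    mapping: MappingResult,
    tables: Sequence[PairTable],
    models: Sequence[InsertSizeModel],
    keep_masks: Sequence[np.ndarray],
    bridges: Sequence[Bridge],
    k: int = 30,
    max_gap: int = 5000,
    max_iterations: int = 10,
    flank_window: int = 1000,
) -> list[GapFillResult]:
    """Run the bounded local assembly for every bridged gap."""
    seqs = {r.id: r.sequence for r in assembly}
    # pre-bin admitted reads per gap in one sweep for speed
    results = []
    for b in bridges:
        rows = collect_gap_reads(
            mapping, tables, keep_masks, b.scaffold, b.gap_start, b.gap_end,
            flank_window,
        )
        graph = KmerGraph(k)
        for r in rows:
            graph.add_read(mapping.reads[r])
        seq = seqs[b.scaffold]
        left = seq[max(b.gap_start - 200, 0) : b.gap_start]
        right = seq[b.gap_end : b.gap_end + 200]
        results.append(
            fill_gap(b, graph, left, right, k, max_gap, max_iterations)
        )
    return results


def apply_gap_fills(
    assembly: Sequence[SeqRecord], results: Sequence[GapFillResult]
) -> list[SeqRecord]:
    """Replace successfully filled N-runs with their fill sequences."""
    by_scaffold: dict[str, list[GapFillResult]] = defaultdict(list)
    for r in results:
        if r.status == "filled":
            by_scaffold[r.scaffold].append(r)
    out = []
    for rec in assembly:
        fills = {r.gap_index: r.fill for r in by_scaffold.get(rec.id, [])}
        if not fills:
            out.append(rec)
            continue
        gaps = find_gaps(rec.sequence)
        parts, cursor = [], 0
        for gidx, (gs, ge) in enumerate(gaps):
            parts.append(rec.sequence[cursor:gs])
            parts.append(fills.get(gidx, rec.sequence[gs:ge]))
            cursor = ge
        parts.append(rec.sequence[cursor:])
        out.append(SeqRecord(rec.id, "".join(parts), tier=rec.tier))
    return out


# ---------------------------------------------------------------------------
# cross-scaffold reordering


@dataclass(frozen=True)
class CrossLink:
    """Evidence that two scaffold ends are adjacent in the true genome."""

    scaffold_a: str
    end_a: str  # "L" | "R"
    scaffold_b: str
    end_b: str


def cross_links_from_mapping(
    mapping: MappingResult,
    tables: Sequence[PairTable],
    models: Sequence[InsertSizeModel],
) -> list[CrossLink]:
    """Derive end-adjacency evidence from pairs with mates on different
    scaffolds.

    A mate within its library's insert range of a scaffold end and
    pointing off that end nominates the end; a pair nominating one end on
    each of two scaffolds yields a link.
    """
    idx = mapping.index
    links: list[CrossLink] = []
    lens = {n: int(l) for n, l in zip(idx.names, idx.lengths)}
    for t, m in zip(tables, models):
        w = m.selected_range[1]
        for r1, r2 in zip(t.rows1, t.rows2):
            if not (mapping.mapped[r1] and mapping.mapped[r2]):
                continue
            c1, p1 = idx.to_local(np.array([mapping.gstart[r1]]))
            c2, p2 = idx.to_local(np.array([mapping.gstart[r2]]))
            if c1[0] == c2[0]:
                continue
            ends = []
            for c, p, row in ((int(c1[0]), int(p1[0]), r1), (int(c2[0]), int(p2[0]), r2)):
                name = idx.names[c]
                # outward-pointing direction depends on library chemistry:
                # FR mates point at each other, RF mates away
                fwd = mapping.strand[row] == 0
                points_right = fwd if t.expected_orientation == "FR" else not fwd
                if points_right and p >= lens[name] - w:
                    ends.append((name, "R"))
                elif not points_right and p + mapping.read_length <= w:
                    ends.append((name, "L"))
            if len(ends) == 2:
                (sa, ea), (sb, eb) = sorted(ends)
                links.append(CrossLink(sa, ea, sb, eb))
    return links


@dataclass
class JoinEvent:
    kind: str  # "join" | "conflict"
    scaffold_a: str
    end_a: str
    scaffold_b: str
    end_b: str
    links: int
    note: str = ""


def reorder_scaffolds(
    scaffolds: Sequence[SeqRecord],
    cross_links: Sequence[CrossLink],
    min_links: int = 5,
    gap_length: int = 100,
) -> tuple[list[JoinEvent], list[SeqRecord]]:
    """Join scaffold ends supported by >= min_links mutually-best links.

    An end supported toward two different partners (both >= min_links) is
    conflicting evidence: reported, nothing joined.  Circular join chains
    are likewise reported as conflicts and left unjoined.
    """
    weight: Counter = Counter()
    for l in cross_links:
        key = ((l.scaffold_a, l.end_a), (l.scaffold_b, l.end_b))
        weight[tuple(sorted(key))] += 1
    partners: dict[tuple, list[tuple[tuple, int]]] = defaultdict(list)
    for (ea, eb), n in weight.items():
        if n >= min_links:
            partners[ea].append((eb, n))
            partners[eb].append((ea, n))
    events: list[JoinEvent] = []
    joins: dict[tuple, tuple] = {}
    conflicted: set[tuple] = set()
    for end, ps in partners.items():
        if len(ps) > 1:
            conflicted.add(end)
            ps_sorted = sorted(ps, key=lambda x: -x[1])
            events.append(
                JoinEvent("conflict", end[0], end[1],
                          ps_sorted[0][0][0], ps_sorted[0][0][1],
                          ps_sorted[0][1],
                          note=f"{len(ps)} competing partners")
            )
    for (ea, eb), n in sorted(weight.items(), key=lambda kv: (-kv[1], kv[0])):
        if n < min_links or ea in conflicted or eb in conflicted:
            continue
        joins[ea] = eb
        joins[eb] = ea
    # assemble chains, detecting cycles
    seq = {r.id: r.sequence for r in scaffolds}
    tier = {r.id: r.tier for r in scaffolds}
    visited: set[str] = set()
    out: list[SeqRecord] = []

    def other_end(e):
        return (e[0], "L" if e[1] == "R" else "R")

    # find chain starts: scaffold ends not joined
    for rec in scaffolds:
        if rec.id in visited:
            continue
        # detect cycle: walk from (id, L); if we come back, it's circular
        start = None
        for e in ((rec.id, "L"), (rec.id, "R")):
            if e not in joins:
                start = e
                break
        if start is None:
            # circular chain through this scaffold
            chain = set()
            e = (rec.id, "L")
            while True:
                chain.add(e[0])
                e = joins[other_end(e)] if other_end(e) in joins else None
                if e is None or e[0] == rec.id:
                    break
            for s in chain:
                visited.add(s)
                out.append(SeqRecord(s, seq[s], tier=tier[s]))
            events.append(
                JoinEvent("conflict", rec.id, "L", rec.id, "L", 0,
                          note="circular join chain")
            )
            continue
        # walk the chain from `start`
        pieces = []
        e = start
        while True:
            sid = e[0]
            visited.add(sid)
            s = seq[sid]
            if e[1] == "R":  # entering from the right end -> flip
                s = _seq.revcomp(s)
            pieces.append(s)
            nxt = other_end(e)
            if nxt in joins:
                partner = joins[nxt]
                events.append(
                    JoinEvent("join", nxt[0], nxt[1], partner[0], partner[1],
                              weight[tuple(sorted((nxt, partner)))])
                )
                e = partner
            else:
                break
        if len(pieces) == 1:
            out.append(SeqRecord(start[0], pieces[0], tier=tier[start[0]]))
        else:
            joined = ("N" * gap_length).join(pieces)
            out.append(SeqRecord(f"join_{start[0]}", joined, tier="scaffold"))
    return events, out


# ---------------------------------------------------------------------------
# merge


@dataclass
class MergeReport:
    kept_assisted: int
    added_denovo: list[str] = field(default_factory=list)
    dropped_denovo: list[tuple[str, str]] = field(default_factory=list)


def merge_assemblies(
    assisted: Sequence[SeqRecord],
    denovo: Sequence[SeqRecord],
    min_identity: float = 0.95,
    min_coverage: float = 0.5,
) -> tuple[list[SeqRecord], MergeReport]:
    """Append de novo contigs the assisted assembly does not already cover.

    A de novo contig is dropped when clusters at >= min_identity cover at
    least ``min_coverage`` of its length; every de novo contig appears in
    exactly one of added/dropped.
    """
    clusters = anchor_map(denovo, assisted) if denovo else []
    cover: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for c in clusters:
        if c.mean_identity >= min_identity:
            cover[c.query_id].append((c.query_start, c.query_end))
    merged = list(assisted)
    report = MergeReport(kept_assisted=len(assisted))
    for rec in denovo:
        ivs = sorted(cover.get(rec.id, []))
        covered = 0
        cur = None
        for s, e in ivs:
            if cur is None or s > cur[1]:
                if cur:
                    covered += cur[1] - cur[0]
                cur = [s, e]
            else:
                cur[1] = max(cur[1], e)
        if cur:
            covered += cur[1] - cur[0]
        frac = covered / len(rec.sequence)
        if frac >= min_coverage:
            report.dropped_denovo.append(
                (rec.id, f"covered {frac:.0%} at >= {min_identity:.0%} identity")
            )
        else:
            report.added_denovo.append(rec.id)
            merged.append(SeqRecord(rec.id, rec.sequence, tier=rec.tier))
    return merged, report
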