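"""Anchor alignment, chromosome placement and comparative structure.

Two aligners live here:

* :func:`anchor_map` — a MUM-style seed-and-chain aligner for placing
  scaffolds and contigs onto reference chromosomes.  Exact unique 20-mer
  seeds are merged into maximal exact segments and chained into colinear
  clusters with the clustering thresholds of the original pipeline
  (minimum cluster match 400 bp, maximum chain gap 500 bp).
* :func:`map_reads` — a fast seed-and-verify short-read mapper used by the
  assisted-assembly and variant-calling stages: unique k-mer seeds vote
  for a candidate locus, an ungapped mismatch check accepts the bulk of
  reads, and a banded edit-distance alignment (edlib) rescues reads whose
  alignment needs indels.

Also here: AGP placement of scaffolds onto chromosomes, assembly summary
statistics, the 20 kb inter-chromosomal rearrangement rule, and
reciprocal-best-hit ortholog pairing with dot-plot table export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np
from Bio.Align import PairwiseAligner

from . import _seq
from .core_io import AgpRow, SeqRecord

__all__ = [
    "GenomeIndex",
    "AnchorCluster",
    "Placement",
    "AssemblyStats",
    "RearrangementEvent",
    "OrthologPair",
    "MappingResult",
    "anchor_map",
    "map_reads",
    "place_scaffolds",
    "assembly_stats",
    "detect_interchromosomal",
    "reciprocal_best",
    "dotplot_table",
]

_SEP = 31  # N-run separating concatenated chromosomes in the global array


class GenomeIndex:
    """Concatenated 2-bit genome with a sorted unique k-mer index."""

    def __init__(self, records: Sequence[SeqRecord], k: int = 20):
        self.records = list(records)
        self.k = k
        self.names = [r.id for r in self.records]
        self.lengths = np.array([len(r.sequence) for r in self.records], dtype=np.int64)
        starts = []
        parts = []
        pos = 0
        sep = np.full(_SEP, 4, dtype=np.uint8)
        for r in self.records:
            starts.append(pos)
            parts.append(_seq.encode(r.sequence))
            parts.append(sep)
            pos += len(r.sequence) + _SEP
        self.starts = np.array(starts, dtype=np.int64)
        self.codes = np.concatenate(parts)
        vals = _seq.kmer_codes(self.codes, k)
        pos_all = np.flatnonzero(vals >= 0)
        vals = vals[pos_all]
        order = np.argsort(vals, kind="stable")
        sv, sp = vals[order], pos_all[order]
        # unique-k-mer seeding: multi-copy k-mers are dropped from the index
        if len(sv):
            first = np.concatenate([[True], sv[1:] != sv[:-1]])
            last = np.concatenate([sv[1:] != sv[:-1], [True]])
            uniq = first & last
            sv, sp = sv[uniq], sp[uniq]
        self._kmers = sv
        self._positions = sp

    def lookup(self, query_vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Match packed k-mers against the index.

        Returns (indices into query_vals, global positions) for hits.
        """
        ok = query_vals >= 0
        idx = np.flatnonzero(ok)
        vals = query_vals[idx]
        loc = np.searchsorted(self._kmers, vals)
        loc = np.clip(loc, 0, len(self._kmers) - 1)
        hit = len(self._kmers) > 0
        found = hit & (self._kmers[loc] == vals) if len(self._kmers) else np.zeros(len(vals), bool)
        return idx[found], self._positions[loc[found]]

    def to_local(self, gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Global concatenated positions -> (chromosome index, local position)."""
        ci = np.searchsorted(self.starts, gpos, side="right") - 1
        return ci, gpos - self.starts[ci]

    def slice_codes(self, gstart: int, gend: int) -> np.ndarray:
        return self.codes[max(gstart, 0) : gend]


# ---------------------------------------------------------------------------
# anchor_map


@dataclass
class AnchorCluster:
    query_id: str
    target_id: str
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    strand: str
    total_match: int
    mean_identity: float

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


def _merge_seed_runs(qp: np.ndarray, tp: np.ndarray, k: int):
    """Merge seed hits on a shared diagonal into maximal exact segments.

    Returns arrays (q_start, q_end, t_start) per segment, query-sorted.
    """
    if len(qp) == 0:
        return (np.empty(0, np.int64),) * 3
    diag = tp - qp
    order = np.lexsort((qp, diag))
    qp, tp, diag = qp[order], tp[order], diag[order]
    brk = np.concatenate(
        [[True], (diag[1:] != diag[:-1]) | (qp[1:] != qp[:-1] + 1)]
    )
    seg_id = np.cumsum(brk) - 1
    firsts = np.flatnonzero(brk)
    lasts = np.concatenate([firsts[1:] - 1, [len(qp) - 1]])
    qs = qp[firsts]
    qe = qp[lasts] + k
    ts = tp[firsts]
    order2 = np.argsort(qs, kind="stable")
    return qs[order2], qe[order2], ts[order2]


class _OpenCluster:
    __slots__ = ("segs", "q_end", "t_end", "match")

    def __init__(self, qs, qe, ts):
        self.segs = [(qs, qe, ts)]
        self.q_end = qe
        self.t_end = ts + (qe - qs)
        self.match = qe - qs


def _chain(qs, qe, ts, max_gap: int, k: int):
    """Greedy colinear chaining of exact segments (Nucmer-style clustering)."""
    clusters: list[_OpenCluster] = []
    done: list[_OpenCluster] = []
    for a, b, t in zip(qs, qe, ts):
        # retire clusters that can no longer be extended
        still = []
        for c in clusters:
            if a - c.q_end > max_gap:
                done.append(c)
            else:
                still.append(c)
        clusters = still
        best, best_gap = None, None
        for c in clusters:
            qgap = a - c.q_end
            tgap = t - c.t_end
            if -k < qgap <= max_gap and -k < tgap <= max_gap:
                g = abs(qgap) + abs(tgap)
                if best is None or g < best_gap:
                    best, best_gap = c, g
        if best is None:
            clusters.append(_OpenCluster(a, b, t))
        else:
            gain = b - max(a, best.q_end)
            if gain > 0:
                best.match += gain
            best.segs.append((a, b, t))
            best.q_end = max(best.q_end, b)
            best.t_end = t + (b - a)
    done.extend(clusters)
    return done


def _cluster_identity(c: _OpenCluster, qcodes, ref_codes, max_gap):
    """Identity over chained segments plus equal-length inter-segment gaps."""
    match = 0
    sites = 0
    prev = None
    for a, b, t in c.segs:
        match += b - a
        sites += b - a
        if prev is not None:
            pa, pb, pt = prev
            qgap = a - pb
            tgap = t - (pt + (pb - pa))
            if qgap == tgap and 0 < qgap <= max_gap:
                qseg = qcodes[pb:a]
                tseg = ref_codes[pt + (pb - pa) : pt + (pb - pa) + tgap]
                if len(qseg) == len(tseg):
                    m = int(np.sum(qseg == tseg))
                    match += m
                    sites += len(qseg)
        prev = (a, b, t)
    return match / sites if sites else 0.0


def anchor_map(
    queries: Sequence[SeqRecord],
    references: Sequence[SeqRecord] | GenomeIndex,
    seed_len: int = 20,
    min_cluster: int = 400,
    max_gap: int = 500,
) -> list[AnchorCluster]:
    """Seed-and-chain alignment of query sequences to reference chromosomes.

    Exact unique ``seed_len``-mers are chained into colinear clusters in
    which consecutive anchors sit at most ``max_gap`` apart on both
    sequences; clusters with less than ``min_cluster`` matched bp are
    discarded.  Both strands of each query are searched.
    """
    if not queries:
        raise ValueError("empty query set")
    index = (
        references
        if isinstance(references, GenomeIndex)
        else GenomeIndex(references, k=seed_len)
    )
    if index.k != seed_len:
        raise ValueError("index k does not match seed_len")
    out: list[AnchorCluster] = []
    for q in queries:
        qlen = len(q.sequence)
        fwd = _seq.encode(q.sequence)
        for strand, qcodes in (("+", fwd), ("-", _seq.revcomp_codes(fwd))):
            vals = _seq.kmer_codes(qcodes, seed_len)
            qidx, gpos = index.lookup(vals)
            if len(qidx) == 0:
                continue
            ci, _local = index.to_local(gpos)
            for c in np.unique(ci):
                sel = ci == c
                qs, qe, ts = _merge_seed_runs(qidx[sel], gpos[sel], seed_len)
                for cl in _chain(qs, qe, ts, max_gap, seed_len):
                    if cl.match < min_cluster:
                        continue
                    q0 = cl.segs[0][0]
                    q1 = cl.q_end
                    t0 = cl.segs[0][2]
                    t1 = cl.t_end
                    ident = _cluster_identity(cl, qcodes, index.codes, max_gap)
                    if strand == "-":
                        q0, q1 = qlen - q1, qlen - q0
                    lt0 = int(t0 - index.starts[c])
                    lt1 = int(t1 - index.starts[c])
                    out.append(
                        AnchorCluster(
                            query_id=q.id,
                            target_id=index.names[c],
                            query_start=int(q0),
                            query_end=int(q1),
                            target_start=lt0,
                            target_end=lt1,
                            strand=strand,
                            total_match=int(cl.match),
                            mean_identity=float(ident),
                        )
                    )
    return out


# ---------------------------------------------------------------------------
# short-read mapping


@dataclass
class PairBlock:
    """Row layout of one library inside a MappingResult."""

    library_name: str
    orientation: str
    insert_mean: int
    insert_sd: float
    n_pairs: int
    first1: int  # rows [first1, first1+n_pairs) are mate 1
    first2: int


@dataclass
class MappingResult:
    """Mapping of a batch of fixed-length reads against a GenomeIndex.

    ``gstart`` holds global (concatenated) target start positions;
    ``strand`` is 0 for forward, 1 for reverse; ``cigars[i]`` is None for
    plain full-length matches.  ``reads`` keeps the read codes in original
    (FASTQ) orientation.
    """

    index: GenomeIndex
    reads: np.ndarray
    mapped: np.ndarray
    gstart: np.ndarray
    strand: np.ndarray
    nm: np.ndarray
    cigars: list
    pair_blocks: list[PairBlock]
    read_length: int

    @property
    def n_reads(self) -> int:
        return len(self.reads)

    def oriented_read(self, i: int) -> np.ndarray:
        r = self.reads[i]
        return r if self.strand[i] == 0 else _seq.revcomp_codes(r)

    def target_span(self, i: int) -> tuple[int, int]:
        """Global target interval of read i (cigar-aware)."""
        if self.cigars[i] is None:
            return int(self.gstart[i]), int(self.gstart[i]) + self.read_length
        tlen = 0
        for n, op in _iter_cigar(self.cigars[i]):
            if op in "MDX=":
                tlen += n
        return int(self.gstart[i]), int(self.gstart[i]) + tlen


def _iter_cigar(cigar: str):
    n = 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + ord(ch) - 48
        else:
            yield n, ch
            n = 0


def _pack_kmers_matrix(m: np.ndarray, k: int) -> np.ndarray:
    """Pack columns [0,k) of a read matrix into int64 k-mer codes."""
    v = np.zeros(len(m), dtype=np.int64)
    bad = np.zeros(len(m), dtype=bool)
    for j in range(k):
        col = m[:, j].astype(np.int64)
        bad |= col >= 4
        v = (v << 2) | np.where(col >= 4, 0, col)
    v[bad] = -1
    return v


def _clip_cigar(ext_cigar: str, anchor: int = 12):
    """Anchor-clip an extended (=/X) edlib CIGAR.

    The alignment must start and end with an exact-match run of at least
    ``anchor`` bases; anything outside the outermost such runs (mismatch
    tails, marginal indels) is soft-clipped.  Near an InDel the cheapest
    edit script often paints the read tail as a mismatch run rather than
    opening the gap, and those tail bases are misplaced — clipping them
    keeps them out of downstream pileups.

    Returns (sam_cigar, leading_target_shift, matched, edits) or None when
    no anchored region exists.
    """
    ops = list(_iter_cigar(ext_cigar))
    first = last = None
    for i, (n, op) in enumerate(ops):
        if op == "=" and n >= anchor:
            if first is None:
                first = i
            last = i
    if first is None:
        return None
    pre_q = pre_t = 0
    for n, op in ops[:first]:
        if op in "=XM":
            pre_q += n
            pre_t += n
        elif op == "I":
            pre_q += n
        elif op == "D":
            pre_t += n
    post_q = 0
    for n, op in ops[last + 1 :]:
        if op in "=XMI":
            post_q += n
    kept = ops[first : last + 1]
    # merge =/X into M runs; count edits inside the kept region
    merged: list[tuple[int, str]] = []
    edits = 0
    for n, op in kept:
        if op == "X":
            edits += n
        elif op in "ID":
            edits += n
        o = "M" if op in "=X" else op
        if merged and merged[-1][1] == o:
            merged[-1] = (merged[-1][0] + n, o)
        else:
            merged.append((n, o))
    parts = []
    if pre_q:
        parts.append(f"{pre_q}S")
    parts.extend(f"{n}{o}" for n, o in merged)
    if post_q:
        parts.append(f"{post_q}S")
    matched = sum(n for n, o in merged if o == "M")
    return "".join(parts), pre_t, matched, edits


def _make_affine_aligner() -> PairwiseAligner:
    """Affine-gap aligner preferring one long gap over several short ones.

    Edit-distance alignment (unit costs) may split a single planted indel
    into fragments when intermediate bases match by chance; affine gap
    costs restore the single-gap representation.
    """
    a = PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = -2.0
    a.open_gap_score = -6.0
    a.extend_gap_score = -0.5
    # infix alignment: free end gaps on the target side
    try:
        a.end_insertion_score = 0.0
    except AttributeError:  # older attribute name
        a.target_end_gap_score = 0.0
    return a


def _affine_ext_cigar(aligner: PairwiseAligner, target: str, query: str):
    """Extended (=/X/I/D) CIGAR of the best affine alignment, plus the
    target offset of its first aligned base.  Unaligned query tails are
    emitted as I so the downstream anchor clip turns them into soft clips.
    """
    aln = aligner.align(target, query)[0]
    blocks_t, blocks_q = aln.aligned
    if len(blocks_t) == 0:
        return None
    ops: list[str] = []
    if blocks_q[0][0] > 0:
        ops.append(f"{blocks_q[0][0]}I")
    prev_t = prev_q = None
    for (t0, t1), (q0, q1) in zip(blocks_t, blocks_q):
        if prev_t is not None:
            dt, dq = t0 - prev_t, q0 - prev_q
            if dt:
                ops.append(f"{dt}D")
            if dq:
                ops.append(f"{dq}I")
        run_op = None
        run = 0
        for tc, qc in zip(target[t0:t1], query[q0:q1]):
            o = "=" if tc == qc else "X"
            if o == run_op:
                run += 1
            else:
                if run:
                    ops.append(f"{run}{run_op}")
                run_op, run = o, 1
        if run:
            ops.append(f"{run}{run_op}")
        prev_t, prev_q = t1, q1
    if blocks_q[-1][1] < len(query):
        ops.append(f"{len(query) - blocks_q[-1][1]}I")
    return "".join(ops), int(blocks_t[0][0])


def map_reads(
    readsets: Sequence,
    index: GenomeIndex,
    max_mismatch: int = 3,
    max_edit: int = 12,
    chunk: int = 200_000,
    clip_anchor: int = 12,
) -> MappingResult:
    """Map fixed-length paired reads with seed-vote / verify / edlib-rescue.

    Accepts :class:`~congener.synthdata.ReadSet` objects.  Reads whose best
    candidate fails the ungapped mismatch check are realigned with a banded
    edit-distance alignment in a padded window so short InDels still map
    with a correct CIGAR; rescued alignments are anchor-clipped (see
    :func:`_clip_cigar`) so misplaced tails never reach the pileup.
    """
    k = index.k
    L = readsets[0].read_length
    blocks: list[PairBlock] = []
    mats = []
    row = 0
    for rs in readsets:
        n = rs.n_pairs
        blocks.append(
            PairBlock(
                rs.library.name,
                rs.library.orientation,
                rs.library.insert_mean,
                rs.library.insert_sd,
                n,
                row,
                row + n,
            )
        )
        mats.append(rs.reads1)
        mats.append(rs.reads2)
        row += 2 * n
    reads = np.concatenate(mats) if mats else np.empty((0, L), np.uint8)
    n_reads = len(reads)
    mapped = np.zeros(n_reads, dtype=bool)
    gstart = np.full(n_reads, -1, dtype=np.int64)
    strand = np.zeros(n_reads, dtype=np.uint8)
    nm = np.zeros(n_reads, dtype=np.int32)
    cigars: list = [None] * n_reads

    offs = [0]
    step = max((L - k) // 3, 1)
    for o in (step, 2 * step, L - k):
        if o not in offs and 0 < o <= L - k:
            offs.append(o)
    affine = _make_affine_aligner()

    for lo in range(0, n_reads, chunk):
        hi = min(lo + chunk, n_reads)
        R = reads[lo:hi]
        rev = R[:, ::-1]
        Rrc = np.where(rev >= 4, 4, 3 - rev).astype(np.uint8)
        cand_read, cand_key = [], []
        for s, M in ((0, R), (1, Rrc)):
            for off in offs:
                vals = _pack_kmers_matrix(M[:, off : off + k], k)
                qidx, gpos = index.lookup(vals)
                start = gpos - off
                ok = start >= 0
                cand_read.append(qidx[ok])
                cand_key.append(start[ok] * 2 + s)
        cand_read = np.concatenate(cand_read)
        cand_key = np.concatenate(cand_key)
        if len(cand_read) == 0:
            continue
        # majority vote per read on (start, strand) candidates
        order = np.lexsort((cand_key, cand_read))
        cr, ck = cand_read[order], cand_key[order]
        new = np.concatenate([[True], (cr[1:] != cr[:-1]) | (ck[1:] != ck[:-1])])
        grp = np.flatnonzero(new)
        counts = np.diff(np.concatenate([grp, [len(cr)]]))
        g_read, g_key = cr[grp], ck[grp]
        # pick the best-supported candidate per read (ties -> lowest key)
        order2 = np.lexsort((g_key, -counts, g_read))
        gr2, gk2 = g_read[order2], g_key[order2]
        first = np.concatenate([[True], gr2[1:] != gr2[:-1]])
        sel_reads = gr2[first]
        sel_keys = gk2[first]
        sel_start = sel_keys >> 1
        sel_strand = (sel_keys & 1).astype(np.uint8)
        # ungapped verification
        valid = sel_start + L <= len(index.codes)
        sel_reads, sel_start, sel_strand = (
            sel_reads[valid], sel_start[valid], sel_strand[valid],
        )
        win = index.codes[sel_start[:, None] + np.arange(L)]
        qmat = np.where(sel_strand[:, None] == 0, R[sel_reads], Rrc[sel_reads])
        mm = np.sum(win != qmat, axis=1)
        good = mm <= max_mismatch
        gi = sel_reads[good] + lo
        mapped[gi] = True
        gstart[gi] = sel_start[good]
        strand[gi] = sel_strand[good]
        nm[gi] = mm[good]
        # edlib rescue for the rest
        pad = 2 * max_edit
        for r_, s_, st_ in zip(
            sel_reads[~good], sel_start[~good], sel_strand[~good]
        ):
            q = _seq.decode(R[r_] if st_ == 0 else Rrc[r_])
            a = max(int(s_) - pad, 0)
            t = _seq.decode(index.codes[a : int(s_) + L + pad])
            res = edlib.align(q, t, mode="HW", task="path")
            if res["editDistance"] < 0 or res["editDistance"] > max_edit:
                continue
            clip = _clip_cigar(res["cigar"] or "", clip_anchor)
            if clip is None:
                continue
            sam_cigar, pre_t, matched, edits = clip
            t_origin = res["locations"][0][0]
            n_gap_ops = sum(op in "ID" for _n, op in _iter_cigar(sam_cigar))
            if n_gap_ops >= 2:
                # edit distance fragmented the gap; redo with affine costs
                aff = _affine_ext_cigar(affine, t, q)
                if aff is not None:
                    clip2 = _clip_cigar(aff[0], clip_anchor)
                    if clip2 is not None and clip2[3] <= max_edit + 4:
                        sam_cigar, pre_t, matched, edits = clip2
                        t_origin = aff[1]
            if matched < 20:
                continue
            i = int(r_) + lo
            mapped[i] = True
            gstart[i] = a + t_origin + pre_t
            strand[i] = st_
            nm[i] = edits
            cigars[i] = None if _is_trivial_match(sam_cigar, L) else sam_cigar
    return MappingResult(
        index, reads, mapped, gstart, strand, nm, cigars, blocks, L
    )


def _is_trivial_match(cigar: str, L: int) -> bool:
    ops = list(_iter_cigar(cigar))
    return len(ops) == 1 and ops[0] == (L, "M")


# ---------------------------------------------------------------------------
# placement


@dataclass
class Placement:
    scaffold: str
    chromosome: str | None
    orientation: str
    order_key: float
    status: str  # "placed" | "unplaced"
    matched_bp: int = 0


def place_scaffolds(
    clusters: Sequence[AnchorCluster],
    scaffolds: Sequence[SeqRecord],
    tie_fraction: float = 0.10,
    gap_length: int = 100,
) -> tuple[list[Placement], list[AgpRow]]:
    """Assign each scaffold to the chromosome with the most matched bp.

    A scaffold whose runner-up chromosome comes within ``tie_fraction`` of
    the winner's matched bp is reported unplaced rather than guessed.
    Orientation follows the strand carrying the majority of matched bp;
    scaffolds on a chromosome are ordered by the match-weighted median
    target coordinate and joined by ``gap_length`` N gaps in the AGP.
    """
    by_scaffold: dict[str, list[AnchorCluster]] = {}
    for c in clusters:
        by_scaffold.setdefault(c.query_id, []).append(c)
    placements: list[Placement] = []
    lengths = {s.id: len(s.sequence) for s in scaffolds}
    for s in scaffolds:
        cls = by_scaffold.get(s.id, [])
        if not cls:
            placements.append(Placement(s.id, None, "+", 0.0, "unplaced"))
            continue
        per_chrom: dict[str, int] = {}
        for c in cls:
            per_chrom[c.target_id] = per_chrom.get(c.target_id, 0) + c.total_match
        ranked = sorted(per_chrom.items(), key=lambda kv: (-kv[1], kv[0]))
        best_chrom, best_bp = ranked[0]
        if len(ranked) > 1 and ranked[1][1] >= (1.0 - tie_fraction) * best_bp:
            placements.append(Placement(s.id, None, "+", 0.0, "unplaced"))
            continue
        on = [c for c in cls if c.target_id == best_chrom]
        plus = sum(c.total_match for c in on if c.strand == "+")
        minus = sum(c.total_match for c in on if c.strand == "-")
        orient = "+" if plus >= minus else "-"
        mids = np.repeat(
            [0.5 * (c.target_start + c.target_end) for c in on],
            [max(c.total_match // 100, 1) for c in on],
        )
        placements.append(
            Placement(s.id, best_chrom, orient, float(np.median(mids)), "placed",
                      matched_bp=best_bp)
        )
    # AGP per chromosome
    rows: list[AgpRow] = []
    by_chrom: dict[str, list[Placement]] = {}
    for p in placements:
        if p.status == "placed":
            by_chrom.setdefault(p.chromosome, []).append(p)
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda p: p.order_key)
        pos = 0
        part = 1
        for j, p in enumerate(ordered):
            if j > 0:
                rows.append(
                    AgpRow(chrom, pos, pos + gap_length, part, "N",
                           gap_length=gap_length, gap_type="contig")
                )
                pos += gap_length
                part += 1
            slen = lengths[p.scaffold]
            rows.append(
                AgpRow(chrom, pos, pos + slen, part, "W",
                       component_id=p.scaffold, component_start=0,
                       component_end=slen, orientation=p.orientation)
            )
            pos += slen
            part += 1
    return placements, rows


# ---------------------------------------------------------------------------
# statistics


@dataclass
class AssemblyStats:
    tier: str
    count: int
    n50: int
    shortest: int
    gc_percent: float
    total_size: int


def assembly_stats(assembly: Sequence[SeqRecord], tier: str | None = None) -> AssemblyStats:
    """Count/N50/shortest/GC/total for one assembly tier.

    N50 is the length of the smallest sequence in the minimal set of
    longest sequences whose summed length reaches half the assembly total;
    GC excludes N from both numerator and denominator.
    """
    if not assembly:
        raise ValueError("empty assembly")
    lengths = sorted((len(r.sequence) for r in assembly), reverse=True)
    total = sum(lengths)
    acc = 0
    n50 = lengths[-1]
    for l in lengths:
        acc += l
        if acc * 2 >= total:
            n50 = l
            break
    gc = at = 0
    for r in assembly:
        codes = _seq.encode(r.sequence)
        gc += int(np.sum((codes == 1) | (codes == 2)))
        at += int(np.sum((codes == 0) | (codes == 3)))
    gc_percent = 100.0 * gc / (gc + at) if gc + at else 0.0
    return AssemblyStats(
        tier=tier or assembly[0].tier,
        count=len(assembly),
        n50=n50,
        shortest=lengths[-1],
        gc_percent=gc_percent,
        total_size=total,
    )


# ---------------------------------------------------------------------------
# inter-chromosomal rearrangements


@dataclass
class RearrangementEvent:
    contig: str
    chrom_a: str
    bp_a: int
    chrom_b: str
    bp_b: int
    breakpoint: int


def detect_interchromosomal(
    clusters: Sequence[AnchorCluster], min_span: int = 20_000
) -> list[RearrangementEvent]:
    """Call a rearrangement when one contig aligns >= min_span bp to EACH of
    two different chromosomes (the conservative reading of the 20 kb rule).

    The breakpoint estimate is the midpoint between the two
    chromosome-partitioned query intervals.
    """
    by_contig: dict[str, list[AnchorCluster]] = {}
    for c in clusters:
        by_contig.setdefault(c.query_id, []).append(c)
    events = []
    for contig, cls in sorted(by_contig.items()):
        per: dict[str, int] = {}
        for c in cls:
            per[c.target_id] = per.get(c.target_id, 0) + c.total_match
        big = sorted(
            ((bp, ch) for ch, bp in per.items() if bp >= min_span), reverse=True
        )
        if len(big) < 2:
            continue
        # one event per secondary chromosome: a contig spanning the
        # junctions of two distinct translocations reports both
        bp_a, ch_a = big[0]
        qa = [c for c in cls if c.target_id == ch_a]
        mid_a = float(np.median([0.5 * (c.query_start + c.query_end) for c in qa]))
        for bp_b, ch_b in big[1:]:
            qb = [c for c in cls if c.target_id == ch_b]
            mid_b = float(np.median([0.5 * (c.query_start + c.query_end) for c in qb]))
            if mid_a <= mid_b:
                left, right = qa, qb
            else:
                left, right = qb, qa
            bpt = (
                max(c.query_end for c in left) + min(c.query_start for c in right)
            ) // 2
            events.append(
                RearrangementEvent(contig, ch_a, bp_a, ch_b, bp_b, int(bpt))
            )
    return events


# ---------------------------------------------------------------------------
# orthologs / synteny


@dataclass(frozen=True)
class OrthologPair:
    query_gene: str
    ref_gene: str
    score: float


def _unique_best(hits: Iterable[tuple[str, str, float]]) -> dict[str, str]:
    best: dict[str, tuple[str, float, bool]] = {}
    for q, s, sc in hits:
        cur = best.get(q)
        if cur is None or sc > cur[1]:
            best[q] = (s, sc, False)
        elif sc == cur[1] and s != cur[0]:
            best[q] = (cur[0], cur[1], True)  # tied top score -> poisoned
    return {q: s for q, (s, _sc, tied) in best.items() if not tied}


def reciprocal_best(
    hits_ab: Iterable[tuple[str, str, float]],
    hits_ba: Iterable[tuple[str, str, float]],
) -> list[OrthologPair]:
    """Reciprocal best hits: (a, b) kept iff b is a's unique top score and
    a is b's unique top score; ties disqualify."""
    hits_ab = list(hits_ab)
    fwd = _unique_best(hits_ab)
    rev = _unique_best(hits_ba)
    score = {(q, s): sc for q, s, sc in hits_ab}
    out = []
    for a, b in sorted(fwd.items()):
        if rev.get(b) == a:
            out.append(OrthologPair(a, b, score.get((a, b), 0.0)))
    return out


def dotplot_table(
    pairs: Sequence[OrthologPair],
    query_coords: dict[str, tuple[str, int, int]],
    ref_coords: dict[str, tuple[str, int, int]],
) -> tuple[list[tuple[str, int, str, int]], int]:
    """One (query_chr, query_mid, ref_chr, ref_mid) row per ortholog pair.

    Pairs lacking coordinates on either side are skipped and counted.
    Rows come back sorted by query chromosome then position.
    """
    rows = []
    skipped = 0
    for p in pairs:
        qc = query_coords.get(p.query_gene)
        rc = ref_coords.get(p.ref_gene)
        if qc is None or rc is None:
            skipped += 1
            continue
        rows.append((qc[0], (qc[1] + qc[2]) // 2, rc[0], (rc[1] + rc[2]) // 2))
    rows.sort(key=lambda r: (r[0], r[1]))
    return rows, skipped
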