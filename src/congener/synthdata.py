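"""Synthetic congener genomes with known truth.

The generator emulates the sequencing design of the comparative study this
toolkit supports: a reference genome (the well-assembled congener), a
diverged sister genome carrying point mutations at roughly 1 change per
50-100 bp, short InDels, large (>= 20 kb) inter-chromosomal translocations
and transposable-element insertions with a chosen age distribution, plus
tiered paired-end libraries (~300 bp fragment inserts read inward, 3 kb and
8 kb mate pairs read outward, 100 bp reads).  Every planted event is
recorded in a :class:`TruthSet` so downstream recovery can be scored
exactly; applying the truth set to the reference reproduces the derived
genome byte for byte.

All randomness flows through a single integer seed via
``numpy.random.default_rng``; no hash ordering is relied upon, so output is
reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml

from . import _seq
from .core_io import SeqRecord

__all__ = [
    "LibrarySpec",
    "TEFamily",
    "SimConfig",
    "TruthVariant",
    "Rearrangement",
    "TECopy",
    "GapFill",
    "TruthSet",
    "ReadSet",
    "simulate_reference",
    "diverge_genome",
    "plant_tes",
    "simulate_pairs",
    "fragment_scaffolds",
    "shred_genome",
    "apply_truth",
]

_TRANSITION = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T on the 2-bit codes


@dataclass(frozen=True)
class LibrarySpec:
    """One paired-end library tier.

    ``FR`` libraries read inward from the ends of short fragments (the
    ~300 bp tier); ``RF`` libraries are outward-facing mate pairs (3 kb and
    8 kb tiers).  ``coverage`` is fold sequence coverage contributed by the
    library.
    """

    name: str
    insert_mean: int
    insert_sd: float
    orientation: str = "FR"
    coverage: float = 30.0

    def __post_init__(self):
        if self.orientation not in ("FR", "RF"):
            raise ValueError("orientation must be FR or RF")


#: the tiered design used throughout: 30x 300 bp fragments, 17x 3 kb and
#: 5x 8 kb mate pairs, mirroring a ~50x short-read sequencing effort.
DEFAULT_LIBRARIES = (
    LibrarySpec("frag300", 300, 30.0, "FR", 30.0),
    LibrarySpec("mp3k", 3000, 300.0, "RF", 17.0),
    LibrarySpec("mp8k", 8000, 800.0, "RF", 5.0),
)


@dataclass(frozen=True)
class TEFamily:
    """A TE family to plant: consensus, copy number and age distribution.

    ``divergences`` is either an explicit per-copy list of divergence
    fractions, or a tuple ``("uniform", lo, hi)`` / ``("normal", mu, sd)``.
    """

    name: str
    consensus: str
    copies: int
    divergences: object = ("uniform", 0.0, 0.3)
    superfamily: str = "Unknown"


@dataclass
class SimConfig:
    genome_length: int = 2_000_000
    n_chromosomes: int = 4
    gc_fraction: float = 0.35
    snp_rate: float = 0.01
    indel_rate: float = 0.001
    indel_max_len: int = 10
    n_translocations: int = 0
    translocation_min_len: int = 25_000
    te_families: tuple[TEFamily, ...] = ()
    libraries: tuple[LibrarySpec, ...] = DEFAULT_LIBRARIES
    read_length: int = 100
    per_base_error: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for r in (self.snp_rate, self.indel_rate, self.per_base_error, self.gc_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_translocations > 0 and (
            self.genome_length < 10 * self.translocation_min_len
        ):
            raise ValueError(
                "genome_length must be >= 10 x translocation_min_len "
                "when translocations are requested"
            )
        for lib in self.libraries:
            if lib.orientation == "FR" and lib.insert_mean <= 2 * self.read_length:
                raise ValueError(
                    f"library {lib.name}: FR insert_mean must exceed 2 x read_length"
                )

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        libs = raw.pop("libraries", None)
        tes = raw.pop("te_families", None)
        cfg = cls(**raw)
        if libs is not None:
            cfg = replace(cfg, libraries=tuple(LibrarySpec(**d) for d in libs))
        if tes is not None:
            cfg = replace(cfg, te_families=tuple(TEFamily(**d) for d in tes))
        return cfg


# --- truth records ---------------------------------------------------------


@dataclass(frozen=True)
class TruthVariant:
    """A planted variant, addressed in both genomes.

    ``chrom``/``pos`` are reference-genome coordinates (what a caller
    aligned against the reference should report, VCF-style anchoring for
    InDels); ``derived_chrom``/``derived_pos`` locate the event in the
    derived genome.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    type: str  # "SNC" | "InDel"
    derived_chrom: str
    derived_pos: int

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class Rearrangement:
    src_chrom: str
    src_start: int
    src_end: int
    dest_chrom: str
    dest_pos: int  # insertion offset in the destination, pre-mutation coords
    derived_start: int = 0  # segment interval in the derived genome
    derived_end: int = 0


@dataclass(frozen=True)
class TECopy:
    chrom: str
    start: int
    end: int
    family: str
    superfamily: str
    divergence: float


@dataclass(frozen=True)
class GapFill:
    scaffold: str
    gap_index: int
    start: int
    end: int
    fill: str


@dataclass
class TruthSet:
    variants: list[TruthVariant] = field(default_factory=list)
    rearrangements: list[Rearrangement] = field(default_factory=list)
    te_copies: list[TECopy] = field(default_factory=list)
    gap_fills: list[GapFill] = field(default_factory=list)

    def snc_keys(self) -> set[tuple]:
        return {v.key for v in self.variants if v.type == "SNC"}


# --- reference -------------------------------------------------------------


def simulate_reference(config: SimConfig) -> list[SeqRecord]:
    """I.i.d. chromosomes named chr1..chrN with expected GC = gc_fraction."""
    rng = np.random.default_rng(config.seed)
    clen = config.genome_length // config.n_chromosomes
    gc = config.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    records = []
    for i in range(config.n_chromosomes):
        codes = rng.choice(4, size=clen, p=p).astype(np.uint8)
        records.append(
            SeqRecord(f"chr{i + 1}", _seq.decode(codes), tier="chromosome")
        )
    return records


# --- divergence ------------------------------------------------------------


def _translocate(
    reference: list[SeqRecord], config: SimConfig, rng: np.random.Generator
) -> tuple[list[SeqRecord], list[Rearrangement]]:
    """Cut-and-paste n_translocations segments between chromosomes.

    All events are planned up front on reference coordinates with strict
    disjointness (segments never overlap each other, and no insertion
    point falls inside a removed segment), so moved segments stay intact:
    no translocation can excise or split material moved by another.
    ``dest_pos``/``derived_start`` in the truth records are coordinates in
    the final rearranged genome.
    """
    order = [r.id for r in reference]
    seqs = {r.id: r.sequence for r in reference}
    lens = {r.id: len(r.sequence) for r in reference}
    min_len = config.translocation_min_len
    pad = 1000
    segments: dict[str, list[tuple[int, int]]] = {c: [] for c in order}
    dests: dict[str, list[int]] = {c: [] for c in order}
    plans = []  # (src, s, e, dest, dpos_orig)
    for _ in range(config.n_translocations):
        for _attempt in range(500):
            src = order[rng.integers(len(order))]
            seg_len = int(min_len + rng.integers(0, max(min_len // 5, 1)))
            if lens[src] < 2 * min_len + 2 * seg_len:
                continue
            s = int(rng.integers(min_len, lens[src] - min_len - seg_len))
            e = s + seg_len
            if any(s - pad < b and e + pad > a for a, b in segments[src]):
                continue
            if any(s - pad < d < e + pad for d in dests[src]):
                continue
            dest = order[int(rng.integers(len(order) - 1))]
            if dest == src:
                dest = order[-1]
            if lens[dest] < 2 * min_len + seg_len + 2:
                continue
            # both junctions stay >= min_len from the destination ends
            dpos = int(rng.integers(min_len, lens[dest] - min_len - seg_len))
            if any(a - pad < dpos < b + pad for a, b in segments[dest]):
                continue
            if any(abs(dpos - d) < pad for d in dests[dest]):
                continue
            segments[src].append((s, e))
            dests[dest].append(dpos)
            plans.append((src, s, e, dest, dpos))
            break
        else:
            raise RuntimeError("could not place translocation; genome too small")

    # post-removal coordinate of an original position (never inside a segment)
    def post_removal(chrom: str, pos: int) -> int:
        return pos - sum(b - a for a, b in segments[chrom] if b <= pos)

    # assemble derived chromosomes: removals first, then insertions in
    # ascending final coordinate
    removed = {}
    for c in order:
        seq = seqs[c]
        for a, b in sorted(segments[c], reverse=True):
            seq = seq[:a] + seq[b:]
        removed[c] = seq
    incoming: dict[str, list[tuple[int, tuple]]] = {c: [] for c in order}
    for plan in plans:
        src, s, e, dest, dpos = plan
        incoming[dest].append((post_removal(dest, dpos), plan))
    events: list[Rearrangement] = []
    out_seqs = {}
    for c in order:
        seq = removed[c]
        shift = 0
        for pr_pos, (src, s, e, dest, dpos) in sorted(incoming[c]):
            at = pr_pos + shift
            seq = seq[:at] + seqs[src][s:e] + seq[at:]
            events.append(
                Rearrangement(src, s, e, dest, at,
                              derived_start=at, derived_end=at + (e - s))
            )
            shift += e - s
        out_seqs[c] = seq
    return [SeqRecord(c, out_seqs[c], tier="chromosome") for c in order], events


def diverge_genome(
    reference: list[SeqRecord], config: SimConfig
) -> tuple[list[SeqRecord], TruthSet]:
    """Derive a congener genome: translocations, then SNCs and short InDels.

    Point mutations fall at ``snp_rate`` per bp with a 2:1
    transition:transversion ratio; InDels fall at ``indel_rate`` with
    lengths uniform on 1..indel_max_len and a 50/50 insertion/deletion
    split.  Events are spaced so that no two planted events overlap
    (colliding draws are dropped, never stacked).  Variant truth is
    recorded with VCF-style anchoring in reference coordinates.

    With translocations requested, reference coordinates of variants inside
    a moved segment refer to the segment's source location.
    """
    rng = np.random.default_rng(config.seed + 1)
    truth = TruthSet()

    intermediate, truth.rearrangements = (
        _translocate(reference, config, rng)
        if config.n_translocations
        else (reference, [])
    )

    ref_map = _build_reference_map(reference, truth.rearrangements)

    derived: list[SeqRecord] = []
    for rec in intermediate:
        seq = rec.sequence
        n = len(seq)
        is_snp = rng.random(n) < config.snp_rate
        is_indel = rng.random(n) < config.indel_rate
        indel_pos = np.flatnonzero(is_indel)
        # enforce spacing between indels and keep them off the ends
        keep = []
        last = -(10 * config.indel_max_len)
        for p in indel_pos:
            if p - last > 2 * config.indel_max_len and config.indel_max_len < p < n - 2 * config.indel_max_len:
                keep.append(p)
                last = p
        indel_pos = np.array(keep, dtype=np.int64)
        indel_len = rng.integers(1, config.indel_max_len + 1, size=len(indel_pos))
        indel_ins = rng.random(len(indel_pos)) < 0.5
        # SNCs may not fall on, inside, or immediately beside an InDel
        # footprint: an SNC adjacent to an indel forms a composite event
        # with no unique normalized representation, and the left margin
        # additionally covers anchor shifts from indel left-normalization
        margin = 12
        for p, L, ins in zip(indel_pos, indel_len, indel_ins):
            hi = p + L + 1 if not ins else p + 1
            is_snp[max(p - margin, 0) : hi + margin] = False
        snp_pos = np.flatnonzero(is_snp)
        ti = rng.random(len(snp_pos)) < (2.0 / 3.0)
        tv_pick = rng.integers(0, 2, size=len(snp_pos))

        events = []  # (pos, kind, payload)
        codes = _seq.encode(seq)
        for p, t, w in zip(snp_pos, ti, tv_pick):
            old = int(codes[p])
            if t:
                new = _TRANSITION[old]
            else:
                tvs = [b for b in range(4) if b != old and b != _TRANSITION[old]]
                new = tvs[w]
            events.append((int(p), "S", _seq.decode(np.array([new], dtype=np.uint8))))
        for p, L, ins in zip(indel_pos, indel_len, indel_ins):
            if ins:
                fill = _seq.decode(
                    rng.integers(0, 4, size=int(L)).astype(np.uint8)
                )
                events.append((int(p), "I", fill))
            else:
                events.append((int(p), "D", int(L)))
        events.sort(key=lambda e: e[0])

        out_parts = []
        cursor = 0
        offset = 0  # derived - intermediate
        for pos, kind, payload in events:
            rchrom, rpos = ref_map(rec.id, pos)
            if kind == "S":
                out_parts.append(seq[cursor:pos])
                out_parts.append(payload)
                truth.variants.append(
                    TruthVariant(rchrom, rpos, seq[pos], payload, "SNC",
                                 rec.id, pos + offset)
                )
                cursor = pos + 1
            elif kind == "I":
                # insertion after `pos`, anchored at `pos`; truth is stored
                # in canonical left-normalized form
                out_parts.append(seq[cursor : pos + 1])
                out_parts.append(payload)
                np_, nref, nalt = _seq.left_align_indel(
                    seq.__getitem__, pos, seq[pos], seq[pos] + payload
                )
                nchrom, nrpos = ref_map(rec.id, np_)
                truth.variants.append(
                    TruthVariant(nchrom, nrpos, nref, nalt, "InDel",
                                 rec.id, np_ + offset)
                )
                cursor = pos + 1
                offset += len(payload)
            else:  # deletion of `payload` bases after `pos`
                L = payload
                out_parts.append(seq[cursor : pos + 1])
                np_, nref, nalt = _seq.left_align_indel(
                    seq.__getitem__, pos, seq[pos : pos + L + 1], seq[pos]
                )
                nchrom, nrpos = ref_map(rec.id, np_)
                truth.variants.append(
                    TruthVariant(nchrom, nrpos, nref, nalt, "InDel",
                                 rec.id, np_ + offset)
                )
                cursor = pos + 1 + L
                offset -= L
        out_parts.append(seq[cursor:])
        derived.append(SeqRecord(rec.id, "".join(out_parts), tier="chromosome"))
    return derived, truth


def _build_reference_map(reference, rearrangements):
    """Return f(derived_chrom, derived_pos) -> (ref_chrom, ref_pos).

    Maintains per-chromosome block lists (ref_chrom, ref_start, ref_end):
    all source segments are removed first (coordinates are original), then
    segments are inserted at their final destination coordinates in
    ascending order — matching how :func:`_translocate` assembles the
    rearranged genome.
    """
    blocks = {r.id: [(r.id, 0, len(r.sequence))] for r in reference}

    def remove(chrom, start, end):
        out = []
        for rc, rs, re_ in blocks[chrom]:
            if rc != chrom:
                out.append((rc, rs, re_))
                continue
            lo, hi = max(rs, start), min(re_, end)
            if lo >= hi:
                out.append((rc, rs, re_))
                continue
            if rs < start:
                out.append((rc, rs, start))
            if re_ > end:
                out.append((rc, end, re_))
        blocks[chrom] = out

    def insert(chrom, dpos, segment_block):
        out, pos, done = [], 0, False
        for rc, rs, re_ in blocks[chrom]:
            blen = re_ - rs
            if not done and pos <= dpos <= pos + blen:
                k = dpos - pos
                if k > 0:
                    out.append((rc, rs, rs + k))
                out.append(segment_block)
                if k < blen:
                    out.append((rc, rs + k, re_))
                done = True
            else:
                out.append((rc, rs, re_))
            pos += blen
        if not done:
            out.append(segment_block)
        blocks[chrom] = out

    for ev in rearrangements:
        remove(ev.src_chrom, ev.src_start, ev.src_end)
    for ev in sorted(rearrangements, key=lambda e: (e.dest_chrom, e.dest_pos)):
        insert(ev.dest_chrom, ev.dest_pos, (ev.src_chrom, ev.src_start, ev.src_end))

    def mapper(chrom, pos):
        cursor = 0
        for rc, rs, re_ in blocks[chrom]:
            blen = re_ - rs
            if pos < cursor + blen:
                return rc, rs + (pos - cursor)
            cursor += blen
        raise IndexError(f"{chrom}:{pos} beyond chromosome end")

    return mapper


# --- transposable elements -------------------------------------------------


def _draw_divergences(fam: TEFamily, rng: np.random.Generator) -> np.ndarray:
    d = fam.divergences
    if isinstance(d, (list, np.ndarray)):
        if len(d) != fam.copies:
            raise ValueError(f"family {fam.name}: need one divergence per copy")
        return np.asarray(d, dtype=float)
    kind = d[0]
    if kind == "uniform":
        return rng.uniform(d[1], d[2], size=fam.copies)
    if kind == "normal":
        return np.clip(rng.normal(d[1], d[2], size=fam.copies), 0.0, 0.75)
    raise ValueError(f"unknown divergence distribution {d!r}")


def mutate_to_divergence(
    consensus: str, divergence: float, rng: np.random.Generator
) -> str:
    """Mutate a consensus to a target divergence with 2:1 transitions:transversions."""
    codes = _seq.encode(consensus).copy()
    n_mut = int(round(divergence * len(codes)))
    if n_mut == 0:
        return consensus
    pos = rng.choice(len(codes), size=n_mut, replace=False)
    ti = rng.random(n_mut) < (2.0 / 3.0)
    pick = rng.integers(0, 2, size=n_mut)
    for p, t, w in zip(pos, ti, pick):
        old = int(codes[p])
        if t:
            codes[p] = _TRANSITION[old]
        else:
            tvs = [b for b in range(4) if b != old and b != _TRANSITION[old]]
            codes[p] = tvs[w]
    return _seq.decode(codes)


def plant_tes(
    genome: list[SeqRecord], config: SimConfig, seed_offset: int = 2
) -> tuple[list[SeqRecord], TruthSet]:
    """Insert diverged TE copies; truth records final-genome intervals."""
    rng = np.random.default_rng(config.seed + seed_offset)
    truth = TruthSet()
    lengths = np.array([len(r.sequence) for r in genome], dtype=float)
    placements: dict[int, list[tuple[int, str, TEFamily, float]]] = {
        i: [] for i in range(len(genome))
    }
    for fam in config.te_families:
        divs = _draw_divergences(fam, rng)
        for d in divs:
            ci = int(rng.choice(len(genome), p=lengths / lengths.sum()))
            pos = int(rng.integers(0, len(genome[ci].sequence)))
            copy = mutate_to_divergence(fam.consensus, float(d), rng)
            placements[ci].append((pos, copy, fam, float(d)))
    out = []
    for i, rec in enumerate(genome):
        plist = sorted(placements[i], key=lambda t: t[0])
        parts, cursor, offset = [], 0, 0
        for pos, copy, fam, d in plist:
            parts.append(rec.sequence[cursor:pos])
            start = pos + offset
            parts.append(copy)
            truth.te_copies.append(
                TECopy(rec.id, start, start + len(copy), fam.name, fam.superfamily, d)
            )
            offset += len(copy)
            cursor = pos
        parts.append(rec.sequence[cursor:])
        out.append(SeqRecord(rec.id, "".join(parts), tier=rec.tier))
    return out, truth


# --- reads -----------------------------------------------------------------


@dataclass
class ReadSet:
    """Paired reads of one library as 2-bit code matrices (one row per read).

    Rows of ``reads1``/``reads2`` are the sequences as they would appear in
    FASTQ, i.e. already reverse-complemented where the protocol dictates.
    """

    library: LibrarySpec
    read_length: int
    reads1: np.ndarray
    reads2: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.reads1)

    def read_strings(self, which: int):
        m = self.reads1 if which == 1 else self.reads2
        return [_seq.decode(m[i]) for i in range(len(m))]

    def to_fastq(self, path1, path2) -> None:
        for path, m, suffix in ((path1, self.reads1, "/1"), (path2, self.reads2, "/2")):
            with open(path, "w") as fh:
                qual = "I" * self.read_length
                for i in range(len(m)):
                    fh.write(
                        f"@{self.library.name}_{i}{suffix}\n"
                        f"{_seq.decode(m[i])}\n+\n{qual}\n"
                    )


def _revcomp_matrix(m: np.ndarray) -> np.ndarray:
    return (3 - m[:, ::-1]).astype(np.uint8)


def simulate_pairs(
    genome: list[SeqRecord],
    libraries: Sequence[LibrarySpec] | None = None,
    read_length: int = 100,
    per_base_error: float = 0.0,
    seed: int = 0,
) -> list[ReadSet]:
    """Simulate tiered paired-end reads.

    Pair count per library is ``round(coverage * genome_length /
    (2 * read_length))``; inserts are normal(mean, sd) draws (rounded,
    clipped to at least 2 reads and to the chromosome); FR pairs read
    inward from the fragment ends, RF pairs outward.  Substitution errors
    are injected uniformly at ``per_base_error``.
    """
    libraries = list(libraries) if libraries is not None else list(DEFAULT_LIBRARIES)
    rng = np.random.default_rng(seed + 3)
    lens = np.array([len(r.sequence) for r in genome], dtype=np.int64)
    shortest = int(lens.min())
    offsets = np.concatenate([[0], np.cumsum(lens)])[:-1]
    big = np.concatenate([_seq.encode(r.sequence) for r in genome])
    G = int(lens.sum())
    out = []
    L = read_length
    for lib in libraries:
        if lib.insert_mean >= shortest:
            raise ValueError(
                f"library {lib.name}: insert_mean exceeds shortest chromosome"
            )
        n = int(round(lib.coverage * G / (2 * L)))
        ci = rng.choice(len(genome), size=n, p=lens / lens.sum())
        ins = np.clip(
            np.rint(rng.normal(lib.insert_mean, lib.insert_sd, size=n)).astype(np.int64),
            2 * L,
            lens[ci] - 1,
        )
        start = (rng.random(n) * (lens[ci] - ins)).astype(np.int64)
        g1 = offsets[ci] + start
        g2 = offsets[ci] + start + ins - L
        idx = np.arange(L, dtype=np.int64)
        left = big[g1[:, None] + idx]
        right = big[g2[:, None] + idx]
        if lib.orientation == "FR":
            r1, r2 = left, _revcomp_matrix(right)
        else:
            r1, r2 = _revcomp_matrix(left), right
        if per_base_error > 0:
            for m in (r1, r2):
                mask = rng.random(m.shape) < per_base_error
                shift = rng.integers(1, 4, size=int(mask.sum())).astype(np.uint8)
                m[mask] = (m[mask] + shift) % 4
        out.append(ReadSet(lib, L, r1.astype(np.uint8), r2.astype(np.uint8)))
    return out


# --- scaffolding / shredding ----------------------------------------------


def fragment_scaffolds(
    genome: list[SeqRecord],
    gap_count: int,
    gap_len_range: tuple[int, int] = (20, 500),
    seed: int = 0,
    min_spacing: int = 2000,
) -> tuple[list[SeqRecord], TruthSet]:
    """Replace gap_count stretches of true sequence with equal-length N-runs.

    Gaps are spaced at least ``min_spacing`` apart and from chromosome
    ends; the removed (true) sequence is stored per gap so fills can be
    checked byte for byte.  Raises if the requested gaps cannot be spaced.
    """
    rng = np.random.default_rng(seed + 4)
    lens = np.array([len(r.sequence) for r in genome], dtype=float)
    per = np.floor(gap_count * lens / lens.sum()).astype(int)
    while per.sum() < gap_count:
        per[int(np.argmax(lens / (per + 1)))] += 1
    truth = TruthSet()
    out = []
    lo, hi = gap_len_range
    for rec, k in zip(genome, per):
        n = len(rec.sequence)
        if k == 0:
            out.append(SeqRecord(rec.id, rec.sequence, tier="scaffold"))
            continue
        stride = min_spacing + hi
        slack = n - 2 * min_spacing - k * stride
        if slack <= 0:
            raise ValueError(f"{rec.id}: cannot space {k} gaps {min_spacing} apart")
        # sorted uniform draws in the slack space, then restore the strides:
        # guarantees pairwise spacing >= min_spacing + hi deterministically
        starts = (
            np.sort(rng.integers(0, slack, size=k))
            + min_spacing
            + np.arange(k) * stride
        )
        glens = rng.integers(lo, hi + 1, size=k)
        seq = rec.sequence
        parts, cursor = [], 0
        for gi, (s, gl) in enumerate(zip(starts, glens)):
            parts.append(seq[cursor:s])
            parts.append("N" * int(gl))
            truth.gap_fills.append(
                GapFill(rec.id, gi, int(s), int(s + gl), seq[s : s + gl])
            )
            cursor = int(s + gl)
        parts.append(seq[cursor:])
        out.append(SeqRecord(rec.id, "".join(parts), tier="scaffold"))
    return out, truth


@dataclass(frozen=True)
class PieceOrigin:
    piece_id: str
    chrom: str
    start: int
    end: int
    strand: str


def shred_genome(
    genome: list[SeqRecord],
    piece_len: int,
    seed: int = 0,
    avoid: Sequence[tuple[str, int]] = (),
    margin: int = 0,
    flip_fraction: float = 0.5,
    jitter: float = 0.2,
    tier: str = "scaffold",
) -> tuple[list[SeqRecord], list[PieceOrigin]]:
    """Cut chromosomes into pieces of roughly piece_len for recovery tests.

    Cut points are jittered; any cut landing within ``margin`` of a
    position in ``avoid`` (e.g. a planted breakpoint that a test wants
    contained inside one piece) is shifted away from it.  A
    ``flip_fraction`` of pieces is reverse-complemented so orientation
    recovery is exercised.
    """
    rng = np.random.default_rng(seed + 5)
    avoid_by_chrom: dict[str, list[int]] = {}
    for c, p in avoid:
        avoid_by_chrom.setdefault(c, []).append(p)
    pieces, origins = [], []
    pid = 0
    for rec in genome:
        n = len(rec.sequence)
        cuts = [0]
        pos = 0
        while pos + piece_len < n:
            nxt = pos + piece_len + int(rng.integers(-int(jitter * piece_len),
                                                     int(jitter * piece_len) + 1))
            nxt = min(max(nxt, pos + piece_len // 2), n)
            for ap in avoid_by_chrom.get(rec.id, ()):
                if abs(nxt - ap) < margin:
                    nxt = ap + margin if nxt >= ap else ap - margin
            nxt = min(max(nxt, pos + piece_len // 4), n)
            cuts.append(nxt)
            pos = nxt
        cuts.append(n)
        for a, b in zip(cuts, cuts[1:]):
            if b - a == 0:
                continue
            pid += 1
            name = f"piece{pid}"
            seq = rec.sequence[a:b]
            strand = "+"
            if rng.random() < flip_fraction:
                seq = _seq.revcomp(seq)
                strand = "-"
            pieces.append(SeqRecord(name, seq, tier=tier))
            origins.append(PieceOrigin(name, rec.id, a, b, strand))
    return pieces, origins


# --- truth closure ---------------------------------------------------------


def apply_truth(reference: list[SeqRecord], truth: TruthSet) -> list[SeqRecord]:
    """Replay a TruthSet against the reference (rearrangements, then variants).

    Used to verify the closure invariant: the result must equal the derived
    genome byte for byte.  TE copies and gap fills are separate layers and
    are not replayed here.
    """
    original = {r.id: r.sequence for r in reference}
    seqs = dict(original)
    order = [r.id for r in reference]
    # removals by original coordinates (descending so coordinates hold),
    # then insertions in ascending final coordinates
    by_src: dict[str, list] = {}
    for ev in truth.rearrangements:
        by_src.setdefault(ev.src_chrom, []).append(ev)
    for chrom, evs in by_src.items():
        for ev in sorted(evs, key=lambda e: -e.src_start):
            seqs[chrom] = (
                seqs[chrom][: ev.src_start] + seqs[chrom][ev.src_end :]
            )
    for ev in sorted(truth.rearrangements, key=lambda e: (e.dest_chrom, e.dest_pos)):
        seg = original[ev.src_chrom][ev.src_start : ev.src_end]
        seqs[ev.dest_chrom] = (
            seqs[ev.dest_chrom][: ev.dest_pos] + seg + seqs[ev.dest_chrom][ev.dest_pos :]
        )
    # variants carry derived coordinates; apply left to right per chromosome
    by_chrom: dict[str, list[TruthVariant]] = {}
    for v in truth.variants:
        by_chrom.setdefault(v.derived_chrom, []).append(v)
    out = []
    for cid in order:
        seq = seqs[cid]
        parts, cursor, shift = [], 0, 0
        for v in sorted(by_chrom.get(cid, []), key=lambda v: v.derived_pos):
            pos = v.derived_pos - shift  # back to pre-mutation coords
            if v.type == "SNC":
                parts.append(seq[cursor:pos])
                parts.append(v.alt)
                cursor = pos + 1
            elif len(v.alt) > len(v.ref):  # insertion
                parts.append(seq[cursor : pos + 1])
                parts.append(v.alt[1:])
                cursor = pos + 1
                shift += len(v.alt) - 1
            else:  # deletion
                parts.append(seq[cursor : pos + 1])
                cursor = pos + len(v.ref)
                shift -= len(v.ref) - 1
        parts.append(seq[cursor:])
        out.append(SeqRecord(cid, "".join(parts), tier="chromosome"))
    return out
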