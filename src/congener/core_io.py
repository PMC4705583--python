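"""Readers and writers for the standard formats the toolkit touches.

Everything inside the package uses 0-based half-open coordinates; the
conversion to and from each format's native convention (1-based inclusive
for SAM, GFF3, AGP, VCF and RepeatMasker ``.out``) happens here and only
here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

__all__ = [
    "SeqRecord",
    "AlignmentRecord",
    "GeneModel",
    "RepeatHit",
    "VariantRecordOut",
    "AgpRow",
    "ParseError",
    "read_sequences",
    "write_sequences",
    "read_alignments",
    "write_alignments",
    "read_gene_models",
    "read_repeat_hits",
    "scaffold_agp_rows",
    "write_agp",
    "write_vcf",
    "write_tsv",
    "find_gaps",
]

TIERS = ("contig", "scaffold", "chromosome")

#: minimum N-run length that counts as an assembly gap (contig boundary);
#: shorter N-runs are treated as ordinary sequence.
MIN_GAP_RUN = 10


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SeqRecord:
    """A nucleotide sequence at one of the three assembly tiers."""

    id: str
    sequence: str
    tier: str = "contig"
    quality: str | None = None

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AlignmentRecord:
    """A mapped read or segment, SAM-flavoured but 0-based half-open."""

    query_id: str
    target_id: str
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    strand: str
    is_paired: bool = False
    mate_target_id: str | None = None
    mate_target_start: int | None = None
    flags: int = 0
    cigar: str = ""
    query_sequence: str | None = None

    @property
    def is_reverse(self) -> bool:
        return self.strand == "-"


@dataclass
class GeneModel:
    """A transcript with exon and CDS structure.

    ``exons`` and ``cds`` are sorted, disjoint 0-based half-open intervals;
    ``cds`` lies within ``exons``.  ``complete`` is False when the summed CDS
    length is not a multiple of three.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    phase: int = 0

    def __post_init__(self) -> None:
        for ivs in (self.exons, self.cds):
            for (a, b), (c, d) in zip(ivs, ivs[1:]):
                if c < b:
                    raise ValueError(
                        f"{self.transcript_id}: intervals overlap or are unsorted"
                    )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.cds)

    @property
    def complete(self) -> bool:
        return bool(self.cds) and self.cds_length % 3 == 0


@dataclass
class RepeatHit:
    """One masked repeat interval from a RepeatMasker ``.out`` file."""

    chrom: str
    start: int
    end: int
    family: str
    superfamily_class: str
    percent_divergence: float
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("repeat hit interval is empty")
        if not 0.0 <= self.percent_divergence <= 100.0:
            raise ValueError("percent_divergence outside [0, 100]")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def identity(self) -> float:
        """Percent identity to the library consensus."""
        return 100.0 - self.percent_divergence

    @property
    def class_family(self) -> str:
        """Full RepeatMasker-style label, e.g. ``LINE/Rex-Babar``."""
        if self.family and self.family != self.superfamily_class:
            return f"{self.superfamily_class}/{self.family}"
        return self.superfamily_class


@dataclass
class VariantRecordOut:
    """A called variant ready for VCF emission (pos converted on write)."""

    chrom: str
    pos: int  # 0-based internally; written 1-based
    ref: str
    alt: str
    depth: int
    alt_depth: int
    p_value: float

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")
        if not self.depth >= self.alt_depth >= 1:
            raise ValueError("require depth >= alt_depth >= 1")


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_sequences(path, format: str = "FASTA", tier: str = "contig") -> list[SeqRecord]:
    """Read a FASTA or FASTQ file into uppercased :class:`SeqRecord` objects."""
    fmt = format.upper()
    if fmt not in ("FASTA", "FASTQ"):
        raise ValueError(f"unsupported sequence format {format!r}")
    out: list[SeqRecord] = []
    seen: set[str] = set()
    try:
        for rec in SeqIO.parse(str(path), fmt.lower()):
            if rec.id in seen:
                raise ParseError(f"{path}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
            qual = None
            if fmt == "FASTQ":
                qual = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
            out.append(SeqRecord(rec.id, str(rec.seq).upper(), tier=tier, quality=qual))
    except ValueError as exc:  # Biopython's malformed-record errors
        raise ParseError(f"{path}: {exc}") from exc
    return out


def write_sequences(records: Iterable[SeqRecord], path, format: str = "FASTA") -> None:
    fmt = format.upper()
    bio = []
    for r in records:
        b = BioSeqRecord(Seq(r.sequence), id=r.id, description="")
        if fmt == "FASTQ":
            qual = r.quality or "I" * len(r.sequence)
            b.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
        bio.append(b)
    SeqIO.write(bio, str(path), fmt.lower())


def find_gaps(sequence: str, min_run: int = MIN_GAP_RUN) -> list[tuple[int, int]]:
    """0-based half-open intervals of N-runs of length >= min_run (the gaps)."""
    gaps = []
    i = sequence.find("N")
    n = len(sequence)
    while i != -1:
        j = i
        while j < n and sequence[j] == "N":
            j += 1
        if j - i >= min_run:
            gaps.append((i, j))
        i = sequence.find("N", j)
    return gaps


# ---------------------------------------------------------------------------
# SAM


def read_alignments(path) -> list[AlignmentRecord]:
    """Parse a SAM file (header required); only mapped records are yielded."""
    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            qlen = rec.infer_query_length()
            if rec.query_sequence is not None and qlen is not None:
                if qlen != len(rec.query_sequence):
                    raise ParseError(
                        f"{path}: read {rec.query_name}: CIGAR consumes {qlen} "
                        f"bases but SEQ has {len(rec.query_sequence)}"
                    )
            out.append(
                AlignmentRecord(
                    query_id=rec.query_name,
                    target_id=rec.reference_name,
                    query_start=rec.query_alignment_start,
                    query_end=rec.query_alignment_end,
                    target_start=rec.reference_start,
                    target_end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    is_paired=rec.is_paired,
                    mate_target_id=(
                        sam.get_reference_name(rec.next_reference_id)
                        if rec.next_reference_id >= 0
                        else None
                    ),
                    mate_target_start=(
                        rec.next_reference_start if rec.next_reference_start >= 0 else None
                    ),
                    flags=rec.flag,
                    cigar=rec.cigarstring or "",
                    query_sequence=rec.query_sequence,
                )
            )
    return out


def write_alignments(
    records: Iterable[AlignmentRecord], references: Sequence[SeqRecord], path
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": r.id, "LN": len(r.sequence)} for r in references],
    }
    ref_index = {r.id: i for i, r in enumerate(references)}
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for rec in records:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = rec.query_id
            a.flag = rec.flags
            a.reference_id = ref_index[rec.target_id]
            a.reference_start = rec.target_start
            a.mapping_quality = 60
            a.cigarstring = rec.cigar or None
            if rec.query_sequence:
                a.query_sequence = rec.query_sequence
                a.query_qualities = pysam.qualitystring_to_array(
                    "I" * len(rec.query_sequence)
                )
            if rec.mate_target_id is not None:
                a.next_reference_id = ref_index[rec.mate_target_id]
                a.next_reference_start = rec.mate_target_start or 0
            sam.write(a)


# ---------------------------------------------------------------------------
# GFF3 gene models


def read_gene_models(path) -> list[GeneModel]:
    """Load transcript models (mRNA + exon + CDS) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for mrna in db.features_of_type(("mRNA", "transcript")):
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds_feats = sorted(
            db.children(mrna, featuretype="CDS"), key=lambda f: f.start
        )
        cds = [(f.start - 1, f.end) for f in cds_feats]
        phase = 0
        if cds_feats:
            first = cds_feats[0] if mrna.strand == "+" else cds_feats[-1]
            if first.frame not in (None, "."):
                phase = int(first.frame)
        parents = list(db.parents(mrna, featuretype="gene"))
        gene_id = parents[0].id if parents else mrna.id
        models.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=mrna.id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                exons=exons or cds,
                cds=cds,
                phase=phase,
            )
        )
    return models


# ---------------------------------------------------------------------------
# RepeatMasker .out


def read_repeat_hits(path) -> list[RepeatHit]:
    """Parse a RepeatMasker ``.out`` file (two header lines, one blank line)."""
    hits: list[RepeatHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if fields[0] in ("SW", "score") or fields[0].startswith("-"):
                continue  # header furniture
            try:
                int(fields[0])
            except ValueError:
                continue
            try:
                div = float(fields[1])
                chrom = fields[4]
                begin = int(fields[5])
                end = int(fields[6])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field: {exc}") from exc
            strand = "+" if fields[8] == "+" else "-"
            label = fields[10]
            if "/" in label:
                superfamily, family = label.split("/", 1)
            else:
                superfamily, family = label, fields[9]
            hits.append(
                RepeatHit(
                    chrom=chrom,
                    start=begin - 1,
                    end=end,
                    family=family,
                    superfamily_class=superfamily,
                    percent_divergence=div,
                    strand=strand,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# AGP 2.0


@dataclass
class AgpRow:
    """One AGP 2.0 line; object coordinates are kept 0-based internally."""

    object_id: str
    object_start: int  # 0-based half-open internally
    object_end: int
    part_number: int
    component_type: str  # "W" or "N"
    component_id: str | None = None
    component_start: int | None = None  # 0-based half-open
    component_end: int | None = None
    orientation: str = "+"
    gap_length: int | None = None
    gap_type: str = "scaffold"
    linkage_evidence: str = "align_genus"

    def to_line(self) -> str:
        if self.component_type == "N":
            tail = [
                str(self.gap_length),
                self.gap_type,
                "yes",
                self.linkage_evidence,
            ]
        else:
            tail = [
                self.component_id,
                str(self.component_start + 1),
                str(self.component_end),
                self.orientation,
            ]
        return "\t".join(
            [
                self.object_id,
                str(self.object_start + 1),
                str(self.object_end),
                str(self.part_number),
                self.component_type,
            ]
            + tail
        )


def scaffold_agp_rows(record: SeqRecord, min_gap: int = MIN_GAP_RUN) -> list[AgpRow]:
    """Decompose one scaffold into alternating W (contig) and N (gap) AGP rows."""
    gaps = find_gaps(record.sequence, min_gap)
    rows: list[AgpRow] = []
    part = 1
    pos = 0
    n_contig = 1
    for gs, ge in gaps + [(len(record.sequence), len(record.sequence))]:
        if gs > pos:
            rows.append(
                AgpRow(
                    record.id,
                    pos,
                    gs,
                    part,
                    "W",
                    component_id=f"{record.id}_ctg{n_contig}",
                    component_start=0,
                    component_end=gs - pos,
                )
            )
            part += 1
            n_contig += 1
        if ge > gs:
            rows.append(
                AgpRow(record.id, gs, ge, part, "N", gap_length=ge - gs)
            )
            part += 1
        pos = ge
    return rows


def write_agp(rows: Iterable[AgpRow], path) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version 2.0\n")
        for row in rows:
            fh.write(row.to_line() + "\n")


def read_agp(path) -> list[AgpRow]:
    rows: list[AgpRow] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if f[4] == "N":
                rows.append(
                    AgpRow(
                        f[0], int(f[1]) - 1, int(f[2]), int(f[3]), "N",
                        gap_length=int(f[5]), gap_type=f[6], linkage_evidence=f[8],
                    )
                )
            else:
                rows.append(
                    AgpRow(
                        f[0], int(f[1]) - 1, int(f[2]), int(f[3]), f[4],
                        component_id=f[5], component_start=int(f[6]) - 1,
                        component_end=int(f[7]), orientation=f[8],
                    )
                )
    return rows


# ---------------------------------------------------------------------------
# VCF / TSV


def write_vcf(
    variants: Iterable[VariantRecordOut],
    contigs: Sequence[tuple[str, int]],
    path,
) -> None:
    """Write variants as minimal VCF 4.2 (positions converted to 1-based)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=congener\n")
        for name, length in contigs:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##INFO=<ID=AD,Number=1,Type=Integer,Description="Alt depth">\n')
        fh.write('##INFO=<ID=PV,Number=1,Type=Float,Description="Binomial tail p">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            info = f"DP={v.depth};AD={v.alt_depth};PV={v.p_value:.3g}"
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\n"
            )


def read_vcf(path) -> list[VariantRecordOut]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            info = dict(
                kv.split("=", 1) for kv in f[7].split(";") if "=" in kv
            )
            out.append(
                VariantRecordOut(
                    chrom=f[0],
                    pos=int(f[1]) - 1,
                    ref=f[3],
                    alt=f[4],
                    depth=int(info.get("DP", 1)),
                    alt_depth=int(info.get("AD", 1)),
                    p_value=float(info.get("PV", 0.0)),
                )
            )
    return out


def write_tsv(rows: Iterable[Sequence], header: Sequence[str], path) -> None:
    """Write rows as TSV with a header line; an empty list yields header only."""
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
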