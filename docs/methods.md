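# Methods

This note documents the models, algorithms and design choices behind
`congener`, in the spirit of the methods documentation of simulation and
statistics packages: enough detail to reproduce or criticize every
decision, including the ones the underlying workflow leaves open.

## The guided-assembly model

The toolkit models the situation where species B's genome is assembled
with the help of species A's finished, chromosome-scale reference, the
two being congeners separated by roughly one base change per 50–100 bp.
The workflow has four stages: (a) assisted assembly — reads and contigs
of B aligned to A drive gap filling and scaffold ordering; (b) an
independent de novo assembly of B; (c) a merge that appends de novo
sequence the assisted assembly could not anchor; (d) chromosome
formatting against A's chromosome map.  All comparative statistics
(variant rates and effects, rearrangements, TE landscapes) are then
computed between the resulting genomes.

Everything here operates on synthetic data with planted truth.  Internal
coordinates are 0-based half-open everywhere; conversion to each file
format's convention (SAM, GFF3, AGP, VCF, RepeatMasker `.out` are all
1-based inclusive) happens only in `core_io`, so there is exactly one
place where an off-by-one can live.  An N-run of ≥ 10 bases inside a
scaffold defines an assembly gap (a contig boundary); shorter N-runs are
ordinary sequence.  This threshold is a convention of this package — gap
definitions vary between assemblers and the workflow does not fix one.

## The synthetic-data generator

`synthdata` emulates the study design the toolkit is built around:

- **Reference genome**: i.i.d. bases at a configurable GC fraction
  (default 0.35, matching the ~34–35 % GC of the fish genomes this
  models).  Default scale 2 Mb over 4 chromosomes — large enough that
  20-mers are effectively unique and 25 kb translocations fit with
  margins, small enough that every benchmark runs in tens of seconds.
- **Divergence**: point mutations at `snp_rate` (default 0.01, the
  midpoint of the 1/52–1/69 observed range rounded to 1/100) with a 2:1
  transition:transversion ratio — realistic for vertebrate genomes and
  necessary for the Kimura p ≠ q machinery to be testable; InDels at
  one tenth that rate with lengths uniform on 1..10 (the workflow reports
  no InDel length spectrum; the uniform model is a stand-in, not an
  inference).  Planted InDels are recorded in left-normalized VCF form.
  No SNC is planted on, inside, or within 12 bp of an InDel footprint:
  an SNC adjacent to an indel forms a composite event with no unique
  normalized representation, so truth comparison would be ill-posed.
- **Translocations**: cut-and-paste of segments ≥ `translocation_min_len`
  (default 25 kb) between chromosomes.  All events are planned up front
  on reference coordinates with strict disjointness — no segment
  overlaps another, no insertion point falls inside a removed segment,
  and both junctions stay ≥ min_len from chromosome ends.  Without this,
  a later translocation can excise material moved by an earlier one and
  the planted truth stops being a set of intact segments.
- **TE copies**: family consensus sequences mutated to a drawn divergence
  (2:1 ti:tv, substitutions only) and inserted at random positions.
- **Reads**: tiered paired-end libraries, by default 30× 300 ± 30 bp
  fragments read inward (FR), 17× 3 kb ± 300 and 5× 8 kb ± 800 mate
  pairs read outward (RF), 100 bp reads — the ~50× tiered design of the
  sequencing effort this models.  Pair count per library is
  round(coverage × G / (2 × read length)); inserts are rounded normal
  draws clipped to the chromosome.
- **Truth closure**: replaying a `TruthSet` against the reference must
  reproduce the derived genome byte for byte; this is a tested invariant,
  which is what makes every downstream recovery number trustworthy.

What the generator does **not** emulate: base-quality error profiles,
PCR duplicates, GC coverage bias, heterozygosity (the modeled lines are
inbred), repeat-driven multi-mapping beyond chance k-mer collisions, and
chimeric mate pairs.  Passing benchmarks therefore demonstrate the
correctness and calibration of the algorithms under clean conditions,
not performance on real libraries, where mapping ambiguity in repeats
would dominate the error budget.

## Read mapping

`chromo.map_reads` is a deliberately small seed-and-verify mapper
standing in for the production aligner of the original workflow (whose
multi-mapping semantics are not re-implemented).  Unique 20-mers of the
target are indexed; four seeds per read and strand vote for a candidate
locus; an ungapped comparison accepts reads with ≤ 3 mismatches; the
rest are realigned with a banded edit-distance alignment (edlib) in a
padded window.  Two robustness measures matter near InDels:

- **Anchor clipping**: the cheapest edit script often paints the read
  tail beyond an indel as a mismatch run instead of opening the gap.
  Rescued alignments must begin and end with an exact run of ≥ 12
  matches; anything outside is soft-clipped.  Unit edit costs also
  sometimes split one planted indel into fragments when intermediate
  bases match by chance, so alignments with two or more gap ops are
  redone with affine gap costs (open −6, extend −0.5, match 1,
  mismatch −2), which restores the single-gap representation.
- **End trimming**: the pileup ignores the outer 10 bases of every
  aligned read.  Misplaced tail bases are systematic, not random — every
  read overhanging the same indel by a few bases misaligns the same way
  — and on reference columns that correct reads skip (deleted bases)
  they would otherwise fabricate a confident variant.

## Variant calling

The caller re-specifies the pileup test of the original workflow in a
fully defined form: a site is called when depth ≥ 3, the top non-reference
allele reaches ≥ 20 % of the depth, and the one-sided binomial tail
P(X ≥ alt_depth | n = depth, ε = 0.01) falls below 0.1.  The minimum
coverage (3) and p cutoff (0.1) are the workflow's printed thresholds;
the error rate and allele-fraction floor make them meaningful for an
inbred (haploid-equivalent) comparison, where a true change should be
near-unanimous.  InDel observations are anchored VCF-style at the
preceding base, pooled across equivalent left-normalized representations,
and tested identically against the anchor-column depth.  An SNC call
inside a called deletion span is discarded: a deleted interval has no
bases to change, so such calls are always alignment artifacts.

Effect classification follows the standard annotator categories.  Open
parameters are set to the conventional defaults the original workflow's
annotator ships with: 5 kb up/downstream windows, 2 bp splice-site
windows.  The high-impact tier is the protein-disrupting list (frame
shift, stop gained/lost, start lost, splice site, exon deleted, deletion
of > 1 % of a chromosome).  The "rare amino acid" category is omitted —
it needs an external amino-acid frequency resource.  One variant yields
one effect per nearby transcript, so effects can outnumber variants;
summaries count effects.

## Assisted assembly

- **Insert model**: "the tightest or 99th percentile" is resolved as the
  central 99 % interval of the dominant mode of the insert histogram,
  with the mode found as the contiguous non-zero region around the peak
  of a 10 bp moving-average smoothing.  This is deterministic and
  consistent with both readings.  Fewer than 100 usable pairs is an
  error, not a guess.
- **Bridging**: a pair supports a bridge when one mate lies wholly in
  the left flank and the other wholly in the right flank, each with an
  exact match run of ≥ 30 bases, and the implied span across the gap
  (counting the N-run) falls inside the library's selected insert range.
  That acceptance window is symmetric around the expected insert, which
  keeps the median gap estimate unbiased — a one-sided cut was observed
  to bias it upward during development.  Default minimum support is 3
  pairs; scaffold joins require 5 links.  These small integers are
  package choices (the workflow states none) sized to be exercised by
  constructed fixtures.
- **Gap filling**: a 30-mer graph is built per gap from filtered reads
  mapped within 1 kb of the gap plus unmapped reads whose mapped mate
  sits within its library's insert range of the gap (those carry the gap
  interior, since reads from the missing sequence cannot map to an
  N-run).  The walk from the left flank's terminal 30-mer demands a
  unique successor at every step; a fork is an explicit
  `unfilled_ambiguous`, never a heuristic choice, so a reported fill
  with error-free reads is exact or absent.  Extension is capped at
  min(max_gap, iterations × 500) bases with defaults 5,000 and 10 —
  the bounded-resources rule of the original procedure made concrete.
- **Merge**: a de novo contig is dropped when clusters at ≥ 95 %
  identity cover ≥ 50 % of its length, otherwise appended unplaced.

## Placement and rearrangements

`anchor_map` chains exact unique-20-mer seeds into colinear clusters with
the stated thresholds (min cluster match 400 bp, max gap 500 bp).  It is
a MUM-style stand-in for the production chromosome-placement aligner:
only the clustering thresholds are specified by the workflow, so only
those are treated as fixed.  Identity is measured over chained segments
and equal-length inter-segment gaps; indel-containing gaps are excluded.

Placement assigns each scaffold to the chromosome with the most matched
bp; a runner-up within 10 % of the winner makes the scaffold unplaced
rather than guessed (explicit, testable tie handling).  Orientation is
the majority strand by matched bp; order is the match-weighted median
target coordinate; AGP joins use 100 bp N gaps (a required AGP value the
workflow does not state).

The 20 kb rearrangement rule is read conservatively: a contig must carry
≥ 20 kb of aligned sequence on **each** of two chromosomes (the
alternative reading — 20 kb total split across two chromosomes — admits
far more false positives; the ambiguity is inherent to the one-sentence
rule).  A contig aligning ≥ 20 kb to three chromosomes reports one event
per secondary chromosome, since it spans the junctions of two distinct
translocations.

## TE statistics

Hits shorter than 80 bp or below 80 % identity are discarded (boundaries
inclusive).  Coverage is the per-position union within each class and
across all classes for the total row, so overlaps never double-count.
The Kimura two-parameter distance uses the standard assignment — p for
transitions (purine↔purine, pyrimidine↔pyrimidine), q for transversions
— with domain violations (2p + q ≥ 1 or 2q ≥ 1) flagged as undefined
records rather than silently clamped.  Landscape bins are integer-width
on K × 100 over [0, 50], matching the conventional 0–50 age axis, with
an explicit overflow tally.  Spider rows compare log10 percent coverage
of genome and transcriptome; a two-fold ratio separates over/under
representation from proportional, and a zero on either side is flagged
absent because its log is undefined.

## Benchmark problem sizes

The end-to-end benchmarks (`congener.benchmarks`, also driven by
`scripts/acceptance.py`) use 2 Mb genomes over 4 chromosomes: gap
filling with 100 planted 20–500 bp gaps under the full tiered library
set; variant recovery at 30× with snp_rate 0.01 and indel_rate 0.001;
five 25–30 kb translocations plus a translocation-free control;
placement of ~50 kb shredded scaffolds; Kimura recovery at 1/5/10/20 %
planted divergence on 1 kb copies, scored against the Jukes–Cantor
corrected divergence.  Rearrangement contigs are cut so every planted
junction lies ≥ 25 kb inside a contig: the rule can only fire on
breakpoint-spanning contigs, and contig length as a detection confounder
is a property of the input assembly, not of the rule.

## Known limitations

- The mapper has no mapping-quality model and drops ambiguous reads
  silently; on repeat-rich real genomes it would need multi-mapping
  handling it does not have.
- The gap filler's unique-successor rule trades recall for exactness:
  repetitive gap content longer than the k-mer size stops the walk.
- Effect classification assumes clean transcript models (sorted,
  disjoint exons; CDS within exons) and classifies InDels by region and
  frame only — it does not recompute the mutant protein.
- `reorder_scaffolds` joins only mutually-best, conflict-free ends and
  reports everything else unchanged; it is a structural-difference
  detector, not a general scaffolder.
- TE coverage attribution inside the total row resolves overlapping
  hits by position union; per-family rows are independent unions, so
  family rows can sum to more than the total — as in the conventional
  masking reports this mirrors.
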