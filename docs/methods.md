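# Methods

## Problem setting

Single-cell IGHV sequencing of rare B-cell populations yields, per
sample, a few dozen FR1-to-J amplicons of rearranged heavy-chain V
regions. Two properties of each sample are of interest: the fraction of
cells carrying somatically mutated V genes (germinal-center experience)
and the presence of clonal expansions, including intraclonal sequence
diversity within expanded clones. `ighclone` implements this analysis as
a deterministic pipeline over an IMGT-style germline reference, and pairs
it with a generative model of the same data for validation.

## Germline reference and anchors

V, D and J genes are loaded from FASTA (IMGT pipe-delimited or plain
headers; IMGT-gapped or ungapped sequences). Two anchor positions drive
junction extraction:

* **V (2nd-CYS)** — for IMGT-gapped V sequences the conserved second
  cysteine occupies codon 104 of the unique numbering, so the anchor is
  the count of non-gap characters before gapped column 309. For ungapped
  references the anchor can be supplied via a sidecar TSV; genes without
  a resolvable anchor are listed in the set's load report and yield
  "junction unresolved" downstream rather than wrong junctions.
* **J (J-TRP/J-PHE)** — located by scanning for the conserved W/F-G-x-G
  motif (TGG/TTT/TTC followed by two glycine codons at the expected
  spacing).

Assignments are reported at allele level, but clone grouping and V-usage
counts collapse alleles to the gene (`IGHV3-30*01 → IGHV3-30`): SHM can
move a sequence between alleles of one gene, and repertoire summaries are
conventionally reported per gene.

## Alignment scheme

One fixed scoring scheme is used everywhere: match +1, mismatch −1, gap
open −4, gap extend −1, where a gap of length L costs 4 + (L − 1). 'N'
is penalised like a mismatch against every base, including another 'N',
so ambiguous bases can never create evidence. Alignment is delegated to
Biopython's `PairwiseAligner` (local mode for segment assignment, global
mode for CDR3 identity); an independent pure-Python dynamic program in
the test suite cross-checks scores. Acceptance thresholds — V score
≥ 40, J score ≥ 15 — behave BLAST-like on 100–400-nt amplicons: random
120-nt sequences stay well below the V threshold while genuine V genes
with up to ~10% SHM clear it comfortably. Equal-scoring genes are
ordered by (higher identity, longer span, lexicographically smaller
name), making annotation fully deterministic. Only the plus strand is
annotated; a pre-step reverse-complements a record when its best V score
on the reverse complement exceeds the forward one.

## Junction, CDR3 and productivity

The junction runs from the first base of the mapped 2nd-CYS codon to the
last base of the mapped J-TRP codon; the CDR3 strips both anchor codons.
When an anchor cannot be mapped through its alignment (trimmed or heavily
mutated anchor region) or the junction is shorter than 9 nt, the record
is kept but marked junction-unresolved. A rearrangement is *productive*
iff its junction is resolved, in frame (length divisible by 3), stop-free,
and the V reading frame (anchored at the 2nd-CYS codon) is stop-free
across the aligned query through the junction end; *nonproductive* iff
the junction is resolved but out of frame or interrupted; *unresolved*
otherwise. Codons containing 'N' translate to 'X', never to a stop.

## D assignment

A D gene is assigned only if at least `d_min_run` (default 7) consecutive
CDR3 bases exactly match the germline D, in forward orientation and
without any reading-frame requirement. The longest exact common
substring is found by dynamic programming; ties go to the longest run,
then the smallest gene name. Absence of a D call is a legitimate value,
not an error — short D remnants after trimming are common.

## Mutation profile

Differences to the assigned germline V are counted over the aligned
V-gene span only: germline positions upstream of the 2nd-CYS anchor.
Substitutions count one each; indels count one per inserted or deleted
base (the rule counts "nucleotide differences", and per-base counting
keeps the frequency well defined). Positions where either base is 'N'
are excluded from numerator and denominator. The frequency denominator
is the number of germline positions covered (~290 nt for a full FR1
amplicon against the bundled synthetic reference); an optional
`leading_trim` excludes a primer-covered FR1 stretch (default 0). Spans
under 50 nt refuse a mutation call. A cell is **unmutated** iff it has
at most `unmutated_max_diff` (default 1) differences — one difference in
a ~200-nt read is ~0.5% and indistinguishable from a first-round
polymerase error. Summaries report the percentage of mutated cells and
the arithmetic mean frequency of the mutated cells only, rounded to one
decimal.

## Clone calling

Cells are co-clonal when they use the same V gene (allele-stripped),
their CDR3 lengths differ by at most `cdr3_max_len_diff_pct` (default
5%, inclusive, relative to the longer sequence), and their CDR3
nucleotide identity under global end-to-end alignment exceeds
`cdr3_min_identity_pct` (default 90%, strict). "Identity among all"
members is interpreted as **complete linkage**: every pair inside an
emitted clone satisfies both thresholds, which prevents chaining of
gradually diverging CDR3s. Agglomeration merges the pair of clusters
with the highest mean cross-identity first (ties resolved by input
order), so the partition is reproducible and, when the complete-linkage
solution is unique, independent of input order. Records without a
resolved CDR3 become singletons flagged `unclustered`. By default only
productive records enter clone calling (`productive_only=False` admits
all annotated records). A clone is *mutated* if any member is mutated —
a shared mutated ancestry dominates the dichotomy — and shows
*intraclonal diversity* when its members carry more than one distinct
(V-mutation-position-set, CDR3) variant.

## The synthetic repertoire model

`simulate_sample` emulates the statistical structure of a single-cell
IGHV study of a lymph-node B-cell population:

* **Study conditions (defaults).** 30 cells per sample (studies of this
  design report 20–36 informative cells), a mutated-cell fraction of
  0.65 (observed range ~0.46–0.86), per-base SHM rate 0.06 on the V
  segment (observed mean frequencies ~3–9%), and a clone plan of three
  mutated clones (2+2+3 cells, one extra branch mutation per member on
  average) plus one unmutated 2-cell clone, the remainder singletons.
* **Rearrangement.** Uniform V/D/J draw; independent uniform trims in
  [0, 5] nt at the 3′V, 5′D, 3′D and 5′J ends; N-insertions of uniform
  length in [0, 7] with uniform base composition. With
  `productive_only` the junction arithmetic is redrawn (≤ 100 attempts)
  until in frame and stop-free.
* **SHM.** Independent per-base Bernoulli substitutions over the V
  segment upstream of the 2nd-CYS codon, the new base uniform over the
  three alternatives. Restricting SHM to the pre-junction V span keeps
  clone members sharing their junction exactly and keeps every implanted
  mutation inside the span the profiler measures; real hypermutation
  also hits CDR3 and flanks, which this model deliberately omits. No
  hotspot bias, no indels, no sequencing-error model (the 1-difference
  unmutated tolerance conceptually absorbs Sanger/PCR error).
* **Clonal lineages.** One founder rearrangement per planned clone
  (plus founder SHM if mutated); each member inherits the founder and
  receives Poisson-distributed extra substitutions — a star phylogeny,
  sufficient to create intraclonal diversity patterns, not a birth–death
  lineage.
* **Junction separation.** Founder junctions (clones and singletons) are
  resampled until pairwise CDR3 identity to every previously accepted
  junction is ≤ 80%. Independent real junctions are essentially always
  that distinct; enforcing it makes the truth partition unambiguous.
* **Truth.** Implanted mutations and productivity are re-derived from
  the final emitted sequence, so the truth table is consistent by
  construction; truth summaries use the same formulas as the analysis
  stage. Cell identifiers are assigned after shuffling and encode
  nothing.

The synthetic germline reference (`synthetic_germline_set`) carries real
human gene *names* but synthetic sequences: IMGT-gapped V genes with the
2nd-CYS at gapped codon 104 and whole-codon gaps, J genes built around
the W-G-x-G motif, D genes mutually distinct (pairwise longest common
run ≤ 6, so the 7-base D rule separates them). D genes are generated
stop-free in all three frames and J prefixes stop-free in the anchor
frame, so productive junctions exist for every gene triple; real D genes
do contain stops in some frames, a simplification that does not affect
the rules under test. Random V sequences are mutually ~25% identical —
far more separable than real V-family members, so simulator-based
recovery rates are an upper bound on real-data performance; the
two-allele pair (`IGHV3-30*01/*02`, two substitutions apart) exercises
allele collapsing.

## What passing tests show — and what they do not

Exact recovery (ARI 1.0, 100% V-gene recovery) on simulated samples
shows the pipeline implements its own rules correctly under the
generative model, where between-clone junctions are well separated and
SHM is uniform. Real data add allele ambiguity within V families,
hotspot-clustered and indel-containing SHM, primer artefacts and
sequencing error; gene-level V calls and clone partitions are robust to
moderate versions of these, but mutation frequencies near the unmutated
boundary and D calls on short CDR3s are not. The published quantities
this package is designed around derive from deposited sequences plus an
IMGT reference and can be recomputed by running `ighclone run` on that
FASTA; no such data ships with the package.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open internally; 1-based only in rendered
  reports.
* Percentages in summaries are rounded to one decimal (Python banker's
  rounding), matching the conventional presentation.
* CDR3 identity orders the pair canonically before aligning, making the
  measure exactly symmetric under co-optimal alignments.
* A mutation at the extreme 5′ end of the V span can be trimmed by the
  local alignment (a leading mismatch never improves a local score), so
  measured counts can undercount truth by the edge mutations; with a
  ~290-nt span this moves sample means by at most one rounding step.
* Empty germline files, duplicate gene names, non-DNA characters, empty
  input FASTA and empty samples are hard errors; missing J, unresolved
  junctions and absent D calls are soft per-record outcomes.
* The grouped-merge loop in clone calling is worst-case quartic in the
  per-V-gene group size; groups in this design (tens of cells) keep it
  trivially fast.

## Problem sizes used in validation

The test suite and acceptance script validate at the study's own scale:
8 samples of 20–36 cells for end-to-end runs, 20 × 100 cells for SHM-rate
recovery, a 500-cell sample for the complete-linkage stress check, and
200 random CDR3s for the D-assignment oracle comparison.
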