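# Methods

This note records the scientific model behind each stage, the parameters
that matter, the numerical choices made where the method is genuinely open,
and what the synthetic-data tests do and do not demonstrate.

## Population model and simulator

Lines are biparental selfing-series RILs: an F1 (fully heterozygous) is
selfed `selfing_generations` = k times (default 4, i.e. F5-derived lines).
Each meiosis draws crossovers as a Poisson process on the true genetic
scale with **no interference**: between adjacent markers separated by
d Morgans, the crossover count is Poisson(d), independent across intervals,
and the gamete's phase at each marker is the running parity of those
counts. This is deliberate: in a no-interference world the recombinant-line
fraction between two loci at selfing fixation has the exact closed form
R = 2r/(1+2r) (Haldane & Waddington), and residual heterozygosity per locus
is exactly (1/2)^k, so the simulator can be tested against closed forms
rather than against itself. Kosambi is still used downstream to convert
estimated r to cM, as is conventional for these maps; where tests compare
recombination fractions the mapping-function choice cancels. A visible
consequence: estimated map lengths are shorter than the generator's nominal
cM (Kosambi compresses Haldane-world r), which is why the worked example
reports ~284 cM for a nominally ~330 cM genome. No test asserts absolute cM
lengths for this reason.

Call perturbations are applied after genotyping: with probability
`error_rate` a call is resampled uniformly among the other two genotype
symbols; with probability `missing_rate` it is masked. Segregation
distortion, when requested, is modelled as line-level viability selection:
a line's weight is the product over distortion-loaded markers of w for a
B/B genotype and sqrt(w) for H, and lines are rejection-sampled against
that weight. The mechanism is not meant to be biological — QC only needs
realistically distorted ratios to exist.

The default model genome is a desk-scale mimic of a 20-chromosome ~1 Gb
genome: 5 chromosomes of 40–60 Mb and 100–130 cM, 500 evenly spaced markers
each, and one low-recombination middle block per chromosome with slope
ratio 1:10 against the flanks — the pericentric-heterochromatin pattern
that drives the Marey-map stage. `random_genome` draws the same structure
with randomized lengths, block placement and marker positions for
recovery-statistics tests.

What the generator does **not** emulate: genotyping-intensity artifacts and
cluster-calling errors (errors here are symbol resampling, not allele-
signal confusions), interference (see above), segmental duplication or
paralogy (every marker is single-copy by construction), and population
structure beyond a single biparental cross. Passing the planted-error tests
therefore shows the pipeline's logic is correct under clean single-copy
genetics; it does not bound performance against paralogous markers, which
in real data are the main source of spurious "translocations".

## QC filters

Markers are filtered before lines. A marker is removed when its missing
fraction strictly exceeds `max_missing` (default 0.10 — exactly 10 %
survives) or when a chi-square test of its A:B homozygote counts against
1:1 (1 df, no continuity correction) gives p < `alpha` (default 0.01).
Heterozygous calls are excluded from the distortion counts: including them
would require committing to a generation-specific H expectation, and with
~6 % H at F5 the homozygote-only test loses almost nothing. Markers with no
homozygous calls at all are removed as uninformative. Lines are then
filtered on their missing fraction over the retained markers, same strict
threshold.

## Binning

Markers with byte-identical call vectors (missing is a distinct symbol, so
the partition is order-independent) collapse to the first member in input
order; representatives carry the linkage analysis and members re-expand at
the representative's cM, ordered by marker id for determinism. No
tolerance-based binning: near-identical patterns stay separate.

## Two-point estimation, grouping, ordering

R̂ is clamped to [0, 0.5]; the selfing-fixation inversion r = R/(2(1−R)) is
used even though the populations are F5-derived — the finite-generation
bias is far below sampling noise at several hundred lines, and the
convention is recorded in map metadata. The two-point LOD is the binomial
likelihood ratio against R = 1/2 with 0·log 0 = 0; it is floored at 0.
Pairwise tables are computed as BLAS products over A/B indicator matrices
and are tested to be identical to the per-pair definition.

Groups are connected components at LOD ≥ `lod_threshold` (default 11).
Ordering minimizes the sum of adjacent r̂: the minimum-spanning-tree of the
r̂-weighted complete graph (a small epsilon keeps r̂ = 0 edges present)
supplies its weighted-diameter path as backbone, off-path markers insert at
the position of least added length, and a windowed 2-opt (window 8,
config-exposed; chosen as the largest window that keeps desk-scale groups
sub-second) reverses improving segments to convergence. For ≤ 8 markers
this provably reaches the exhaustive optimum in the test suite. Group
orientation: positive rank correlation with physical position when a
placement is supplied, else the lexicographically smaller end marker leads.
cM positions accumulate kosambi(r̂) over adjacent pairs, anchored at 0;
r ≥ 0.5 − 1e−6 is clamped before the log.

## Concordance detection

Each linkage group is assigned to the chromosome holding the majority of
its placed markers (ties unresolved; two groups claiming one chromosome is
reported as a conflict, larger group wins). Per chromosome, in physical
order:

1. **Foreign runs.** Maximal runs of markers whose group differs from the
   assigned group become MOVE entries toward the foreign group's
   chromosome; a run whose internal genetic order is strictly decreasing is
   MOVE_AND_REORIENT. Single-marker moves are allowed; single-marker
   reorientations are impossible by definition (a point has no
   orientation).
2. **Monotone segmentation.** Same-group markers are split into maximal
   monotone runs by a greedy sweep. Greedy alone systematically leaves the
   apex marker of an inverted block in the preceding ascending run; a
   peak-reassignment pass moves the apex into the descending run whenever
   reversing the extended run restores local sorted order. Without this
   fix, every planted inversion would be recovered with one boundary off by
   one marker; with it, boundaries are exact. A symmetric rule splits a
   single spike or dip at an ascending–ascending junction into its own
   unit, which the singleton guard then reports separately instead of as a
   correction.
3. **Classification.** Strictly decreasing runs of ≥ `min_run` (default 2)
   markers are REORIENT. Ascending runs off the maximum-weight chain of
   runs with non-decreasing cM intervals (weight = run length) are
   REPOSITION_WITHIN when ≥ `min_run`, singletons otherwise. A chromosome
   whose overall bp–cM rank correlation is negative is flagged as a
   chromosome-orientation issue and analyzed in the map's own orientation,
   rather than emitted as wall-to-wall segment noise. More than
   `complex_threshold` (default 5) entries on one chromosome collapse to a
   single COMPLEX entry spanning them.

`min_run` and the COMPLEX threshold are declared package defaults: the
source material for this kind of curation does not define a quantitative
minimum for a "region", so these are design choices, config-exposed.

**Destinations.** Detected MOVE entries carry a destination interpolated
from the target chromosome's own markers: the moved block lands centered in
the bp gap between the target markers flanking its cM interval. This makes
apply-then-detect idempotent (the re-homed block interleaves correctly)
instead of parking moved sequence at the chromosome end. Generator-planted
entries carry the exact original start instead, which is what makes the
truth-ledger round trip exact; entries without any destination fall back to
append-at-end. Applying rejects overlapping entries before any mutation;
REORIENT reflects positions within the span (an involution). The emitted
AGP splits source chromosomes at every correction span, with reoriented
pieces on the minus strand and uncovered stretches written as U gaps.

Support merging: entries from two populations with the same action and
overlapping spans merge to one BOTH entry over the span intersection;
everything else keeps single-population support. Overlap constraints are
enforced within a support class — the two populations may legitimately
disagree.

## Scaffold anchoring

A scaffold anchors to the chromosome assigned to its markers' linkage group
(markers on different groups → conflict, not anchored; no mapped marker →
skipped with reason). Genetic position is the per-population **median** cM
of its markers — robust to a stray marker — and positions are kept per
population without cross-population averaging, since the two maps have
different scales. Orientation is the sign of the (offset, cM) rank
correlation and requires at least two markers with distinct offsets and
distinct cM. Summary length counts each scaffold once regardless of marker
count. Physical insertion coordinates, when needed, come from linear
interpolation of the local Marey segment; published curation pipelines
defer this to the assembly process, so the interpolation is an explicit
stand-in.

## Heterochromatin delimitation

The Marey map of a chromosome is built from markers shared between map and
placement: the map is flipped if its rank correlation with bp is negative,
the largest monotone subset is kept (dropped count reported; dropping
should be rare — ≲ 2 % — on a corrected assembly, and localizes to residual
inversions otherwise), and duplicate bp are collapsed. Note Marey maps are
defined only up to the additive cM origin.

"Two inflection points" is operationalized as the breakpoints of a
continuous piecewise-linear least-squares fit. Candidate models with 1, 2
and 3 segments are compared by BIC; breakpoints are searched over marker
positions coarse-to-fine (≤ 40 coarse candidates, then every marker
position within one coarse step of the optimum — identical to the full
grid at the tested densities and ~100× faster), with every segment at
least `min_segment` = 2 Mb (suppresses spurious micro-segments). In the
chosen model, segments with slope ≤ `slope_ratio_max` = 0.25 × the steepest
slope are "low"; the physically longest contiguous low block is the
heterochromatic interval — this handles both the interior block (3-segment)
and a block abutting a chromosome end (2-segment, or a degenerate 3-segment
fit whose first two segments are both low). Exactly one het interval per
chromosome is reported, bounds rounded to 0.1 Mb; if no segment is low the
chromosome is all-euchromatic. Genome totals can be computed against
declared per-chromosome lengths or against a single published genome
total, in which case euchromatin is the complement of the het sum.

## Marker liftover

`insilico_pcr` places primer pairs by exact string match on both strands
(any mismatch kills a product — IUPAC/N genome bases included), returns all
products up to `max_amplicon` = 10 kb with 1-based coordinates spanning the
primer outer ends, and requires primers ≥ 15 bp. `match_source` is
seed-and-extend: exact seeds (length 50, step 10, plus the final window)
taken from the N-free runs of the source, extended ungapped, kept at
identity ≥ 0.99 over coverage ≥ 0.95 of the source length, overlapping hits
merged to the best. Identity and coverage are deliberately separate,
reported thresholds. Seeds occurring > 1000 times are discarded — a
deterministic stand-in for low-complexity filtering. An SSR is UNAMBIGUOUS
only when exactly one region passes all four criteria (product exists,
source hit overlaps it, product length equals the expectation within
`length_tolerance` = 0 bp, and ≥ 5 tandem motif copies — the conventional
minimum for calling an SSR locus — lie between the primer inner ends, on
either strand); SNP flanks are concatenated with one wildcard position
whose genomic coordinate is the placement. Around a SNP wildcard the
N-free flank itself serves as the seed when it is shorter than 50 bp
(descriptors require ≥ 50 bp combined flanks, so a seedable segment always
exists).

## Problem sizes in the test suite

Parameter-recovery tests run at 1000 lines × 200 markers (adjacent R̂
within 3 binomial SE of the closed form, simulated at 25 selfing
generations so the fixation formula is the exact oracle); planted-error
recovery at the default 5-chromosome, 2500-marker genome with 8 inversions,
4 translocations and 10 detached scaffolds, detected against the noise-free
truth map so that boundary exactness is a property of the detector rather
than of map-estimation noise (the worked example in the README shows the
same recovery through estimated maps); breakpoint accuracy over 50 random
genomes at 500 markers/chromosome; liftover over 200 planted SSRs and 200
planted SNPs with every tenth duplicated. These sizes were chosen as the
smallest at which the statistical assertions have sharp expectations.

## Known limitations

- The F∞ inversion slightly underestimates r for F5 data; at n ≥ ~500
  lines this is invisible next to binomial noise, but at small n both the
  bias and the LOD calibration degrade together.
- Ordering is two-point only; no multipoint likelihood, no error-aware
  ordering. Dense co-segregating blocks (low-recombination regions at
  modest n) order arbitrarily within ties, which is why boundary-exact
  recovery inside heterochromatin needs large populations.
- One heterochromatic interval per chromosome by design; chromosomes with
  fragmented low-recombination structure are summarized by their longest
  block.
- Liftover performs no gapped alignment; an indel between primers shifts
  the amplicon length and the marker is reported UNPLACED with the length
  criterion failed, which is the intended conservative behavior.
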