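# Methods

`treescan` implements a windowed phylogenomic scan of a multi-species
whole-genome alignment: per-window distance trees, relationship
classification of a focal taxon, segmentation into topology blocks, and
strict-clock divergence dating — together with a coalescent simulator that
generates alignments with known ground truth so every stage can be
verified end to end.

## The scan

The alignment (MAF, anchored on one reference taxon's coordinates) is cut
into non-overlapping windows of fixed size (default 50 kb) on reference
coordinates.  Every alignment column is assigned to the window containing
its reference position; columns where the reference carries a gap
(insertions in other taxa) travel with the most recent preceding reference
base, and leading gap columns with the block's first base.  The format
does not dictate this convention for discontiguous blocks; concatenation
in coordinate order is this package's documented choice.

A column is *informative* when every taxon has a determined character
(A/C/G/T — not a gap, not N).  Windows with fewer informative columns than
`min_informative_fraction × window_size` (default 10%, i.e. 5,000 of
50,000) are excluded; the exclusion is strict at the boundary (4,999 is
out, 5,000 is in) and terminal short windows face the same absolute
threshold.  The per-column, all-taxa reading of "informative" follows from
the 10%-of-window gloss: parsimony-informativeness would not scale with
window size that way.

## Per-window trees

Distances are Jukes–Cantor-corrected per-site differences,
d = −(3/4)·ln(1 − 4p/3), computed over the columns determined in both taxa
of a pair.  Pairs with p ≥ 0.75 are flagged saturated and pairs with no
shared determined column are flagged missing; either flag causes the
window to be skipped rather than guessed at.  Taxa determined in fewer
than half of a window's columns are dropped from that window before pairs
are formed, and windows missing the focal, expected-sister or outgroup
taxon are excluded from classification with a logged reason.

Trees are built by neighbor joining and rooted on the outgroup's terminal
branch (midpoint of that branch).  Two determinism rules make output
independent of input order: ties on the Q criterion (within 1e-9 relative
tolerance) are broken toward the lexicographically smallest pair of
cluster-representative labels, and negative branch-length estimates are
clamped to zero with the deficit moved to the sibling branch so the joined
pair's path length is preserved.  NJ replaces a full ML engine
deliberately: it is exactly reproducible, has no optimizer state, and the
quantities consumed downstream — topology frequencies and patristic
distances — agree with the exhaustive least-squares topology on additive
input (tested over random additive matrices, and enumerable exactly for
n ≤ 6, where all 15–105 unrooted topologies are fitted by ordinary least
squares).

Bootstrap supports resample alignment columns with replacement; a branch's
support is the percentage of replicate trees containing the same unrooted
bipartition.  Replicates in which some pair loses all shared determined
columns (or saturates) are counted as not containing any bipartition
rather than being redrawn, which keeps the replicate count fixed and the
procedure seeded and reproducible.

## Classification, blocks, breakpoints

Each window tree is reduced to the focal taxon's relationship pattern on
the outgroup-rooted tree with the outgroup then removed.  If
{focal, expected sister} is exactly a clade, the call is "after
speciation" and reports that clade's sister group; otherwise the call is
"before speciation" and reports the focal taxon's own sister group.
Sister groups are mapped to configured clade names (e.g. "GC", "A(GC)")
when the leaf sets match exactly, otherwise to the sorted taxon list.
Multifurcating sister groups are reported as the union and flagged
ambiguous — the smallest enclosing labelled category, with the ambiguity
visible, rather than a silent bin.

Maximal runs of equal calls form topology blocks.  Runs shorter than
`min_run` are absorbed into the larger flanking run (ties go left);
`min_run` defaults to 1 because the raw per-window pattern is itself the
result of interest, and smoothing is opt-in.  The breakpoint between two
adjacent blocks is reported as the interval from the end of the last
window of the left block to the start of the first window of the right
block — an empty interval when retained windows are contiguous, a real
gap when filtered windows intervene.  Regional contrasts (e.g.
centromere-proximal vs distal) assign each window by its midpoint, so a
window straddling a region edge belongs to exactly one region, and an
optional seeded subsample of windows per region is summarised by alignment
statistics (length, length without all-undetermined columns, gap
proportion, distinct column patterns).

## Dating

For a taxon pair, one patristic distance (path length on the window tree,
substitutions/site) is collected per qualifying window.  The point
estimate is the median over windows, with a percentile bootstrap
(2.5th/97.5th percentiles of the resampled median, default 1,000
resamples); means and window-wise SDs are reported alongside, clearly
labelled, because a spread printed as "±x" can be either and the two are
not interchangeable.  Ages follow the strict clock

    T(Ma) = d / (2 · mu · g · 1e6)

with mu = 1.1e-9 substitutions/site/generation and g = 10
generations/year by default (both are config values).  The CI endpoints
transform through the same linear map.  With these defaults the medians
0.0117 and 0.0067 convert to 0.53 Ma and 0.30 Ma.  Two pairs are called
"distinct" when their median CIs are disjoint; the median difference also
gets its own bootstrap CI when the distance vectors are supplied.

For regional dating (inside vs outside an inversion), a flanking margin
(default 500 kb) is excluded around the region edges: a window counts as
inside only when fully within the region shrunk by the flank, outside
only when fully clear of the region grown by the flank, and
flank-straddling windows are dropped from both sides.

Two caveats are inherent to this estimator and documented rather than
corrected: the coalescent excess above the species split biases ages
upward by roughly Ne generations (≈ 0.0005 Ma at the scenario default of
Ne = 5,000 haploids), and dating from a single rate ignores rate
variation across branches.

## The simulator

The generator draws one genealogy per window under the multispecies
coalescent on a dated, ultrametric species tree (ages in generations,
per-branch haploid Ne; within a branch, k lineages coalesce at rate
k(k−1)/2/Ne).  The default history mirrors an 8-ingroup + 1-outgroup
species complex: focal pair split 0.53 Ma ago, most recently diverged
reference pair 0.31 Ma, ingroup radiation 2.0 Ma, outgroup 8 Ma, at 10
generations/year.  No Ne estimates exist for the system, so every branch
defaults to 50,000 haploids — small enough that deep-branch discordance is
negligible, which is the regime the scan assumes; the MSC machinery is
calibrated separately against the closed form P(discordant topology) =
(2/3)·exp(−t/Ne) and against msprime.

Two signals can be configured:

* **Introgression pulses** are block-wise lineage replacements: inside the
  stated interval, with the stated per-window probability, the recipient
  leaf is detached and re-attached as sister of the donor at the pulse
  time, and the MSC then runs on the modified tree.  This matches the
  signal a window scan detects (whole-window donor ancestry), not
  continuous migration.
* **Inversion regions** draw their genealogy from an override species
  tree.  The shipped override places the three inversion carriers (focal,
  sister, melas) in a clade that diverged from the non-carriers 2.53 Ma
  ago — before the radiation — so inside-region focal–quadriannulatus
  ages exceed outside-region ages, the directional contrast the dating
  stage must recover.

Mutation is Jukes–Cantor with a single rate (a site changes along a
branch of t generations with probability (3/4)(1 − e^(−4·mu·t/3))); the
dating model consumes exactly this quantity, so richer substitution
models would add parameters without adding testable behaviour.  Missing
data is injected i.i.d. per column per taxon as undetermined (`N`)
characters — `N` rather than `-` so reference coordinates in the emitted
MAF stay exact — at a default 2% per taxon.  One genealogy per window
means no intra-window recombination; windows are the unit of inference
throughout, so finer recombination would only blur the ground-truth
labels.

What the simulator does *not* emulate: alignment error, indels,
recombination maps, selection, demographic change, sequencing error.
Passing tests therefore show that the inference chain is correct on
clean, model-generated data at the configured divergences — not that it
is robust to real-alignment artefacts.

Determinism: the full output is a pure function of the config including
its seed.  Per-chromosome RNG streams are split from the top seed in
sorted chromosome name order, so dict order never changes results and
windows within a chromosome consume one sequential stream.

## Scaffold grafting

The assembly-grafting stage places de novo scaffolds into the alignment
as a new taxon row.  Homology search is in-repo seed-and-extend: exact
11-mer seeds, linear chaining by diagonal (new chain at a diagonal jump
> 30 or query gap > 250), lone seeds discarded (two-hit seeding), and the
best-seeded chains refined by an edit-distance alignment (edlib) whose
path is trimmed to the maximal-scoring local segment under match +1 /
mismatch −2 / gap −2.  E-values are Karlin–Altschul with database-size
correction (lambda = 1.28, K = 0.46, the ungapped +1/−2 nucleotide
values).  Only the top-seeded chains are aligned (at most 20 per strand,
and none with fewer than 10% of the best chain's seeds): genuine homologs
and genuine duplicate loci carry orders of magnitude more seeds than
random 11-mer noise, and the duplicates are exactly what the filter must
see.  An adapter for external tabular hit files can stand in for the
in-repo matcher in fidelity runs; the decision rule is the tested
contract:

1. exactly one raw hit → place it, whatever its quality;
2. multiple hits → drop those with e-value > 1e-4 or query coverage
   ≤ 0.40 (inclusive at 0.40); if exactly one survives, it is recovered;
3. zero or ≥ 2 survivors → leave the region unplaced (all-gap row).

Grafting aligns the placed slice (orientation-normalised) against the
block's reference row and threads it through the existing columns.  The
invariant is that existing rows are never edited: their characters and
relative column order are byte-identical before and after; only gap-only
columns may be inserted where the new sequence has insertions.

## Problem sizes in the verification runs

The verification analyses scale the genome down while keeping the
per-window statistics honest.  The demo run uses two 2 Mb chromosomes at
the production 50 kb window (80 windows, 100 bootstrap replicates).  The
breakpoint-recovery analysis uses 5 kb windows over a 200 kb chromosome —
the classifier sees ~500+ informative columns per window, ample at these
divergences, and the criterion "within one window" is window-size
agnostic.  The dating-recovery analysis keeps 50 kb windows: per-window
distances are counts, so their granularity scales as 1/length, and at
5 kb the median's lattice step would exceed the width of its bootstrap
CI, making percentile intervals degenerate.  The 2% missing data matters
for the same reason: it varies each window's shared-column denominator,
taking distances off a common lattice (real alignments do this through
variable coverage).  Ne is 5,000 haploids in the dating scenario so the
coalescent bias stays well inside the CI.

## Numerical and degenerate-input choices

* JC distances are undefined at p ≥ 0.75; such pairs are flagged, never
  clamped.
* NJ on < 4 taxa returns the trivial star/cherry, flagged `few_taxa`.
* The bootstrap of an empty distance vector is an error; an estimate with
  zero qualifying windows is returned as unavailable, not as NaN
  arithmetic downstream.
* Windows are 0-based half-open everywhere internally; report headers
  state the convention.
* All randomness flows from explicit integer seeds through numpy
  Generators; per-window seeds are derived arithmetically from the run
  seed and the window ordinal.

## Known limitations

* NJ branch lengths (hence patristic distances) inherit distance-matrix
  noise; at very short windows the clamping rule can shift length between
  sibling branches (path lengths through the clamped pair are preserved).
* The introgression model replaces whole windows; partial-window
  replacement would dilute the signal in ways the scan cannot label.
* The grafting aligner is not a full BLAST reimplementation; its
  statistics are calibrated for ranking and filtering, not for
  cross-database comparability.
* Strict-clock dating shares the usual caveats: a single rate, no
  coalescent correction, no calibration uncertainty.
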