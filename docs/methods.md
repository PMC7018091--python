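# Methods

This note documents the statistical definitions, algorithmic conventions,
and design choices implemented in `barcodiv`, in the spirit of the methods
notes that accompany simulation and inference packages. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Missing data and alphabets

Sequences are nucleotide strings over `{A, C, G, T}`, the gap `-`, `N`, and
the IUPAC ambiguity codes. Gaps and ambiguity codes (including `N`) are
treated as *missing data* by every statistic: they never count as a state at
a column and are excluded from comparisons. Ambiguity codes are not expanded
combinatorially. This matches the conventions of the DnaSP/MEGA family of
tools whose outputs the statistics mirror. External coordinates are 1-based
inclusive everywhere (the GenBank convention); half-open slicing is an
internal detail.

## Alignment variability statistics (`sitestats`)

For an alignment of n sequences and L columns:

- A column is **variable** when ≥ 2 distinct unambiguous bases occur among
  its scored characters; **parsimony-informative** when ≥ 2 distinct bases
  each occur in ≥ 2 sequences. Informative ⇒ variable; all-gap and
  single-state columns are invariant.
- **η (minimum mutation count)** = Σ over columns of
  max(distinct bases − 1, 0). η ≥ number of variable sites always.
- An **indel event** is a maximal run of gaps in one sequence, identified by
  its (start, end) column span; identical spans in several sequences count
  once, while nested or overlapping runs with different endpoints count
  separately. Exact event-counting conventions differ between programs and
  are rarely documented; this span-deduplication rule is this package's
  fixed, documented choice, and indel counts from other software should not
  be expected to match cell-for-cell.
- **GC content** = (G+C) / (A+C+G+T) pooled over all sequences.
- **Nucleotide diversity π** is the mean pairwise difference proportion
  under *complete deletion*: columns containing a gap or ambiguous base in
  any sequence are dropped, and
  π = Σ_cols [C(n,2) − Σ_b C(count_b, 2)] / (C(n,2) · L_clean).
  This per-column count formula is algebraically identical to the mean of
  pairwise p-distances on the same column set, and the test suite checks the
  two independent computations against each other on random alignments.
  Complete deletion is the default because it is the common default of the
  diversity software this mirrors; a pairwise-deletion variant is available
  behind a flag for sensitivity analysis.

## Sliding-window scans (`windows`)

Windows start at columns 1, 1+step, … and must fit entirely; a trailing
partial window is dropped (the usual sliding-window convention). Defaults
are 600 bp windows with 200 bp steps, the standard geometry for plastome
hotspot scans. π within a window uses complete deletion restricted to the
window; a window with no clean column records NaN and is excluded from
ranking. Coordinates (midpoints) are alignment columns, not any single
genome's coordinates. `top_regions` ranks windows by π (ties broken toward
the smaller midpoint), merges overlapping selections into single regions
carrying the maximum π among their members, and maps each region to the
annotated features overlapping its span.

## p-distances and the barcoding gap (`distances`)

The p-distance between two sequences is mismatches / compared columns,
where compared columns exclude positions missing in either sequence
(**pairwise deletion**, the default) or in any sequence (complete deletion,
used for the π cross-check). No multiple-hit correction is applied anywhere:
the evaluation is defined on uncorrected distances, which are also what the
tree building consumes. A pair with zero comparable columns is an error
naming the pair.

Distances among ingroup samples are partitioned by the metadata: a pair is
intraspecific iff both samples carry the same species label; the outgroup is
excluded. Summaries are ranges and mean ± SE, where SE is the sample
standard deviation over pairs divided by √(number of pairs). Pairwise
distances are not independent (pairs share sequences), so this SE
understates uncertainty; it is reported in this conventional form because
that is how such tables are usually presented, and the caveat stands.
Histograms use equal-width bins (default width 0.001) on a shared grid from
0 to the largest observed distance. Two gap summaries are reported side by
side: `strict_gap` (min inter > max intra) and the overlap fraction
P(inter ≤ max intra), because the two can disagree in interesting ways on
real data and a single boolean hides that.

## Neighbor joining (`njtree`)

Saitou–Nei agglomeration: with m active nodes and R_i the working-matrix
row sums, join the pair minimizing Q(i,j) = (m−2)·d(i,j) − R_i − R_j;
pendant lengths l_i = d(i,j)/2 + (R_i − R_j)/(2(m−2)), l_j = d(i,j) − l_i;
reduced distances d(u,k) = (d(i,k) + d(j,k) − d(i,j))/2. Conventions fixed
here:

- **Ties** in Q are broken toward the smallest (i, j) index pair in input
  order (new nodes appended after the original order). On generic, tie-free
  matrices the unrooted topology is order-invariant.
- **Negative branch lengths** are clamped to 0 without redistributing the
  deficit to the adjacent edge. This affects lengths only, never the
  topology. NJ variants differ in this handling and published trees rarely
  state their choice; clamping is the simplest defensible option.
- The unrooted result has a trifurcating basal node. On additive matrices
  the output tree reproduces the input distances exactly; the tests verify
  this and check topological agreement with exhaustive least-squares
  topology search up to 6 taxa and with an independent NJ implementation.

**Rooting** places the root on the edge subtending the outgroup (the
pendant edge for a single outgroup leaf; the edge whose split isolates the
set otherwise), splitting that edge at its midpoint. A non-monophyletic
outgroup set falls back to the edge above its MRCA with a warning.

**Bootstrap**: columns are resampled with replacement; each replicate is
rebuilt as a p-distance NJ tree; support of an internal edge is the
percentage of usable replicates containing its (unrooted) bipartition,
annotated on the original tree (not a consensus). Replicates in which some
pair loses all comparable columns are skipped and removed from the
denominator. The default of 1000 replicates is conventional. Supports are
attached after rooting so that node–bipartition associations are stable.

## Species discrimination (`discriminate`)

A species is discriminated iff the leaf-descendant set of the MRCA of its
individuals equals exactly those individuals, evaluated on the rooted tree
(the criterion is root-dependent, hence outgroup rooting first). The rate is
100 · (#monophyletic ingroup species) / (#ingroup species); the outgroup is
excluded. Species with a single individual cannot fail the criterion; they
are counted as discriminated but flagged `trivial`, since the criterion is
only informative with ≥ 2 individuals. Zero-length internal edges are kept
resolved (as tie-broken) rather than collapsed to polytomies; collapsing
could flip verdicts and would make the criterion depend on a collapse
threshold. Named sample-set verdicts (`groups`) support coarser questions,
e.g. whether a barcode at least separates adulterant species from the
genuine medicine when it cannot resolve the genuine species individually.

## The synthetic-data generator (`simulate`)

The generator emulates the sampling structure of a congeneric plastome
barcoding study: by default 8 ingroup species × 4 individuals plus a single
outgroup individual, 20 kb of aligned sequence, intraspecific divergence
0.002 and interspecific divergence 0.02 expected substitutions/site —
inside the ranges typical of congeneric plastid datasets (intraspecific
p-distances roughly 0–0.005, interspecific roughly 0.001–0.03). Components:

- **Species tree**: random bifurcating topology by sequential random joins;
  branch lengths uniform(0.5, 1.5) before rescaling, so no species sits on a
  near-zero stem branch that would make it unidentifiable by construction
  (with exponential draws, occasional near-zero stems would make the ground
  truth unrecoverable by any method). All branches are rescaled so the mean
  tip-to-tip path equals inter_divergence − intra_divergence; individual
  pairs from different species then diverge by ≈ inter_divergence on
  average.
- **Within species**: individuals radiate from the species ancestor on a
  star with pendant branches intra_divergence/2 (within-species pairs
  diverge by intra_divergence). No within-species coalescent: the analysis
  consumes only the p-distance scale, which the star controls exactly.
- **Substitutions**: Jukes–Cantor realized as Poisson(branch length × L)
  events per branch, each event replacing a uniformly chosen site (weighted
  by the optional hotspot multiplier) with one of the three other bases
  uniformly. The expected p-distance after divergence d is the JC curve
  (3/4)(1 − e^{−4d/3}); below d ≈ 0.03 the multiple-hit adjustment is under
  2%, and the parameter-recovery tests compare against the adjusted value.
- **Indels**: per-branch deletion events, Poisson(indel_rate × L) per
  lineage with geometric lengths (mean indel_mean_length, default 3 bp),
  realized as gap characters inherited by descendants. Because only
  deletions are modelled, column homology is the identity and the emitted
  FASTA is a true alignment — no aligner is needed anywhere in the tests.
  Insertions are not modelled; an insertion on one lineage produces the
  same gap pattern as a deletion on the complementary lineages, so nothing
  the pipeline measures distinguishes the two.
- **Polyphyletic species**: its individuals are split between two donor
  lineages, each half grafted midway along a donor's terminal branch as a
  *sister* group to the donor (not inside it), so the donors remain
  monophyletic while the injected species cannot be. This mirrors the
  real-world case of a nominal species harbouring two independent plastid
  lineages, each closer to a different neighbour species.
- **Outgroup**: attached above the ingroup root with a pendant length
  chosen so the outgroup-to-ingroup divergence ≈ outgroup_divergence
  (default 0.03), floored at half that value.
- Everything is reproducible from the single mandatory seed.

What the generator does *not* emulate — incomplete lineage sorting,
recombination, rate heterogeneity across sites, alignment error, sequencing
error — bounds what passing tests show: they validate the statistics, the
tree building, and the verdict logic on data whose truth is known, not the
biological adequacy of any barcode for a particular taxon.

## Validation problem sizes

The test suite and acceptance script run at deliberately desk-scale sizes:
parameter recovery and discrimination use 20 (tests) or 10 (acceptance
script) seeds of 8 species × 4 individuals at 20 kb; the π cross-check runs
1000 random alignments of 3–6 sequences × 20–60 columns; NJ is checked
exhaustively up to 6 taxa and monophyly up to 8 leaves (every subset);
hotspot localization uses a 600 bp high-rate block at 25× the background
rate. These sizes give stable Monte-Carlo behaviour (3-SE criteria for
recovered means; ≥ 95%-of-seeds criteria for verdict recovery) while keeping
the whole suite fast. Applying the pipeline to full plastome alignments
(~150 kb × ~33 samples) is a matter of input size only; no algorithm here
is worse than O(n²·L) (distances) or O(n³) (NJ).

## Known limitations

- The SE attached to mean intra-/inter-specific distances ignores pair
  non-independence (documented above).
- Indel-event counts follow this package's span-deduplication rule and are
  not comparable across tools with undocumented conventions.
- p-distances under pairwise deletion need not satisfy the triangle
  inequality; symmetry and zero diagonal are enforced, metricity is not.
- The NJ tie-break and negative-branch policy are fixed choices among
  several defensible ones; topologies from other NJ implementations can
  differ on tied or highly non-additive inputs.
- Bootstrap supports are computed on the single original topology, not on a
  consensus; degenerate (invariant) alignments yield arbitrary tie-broken
  topologies whose supports are not meaningful.
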