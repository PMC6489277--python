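# Methods

## Peptide representation

A protein is represented as a bag of degenerate peptides.  A window of
length N = 8 slides over the sequence one residue at a time; each clean
window (only the 20 standard residues) is expanded into all C(8,2) = 28
variants with exactly A = 2 positions replaced by the wildcard `X`.  The
8×2 parameters are the defaults throughout; they balance sensitivity of
approximate matching against index size.  Because a variant of window *u*
equals a variant of window *v* exactly when Hamming(u, v) ≤ A, approximate
motif matching reduces to exact string equality — the property every later
stage relies on.

Conventions fixed here, since several are underdetermined by the method
description alone:

- `X` is reserved as the wildcard.  An `X` (or `B`, `Z`, `J`, `U`, `O`,
  `*`, gap) in input data is nonstandard; only the windows containing it
  are skipped, not the protein, preserving maximal signal.
- Coordinates are 0-based half-open `[start, start + N)`.
- Wildcards may sit at any window position including the ends.
- A sequence shorter than N yields an empty pool and a warning, not an
  error.

## Clustering

Dissimilarity between two proteins is
`(1 − shared_positions / (2 · max_positions)) ^ c_clust` with
`shared_positions` the distinct start positions of shared peptides summed
over both proteins and `max_positions` the larger of the two proteins'
distinct conserved-peptide start counts.  `c_clust` (default 9, positive
integer) exponentiates the shared fraction; larger values produce fewer,
tighter groups.

The incremental engine runs five passes.  Each pass:

1. prunes peptides found in a single protein (and, after the first pass,
   peptides not conserved in the previous pass);
2. removes proteins covering < 20 residue positions or < 10% of the
   family-median coverage (both rules applied; the union is removed).
   Coverage counts residue positions under surviving windows, not window
   starts;
3. clusters the dissimilarity matrix with Ward linkage and cuts the
   dendrogram at raw height 1.0 (the dissimilarities are fed to the
   linkage directly; no embedding);
4. discards groups below the pass's minimum size (2, 3, 4, 5; members of
   discarded groups are recorded as outliers and not reconsidered);
5. extracts each group's conserved peptides at the pass's conservation
   floor (10, 20, 30, 40%);
6. merges sister groups by complete-linkage clustering of a group
   dissimilarity matrix, cut at 0.7.

The group dissimilarity is `1 − shared_conservation /
individual_conservation` where `shared_conservation` sums, over peptides
conserved in both groups, the mean of the two conservation fractions, and
`individual_conservation` is the larger of the two groups' conservation
sums.  Of the readings consistent with the verbal definition this is the
only one that keeps the score in [0, 1] with 0 for identical and 1 for
peptide-disjoint groups, which is why it was chosen.

The fifth pass clusters on the 40%-conserved peptides carried from pass
four and keeps groups of ≥ 5 members (≥ 3 under the `--reduced` fallback
for sparse families); no sister-merge is applied in the final pass.  All
ties are broken lexicographically by protein id, group numbering follows
the smallest member id, and reruns on identical input are byte-identical.

## Library

Finalization drops peptides whose within-group conservation is not
strictly above 0.20 and squares the survivors into weights (0.9 → 0.81,
0.2 → 0.04), favoring strongly conserved peptides.  Compilation merges all
families' groups into one inverted index: each peptide's weight is divided
by the number of *distinct families* (not groups) containing it, and
peptides whose non-wildcard residues are all in {G, A, V, L, I, P} are
banned to avoid linker/polyproline bias.  The aliphatic set and the
treatment of wildcards (ignored, the most conservative ban) are package
choices; so is applying the ban per stored variant.  Group theoretical
maxima are recomputed on the adjusted weights so that prediction
thresholds and lookup weights stay on one scale.  The archive is a single
self-describing JSON document (format version, peptide parameters, group
summaries, index); loading is bit-exact and refuses version mismatches or
truncated files.

## Prediction

Matching a query records every library hit per group.  Duplicate
occurrences of one peptide count once in the filtering sum but per
occurrence in the positional accumulation profile — the former guards the
score thresholds, the latter lets tandem repeats of one domain show up as
separate coverage clusters.  The filter cascade: matched-weight sum ≥ 5
and ≥ 1% of the group's theoretical maximum; (full mode) ≥ 20 positions of
the accumulation profile above 0.2; greedy occupancy resolution in
decreasing fraction-of-maximum order, a later group surviving only if
≥ 50% of its accumulation mass is unclaimed; ranges read off the profile
with gaps bridged up to the group's average covered-position count clamped
to [50, 200] residues.  Assignment requires ≥ 5% of the theoretical
maximum for a group/EC call, with the family-only sentinel `FAM.0.1`
below it; subfamily needs ≥ 3 members of one subfamily in the group; the
reported EC lists member functions by decreasing abundance joined by `-`,
the first being the assigned one.  Fast mode keeps only the sum filters
plus a requirement of matched peptides at ≥ 8 distinct query start
positions, and reports `FAM.0.0`.

Two kept calls of the same family whose ranges overlap by ≥ 50% of the
shorter call collapse to the `FAM.0.2` sentinel.  The 50% rule is this
package's quantitative reading of "assigned in the same range"; heavier
cross-family overlap is already removed by occupancy resolution.

## Evaluation

Scoring is per-protein label-set comparison (tp/fp/fn), with sensitivity
tp/(tp+fn), precision tp/(tp+fp), and F their harmonic mean; undefined
ratios are reported as undefined rather than zero.  At the EC level an
absent prediction counts as correct when no carrier of that function was
available for training.  Cross-validation folds treat high-similarity
clusters (70% identity) as atomic: clusters are dealt largest-first into
the current fold until it holds ≥ 1/k of the proteins.  When no external
CD-HIT cluster file is given, single-linkage components of the pairwise
identity graph stand in for the fold atoms; exact CD-HIT parity is not
attempted.

## Synthetic families

The generator emulates one enzyme family as a star phylogeny: each group
has a random ancestor, members are copies with i.i.d. substitutions at the
per-residue rate (substitutions never silent, so expected member-ancestor
identity is exactly 1 − rate).  Ancestors share a *family core* — the
leading 10% of positions by default — and are otherwise i.i.d., redrawn
until every pair is below the between-group identity cap (0.5).  The core
models the family-wide conserved catalytic motifs that make a real family
recognizable even in members that fit no current group; without it, a
fully held-out group would carry no family signal at all and the
new-member prediction scenario would be vacuous.  The default core length
(30 residues at length 300) is in the range of real catalytic-motif
regions and is short relative to group-specific signal, so group recovery
is unaffected (between-group dissimilarity stays near 1 while the core
alone passes the family-level prediction filters).  Poly-G multidomain
linkers are used because all-glycine windows are banned from libraries,
guaranteeing linkers never score.

What the generator does *not* emulate: indels (members stay aligned to
their ancestor), non-star phylogenies, domain shuffling, compositional
bias, and realistic subfamily/EC label noise.  Passing tests therefore
demonstrate the correctness of the machinery and its behavior under
controlled divergence, not performance on real CAZy data, where domain
boundary quality and alignment-free divergence are harsher.

## Problem sizes and defaults

The reference synthetic conditions are: group recovery on 5 groups × 12
members, length 300, 3% mutation (three seeds); self-recovery of the same
family's library; hold-out generalization on 10 groups × 6 members at 5%
mutation with a 10-fold cluster-aware plan (one fold evaluated); and
multidomain fusion of two 2-group families of length 200.  These sizes
exercise every code path — pruning, outlier handling, sister merging, the
filter cascade, range splitting — while keeping a full pipeline run in
tens of seconds on one core.  Families of tens of thousands of
representatives should be pre-divided before clustering; the dense
distance matrix is the memory bottleneck.
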