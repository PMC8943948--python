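# Methods

`iegnet` implements a functional-connectivity analysis of regional
immediate-early-gene (IEG) expression: counts of EGR-1- and ARC-positive
cells in 12 brain regions (PrL, IL, Orb, Ins, ACC, Ssp, aRC, pRC, DG, CA3,
CA1, EC) from rats in four behavioural conditions (OPA — retrieval of old
paired-associates; NPA — encoding of new paired-associates; NM — novel map;
CC — caged controls), seven animals per condition.  "Connectivity" here is
inter-animal covariation: if two regions' IEG counts rise and fall together
across animals of a group, they are treated as functionally coupled during
that behavioural episode.

## Observation model and normalization

The unit of observation is an (animal, IEG) pair.  The two IEGs are stacked
as separate observations rather than averaged, giving n = 14 rows per group
(56 pooled) over 12 region columns.  Two normalizations put the IEGs on a
common scale before stacking:

* `zscore_per_ieg_region` (default): within each (region, IEG) cell, counts
  are transformed to sample mean 0, SD 1 (ddof = 1) across all animals in
  the table.  Per-group Pearson correlations are invariant to whether the
  z-scoring is done across all animals or within group, because the Pearson
  statistic is itself affine-invariant per column; the across-all default
  simply makes pooled and per-group matrices share one scale.
* `cc_ratio`: counts divided by the caged-control mean for that
  (region, IEG), expressing expression relative to home-cage baseline.

Missing cells are hard errors — with 7 animals per group, silently dropping
rows would distort every downstream statistic.

## Correlation matrices and thresholded networks

Region-by-region Pearson correlation matrices are computed per group and
pooled.  Networks keep edges with r strictly above a threshold; the
conventional thresholds 0.80 / 0.87 / 0.92 correspond, at n = 14
observations, to two-tailed significance levels of about 0.001 / 0.0001 /
0.00001 under the t-transformation t = r·sqrt(n−2)/sqrt(1−r²).  The n = 14
in this mapping is the 7-animals-x-2-IEGs stacking; it is the only sample
size at which all three printed (r, p) pairs hold simultaneously, which is
why the package treats IEG stacking as the canonical observation model.
The mapping is reported for context only — thresholding is always on r.
Matrix p-values are not multiplicity-corrected by default (a Bonferroni
option over the 66 pairs exists) since the thresholded networks are
descriptive, not inferential.

## Hierarchical clustering

Region dissimilarity is the uncentered-correlation ("amap Pearson")
distance, d(x, y) = 1 − Σxᵢyᵢ / sqrt(Σxᵢ²·Σyᵢ²), i.e. one minus the cosine
of the angle between the two observation vectors; a centered variant
(1 − product-moment r) is available.  The uncentered form is scale-invariant
but not shift-invariant, so it is computed on normalized counts.  Clustering
is classic UPGMA: join the minimum-distance pair, then define the merged
cluster's distance to every other cluster as the size-weighted mean of the
two constituent distances (equivalently, the mean over all cross-pairs of
leaves).  Ties at the minimum are broken toward the pair containing the
earliest leaves in canonical region order, making the dendrogram invariant
to input permutations.  Output is a scipy-compatible merge table and a
Newick string whose branch lengths are height differences.

## Module detection

Modules are found on the full, unthresholded correlation matrix (diagonal
zeroed — self-correlations carry no information and distort the null term)
by Louvain modularity maximization with resolution parameter gamma.  Since
correlations can be negative, the default quality is the asymmetric signed
modularity: positive and negative parts each get their own null model,
Q = Q⁺ − (v⁻/(v⁺+v⁻))·Q⁻, so negative weights discourage but cannot dominate
community formation; `positive_only` (negatives zeroed) is the alternative.
The optimizer is the standard two-phase heuristic — greedy single-node moves
to the best-scoring community until no move improves Q, then aggregation of
communities into super-nodes (self-loops keeping internal weight), repeated
to convergence.  The only randomness is the node visitation order, reshuffled
each pass by a seeded xorshift64 generator inside a numba-compiled kernel;
a seed fully determines the partition.  On small instances the returned Q
matches exhaustive enumeration over all partitions (tested up to 8 nodes).

### Resolution selection

For each gamma on the grid 0.1–2.0 (step 0.01) Louvain is run 100 times with
distinct seeds and the mean pairwise adjusted mutual information (AMI)
between runs is recorded.  AMI uses the exact hypergeometric expectation
E[MI] of the permutation null and the arithmetic-mean normalizer; identical
partitions (up to relabeling) score exactly 1.

Two selection rules are provided.  `select_gamma` returns the largest gamma
at which all runs agree (mean AMI = 1 within tolerance) — the classical
prescription.  On matrices with sharply separated blocks this rule
degenerates: at high resolution the optimizer locks into perfectly *stable*
fragmented partitions (near-singleton modules), so the largest stable gamma
is simply the top of the grid.  The pipeline therefore defaults to
`select_stable_plateau`: group contiguous gammas at which all runs agree
*and* agree on the same partition into plateaus; discard plateaus whose
partition is trivial (one module) or contains modules of fewer than two
regions (a one-region "module" carries no co-activation information, and
such partitions become trivially stable at high resolution); pick the
widest remaining plateau, representing it by its midpoint gamma.  Because
the partition is constant across a plateau, the representative gamma does
not affect the result on the data it was selected from; the midpoint is
simply the most robust choice if the resolution is reused on a replicate.
Plateau width measures exactly what the stability sweep is after — how
robust a partition is to the resolution choice.  On a single-band profile
(stability 1 up to some gamma, degraded above, as in noisy cohort-sized
data) the two rules coincide.

## Group comparisons

Correlations are compared between groups on the Fisher scale,
z = arctanh r, with D = (z₁−z₂)/sqrt(1/(n₁−3) + 1/(n₂−3)) treated as
standard normal (two-tailed).  Pairwise comparison tables carry D in the
upper triangle and p in the lower.  Module-level strength is compared by a
paired t-test across the module's within-pair correlations (15 pairs for a
6-region module; the pair is the pairing unit — the only one available from
per-group matrices), reference group against each other group, Bonferroni
corrected by the number of group comparisons (not by 15).  The t-test runs
on raw r by default, matching how mean module correlations are reported; a
Fisher-z-first option exists because r is bounded.

## Behavioural metrics

Performance index = 100 − 100·(errors/5); 2.5 errors (the expectation when
digging randomly among the 5 incorrect sandwells) maps to 50%.  Cued-recall
dig times at the six sandwells are expressed as percentages of total dig
time per category (original/new x cued/non-cued), with non-cued categories
averaged over their member wells so cued and non-cued values are per-well
comparable.  The chance line for a single well is exposed as 100/6 % — a
package convention, not an asserted empirical value.  Group summaries are
mean ± SEM of animal-level means (SEM across animals, ddof = 1).

## Synthetic cohorts

Because the original counts are unpublished, the generator emulates the
study design: per group, each (animal, IEG) row is an independent draw from
a 12-dimensional multivariate normal with a block target correlation,
scaled to per-(region, IEG) means/SDs (placeholders 100 ± 20; every
downstream statistic is correlation-based and invariant to them).  Planted
structure: NPA — a 6-region block {DG, CA3, CA1, PrL, ACC, aRC} at
within-r = 0.9 over background 0.1; OPA — only the pairs DG–CA1, CA3–CA1,
aRC–Ssp; CC — an allocortical block {DG, CA3, CA1, EC}; NM — uniform
background.  Indefinite naive block targets are repaired by eigenvalue
clipping with diagonal renormalization.  The defaults were chosen once so
that planted edges clear r > 0.80 at n = 14 with high probability while
background does not; they are synthetic conventions, not estimates of the
real data.  What the generator does *not* emulate: within-animal coupling
between the two IEGs, count discreteness and overdispersion (a
`poisson_rounded` mode exists for integer-count realism only), inter-region
mean/variance differences, and any behavioural-covariate structure — so
passing tests demonstrate correctness of the machinery on the planted
correlation geometry, not fidelity to biological IEG data.

## Validation experiments and their observed behaviour

`iegnet.validation.planted_module_recovery` runs the full per-group
pipeline (simulate → normalize → correlate → sweep → plateau selection) on
replicate cohorts of 50 animals per group and scores each group's partition
against the NPA planted bipartition with AMI.  The experiment is sharply
discriminative — the planted structure is essentially never reported in the
wrong group (false-recovery rate at AMI ≥ 0.5 is ~1%) — but exact recovery
(AMI ≥ 0.95, i.e. the exact bipartition) occurs in roughly 70–75% of
cohorts, not ~100%.  The shortfall is a property of the objective, not the
optimizer: enumerating *all* perfectly stable partitions across the whole
gamma grid per cohort shows that in ~25–35% of cohorts no stable partition
equals the planted bipartition — either a background region's empirical
mean correlation to the block (true 0.1, SE ≈ 0.04 over 6 edges at n = 100
observations) crosses the absorption threshold at every resolution that
separates the block, or the weakly cohesive background (within-r 0.1)
splits before the block separates.  In those cohorts the partitions found
have strictly higher modularity than the planted bipartition.  The recovery
rate is reported honestly by the reproduction script rather than tuned.

## Numerical conventions

Sample SDs use ddof = 1 throughout.  Correlation matrices are symmetrized
and clipped to [−1, 1] after computation; |r| = 1 returns p = 0 by
convention.  Louvain move acceptance requires a gain above 1e-12; "perfect
similarity" in the sweep means mean AMI within 1e-9 of 1.  Modularity is
defined matrix-wise (v = ΣᵢⱼWᵢⱼ, strength = row sum), which is exactly
preserved under aggregation.  All seeds are plain integers; every stochastic
function takes one explicitly and is bit-reproducible given it.

## Problem sizes used by the shipped experiments

The reproduction script and acceptance tests use: 100 replicate cohorts of
50 animals per group for the recovery experiment (full 191-point gamma grid,
100 Louvain runs per gamma, per cohort and group); 20,000 replicates for the
type-I calibration; and a pooled 4 x 7-animal cohort for the headline
resolution selection.  These sizes give Monte-Carlo error well below the
decision margins of each check.

## Known limitations

* The stability-plateau rule assumes the informative partition occupies the
  widest stable resolution band; pathological profiles could defeat it.
* The signed-modularity null is heuristic; no exact inference attaches to Q.
* Fisher z comparisons assume independent samples and bivariate normality;
  with n = 14 the normal approximation for D is serviceable but not exact
  (the calibration experiment measures it at ~5.0%).
* The generator's independence of (animal, IEG) rows means per-group n = 14
  behaves like 14 independent observations, which flatters precision
  relative to real data where the two IEGs per animal are correlated.
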