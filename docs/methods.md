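# Methods

This note records the model underlying each stage, the defaults and why
they were chosen, the numerical conventions that make runs deterministic,
and what the synthetic benchmarks do and do not demonstrate.

## Preprocessing

Cell tables are asinh-transformed, x → asinh(x / c), with cofactor
c = 5 by default — the common choice for mass cytometry, where ion counts
are approximately linear above the noise floor and the transform behaves
logarithmically there. The cofactor is configurable; the transform is
tracked by a state flag so it cannot be applied twice. Quality control is
a single post-gating rule: a sample with fewer than 3,000 cells is
discarded (upstream live/intact/singlet gating is assumed done by the
acquisition pipeline and is out of scope). Each retained sample is
downsampled to 6,000 cells uniformly without replacement so that no donor
dominates the pooled map; an optional healthy-adult reference pool
contributes 30,000 extra cells so that populations rare in children (e.g.
highly differentiated memory subsets) still form visible map regions. All
sampling uses a single explicit integer seed recorded in the run manifest.

FCS 3.0/3.1 list-mode files are read and written directly (float32 or
float64, byte-aligned integer data on read); delimited tables with a
header row of marker names and a reserved `sample_id` column are the
text-only interchange format, chosen so fixtures and intermediate
artifacts need no binary container.

## Embedding and hexagonal binning

The default embedding is Barnes–Hut t-SNE with perplexity 60, gradient
accuracy θ = 0.5, and 2,000 iterations, run single-threaded with a fixed
seed so results are reproducible for a given library version. The
embedding is deliberately pluggable — downstream stages consume only a
(cell, x, y) table — because t-SNE is stochastic and any 2-D map with
locally coherent phenotypes works.

The map's bounding box, padded by one hexagon radius, is tiled with
flat-top regular hexagons. The radius is set so that columns × rows of the
offset tiling approximates the target of 10,000 positions:
r = sqrt(W·H / (1.5·√3·target)). Cells are assigned to the nearest
hexagon centre (a k-d tree query), which is exactly the hexagonal Voronoi
partition; the tests verify this against exhaustive nearest-centre search.
Empty bins are dropped. A bin's expression vector is the unweighted mean
of its member cells' marker vectors.

Adjacency: two non-empty bins are adjacent when they share a hexagon
border (the six axial lattice neighbours). A non-empty bin whose six
lattice neighbours are all empty receives exactly **one** fallback edge to
its nearest non-empty bin by centre distance (ties broken toward the
lowest bin id). One edge is the minimal repair that removes isolation
without inventing spurious contiguity; fallback edges count the same as
border edges for the clustering constraint. The resulting graph is
undirected with no isolated vertex.

## Constrained complete-linkage clustering

Bin distances are weighted Euclidean, d(p,q) = sqrt(Σᵢ wᵢ(pᵢ−qᵢ)²), with
user-assigned per-marker weights (default 1; weight 0 removes a marker
from the geometry entirely). Agglomeration is complete linkage — the
distance between clusters is the maximum pairwise bin distance — with the
constraint that only *adjacent* clusters (sharing at least one
cross-cluster bin-adjacency edge) may merge. The merged cluster's
neighbour set is the union of its parents', maintained incrementally; the
complete-linkage distances use the exact max update, so the incremental
algorithm provably equals the brute-force definition (the tests check this
merge-for-merge against a rescan oracle on random instances).

The constrained phase continues until the remaining clusters are exactly
the connected components of the bin graph; all later merges are ordinary
complete linkage, flagged "unconstrained". The phase therefore switches at
most once.

Determinism conventions: clusters carry ids in the scipy linkage
convention (bins 0..n−1, merge t creates id n+t); when several pairs tie
at the minimum linkage distance, the lexicographically smallest
(id_a, id_b) pair merges first.

**Cutting.** Constrained merge heights need not be monotone (a forced
adjacent merge can be cheaper than an earlier unavailable one), so a
height threshold is ill-defined. The tree is instead cut by merge order:
k clusters = undo the last k−1 merges. With a complete adjacency graph
this coincides with the usual height cut.

**Minimum cluster size.** After cutting, while any cluster holds fewer
than 1,500 cells, the smallest such cluster is merged into the cluster it
joins next in the merge history — the first recorded merge connecting any
of its bins to outside bins, with the receiving cluster chosen as the one
holding the most of those partner bins (ties toward the lower label). If
the history provides no partner the nearest cluster by complete linkage
absorbs it. This respects the tree topology rather than re-cutting at a
smaller k, and terminates because every merge reduces the cluster count.

## Occupancy statistics

Occupancy(s, c) = fraction of sample s's cells in cluster c; rows sum
to 1 and reference-pool cells are excluded from sample rows (clusters
occupied only by the reference remain as all-zero columns). Group
comparisons are two-sided Mann–Whitney tests per cluster, stratified by
timepoint, with Benjamini–Hochberg correction applied within each
timepoint across its clusters — matching the testing scope of per-age
cohort comparisons. Exact null distributions are used where feasible
(small groups, no ties), otherwise the tie-corrected normal approximation
with continuity correction.

PCA of the occupancy matrix retains all but the final dimension
(occupancies are compositional, so the last principal axis carries no
variance). The retained scores enter a type-II MANOVA: for each covariate
the hypothesis SSCP is the drop in residual SSCP between the additive
model without that term and the full additive model — appropriate since
the model has no interactions. Significance uses the Pillai trace V with
the standard F approximation; in the univariate single-term case this
reduces exactly to the one-way ANOVA F (verified in tests). The reported
effect share is partial η² = V / s with s = min(term df, number of
responses), a Pillai-derived quantity in [0, 1]. Week/age is coded
categorically because sampling is binned at weeks 53/104/156.

## Stunting screen

Samples are first filtered for condition consistency: k-means with k = 2
on z-scored sample-level feature vectors, each cluster mapped to the
stimulation condition of its majority, and samples landing in the wrong
cluster dropped (they likely reflect an ongoing acute response). Samples
are then grouped: American children form group 0 with HAZ imputed as 0,
Bangladeshi children split at HAZ ≤ −1.5 (group 2, more stunted) versus
HAZ > −1.5 (group 1).

For each feature (a population × marker positive fraction) and threshold
θ the event requires both standardized differences — group 0 minus group 1
and group 2 minus group 1, each divided by the two-sample df-weighted
pooled SD with group 1 — to reach θ. The event is translation-invariant
and scale-equivariant; a zero pooled SD makes it undefined and the feature
is reported missing.

The null permutes HAZ scores among the Bangladeshi samples only and
re-derives groups 1/2; group 0 stays fixed because its pseudo-HAZ is an
imputed constant, so shuffling it would only dilute the null. This is the
single most consequential modelling choice in the screen and is therefore
called out here. Per feature, p = (1 + B) / (1 + N) where B counts
permutations in which the event fires — the add-one form avoids zero
p-values; jointly with the observed event this is a valid (super-uniform)
test because the observed grouping is exchangeable with the permutations
under the null. The per-θ FDR is the plug-in estimate: mean permutation
event count divided by the observed event count, capped at 1. The θ grid
defaults to 0 to 2 in steps of 0.1. Candidates pass p ≤ 0.05 and
FDR ≤ 0.2 either at a fixed θ or at any θ in the grid (both modes are
exposed; the default reports the largest qualifying θ per feature).

Validation of a screened marker measures the same marker across several
populations, takes PC1 of the centered columns (sign-oriented to correlate
positively with the per-sample mean so "higher" means higher expression),
and regresses PC1 on the stunted indicator with a one-sided t test in the
direction "more stunted → higher". Training and validation p-values are
combined with Fisher's method (−2 Σ ln p ~ χ² on 4 df) — a deliberate,
documented choice since several combination rules exist.

## Synthetic data

The generator draws each sample's cells from a shared mixture of Gaussian
populations with diagonal covariance on the asinh scale — the simplest
model that exercises binning and clustering. Population frequencies are
multinomial with per-cohort/per-timepoint log-fold effects; stimulation
adds marker shifts; a planted stunting effect raises chosen functional
markers in stimulated samples of more-stunted donors (and, by default, of
American donors, whose baseline for these markers is high). Default
populations elevate disjoint 2-marker blocks, giving every pair of
populations the same mean separation (8 within-population SDs by
default). Bangladeshi HAZ scores are truncated normal centred at −1.5 so
cohorts straddle the stunting threshold. A screen-level generator
produces sample × feature tables with an optional correlated planted
block, emulating one marker measured across several cell populations.

What this does *not* emulate: spillover and isotopic interference,
doublets, batch/acquisition drift, heavy tails and zero inflation
(toggles exist but default off), or the intricate covariance of real
marker panels. Passing the benchmarks therefore shows the algorithms are
implemented correctly and calibrated under their stated assumptions, not
that real cohorts would yield the same power.

## Problem sizes and tolerances

The test and acceptance runs use desk-scale sizes chosen so the whole
suite runs comfortably on one CPU: end-to-end recovery uses 16 samples ×
1,200 cells (19,200 pooled cells, ~2,000 tiling positions of which ~460
are occupied, k = 8, 1,500-cell floor); determinism reruns use 11 samples
× 400 cells; oracle checks use ≤ 200-bin instances; screen calibration
and power use 50 features with 5/8/8 group sizes and 1,000 permutations
per cohort. Distance-formula agreement is asserted to 1e−12 absolute;
linkage heights to 1e−12 relative; Voronoi assignment to 1e−9 absolute
(k-d tree versus dense distance matrix round-off). Monte-Carlo
assertions use 95% binomial confidence bands plus a small slack for
discreteness.

## Known limitations

* t-SNE coordinates, and hence cluster shapes, depend on the library
  version; only seeded determinism within a version is promised.
* The merge-order cut and the dendrogram-based minimum-size merge are one
  of several defensible conventions; both are documented above and fixed
  by tests.
* The incremental linkage keeps an O(n²) distance matrix and rescans it
  each step — fine up to ~10⁴ bins, not tuned beyond that.
* The MANOVA assumes an additive model; with interactions the type-II
  sums reported here would no longer be the natural choice.
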