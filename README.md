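# adjclust

Adjacency-constrained clustering and cohort statistics for mass-cytometry
(CyTOF) immune profiling.

## The problem

CyTOF measures 30–40 protein markers on hundreds of thousands of single
cells per study. A standard way to find cell populations without manual
gating is to embed the cells into 2-D with t-SNE and cluster the map — but
clustering the raw 2-D coordinates throws away most of the marker
information, while clustering in full marker space ignores the map that
analysts actually interpret. This package implements **AdjClust**, which
uses both: hierarchical clustering on the original *n*-dimensional marker
data, constrained so that clusters are contiguous regions of the 2-D map.
Around the clustering it provides the statistics a cohort comparison needs:
differential cluster abundance between groups of donors, variance
partitioning of sample profiles over clinical covariates, and a permutation
screen for immune features associated with childhood stunting
(height-for-age z-score, HAZ).

## The algorithm

1. **Pool and embed.** Per-sample cell tables are asinh-transformed
   (cofactor 5), QC'd (samples with < 3,000 cells discarded), downsampled
   to 6,000 cells each, pooled (optionally with 30,000 healthy-adult
   reference cells), and embedded with Barnes–Hut t-SNE (perplexity 60,
   θ = 0.5, 2,000 iterations).
2. **Hexagonal binning.** The map is tiled with ~10,000 equal flat-top
   hexagons; each cell goes to its nearest hexagon centre; empty bins are
   dropped; each bin gets a "bin expression" vector — the mean marker
   vector of its member cells. Bins sharing a border are adjacent; a bin
   with no non-empty neighbour is connected to its closest non-empty bin.
3. **Constrained complete linkage.** Pairwise bin distances use
   marker weights *w*:

       d(p, q) = sqrt( Σᵢ wᵢ (pᵢ − qᵢ)² )

   Complete-linkage agglomeration proceeds with the stipulation that two
   clusters may only merge while some bin in each is adjacent to a bin of
   the other. When no adjacent pair remains, the final merges are ordinary
   complete linkage. The tree is cut to the desired number of clusters
   (merge-order cut), clusters below 1,500 cells are merged along the
   dendrogram, and bin labels propagate to cells.
4. **Statistics.** Per-sample *cluster occupancy* (fraction of the
   sample's cells in each cluster) feeds two-sided Mann–Whitney tests per
   cluster and timepoint with Benjamini–Hochberg correction; PCA of the
   occupancy profiles (all but the final dimension retained) feeds a
   type-II MANOVA over clinical covariates with Pillai-trace tests and
   partial η² effect shares. The stunting screen tests, for each
   functional feature *i*, the event
   (μᵢ₀ − μᵢ₁)/sᵢ₀ ≥ θ **and** (μᵢ₂ − μᵢ₁)/sᵢ₂ ≥ θ over groups
   0 (American, HAZ ≡ 0), 1 (HAZ > −1.5), 2 (HAZ ≤ −1.5), against a null
   built by permuting HAZ scores 5,000 times among the Bangladeshi samples.

## Worked example

Simulate a cohort of six Bangladeshi and six American samples drawn from a
shared 6-population mixture, with one population's abundance tripled in the
Bangladeshi samples, then recover the structure end to end:

```python
import numpy as np, pandas as pd
from adjclust.synthetic import CohortSpec, PopulationSpec, default_populations, simulate_cohort
from adjclust import io_prep, embed_hexbin, clustering, group_stats
from adjclust.io_prep import MarkerPanel

pops = [
    PopulationSpec(p.name, p.mean, p.spread, p.baseline_freq,
                   abundance_logfc={("Bangladesh", "53"): np.log(3.0)} if i == 0 else {})
    for i, p in enumerate(default_populations(n_pops=6, n_markers=23))
]
spec = CohortSpec(n_donors={("Bangladesh", "53"): 6, ("USA", "53"): 6})
tables, metas, truths = simulate_cohort(spec, pops, cells_per_sample=800, seed=0)
pooled = io_prep.pool_cells(tables)

emb = embed_hexbin.run_tsne(pooled, perplexity=40, iterations=500, seed=0)
grid = embed_hexbin.build_hexgrid(emb, target_bins=1000)
graph = embed_hexbin.build_adjacency(embed_hexbin.compute_bin_graph(grid, pooled))
panel = MarkerPanel(marker_names=pooled.marker_names)

d = clustering.pairwise_distances(graph, panel)
history = clustering.constrained_complete_linkage(d, graph)
assign = clustering.cut_tree(history, 6)
assign = clustering.enforce_min_size(assign, history, graph, min_cells=500, d=d)
assign = clustering.propagate_to_cells(assign, graph)
print(f"{graph.n_bins} occupied bins -> {assign.k} clusters")

occ = group_stats.compute_occupancy(assign.cell_to_cluster, pooled.sample_id)
meta_df = pd.DataFrame([vars(m) for m in metas])
for r in group_stats.test_occupancy(occ, meta_df, group_levels=("Bangladesh", "USA")):
    print(f"cluster {r.cluster_id}: ratio {r.ratio:.2f}  p {r.p_value:.4f}  FDR {r.fdr:.4f}")
```

Output:

```
299 occupied bins -> 6 clusters
cluster 0: ratio 0.71  p 0.0048  FDR 0.0074
cluster 1: ratio 0.69  p 0.0022  FDR 0.0074
cluster 2: ratio 0.77  p 0.0103  FDR 0.0103
cluster 3: ratio 0.78  p 0.0080  FDR 0.0096
cluster 4: ratio 0.79  p 0.0049  FDR 0.0074
cluster 5: ratio 2.31  p 0.0049  FDR 0.0074
```

Cluster 5 is the planted population: its occupancy ratio (mean Bangladeshi
over mean American occupancy) is near the design value of 2.4 — the
tripled population renormalised against five unchanged ones,
(3/8)/(8/8 + 2/8) ÷ (1/8) = 2.4 — and the abundance shift is significant
after BH correction. The adjusted Rand index of the recovered cell labels
against the ground-truth mixture is 0.9998 here. The compositional
ratios below 1 for the other clusters are real: tripling one population's
share necessarily depresses the rest.

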