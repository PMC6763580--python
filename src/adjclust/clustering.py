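"""AdjClust core: weighted bin distances and adjacency-constrained
complete-linkage clustering.

The algorithm agglomerates hexagonal bins of a 2-D map using complete
linkage on marker-weighted Euclidean distances between bin expression
vectors, with the constraint that two clusters may only merge while at
least one bin in each is adjacent to a bin in the other. When no adjacent
pair of clusters remains (the clusters are the connected components of the
bin graph), the remaining merges proceed as standard, unconstrained
complete linkage. The resulting tree is cut by merge order to a desired
number of clusters, undersized clusters (< 1,500 cells by default) are
merged along the tree, and bin labels are propagated to member cells.

Cluster identifiers follow the scipy linkage convention: the n original
bins are clusters 0..n-1 and the cluster created by merge step t is n+t.
Ties in the minimum linkage distance are broken by the lexicographically
smallest (cluster_a, cluster_b) id pair, which makes runs deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from adjclust.embed_hexbin import BinGraph
from adjclust.errors import ArgumentError
from adjclust.io_prep import MarkerPanel

__all__ = [
    "Merge",
    "MergeHistory",
    "ClusterAssignment",
    "weighted_distance",
    "pairwise_distances",
    "constrained_complete_linkage",
    "cut_tree",
    "enforce_min_size",
    "propagate_to_cells",
]


@dataclass(frozen=True)
class Merge:
    step: int
    cluster_a: int  # cluster_a < cluster_b
    cluster_b: int
    height: float  # complete-linkage distance at the merge
    phase: str  # "constrained" | "unconstrained"


@dataclass
class MergeHistory:
    """Ordered record of all n_bins - 1 merges."""

    n_bins: int
    merges: list[Merge] = field(default_factory=list)

    def members(self) -> list[list[int]]:
        """Bin membership of every cluster id 0 .. 2 * n_bins - 2."""
        out: list[list[int]] = [[i] for i in range(self.n_bins)]
        for m in self.merges:
            out.append(out[m.cluster_a] + out[m.cluster_b])
        return out


@dataclass
class ClusterAssignment:
    """Bin- and cell-level cluster labels with per-cluster cell counts."""

    bin_to_cluster: np.ndarray  # (n_bins,) labels 0..k-1
    cluster_cells: np.ndarray  # (k,) cells per cluster
    cell_to_cluster: np.ndarray | None = None

    @property
    def k(self) -> int:
        return int(self.cluster_cells.shape[0])


def weighted_distance(p: np.ndarray, q: np.ndarray, w: np.ndarray) -> float:
    """d(p, q) = sqrt(sum_i w_i (p_i - q_i)^2)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    w = np.asarray(w, dtype=float)
    if p.shape != q.shape or p.shape != w.shape:
        raise ArgumentError("p, q and w must have equal lengths")
    if np.any(w < 0):
        raise ArgumentError("weights must be nonnegative")
    diff = p - q
    return float(np.sqrt(np.sum(w * diff * diff)))


def pairwise_distances(graph: BinGraph, panel: MarkerPanel) -> np.ndarray:
    """Full symmetric matrix of weighted distances between bin expressions."""
    if len(panel.weights) != graph.expression.shape[1]:
        raise ArgumentError("panel weights do not align with bin expressions")
    from scipy.spatial.distance import cdist

    w = np.asarray(panel.weights, dtype=float)
    x = graph.expression * np.sqrt(w)  # weighted Euclidean == Euclidean on scaled axes
    d = cdist(x, x)
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def constrained_complete_linkage(
    d: np.ndarray, graph: BinGraph | None = None, edges: set[tuple[int, int]] | None = None
) -> MergeHistory:
    """Two-phase adjacency-constrained complete-linkage agglomeration.

    At each step the pair of current clusters with the smallest
    complete-linkage distance *among adjacent pairs* is merged; clusters are
    adjacent when any bin of one shares a bin-graph edge with any bin of the
    other (the merged cluster's neighbour set is the union of its parents').
    Once no adjacent pair remains, all further merges are standard complete
    linkage ("unconstrained" phase).

    ``d`` is the bins x bins distance matrix; adjacency comes from ``graph``
    or an explicit ``edges`` set of bin-id pairs.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ArgumentError("distance matrix must be square")
    history = MergeHistory(n_bins=n)
    if n < 2:
        return history
    if edges is None:
        if graph is None:
            raise ArgumentError("either graph or edges must be supplied")
        edges = graph.edges

    # slot arrays: slot i starts as bin i; merged-away slots are deactivated
    D = d.copy()
    np.fill_diagonal(D, np.inf)
    adj = np.zeros((n, n), dtype=bool)
    for a, b in edges:
        adj[a, b] = adj[b, a] = True
    slot_id = np.arange(n)  # current cluster id held by each slot

    phase = "constrained"
    for step in range(n - 1):
        if phase == "constrained":
            cand = np.where(adj, D, np.inf)
            if not np.isfinite(cand).any():
                phase = "unconstrained"
        if phase == "unconstrained":
            cand = D
        # minimum with deterministic tie-break on (cluster_a, cluster_b) ids
        dmin = cand.min()
        ii, jj = np.nonzero(cand == dmin)
        upper = ii < jj
        ii, jj = ii[upper], jj[upper]
        ids = np.sort(np.column_stack([slot_id[ii], slot_id[jj]]), axis=1)
        order = np.lexsort((ids[:, 1], ids[:, 0]))
        si, sj = int(ii[order[0]]), int(jj[order[0]])
        a, b = sorted((int(slot_id[si]), int(slot_id[sj])))
        history.merges.append(
            Merge(step=step, cluster_a=a, cluster_b=b, height=float(dmin), phase=phase)
        )
        # keep the union in slot si: complete-linkage max update + neighbour union
        np.maximum(D[si, :], D[sj, :], out=D[si, :])
        D[:, si] = D[si, :]
        D[si, si] = np.inf
        np.logical_or(adj[si, :], adj[sj, :], out=adj[si, :])
        adj[:, si] = adj[si, :]
        adj[si, si] = False
        D[sj, :] = np.inf
        D[:, sj] = np.inf
        adj[sj, :] = False
        adj[:, sj] = False
        slot_id[si] = n + step
    return history


def cut_tree(history: MergeHistory, k: int) -> ClusterAssignment:
    """Cut by merge order: replay the first n_bins - k merges.

    Constrained merges need not be height-monotone, so the cut is defined by
    merge order rather than by a height threshold. Cluster labels 0..k-1 are
    assigned in order of each cluster's smallest member bin id.
    """
    n = history.n_bins
    if not 1 <= k <= max(n, 1):
        raise ArgumentError(f"k must be in [1, {n}], got {k}")
    parent = np.arange(2 * n - 1 if n else 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m in history.merges[: n - k]:
        new_id = n + m.step
        parent[find(m.cluster_a)] = new_id
        parent[find(m.cluster_b)] = new_id

    roots = np.array([find(i) for i in range(n)])
    # label clusters by smallest member bin id for a canonical ordering
    order: dict[int, int] = {}
    labels = np.empty(n, dtype=np.int64)
    for i in range(n):
        r = int(roots[i])
        if r not in order:
            order[r] = len(order)
        labels[i] = order[r]
    counts = np.zeros(len(order), dtype=np.int64)
    return ClusterAssignment(bin_to_cluster=labels, cluster_cells=counts)


def _cluster_cell_counts(labels: np.ndarray, bin_cells: np.ndarray) -> np.ndarray:
    k = int(labels.max()) + 1 if labels.size else 0
    counts = np.zeros(k, dtype=np.int64)
    np.add.at(counts, labels, bin_cells)
    return counts


def with_cell_counts(assign: ClusterAssignment, graph: BinGraph) -> ClusterAssignment:
    assign.cluster_cells = _cluster_cell_counts(assign.bin_to_cluster, graph.n_cells)
    return assign


def enforce_min_size(
    assign: ClusterAssignment,
    history: MergeHistory,
    graph: BinGraph,
    min_cells: int = 1500,
    d: np.ndarray | None = None,
) -> ClusterAssignment:
    """Merge clusters below the cell-count floor along the dendrogram.

    While any cluster holds fewer than ``min_cells`` cells, the smallest such
    cluster is merged into the cluster it would join next in the merge
    history (the first merge joining any of its bins to outside bins; the
    receiving cluster is the one holding most of those partner bins' cells).
    If the history provides no partner, the nearest cluster by complete
    linkage on ``d`` is used instead.
    """
    labels = assign.bin_to_cluster.copy()
    bin_cells = graph.n_cells
    members = history.members()
    if int(np.sum(bin_cells)) < min_cells:
        import warnings

        warnings.warn(
            "total cells below the minimum cluster size; returning one cluster",
            stacklevel=2,
        )
        labels[:] = 0
        return ClusterAssignment(
            bin_to_cluster=labels,
            cluster_cells=_cluster_cell_counts(labels, bin_cells),
        )

    while True:
        counts = _cluster_cell_counts(labels, bin_cells)
        small = np.flatnonzero(counts < min_cells)
        if small.size == 0 or counts.size <= 1:
            break
        c = int(small[np.argsort(counts[small], kind="stable")[0]])
        in_c = labels == c
        target = _next_merge_partner(in_c, members, history, labels)
        if target is None:
            target = _nearest_cluster(in_c, labels, d)
        labels[in_c] = target
        labels = _relabel(labels)
    return ClusterAssignment(
        bin_to_cluster=labels, cluster_cells=_cluster_cell_counts(labels, bin_cells)
    )


def _next_merge_partner(
    in_c: np.ndarray,
    members: list[list[int]],
    history: MergeHistory,
    labels: np.ndarray,
) -> int | None:
    """Cluster label that the bin set ``in_c`` first merges with in history."""
    for m in history.merges:
        left = members[m.cluster_a]
        right = members[m.cluster_b]
        l_in = any(in_c[i] for i in left)
        r_in = any(in_c[i] for i in right)
        l_out = any(not in_c[i] for i in left)
        r_out = any(not in_c[i] for i in right)
        if (l_in and r_out) or (r_in and l_out):
            partner_bins = [i for i in left + right if not in_c[i]]
            # receiving cluster: the current cluster holding most partner bins
            votes: dict[int, int] = {}
            for i in partner_bins:
                votes[int(labels[i])] = votes.get(int(labels[i]), 0) + 1
            best = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
            return best
    return None


def _nearest_cluster(in_c: np.ndarray, labels: np.ndarray, d: np.ndarray | None) -> int:
    if d is None:
        others = sorted(set(int(v) for v in labels[~in_c]))
        return others[0]
    best_label, best_dist = None, np.inf
    idx_c = np.flatnonzero(in_c)
    for lab in sorted(set(int(v) for v in labels[~in_c])):
        idx_o = np.flatnonzero(labels == lab)
        dist = d[np.ix_(idx_c, idx_o)].max()
        if dist < best_dist:
            best_dist, best_label = dist, lab
    return int(best_label)


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Compact labels to 0..k-1, ordered by smallest member bin id."""
    order: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if int(lab) not in order:
            order[int(lab)] = len(order)
        out[i] = order[int(lab)]
    return out


def propagate_to_cells(assign: ClusterAssignment, graph: BinGraph) -> ClusterAssignment:
    """Give every cell the cluster label of its bin."""
    assign.cell_to_cluster = assign.bin_to_cluster[graph.cell_bin]
    assign.cluster_cells = _cluster_cell_counts(assign.bin_to_cluster, graph.n_cells)
    return assign
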