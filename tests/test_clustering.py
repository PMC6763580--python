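import numpy as np
import pytest
from scipy.cluster.hierarchy import cut_tree as scipy_cut_tree
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from _oracles import (
    brute_force_constrained_linkage,
    brute_force_partition,
    partition_of_labels,
    random_bin_instance,
)
from adjclust.clustering import (
    constrained_complete_linkage,
    cut_tree,
    enforce_min_size,
    pairwise_distances,
    propagate_to_cells,
    weighted_distance,
)
from adjclust.errors import ArgumentError
from adjclust.io_prep import MarkerPanel
from adjclust.synthetic import make_fixture_bingraph


def _graph_from(d_edges, n_bins, n_cells=None):
    """Wrap raw edges into a fixture graph with unit expressions."""
    axial = np.column_stack([np.arange(n_bins), np.zeros(n_bins, dtype=int)])
    g = make_fixture_bingraph(
        axial, np.zeros((n_bins, 1)), n_cells=n_cells
    )
    g.edges = set(d_edges)
    g.edge_kind = {e: "border" for e in d_edges}
    return g


class TestWeightedDistance:
    def test_identity_and_hand_value(self):
        assert weighted_distance([1.0, 2.0], [1.0, 2.0], [1.0, 1.0]) == 0.0
        assert weighted_distance([1.0, 0.0], [0.0, 0.0], [4.0, 1.0]) == pytest.approx(2.0)

    def test_unit_weights_equal_euclidean(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p, q = rng.normal(size=(2, 6))
            assert weighted_distance(p, q, np.ones(6)) == pytest.approx(
                np.linalg.norm(p - q)
            )

    def test_length_mismatch(self):
        with pytest.raises(ArgumentError):
            weighted_distance([1.0], [1.0, 2.0], [1.0, 1.0])


class TestPairwiseDistances:
    def test_matches_double_loop_and_zero_weight_inert(self):
        rng = np.random.default_rng(1)
        expr = rng.normal(size=(20, 5))
        axial = np.column_stack([np.arange(20), np.zeros(20, dtype=int)])
        graph = make_fixture_bingraph(axial, expr)
        w = (1.0, 0.5, 0.0, 2.0, 1.5)
        panel = MarkerPanel(marker_names=tuple("abcde"), weights=w)
        d = pairwise_distances(graph, panel)
        assert d.shape == (20, 20)
        np.testing.assert_allclose(d, d.T, atol=0)
        assert (np.diag(d) == 0).all()
        for i in range(20):
            for j in range(20):
                expected = np.sqrt(np.sum(np.array(w) * (expr[i] - expr[j]) ** 2))
                assert d[i, j] == pytest.approx(expected, abs=1e-12)
        # zero-weight marker has no effect on any entry
        expr2 = expr.copy()
        expr2[:, 2] = rng.normal(size=20)
        graph2 = make_fixture_bingraph(axial, expr2)
        np.testing.assert_allclose(pairwise_distances(graph2, panel), d, atol=1e-12)


class TestConstrainedLinkage:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 30))
        d, edges = random_bin_instance(rng, n, edge_prob=0.12)
        graph = _graph_from(edges, n)
        history = constrained_complete_linkage(d, graph)
        oracle = brute_force_constrained_linkage(d, edges)
        assert len(history.merges) == n - 1
        for m, (a, b, h, phase) in zip(history.merges, oracle):
            assert (m.cluster_a, m.cluster_b) == (a, b)
            assert m.height == pytest.approx(h, rel=1e-12)
            assert m.phase == phase

    def test_complete_graph_reduces_to_standard_complete_linkage(self):
        rng = np.random.default_rng(3)
        expr = rng.normal(size=(15, 4))
        d = squareform(pdist(expr))
        edges = {(i, j) for i in range(15) for j in range(i + 1, 15)}
        history = constrained_complete_linkage(d, edges=edges)
        z = linkage(pdist(expr), method="complete")
        np.testing.assert_allclose(
            [m.height for m in history.merges], z[:, 2], rtol=1e-12
        )
        assert all(m.phase == "constrained" for m in history.merges)
        for k in range(1, 16):
            ours = partition_of_labels(cut_tree(history, k).bin_to_cluster)
            ref = partition_of_labels(scipy_cut_tree(z, k).ravel())
            assert ours == ref

    def test_two_bins_single_edge(self):
        d = np.array([[0.0, 3.5], [3.5, 0.0]])
        history = constrained_complete_linkage(d, edges={(0, 1)})
        (m,) = history.merges
        assert (m.cluster_a, m.cluster_b, m.height, m.phase) == (0, 1, 3.5, "constrained")

    def test_disconnected_patches_switch_phase_once(self):
        rng = np.random.default_rng(9)
        d, _ = random_bin_instance(rng, 10)
        # two components: 0-4 chain and 5-9 chain
        edges = {(i, i + 1) for i in range(4)} | {(i, i + 1) for i in range(5, 9)}
        history = constrained_complete_linkage(d, edges=edges)
        phases = [m.phase for m in history.merges]
        assert phases[:-1].count("unconstrained") + 1 == phases.count("unconstrained")
        assert phases[-1] == "unconstrained"  # final join crosses components
        switch = phases.index("unconstrained")
        assert all(p == "constrained" for p in phases[:switch])

    def test_constrained_clusters_are_connected(self):
        rng = np.random.default_rng(11)
        n = 24
        d, edges = random_bin_instance(rng, n, edge_prob=0.1)
        history = constrained_complete_linkage(d, edges=edges)
        adj = {i: set() for i in range(n)}
        for a, b in edges:
            adj[a].add(b)
            adj[b].add(a)
        members = history.members()
        for m in history.merges:
            if m.phase != "constrained":
                continue
            group = set(members[n + m.step])
            seen = {next(iter(group))}
            frontier = list(seen)
            while frontier:
                cur = frontier.pop()
                for nb in adj[cur] & group:
                    if nb not in seen:
                        seen.add(nb)
                        frontier.append(nb)
            assert seen == group

    def test_permutation_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(13)
        n = 12
        d, edges = random_bin_instance(rng, n)
        perm = rng.permutation(n)
        d_p = d[np.ix_(perm, perm)]
        edges_p = {
            (min(int(np.where(perm == a)[0][0]), int(np.where(perm == b)[0][0])),
             max(int(np.where(perm == a)[0][0]), int(np.where(perm == b)[0][0])))
            for a, b in edges
        }
        h1 = constrained_complete_linkage(d, edges=edges)
        h2 = constrained_complete_linkage(d_p, edges=edges_p)
        for k in (2, 4, 6):
            p1 = partition_of_labels(cut_tree(h1, k).bin_to_cluster)
            # map the permuted partition back to original bin ids
            labels2 = cut_tree(h2, k).bin_to_cluster
            back = np.empty(n, dtype=int)
            back[perm] = labels2
            p2 = partition_of_labels(back)
            assert p1 == p2


class TestCutTree:
    def test_extremes(self):
        rng = np.random.default_rng(2)
        d, edges = random_bin_instance(rng, 9)
        history = constrained_complete_linkage(d, edges=edges)
        assert cut_tree(history, 9).k == 9
        assert cut_tree(history, 1).k == 1
        with pytest.raises(ArgumentError):
            cut_tree(history, 0)
        with pytest.raises(ArgumentError):
            cut_tree(history, 10)

    def test_matches_oracle_replay_at_k3(self):
        rng = np.random.default_rng(4)
        d, edges = random_bin_instance(rng, 12)
        history = constrained_complete_linkage(d, edges=edges)
        oracle = brute_force_constrained_linkage(d, edges)
        ours = partition_of_labels(cut_tree(history, 3).bin_to_cluster)
        assert ours == brute_force_partition(oracle, 12, 3)


class TestEnforceMinSize:
    def _setup(self, n_cells, seed=0):
        rng = np.random.default_rng(seed)
        n = len(n_cells)
        d, edges = random_bin_instance(rng, n)
        graph = _graph_from(edges, n, n_cells=np.asarray(n_cells))
        history = constrained_complete_linkage(d, graph)
        return d, graph, history

    def test_no_op_when_all_clusters_large(self):
        d, graph, history = self._setup([1000] * 8)
        assign = cut_tree(history, 4)
        out = enforce_min_size(assign, history, graph, min_cells=500, d=d)
        np.testing.assert_array_equal(out.bin_to_cluster, assign.bin_to_cluster)

    def test_small_cluster_absorbed_by_next_merge_partner(self):
        # chain adjacency forces a deterministic dendrogram to inspect
        d = squareform(pdist(np.array([[0.0], [1.0], [1.9], [10.0]])))
        edges = {(0, 1), (1, 2), (2, 3)}
        graph = _graph_from(edges, 4, n_cells=np.array([100, 2000, 2000, 5]))
        history = constrained_complete_linkage(d, graph)
        assign = cut_tree(history, 3)
        out = enforce_min_size(assign, history, graph, min_cells=1500, d=d)
        assert out.cluster_cells.min() >= 1500
        # bins 0 (100 cells) must have joined the cluster its history merge names
        assert out.k < assign.k

    @pytest.mark.parametrize("seed", range(5))
    def test_terminates_with_floor_respected(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 20))
        cells = rng.integers(1, 400, size=n)
        d, graph, history = self._setup(cells.tolist(), seed=seed)
        assign = cut_tree(history, max(2, n // 2))
        floor = 600
        if cells.sum() < floor:
            with pytest.warns(UserWarning):
                out = enforce_min_size(assign, history, graph, min_cells=floor, d=d)
            assert out.k == 1
        else:
            out = enforce_min_size(assign, history, graph, min_cells=floor, d=d)
            assert out.cluster_cells.min() >= floor or out.k == 1


class TestPropagate:
    def test_cells_inherit_bin_labels_and_counts_conserve(self):
        rng = np.random.default_rng(6)
        n = 10
        d, edges = random_bin_instance(rng, n)
        cells = rng.integers(1, 9, size=n)
        graph = _graph_from(edges, n, n_cells=cells)
        history = constrained_complete_linkage(d, graph)
        assign = propagate_to_cells(cut_tree(history, 3), graph)
        assert assign.cell_to_cluster.shape == (cells.sum(),)
        assert assign.cluster_cells.sum() == cells.sum()
        for b in range(n):
            member_cells = assign.cell_to_cluster[graph.cell_bin == b]
            assert (member_cells == assign.bin_to_cluster[b]).all()
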