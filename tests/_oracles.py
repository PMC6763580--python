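"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the package's incremental data structures: cluster
distances are recomputed from the original bin distance matrix at every
step and adjacency is rescanned over the raw edge set, so agreement with
the fast implementation is a real cross-check.
"""

from __future__ import annotations

import numpy as np


def brute_force_constrained_linkage(
    d: np.ndarray, edges: set[tuple[int, int]]
) -> list[tuple[int, int, float, str]]:
    """Rescan-everything constrained complete linkage.

    Returns (cluster_a, cluster_b, height, phase) per merge using the same
    id convention as the package (bins 0..n-1, merge t creates id n+t) and
    the same tie-break (lexicographically smallest id pair).
    """
    n = d.shape[0]
    adj = np.zeros((n, n), dtype=bool)
    for a, b in edges:
        adj[a, b] = adj[b, a] = True
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = []
    phase = "constrained"
    next_id = n
    while len(clusters) > 1:
        ids = sorted(clusters)
        best = None
        # scan every cluster pair, recomputing linkage from scratch
        candidates = []
        for i_pos, a in enumerate(ids):
            for b in ids[i_pos + 1 :]:
                ca, cb = clusters[a], clusters[b]
                height = d[np.ix_(ca, cb)].max()
                adjacent = adj[np.ix_(ca, cb)].any()
                candidates.append((a, b, height, adjacent))
        if phase == "constrained" and not any(c[3] for c in candidates):
            phase = "unconstrained"
        pool = candidates if phase == "unconstrained" else [c for c in candidates if c[3]]
        best = min(pool, key=lambda c: (c[2], c[0], c[1]))
        a, b, height, _ = best
        merges.append((a, b, float(height), phase))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


def brute_force_partition(
    merges: list[tuple[int, int, float, str]], n: int, k: int
) -> list[frozenset[int]]:
    """Replay the first n-k oracle merges into a partition of bins."""
    clusters: dict[int, set[int]] = {i: {i} for i in range(n)}
    next_id = n
    for a, b, _, _ in merges[: n - k]:
        clusters[next_id] = clusters.pop(a) | clusters.pop(b)
        next_id += 1
    return sorted((frozenset(c) for c in clusters.values()), key=min)


def partition_of_labels(labels: np.ndarray) -> list[frozenset[int]]:
    out: dict[int, set[int]] = {}
    for i, lab in enumerate(labels):
        out.setdefault(int(lab), set()).add(i)
    return sorted((frozenset(c) for c in out.values()), key=min)


def random_bin_instance(
    rng: np.random.Generator, n_bins: int, n_markers: int = 4, edge_prob: float = 0.15
):
    """Random distances + random sparse adjacency with no isolated vertex."""
    expr = rng.normal(size=(n_bins, n_markers))
    diff = expr[:, None, :] - expr[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    edges: set[tuple[int, int]] = set()
    for i in range(n_bins):
        for j in range(i + 1, n_bins):
            if rng.random() < edge_prob:
                edges.add((i, j))
    degree = np.zeros(n_bins, int)
    for a, b in edges:
        degree[a] += 1
        degree[b] += 1
    for i in np.flatnonzero(degree == 0):
        j = int(rng.integers(n_bins - 1))
        j = j if j < i else j + 1
        edges.add((min(i, int(j)), max(i, int(j))))
    return d, edges


def hex_lattice_neighbors(axial: np.ndarray) -> set[tuple[int, int]]:
    """Brute-force border adjacency: all pairs at axial lattice distance 1."""
    offsets = {(1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1)}
    edges = set()
    for i in range(len(axial)):
        for j in range(i + 1, len(axial)):
            dq = int(axial[j, 0] - axial[i, 0])
            dr = int(axial[j, 1] - axial[i, 1])
            if (dq, dr) in offsets or (-dq, -dr) in offsets:
                edges.add((i, j))
    return edges


def exact_mannwhitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration of group labels."""
    from itertools import combinations

    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = _rankdata(pooled)

    def u_of(idx: tuple[int, ...]) -> float:
        r = ranks[list(idx)].sum()
        return r - n * (n + 1) / 2.0

    u_obs = u_of(tuple(range(n)))
    mean_u = n * m / 2.0
    dev_obs = abs(u_obs - mean_u)
    total = 0
    extreme = 0
    for idx in combinations(range(n + m), n):
        total += 1
        if abs(u_of(idx) - mean_u) >= dev_obs - 1e-12:
            extreme += 1
    return extreme / total


def _rankdata(a: np.ndarray) -> np.ndarray:
    order = np.argsort(a, kind="stable")
    ranks = np.empty(len(a), dtype=float)
    i = 0
    sorted_a = a[order]
    while i < len(a):
        j = i
        while j + 1 < len(a) and sorted_a[j + 1] == sorted_a[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, from the step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        adj[idx] = running
    return adj
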