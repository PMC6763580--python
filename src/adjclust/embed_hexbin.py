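"""2-D embedding, hexagonal binning of the map, and bin adjacency.

The pooled cells are embedded with Barnes-Hut t-SNE (perplexity 60, theta
0.5, 2,000 gradient iterations by default), the map is tiled with
equal-sized flat-top hexagons (~10,000 positions by default), each cell is
assigned to its nearest hexagon centre, empty hexagons are dropped, and
adjacency between the remaining bins is lattice-border adjacency with a
nearest-neighbour fallback edge for bins whose six lattice neighbours are
all empty — so the bin graph never has an isolated vertex.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from adjclust.errors import ArgumentError
from adjclust.io_prep import CellTable

logger = logging.getLogger(__name__)

SQRT3 = np.sqrt(3.0)

#: axial-coordinate offsets of the six neighbours of a flat-top hexagon
AXIAL_NEIGHBORS = ((1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1))


@dataclass
class Embedding:
    """2-D coordinates per pooled cell plus the parameters that made them."""

    coords: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ArgumentError("embedding coords must be an (n, 2) matrix")
        if not np.all(np.isfinite(self.coords)):
            raise ArgumentError("embedding coords must be finite")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


@dataclass
class HexGrid:
    """Flat-top hexagonal tiling of the embedding plane.

    Grid positions are enumerated in odd-q offset coordinates (column q,
    row j); a cell's bin is the tiling position whose centre is nearest to
    the cell (hexagonal Voronoi assignment).
    """

    hex_radius: float
    origin: np.ndarray  # centre of grid position (0, 0)
    n_cols: int
    n_rows: int
    bin_index: np.ndarray  # per cell: flat grid position q * n_rows + j

    @property
    def n_positions(self) -> int:
        return self.n_cols * self.n_rows

    def center_of(self, flat: np.ndarray) -> np.ndarray:
        q, j = np.divmod(np.asarray(flat), self.n_rows)
        x = self.origin[0] + 1.5 * self.hex_radius * q
        y = self.origin[1] + SQRT3 * self.hex_radius * (j + 0.5 * (q % 2))
        return np.column_stack([x, y])

    def axial_of(self, flat: np.ndarray) -> np.ndarray:
        """Axial (q, r) coordinates of flat grid positions."""
        q, j = np.divmod(np.asarray(flat), self.n_rows)
        r = j - (q - (q % 2)) // 2
        return np.column_stack([q, r])


@dataclass
class BinGraph:
    """Non-empty hexagonal bins with expressions, members, and adjacency."""

    centers: np.ndarray  # (m, 2) bin centres
    axial: np.ndarray  # (m, 2) axial lattice coordinates
    expression: np.ndarray  # (m, n_markers) mean marker vector per bin
    n_cells: np.ndarray  # (m,) member counts
    cell_bin: np.ndarray  # per pooled cell: bin id 0..m-1
    marker_names: tuple[str, ...]
    edges: set[tuple[int, int]] = field(default_factory=set)
    edge_kind: dict[tuple[int, int], str] = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return self.centers.shape[0]

    def neighbors(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in range(self.n_bins)]
        for a, b in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj


def run_tsne(
    table: CellTable,
    perplexity: float = 60.0,
    theta: float = 0.5,
    iterations: int = 2000,
    seed: int = 0,
) -> Embedding:
    """Embed cells in 2-D with Barnes-Hut t-SNE.

    ``theta`` is the Barnes-Hut accuracy/speed trade-off (sklearn's
    ``angle``). Deterministic for a fixed seed and sklearn version.
    """
    if table.n_cells < 3 * perplexity + 1:
        raise ArgumentError(
            f"t-SNE needs > 3 * perplexity cells ({int(3 * perplexity) + 1}); "
            f"got {table.n_cells}. Reduce perplexity for small inputs."
        )
    from sklearn.manifold import TSNE

    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        angle=theta,
        max_iter=iterations,
        init="pca",
        method="barnes_hut",
        random_state=seed,
        n_jobs=1,
    )
    coords = tsne.fit_transform(table.values)
    params = {
        "perplexity": perplexity,
        "theta": theta,
        "iterations": iterations,
        "seed": seed,
    }
    return Embedding(coords=np.asarray(coords, dtype=np.float64), params=params)


def read_embedding(path: str | Path) -> Embedding:
    """Read a (cell_id, x, y) TSV; any externally supplied 2-D map works."""
    df = pd.read_csv(path, sep="\t")
    return Embedding(coords=df[["x", "y"]].to_numpy(), params={"source": str(path)})


def write_embedding(emb: Embedding, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "cell_id": np.arange(emb.n_cells),
            "x": emb.coords[:, 0],
            "y": emb.coords[:, 1],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def build_hexgrid(emb: Embedding, target_bins: int = 10000) -> HexGrid:
    """Tile the embedding's bounding box with ~target_bins equal hexagons.

    The radius is chosen so that (columns x rows) of the flat-top offset
    tiling approximates ``target_bins``; the bounding box is padded by one
    hex radius so boundary points fall strictly inside the tiling.
    """
    if target_bins < 1:
        raise ArgumentError("target_bins must be >= 1")
    coords = emb.coords
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    width, height = hi - lo

    if width <= 0 and height <= 0:
        warnings.warn("all embedding points coincide; using a single bin", stacklevel=2)
        grid = HexGrid(
            hex_radius=1.0,
            origin=lo.astype(float),
            n_cols=1,
            n_rows=1,
            bin_index=np.zeros(emb.n_cells, dtype=np.int64),
        )
        return grid
    # degenerate 1-D clouds get a nominal extent so the tiling has area
    width = max(width, 1e-9)
    height = max(height, 1e-9)

    radius = float(np.sqrt(width * height / (1.5 * SQRT3 * target_bins)))
    pad = radius
    n_cols = int(np.ceil((width + 2 * pad) / (1.5 * radius))) + 1
    n_rows = int(np.ceil((height + 2 * pad) / (SQRT3 * radius))) + 1
    origin = np.array([lo[0] - pad, lo[1] - pad], dtype=float)

    grid = HexGrid(
        hex_radius=radius,
        origin=origin,
        n_cols=n_cols,
        n_rows=n_rows,
        bin_index=np.empty(emb.n_cells, dtype=np.int64),
    )
    centers = grid.center_of(np.arange(grid.n_positions))
    tree = cKDTree(centers)
    _, nearest = tree.query(coords, k=1)
    grid.bin_index = nearest.astype(np.int64)
    logger.info(
        "hex grid: radius %.4g, %d x %d = %d positions (target %d)",
        radius,
        n_cols,
        n_rows,
        grid.n_positions,
        target_bins,
    )
    return grid


def compute_bin_graph(grid: HexGrid, table: CellTable) -> BinGraph:
    """Collapse cells into non-empty bins with mean ('bin expression') vectors."""
    if grid.bin_index.shape[0] != table.n_cells:
        raise ArgumentError("grid assignment does not cover the cell table")
    occupied, inverse, counts = np.unique(
        grid.bin_index, return_inverse=True, return_counts=True
    )
    m = occupied.size
    expr = np.zeros((m, table.n_markers))
    np.add.at(expr, inverse, table.values)
    expr /= counts[:, None]
    return BinGraph(
        centers=grid.center_of(occupied),
        axial=grid.axial_of(occupied),
        expression=expr,
        n_cells=counts.astype(np.int64),
        cell_bin=inverse.astype(np.int64),
        marker_names=table.marker_names,
    )


def build_adjacency(graph: BinGraph) -> BinGraph:
    """Add border edges between lattice-neighbour bins, plus fallback edges.

    A bin whose six lattice neighbours are all empty gains exactly one
    nearest-fallback edge to the closest non-empty bin (ties broken by the
    lowest bin id), so no vertex is isolated.
    """
    m = graph.n_bins
    graph.edges = set()
    graph.edge_kind = {}
    if m <= 1:
        if m == 1:
            warnings.warn("single-bin graph has no adjacency edges", stacklevel=2)
        return graph

    index = {(int(q), int(r)): i for i, (q, r) in enumerate(graph.axial)}
    for i, (q, r) in enumerate(graph.axial):
        for dq, dr in AXIAL_NEIGHBORS:
            j = index.get((int(q) + dq, int(r) + dr))
            if j is not None and j > i:
                e = (i, j)
                graph.edges.add(e)
                graph.edge_kind[e] = "border"

    degree = np.zeros(m, dtype=int)
    for a, b in graph.edges:
        degree[a] += 1
        degree[b] += 1
    isolated = np.flatnonzero(degree == 0)
    if isolated.size:
        tree = cKDTree(graph.centers)
        for i in isolated:
            # k=2: nearest other bin; tie-break toward the lowest bin id
            dists, idxs = tree.query(graph.centers[i], k=min(m, 8))
            dists, idxs = np.atleast_1d(dists), np.atleast_1d(idxs)
            others = idxs[idxs != i]
            odists = dists[idxs != i]
            best = odists.min()
            j = int(others[np.isclose(odists, best)].min())
            i = int(i)
            e = (min(i, j), max(i, j))
            if e not in graph.edges:
                graph.edges.add(e)
                graph.edge_kind[e] = "nearest-fallback"
    return graph


def write_bin_graph(graph: BinGraph, bins_path: str | Path, edges_path: str | Path) -> None:
    bins_df = pd.DataFrame(
        {
            "bin_id": np.arange(graph.n_bins),
            "cx": graph.centers[:, 0],
            "cy": graph.centers[:, 1],
            "n_cells": graph.n_cells,
        }
    )
    for k, name in enumerate(graph.marker_names):
        bins_df[name] = graph.expression[:, k]
    bins_df.to_csv(bins_path, sep="\t", index=False, float_format="%.8g")
    edges = sorted(graph.edges)
    pd.DataFrame(
        {
            "id_a": [a for a, _ in edges],
            "id_b": [b for _, b in edges],
            "kind": [graph.edge_kind[e] for e in edges],
        }
    ).to_csv(edges_path, sep="\t", index=False)
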