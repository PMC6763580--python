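"""Generators for CyTOF-like cohorts with known ground truth.

Cells are drawn from a shared mixture of Gaussian populations on the asinh
scale (diagonal covariance — the simplest model that exercises the
clustering), with cohort- and timepoint-dependent population frequencies,
stimulation-induced shifts of functional markers, and an optional planted
association between functional markers and stunting. Every generated value
is a deterministic function of the seed.

Default scale mirrors the study design: ~6,000 cells per sample, 23
markers, 8-12 populations, Bangladeshi HAZ scores straddling the -1.5
stunting threshold, and screen group sizes of 5 American / 8 non-stunted /
8 more-stunted samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from adjclust.embed_hexbin import AXIAL_NEIGHBORS, BinGraph
from adjclust.errors import ArgumentError
from adjclust.io_prep import CellTable, MarkerPanel, SampleMeta
from adjclust.stunting import HazGroups

__all__ = [
    "PopulationSpec",
    "CohortSpec",
    "default_panel",
    "default_populations",
    "simulate_cohort",
    "plant_haz_effect",
    "make_fixture_bingraph",
    "simulate_screen_features",
]


@dataclass(frozen=True)
class PopulationSpec:
    """One cell population: Gaussian mean/spread per marker plus effects."""

    name: str
    mean: tuple[float, ...]
    spread: tuple[float, ...]
    baseline_freq: float
    #: (location, week) -> log-fold change of this population's frequency
    abundance_logfc: dict = field(default_factory=dict)
    #: marker name -> additive shift under PMA-ionomycin stimulation
    stim_shift: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.mean) != len(self.spread):
            raise ArgumentError(f"population {self.name}: mean/spread length mismatch")
        if any(s <= 0 for s in self.spread):
            raise ArgumentError(f"population {self.name}: spreads must be > 0")
        if self.baseline_freq <= 0:
            raise ArgumentError(f"population {self.name}: baseline_freq must be > 0")


@dataclass(frozen=True)
class CohortSpec:
    """Study layout: donors per location/week, conditions, HAZ distribution."""

    #: (location, week) -> number of donors
    n_donors: dict
    conditions: tuple[str, ...] = ("unstim",)
    haz_mean: float = -1.5
    haz_sd: float = 1.0
    haz_range: tuple[float, float] = (-4.0, 1.5)

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_donors.values()):
            raise ArgumentError("n_donors must be >= 1 per location/week")
        if self.haz_sd <= 0:
            raise ArgumentError("haz_sd must be > 0")


def default_panel(n_markers: int = 23, cofactor: float = 5.0) -> MarkerPanel:
    names = tuple(f"M{i + 1:02d}" for i in range(n_markers))
    return MarkerPanel(marker_names=names, cofactor=cofactor)


def default_populations(
    n_pops: int = 8,
    n_markers: int = 23,
    separation: float = 8.0,
    spread: float = 0.3,
    base: float = 0.5,
) -> list[PopulationSpec]:
    """Well-separated populations, each elevating its own 2-marker block.

    Pairwise mean distance between any two populations is
    ``separation * spread`` (each differs from every other in two of its own
    markers and two of the other's), mimicking mutually exclusive lineage
    markers.
    """
    if 2 * n_pops > n_markers:
        raise ArgumentError("need at least 2 markers per population")
    high = base + separation * spread / 2.0
    pops = []
    for i in range(n_pops):
        mean = np.full(n_markers, base)
        mean[2 * i : 2 * i + 2] = high
        pops.append(
            PopulationSpec(
                name=f"pop{i}",
                mean=tuple(mean),
                spread=(spread,) * n_markers,
                baseline_freq=1.0 / n_pops,
            )
        )
    return pops


def _sample_frequencies(
    pops: list[PopulationSpec], location: str, week: str
) -> np.ndarray:
    f = np.array(
        [
            p.baseline_freq * np.exp(p.abundance_logfc.get((location, week), 0.0))
            for p in pops
        ]
    )
    return f / f.sum()


def simulate_cohort(
    spec: CohortSpec,
    pops: list[PopulationSpec],
    cells_per_sample: int = 6000,
    seed: int = 0,
    marker_names: tuple[str, ...] | None = None,
) -> tuple[list[CellTable], list[SampleMeta], list[np.ndarray]]:
    """Simulate per-sample cell tables with ground-truth population labels.

    For each donor and condition, population counts are multinomial with the
    effect-adjusted frequencies and cell values are Gaussian around the
    population mean (plus any stimulation shift for stimulated samples).
    Returns (tables, metadata, per-table true population index arrays).
    """
    if not pops:
        raise ArgumentError("at least one population is required")
    n_markers = len(pops[0].mean)
    if any(len(p.mean) != n_markers for p in pops):
        raise ArgumentError("populations disagree on marker count")
    names = marker_names or tuple(f"M{i + 1:02d}" for i in range(n_markers))
    marker_idx = {m: i for i, m in enumerate(names)}
    rng = np.random.default_rng(seed)

    tables: list[CellTable] = []
    metas: list[SampleMeta] = []
    truths: list[np.ndarray] = []
    for (location, week), n_donors in sorted(spec.n_donors.items()):
        for d in range(n_donors):
            donor_id = f"{location}-w{week}-d{d:02d}"
            if location == "Bangladesh":
                haz = float(
                    np.clip(
                        rng.normal(spec.haz_mean, spec.haz_sd),
                        spec.haz_range[0],
                        spec.haz_range[1],
                    )
                )
            else:
                haz = None
            freqs = _sample_frequencies(pops, location, week)
            for cond in spec.conditions:
                counts = rng.multinomial(cells_per_sample, freqs)
                values = np.empty((cells_per_sample, n_markers))
                labels = np.empty(cells_per_sample, dtype=np.int64)
                row = 0
                for k, (p, c) in enumerate(zip(pops, counts)):
                    mean = np.array(p.mean, dtype=float)
                    if cond != "unstim":
                        for m, shift in p.stim_shift.items():
                            mean[marker_idx[m]] += shift
                    values[row : row + c] = rng.normal(
                        mean, np.array(p.spread), size=(c, n_markers)
                    )
                    labels[row : row + c] = k
                    row += c
                sid = f"{donor_id}-{cond}"
                tables.append(
                    CellTable(
                        values=values,
                        marker_names=names,
                        sample_id=np.full(cells_per_sample, sid, dtype=object),
                        transformed=True,
                    )
                )
                metas.append(
                    SampleMeta(
                        sample_id=sid,
                        donor_id=donor_id,
                        location=location,
                        week=str(week),
                        condition=cond,
                        sex=("F" if d % 2 else "M"),
                        ethnicity=("South-Asian" if location == "Bangladesh" else "mixed"),
                        cmv_status=("pos" if (location == "Bangladesh") != (d % 3 == 0) else "neg"),
                        haz=haz,
                        batch_set=f"set{d % 2 + 1}",
                    )
                )
                truths.append(labels)
    return tables, metas, truths


def plant_haz_effect(
    tables: list[CellTable],
    metas: list[SampleMeta],
    truths: list[np.ndarray],
    markers: tuple[str, ...],
    effect_sd: float,
    populations: tuple[int, ...] | None = None,
    also_american: bool = True,
) -> list[CellTable]:
    """Plant a stunting-linked elevation of functional markers.

    For stimulated samples of more-stunted donors (HAZ <= -1.5) — and, by
    default, of American donors, emulating the high baseline of these
    markers in American children — the listed markers are shifted upward by
    ``effect_sd`` within-population SD units in the selected populations
    (all populations when None).
    """
    out = []
    for table, meta, labels in zip(tables, metas, truths):
        missing = [m for m in markers if m not in table.marker_names]
        if missing:
            raise ArgumentError(f"unknown markers: {missing}")
        stunted = (
            meta.location == "Bangladesh"
            and meta.haz is not None
            and meta.haz <= -1.5
        )
        target = meta.condition != "unstim" and (
            stunted or (also_american and meta.location == "USA")
        )
        if not target or effect_sd == 0:
            out.append(table)
            continue
        values = table.values.copy()
        in_pop = (
            np.isin(labels, populations) if populations is not None else np.ones(len(labels), bool)
        )
        for m in markers:
            j = table.marker_names.index(m)
            col_sd = values[in_pop, j].std(ddof=1) or 1.0
            values[in_pop, j] += effect_sd * col_sd
        out.append(
            CellTable(
                values=values,
                marker_names=table.marker_names,
                sample_id=table.sample_id.copy(),
                transformed=table.transformed,
            )
        )
    return out


def make_fixture_bingraph(
    axial: np.ndarray,
    expression: np.ndarray,
    n_cells: np.ndarray | None = None,
    marker_names: tuple[str, ...] | None = None,
    hex_radius: float = 1.0,
) -> BinGraph:
    """Hand-specified small bin graph on a hexagonal lattice (<= 200 bins).

    Centres derive from the axial coordinates; border adjacency is computed
    by direct lattice-neighbour enumeration. Intended for clustering
    oracle fixtures.
    """
    axial = np.asarray(axial, dtype=np.int64)
    expression = np.asarray(expression, dtype=float)
    m = axial.shape[0]
    if m > 200:
        raise ArgumentError("fixture graphs are capped at 200 bins")
    if expression.shape[0] != m:
        raise ArgumentError("expression rows must match bin count")
    if n_cells is None:
        n_cells = np.ones(m, dtype=np.int64)
    sqrt3 = np.sqrt(3.0)
    centers = np.column_stack(
        [
            1.5 * hex_radius * axial[:, 0],
            sqrt3 * hex_radius * (axial[:, 1] + axial[:, 0] / 2.0),
        ]
    )
    names = marker_names or tuple(f"M{i + 1:02d}" for i in range(expression.shape[1]))
    cell_bin = np.repeat(np.arange(m), n_cells)
    graph = BinGraph(
        centers=centers,
        axial=axial,
        expression=expression,
        n_cells=np.asarray(n_cells, dtype=np.int64),
        cell_bin=cell_bin,
        marker_names=names,
    )
    index = {(int(q), int(r)): i for i, (q, r) in enumerate(axial)}
    for i, (q, r) in enumerate(axial):
        for dq, dr in AXIAL_NEIGHBORS:
            j = index.get((int(q) + dq, int(r) + dr))
            if j is not None and j > i:
                graph.edges.add((i, j))
                graph.edge_kind[(i, j)] = "border"
    return graph


def simulate_screen_features(
    n_features: int = 50,
    n0: int = 5,
    n1: int = 8,
    n2: int = 8,
    planted: tuple[int, ...] = (),
    effect_sd: float = 0.0,
    correlated_share: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, HazGroups]:
    """Sample-level feature table for screen tests, with known truth.

    Baseline features are independent standard normal. The ``planted``
    features form one correlated block (a shared per-sample factor with
    weight ``correlated_share``, emulating the same marker measured across
    several cell populations) elevated by ``effect_sd`` SD units in groups 0
    and 2 relative to group 1 — the signature of a stunting-associated
    stimulated marker that is also high in American children.
    """
    rng = np.random.default_rng(seed)
    n = n0 + n1 + n2
    x = rng.normal(size=(n, n_features))
    if planted:
        factor = rng.normal(size=n)
        for j in planted:
            x[:, j] = (
                np.sqrt(correlated_share) * factor
                + np.sqrt(1 - correlated_share) * rng.normal(size=n)
            )
        lifted = np.r_[np.ones(n0), np.zeros(n1), np.ones(n2)].astype(bool)
        x[np.ix_(lifted, list(planted))] += effect_sd

    ids = (
        [f"usa{i:02d}" for i in range(n0)]
        + [f"bgd{i:02d}" for i in range(n1 + n2)]
    )
    features = pd.DataFrame(
        x, index=ids, columns=[f"feat{j:02d}" for j in range(n_features)]
    )
    haz1 = rng.uniform(-1.4, 1.0, size=n1)
    haz2 = rng.uniform(-3.5, -1.5, size=n2)
    haz = {s: 0.0 for s in ids[:n0]}
    haz.update({s: float(h) for s, h in zip(ids[n0 : n0 + n1], haz1)})
    haz.update({s: float(h) for s, h in zip(ids[n0 + n1 :], haz2)})
    groups = HazGroups(
        group0=tuple(ids[:n0]),
        group1=tuple(ids[n0 : n0 + n1]),
        group2=tuple(ids[n0 + n1 :]),
        haz=haz,
    )
    return features, groups
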