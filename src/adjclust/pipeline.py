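"""Stage orchestration: prep -> embed -> cluster -> stats -> screen.

Every stage writes plain TSV/YAML artifacts so any stage can be replaced by
an external tool (e.g. a pre-computed embedding); the run manifest records
seeds, parameters, per-stage row counts and content hashes of every output,
so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from adjclust import clustering, embed_hexbin, group_stats, io_prep, stunting
from adjclust.errors import ArgumentError

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """All pipeline parameters; defaults follow the study design."""

    input_dir: str = "."
    out_dir: str = "out"
    seed: int = 0
    # prep
    apply_transform: bool = False
    cofactor: float = 5.0
    qc_min_cells: int = 3000
    cells_per_sample: int = 6000
    n_reference: int = 30000
    reference_file: str | None = None
    markers: list[str] | None = None
    weights: dict[str, float] | None = None
    # embed
    embedding_file: str | None = None
    perplexity: float = 60.0
    theta: float = 0.5
    iterations: int = 2000
    # cluster
    target_bins: int = 10000
    k: int = 28
    min_cells: int = 1500
    # stats
    grouping: str = "location"
    stratify: str = "week"
    covariates: tuple[str, ...] = (
        "batch_set",
        "week",
        "location",
        "ethnicity",
        "sex",
        "cmv_status",
    )
    # screen
    run_screen: bool = False
    functional_markers: list[str] | None = None
    positive_cutoff: float = 1.0
    n_perm: int = 5000
    theta_grid: tuple[float, ...] = stunting.DEFAULT_THETA_GRID
    extras: dict = field(default_factory=dict)


def validate_config(config: RunConfig) -> list[str]:
    """Range and consistency checks; returns a list of violations (empty = ok)."""
    v = []
    if config.perplexity <= 0:
        v.append("perplexity must be > 0")
    if config.k < 1:
        v.append("k must be >= 1")
    if config.min_cells < 1:
        v.append("min_cells must be >= 1")
    if config.n_perm < 1:
        v.append("n_perm must be >= 1")
    if config.target_bins < 1:
        v.append("target_bins must be >= 1")
    if config.cells_per_sample < 1:
        v.append("cells_per_sample must be >= 1")
    if config.cofactor <= 0:
        v.append("cofactor must be > 0")
    if config.weights:
        for marker, w in config.weights.items():
            if w < 0:
                v.append(f"negative weight for marker {marker}")
    if config.iterations < 250:
        v.append("iterations must be >= 250")
    return v


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    extras = {k: v for k, v in raw.items() if k not in known}
    kwargs = {k: v for k, v in raw.items() if k in known}
    if "theta_grid" in kwargs:
        kwargs["theta_grid"] = tuple(kwargs["theta_grid"])
    if "covariates" in kwargs:
        kwargs["covariates"] = tuple(kwargs["covariates"])
    cfg = RunConfig(**kwargs)
    cfg.extras = extras
    return cfg


def save_config(config: RunConfig, path: str | Path) -> None:
    data = asdict(config)
    data["theta_grid"] = list(config.theta_grid)
    data["covariates"] = list(config.covariates)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _panel_for(table: io_prep.CellTable, config: RunConfig) -> io_prep.MarkerPanel:
    names = tuple(table.marker_names)
    weights = tuple((config.weights or {}).get(m, 1.0) for m in names)
    return io_prep.MarkerPanel(marker_names=names, weights=weights, cofactor=config.cofactor)


def functional_features(
    cell_labels: np.ndarray,
    sample_ids: np.ndarray,
    values: np.ndarray,
    marker_names: tuple[str, ...],
    markers: list[str],
    cutoff: float = 1.0,
    exclude: tuple[str, ...] = (io_prep.REFERENCE_SAMPLE_ID,),
) -> pd.DataFrame:
    """Per-sample positive fractions of functional markers within clusters.

    Feature "c<k>.<marker>+" is the fraction of a sample's cells in cluster
    k whose (transformed) marker value exceeds ``cutoff`` — the screen's
    population x marker functional frequency.
    """
    df = pd.DataFrame({"sample": sample_ids, "cluster": cell_labels})
    keep = ~df["sample"].isin(exclude)
    rows: dict[str, dict[str, float]] = {}
    midx = [marker_names.index(m) for m in markers]
    for (sample, cluster), grp in df[keep].groupby(["sample", "cluster"], sort=True):
        sub = values[grp.index.to_numpy()]
        for m, j in zip(markers, midx):
            rows.setdefault(str(sample), {})[f"c{cluster}.{m}+"] = float(
                np.mean(sub[:, j] > cutoff)
            )
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    return out.fillna(0.0).sort_index(axis=1)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run manifest."""
    violations = validate_config(config)
    if violations:
        raise ArgumentError("invalid configuration: " + "; ".join(violations))
    in_dir = Path(config.input_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta_path = in_dir / "metadata.tsv"
    if not meta_path.exists():
        raise OSError(f"metadata file not found: {meta_path}")

    manifest: dict = {
        "seed": config.seed,
        "stages": [],
        "outputs": {},
        "params_hash": hashlib.sha256(
            yaml.safe_dump(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
    }

    def record(stage: str, **counts) -> None:
        manifest["stages"].append({"stage": stage, **counts})
        logger.info("stage %s done: %s", stage, counts)

    def register(path: Path) -> None:
        manifest["outputs"][path.name] = _sha256(path)

    # ---- prep ----------------------------------------------------------
    metas = io_prep.read_metadata(meta_path)
    tables = []
    kept_metas = []
    for meta in metas:
        sample_path = in_dir / f"{meta.sample_id}.tsv"
        if not sample_path.exists():
            raise OSError(f"sample file not found: {sample_path}")
        table = io_prep.read_cells(sample_path, sample_id=meta.sample_id)
        panel = _panel_for(table, config)
        if config.apply_transform:
            table = io_prep.asinh_transform(table, panel)
        else:
            table.transformed = True
        if not io_prep.qc_filter(table, config.qc_min_cells):
            continue
        table = io_prep.downsample(table, config.cells_per_sample, seed=config.seed)
        if config.markers:
            table, panel = io_prep.select_markers(table, panel, config.markers)
        tables.append(table)
        kept_metas.append(meta)
    if not tables:
        raise ArgumentError("no samples passed QC")
    reference = None
    if config.reference_file:
        reference = io_prep.read_cells(in_dir / config.reference_file)
        ref_panel = _panel_for(reference, config)
        if config.apply_transform:
            reference = io_prep.asinh_transform(reference, ref_panel)
        else:
            reference.transformed = True
        if config.markers:
            reference, _ = io_prep.select_markers(reference, ref_panel, config.markers)
    pooled = io_prep.pool_cells(
        tables, reference=reference, n_reference=config.n_reference, seed=config.seed
    )
    panel = _panel_for(pooled, config)
    record("prep", samples=len(tables), pooled_cells=pooled.n_cells)

    # ---- embed ---------------------------------------------------------
    if config.embedding_file:
        emb = embed_hexbin.read_embedding(in_dir / config.embedding_file)
        if emb.n_cells != pooled.n_cells:
            raise ArgumentError("supplied embedding does not match pooled cell count")
    else:
        emb = embed_hexbin.run_tsne(
            pooled,
            perplexity=config.perplexity,
            theta=config.theta,
            iterations=config.iterations,
            seed=config.seed,
        )
    emb_path = out_dir / "embedding.tsv"
    embed_hexbin.write_embedding(emb, emb_path)
    register(emb_path)
    record("embed", cells=emb.n_cells)

    # ---- cluster -------------------------------------------------------
    grid = embed_hexbin.build_hexgrid(emb, target_bins=config.target_bins)
    graph = embed_hexbin.compute_bin_graph(grid, pooled)
    graph = embed_hexbin.build_adjacency(graph)
    d = clustering.pairwise_distances(graph, panel)
    history = clustering.constrained_complete_linkage(d, graph)
    assign = clustering.cut_tree(history, min(config.k, graph.n_bins))
    assign = clustering.enforce_min_size(
        assign, history, graph, min_cells=config.min_cells, d=d
    )
    assign = clustering.propagate_to_cells(assign, graph)

    bins_path, edges_path = out_dir / "bins.tsv", out_dir / "edges.tsv"
    embed_hexbin.write_bin_graph(graph, bins_path, edges_path)
    labels_df = pd.DataFrame(
        {
            "cell_id": np.arange(pooled.n_cells),
            "sample_id": pooled.sample_id,
            "cluster": assign.cell_to_cluster,
        }
    )
    labels_path = out_dir / "labels.tsv"
    labels_df.to_csv(labels_path, sep="\t", index=False)
    merges_path = out_dir / "merges.tsv"
    pd.DataFrame([vars(m) for m in history.merges]).to_csv(
        merges_path, sep="\t", index=False, float_format=FLOAT_FMT
    )
    for p in (bins_path, edges_path, labels_path, merges_path):
        register(p)
    record("cluster", bins=graph.n_bins, k=assign.k)

    # ---- stats ---------------------------------------------------------
    occ = group_stats.compute_occupancy(assign.cell_to_cluster, pooled.sample_id)
    occ_path = out_dir / "occupancy.tsv"
    occ.to_csv(occ_path, sep="\t", float_format=FLOAT_FMT)
    register(occ_path)
    meta_df = pd.DataFrame([vars(m) for m in kept_metas])
    tests = group_stats.test_occupancy(
        occ, meta_df, grouping=config.grouping, stratify=config.stratify
    )
    tests_path = out_dir / "occupancy_tests.tsv"
    group_stats.results_frame(tests).to_csv(
        tests_path, sep="\t", index=False, float_format=FLOAT_FMT
    )
    register(tests_path)
    n_var = 0
    try:
        scores = group_stats.pca_occupancy(occ)
        partition = group_stats.manova_partition(
            scores, meta_df, covariates=config.covariates
        )
        var_path = out_dir / "variance_partition.tsv"
        pd.DataFrame([vars(p) for p in partition]).to_csv(
            var_path, sep="\t", index=False, float_format=FLOAT_FMT
        )
        register(var_path)
        n_var = len(partition)
    except ArgumentError as exc:
        logger.warning("variance partition skipped: %s", exc)
    record("stats", tests=len(tests), covariates=n_var)

    # ---- screen --------------------------------------------------------
    if config.run_screen:
        func_markers = config.functional_markers or list(pooled.marker_names)
        feats = functional_features(
            assign.cell_to_cluster,
            pooled.sample_id,
            pooled.values,
            pooled.marker_names,
            func_markers,
            cutoff=config.positive_cutoff,
        )
        groups = stunting.assign_groups(meta_df)
        screen = stunting.permutation_screen(
            feats,
            groups,
            theta_grid=config.theta_grid,
            n_perm=config.n_perm,
            seed=config.seed,
        )
        screen_path = out_dir / "screen.tsv"
        screen.to_csv(screen_path, sep="\t", index=False, float_format=FLOAT_FMT)
        register(screen_path)
        cand = stunting.candidates(screen)
        cand_path = out_dir / "candidates.tsv"
        cand.to_csv(cand_path, sep="\t", index=False, float_format=FLOAT_FMT)
        register(cand_path)
        record("screen", features=feats.shape[1], candidates=len(cand))

    manifest_path = out_dir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
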