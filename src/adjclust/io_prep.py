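"""Cytometry input, QC, transforms, subsampling, marker selection, pooling.

The in-memory unit is a :class:`CellTable` (cells x markers matrix with a
per-cell sample identifier and a transform flag). Upstream gating (live,
intact, singlet) is assumed done; the QC rule here is the post-gating cell
count floor of 3,000 cells per sample, below which a sample is discarded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from adjclust.errors import ArgumentError, SchemaError, StateError
from adjclust.fcs import read_fcs, write_fcs

logger = logging.getLogger(__name__)

#: reserved column name for the per-cell sample identifier in tabular files
SAMPLE_ID_COLUMN = "sample_id"

#: sample_id assigned to pooled healthy-adult reference cells
REFERENCE_SAMPLE_ID = "adult-reference"


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered marker channels with clustering weights and transform cofactor.

    ``weights`` are the per-marker w_i of the weighted bin distance
    d(p,q) = sqrt(sum_i w_i (p_i - q_i)^2); markers with weight 0 are carried
    through transforms but do not influence clustering. ``cofactor`` is the
    asinh scaling constant (5 is the community standard for CyTOF).
    """

    marker_names: tuple[str, ...]
    weights: tuple[float, ...] = ()
    cofactor: float = 5.0
    role_tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        names = tuple(str(n) for n in self.marker_names)
        object.__setattr__(self, "marker_names", names)
        weights = tuple(float(w) for w in (self.weights or (1.0,) * len(names)))
        object.__setattr__(self, "weights", weights)
        tags = tuple(self.role_tags or ("phenotype",) * len(names))
        object.__setattr__(self, "role_tags", tags)
        if len(weights) != len(names):
            raise ArgumentError("weights length must equal marker count")
        if len(tags) != len(names):
            raise ArgumentError("role_tags length must equal marker count")
        if any(w < 0 for w in weights):
            raise ArgumentError("marker weights must be nonnegative")
        if len(names) and not any(w > 0 for w in weights):
            raise ArgumentError("at least one marker weight must be positive")
        if not self.cofactor > 0:
            raise ArgumentError("cofactor must be positive")

    @property
    def n_markers(self) -> int:
        return len(self.marker_names)

    def subset(self, markers: list[str]) -> "MarkerPanel":
        unknown = [m for m in markers if m not in self.marker_names]
        if unknown:
            raise SchemaError(f"markers not in panel: {unknown}")
        idx = [self.marker_names.index(m) for m in markers]
        return MarkerPanel(
            marker_names=tuple(self.marker_names[i] for i in idx),
            weights=tuple(self.weights[i] for i in idx),
            cofactor=self.cofactor,
            role_tags=tuple(self.role_tags[i] for i in idx),
        )


@dataclass
class CellTable:
    """Cells x markers matrix with per-cell sample ids and transform state."""

    values: np.ndarray
    marker_names: tuple[str, ...]
    sample_id: np.ndarray
    transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ArgumentError("values must be a 2-D cells x markers matrix")
        self.marker_names = tuple(str(n) for n in self.marker_names)
        if self.values.shape[1] != len(self.marker_names):
            raise SchemaError("marker axis does not match marker_names")
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        if self.sample_id.shape != (self.values.shape[0],):
            raise SchemaError("sample_id must have one entry per cell")
        if not np.all(np.isfinite(self.values)):
            raise SchemaError("cell values must be finite with no missing entries")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.marker_names))
        df.insert(0, SAMPLE_ID_COLUMN, self.sample_id)
        return df


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample clinical/experimental metadata."""

    sample_id: str
    donor_id: str
    location: str  # Bangladesh | USA | adult-reference
    week: str  # 53 | 104 | 156 | adult
    condition: str  # unstim | PMA-ionomycin
    sex: str = "unknown"
    ethnicity: str = "unknown"
    cmv_status: str = "unknown"  # pos | neg | unknown
    haz: float | None = None
    batch_set: str = "set1"


def read_metadata(path: str | Path) -> list[SampleMeta]:
    """Read a metadata TSV with the SampleMeta columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "donor_id", "location", "week", "condition"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise SchemaError(f"metadata file {path} missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise SchemaError(f"duplicate sample_id in metadata: {dups}")
    out = []
    for row in df.to_dict("records"):
        haz = row.get("haz")
        haz_val = None if haz in (None, "", "NA", "nan") else float(haz)
        out.append(
            SampleMeta(
                sample_id=row["sample_id"],
                donor_id=row["donor_id"],
                location=row["location"],
                week=str(row["week"]),
                condition=row["condition"],
                sex=row.get("sex") or "unknown",
                ethnicity=row.get("ethnicity") or "unknown",
                cmv_status=row.get("cmv_status") or "unknown",
                haz=haz_val,
                batch_set=row.get("batch_set") or "set1",
            )
        )
    return out


def write_metadata(metas: list[SampleMeta], path: str | Path) -> None:
    pd.DataFrame([vars(m) for m in metas]).to_csv(path, sep="\t", index=False)


def read_cells(
    path: str | Path,
    format: str = "auto",
    sample_id: str | None = None,
    panel: MarkerPanel | None = None,
) -> CellTable:
    """Read one sample's cells from FCS 3.x or a delimited table.

    Tabular files carry one header row of marker names and may include a
    reserved ``sample_id`` column; FCS files take their sample id from
    ``sample_id`` (default: the file stem). When a ``panel`` is given, its
    markers must all be present (error names the absent ones); extra columns
    are kept.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"cannot read cell data: {path} does not exist")
    if format == "auto":
        format = "fcs" if path.suffix.lower() == ".fcs" else "tabular"

    if format == "fcs":
        values, names = read_fcs(path)
        sid = sample_id if sample_id is not None else path.stem
        table = CellTable(
            values=values,
            marker_names=tuple(names),
            sample_id=np.full(values.shape[0], sid, dtype=object),
        )
    elif format == "tabular":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep)
        except Exception as exc:  # noqa: BLE001 - surfaced with path context
            raise OSError(f"cannot parse {path} as a delimited table: {exc}") from exc
        if SAMPLE_ID_COLUMN in df.columns:
            sids = df.pop(SAMPLE_ID_COLUMN).astype(str).to_numpy(dtype=object)
        else:
            sid = sample_id if sample_id is not None else path.stem
            sids = np.full(len(df), sid, dtype=object)
        table = CellTable(
            values=df.to_numpy(dtype=np.float64),
            marker_names=tuple(df.columns),
            sample_id=sids,
        )
    else:
        raise ArgumentError(f"unknown format {format!r}; use 'fcs' or 'tabular'")

    if panel is not None:
        absent = [m for m in panel.marker_names if m not in table.marker_names]
        if absent:
            raise SchemaError(f"{path} is missing panel markers: {absent}")
    return table


def write_cells(table: CellTable, path: str | Path, format: str = "auto") -> None:
    """Write a CellTable as a TSV/CSV (with sample_id column) or FCS file."""
    path = Path(path)
    if format == "auto":
        format = "fcs" if path.suffix.lower() == ".fcs" else "tabular"
    if format == "fcs":
        write_fcs(path, table.values, list(table.marker_names))
    elif format == "tabular":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        table.to_frame().to_csv(path, sep=sep, index=False, float_format="%.8g")
    else:
        raise ArgumentError(f"unknown format {format!r}")


def asinh_transform(table: CellTable, panel: MarkerPanel) -> CellTable:
    """Apply x -> asinh(x / cofactor) to every marker value."""
    if table.transformed:
        raise StateError("table is already asinh-transformed")
    return CellTable(
        values=np.arcsinh(table.values / panel.cofactor),
        marker_names=table.marker_names,
        sample_id=table.sample_id.copy(),
        transformed=True,
    )


def qc_filter(table: CellTable, min_cells: int = 3000) -> bool:
    """Keep-or-discard decision: discard iff the sample has < min_cells cells."""
    keep = table.n_cells >= min_cells
    sid = table.sample_id[0] if table.n_cells else "<empty>"
    logger.info(
        "QC %s: %d cells (floor %d) -> %s",
        sid,
        table.n_cells,
        min_cells,
        "keep" if keep else "discard",
    )
    return keep


def downsample(table: CellTable, n: int, seed: int) -> CellTable:
    """Draw n cells uniformly without replacement (all cells if fewer)."""
    if n <= 0:
        raise ArgumentError(f"downsample size must be >= 1, got {n}")
    if table.n_cells <= n:
        if table.n_cells < n:
            warnings.warn(
                f"sample has only {table.n_cells} cells (< {n}); keeping all",
                stacklevel=2,
            )
        return replace(table, values=table.values.copy(), sample_id=table.sample_id.copy())
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(table.n_cells, size=n, replace=False))
    return replace(table, values=table.values[idx], sample_id=table.sample_id[idx])


def pool_cells(
    samples: list[CellTable],
    reference: CellTable | None = None,
    n_reference: int = 30000,
    seed: int = 0,
) -> CellTable:
    """Concatenate sample cells, plus n_reference cells from a reference pool.

    The reference cells keep (or are given) the ``adult-reference`` sample id
    so occupancy computations can exclude them later.
    """
    if not samples:
        raise ArgumentError("no sample tables to pool")
    panel_names = samples[0].marker_names
    state = samples[0].transformed
    parts = []
    for t in samples:
        if t.marker_names != panel_names:
            raise SchemaError("marker panels differ across pooled tables")
        if t.transformed != state:
            raise SchemaError("mixed transform states across pooled tables")
        parts.append(t)
    if reference is not None:
        if reference.marker_names != panel_names:
            raise SchemaError("reference panel differs from sample panel")
        if reference.transformed != state:
            raise SchemaError("reference transform state differs from samples")
        ref = downsample(reference, min(n_reference, reference.n_cells), seed=seed)
        ref = replace(
            ref,
            sample_id=np.full(ref.n_cells, REFERENCE_SAMPLE_ID, dtype=object),
        )
        parts.append(ref)
    pooled = CellTable(
        values=np.vstack([t.values for t in parts]),
        marker_names=panel_names,
        sample_id=np.concatenate([t.sample_id for t in parts]),
        transformed=state,
    )
    logger.info("pooled %d tables -> %d cells", len(parts), pooled.n_cells)
    return pooled


def select_markers(
    table: CellTable, panel: MarkerPanel, subset: list[str]
) -> tuple[CellTable, MarkerPanel]:
    """Restrict and reorder columns to ``subset``; weights follow along."""
    unknown = [m for m in subset if m not in table.marker_names]
    if unknown:
        raise SchemaError(f"unknown markers requested: {unknown}")
    sub_panel = panel.subset(list(subset))
    idx = [table.marker_names.index(m) for m in subset]
    sub_table = CellTable(
        values=table.values[:, idx],
        marker_names=tuple(subset),
        sample_id=table.sample_id.copy(),
        transformed=table.transformed,
    )
    return sub_table, sub_panel
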