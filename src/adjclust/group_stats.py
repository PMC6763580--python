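"""Cluster occupancy statistics and variance partitioning.

Occupancy of cluster c in sample s is the fraction of s's cells that fall
in c. Per timepoint, group differences in occupancy are tested cluster by
cluster with two-sided Mann-Whitney tests and Benjamini-Hochberg correction
across clusters within the timepoint. Sample-level occupancy profiles are
summarised by PCA (retaining all but the final dimension) and the retained
scores are partitioned over clinical covariates with a type-II MANOVA:
each covariate's Pillai trace, a Pillai-derived partial eta-squared
(V / s, with s = min(term df, number of responses)), and the Pillai F
approximation p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from adjclust.errors import ArgumentError
from adjclust.io_prep import REFERENCE_SAMPLE_ID

__all__ = [
    "OccupancyTestResult",
    "VariancePartition",
    "compute_occupancy",
    "occupancy_ratio",
    "test_occupancy",
    "pca_occupancy",
    "manova_partition",
]


@dataclass(frozen=True)
class OccupancyTestResult:
    cluster_id: object
    week: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    fdr: float
    ratio: float  # mean occupancy group A / mean occupancy group B


@dataclass(frozen=True)
class VariancePartition:
    covariate: str
    pillai: float
    partial_eta2: float
    p_value: float
    df_term: int


def compute_occupancy(
    cell_labels: np.ndarray,
    sample_ids: np.ndarray,
    exclude: tuple[str, ...] = (REFERENCE_SAMPLE_ID,),
) -> pd.DataFrame:
    """Samples x clusters table of per-sample cell fractions (rows sum to 1).

    Reference-pool cells (``exclude`` sample ids) contribute no rows but
    their clusters remain as columns, so a cluster occupied only by the
    adult reference shows occupancy 0 for every sample.
    """
    cell_labels = np.asarray(cell_labels)
    sample_ids = np.asarray(sample_ids)
    if cell_labels.shape != sample_ids.shape:
        raise ArgumentError("cell_labels and sample_ids must align")
    counts = pd.crosstab(pd.Series(sample_ids, name="sample_id"),
                         pd.Series(cell_labels, name="cluster"))
    counts = counts.drop(index=[s for s in exclude if s in counts.index])
    empty = counts.index[counts.sum(axis=1) == 0]
    if len(empty):
        warnings.warn(f"samples with zero cells excluded: {list(empty)}", stacklevel=2)
        counts = counts.drop(index=empty)
    occ = counts.div(counts.sum(axis=1), axis=0)
    return occ


def occupancy_ratio(
    occ: pd.DataFrame, group_a: list[str], group_b: list[str]
) -> pd.Series:
    """Per-cluster mean occupancy of group A over group B (NaN when 0/0)."""
    a = [s for s in group_a if s in occ.index]
    b = [s for s in group_b if s in occ.index]
    if not a or not b:
        raise ArgumentError("both groups must contain at least one sample")
    mean_a = occ.loc[a].mean(axis=0)
    mean_b = occ.loc[b].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mean_a / mean_b
    ratio[(mean_a == 0) & (mean_b == 0)] = np.nan
    return ratio


def test_occupancy(
    occ: pd.DataFrame,
    meta: pd.DataFrame,
    grouping: str = "location",
    stratify: str = "week",
    group_levels: tuple[str, str] | None = None,
) -> list[OccupancyTestResult]:
    """Per-stratum, per-cluster two-sided Mann-Whitney tests with BH.

    ``meta`` is indexed (or indexable) by sample_id with at least the
    grouping and stratification columns. BH correction is applied within
    each stratum across its clusters. Exact null distribution is used when
    scipy deems it feasible (small groups, no ties), else the normal
    approximation with continuity and tie correction.
    """
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    meta = meta.loc[[s for s in occ.index if s in meta.index]]
    levels = group_levels or tuple(sorted(meta[grouping].unique()))[:2]
    if len(levels) < 2:
        raise ArgumentError("grouping must have two levels to compare")

    results: list[OccupancyTestResult] = []
    for week, sub in meta.groupby(stratify, sort=True):
        a_ids = sub.index[sub[grouping] == levels[0]]
        b_ids = sub.index[sub[grouping] == levels[1]]
        if len(a_ids) < 2 or len(b_ids) < 2:
            warnings.warn(
                f"stratum {week!r}: group sizes {len(a_ids)}/{len(b_ids)} too small; skipped",
                stacklevel=2,
            )
            continue
        pvals, stats_u, ratios = [], [], []
        for cluster in occ.columns:
            x = occ.loc[a_ids, cluster].to_numpy()
            y = occ.loc[b_ids, cluster].to_numpy()
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
            pvals.append(res.pvalue)
            stats_u.append(res.statistic)
            mb = y.mean()
            ratios.append(x.mean() / mb if mb > 0 else (np.nan if x.mean() == 0 else np.inf))
        _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
        for cluster, u, p, q, r in zip(occ.columns, stats_u, pvals, fdr, ratios):
            results.append(
                OccupancyTestResult(
                    cluster_id=cluster,
                    week=str(week),
                    n_a=len(a_ids),
                    n_b=len(b_ids),
                    u_statistic=float(u),
                    p_value=float(p),
                    fdr=float(q),
                    ratio=float(r),
                )
            )
    return results


def results_frame(
    results: list[OccupancyTestResult],
    flag_thresholds: tuple[float, ...] = (0.1, 0.05, 0.01, 0.001),
) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in results])
    if len(df):
        df["significance"] = [
            "".join("*" for t in flag_thresholds if q < t) for q in df["fdr"]
        ]
    return df


def pca_occupancy(occ: pd.DataFrame) -> pd.DataFrame:
    """Centered PCA of the occupancy matrix, retaining all but the last
    non-trivial dimension (rank - 1 components)."""
    x = occ.to_numpy(dtype=float)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ArgumentError("PCA needs at least 2 samples and 2 clusters")
    xc = x - x.mean(axis=0)
    rank = np.linalg.matrix_rank(xc)
    # rows sum to 1, so the final dimension carries no variance: drop it
    n_keep = max(min(x.shape[1] - 1, rank), 1)
    if rank < min(x.shape[0] - 1, x.shape[1] - 1):
        warnings.warn(
            f"occupancy matrix is rank-deficient (rank {rank}); retaining {n_keep} PCs",
            stacklevel=2,
        )
    from sklearn.decomposition import PCA

    pca = PCA(n_components=n_keep, svd_solver="full")
    scores = pca.fit_transform(xc)
    return pd.DataFrame(
        scores, index=occ.index, columns=[f"PC{i + 1}" for i in range(n_keep)]
    )


def _design_columns(meta: pd.DataFrame, covariates: list[str]) -> dict[str, np.ndarray]:
    """Per-covariate design blocks; categoricals are dummy-coded (drop-first)."""
    blocks: dict[str, np.ndarray] = {}
    for cov in covariates:
        col = meta[cov]
        if col.dtype.kind in "ifu" and col.nunique() > 8:
            blocks[cov] = col.to_numpy(dtype=float)[:, None]
        else:
            dummies = pd.get_dummies(col.astype(str), drop_first=True, dtype=float)
            if dummies.shape[1] == 0:
                raise ArgumentError(f"covariate {cov!r} has a single level")
            blocks[cov] = dummies.to_numpy()
    return blocks


def _pillai_f(v: float, q: int, p: int, df_e: int) -> tuple[float, float, float, float]:
    """Pillai trace F approximation: returns (F, df1, df2, p-value)."""
    s = min(q, p)
    m = (abs(p - q) - 1) / 2.0
    nn = (df_e - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    if df2 <= 0 or v >= s:
        return np.nan, df1, df2, np.nan
    f = (df2 / df1) * (v / (s - v))
    return f, df1, df2, float(stats.f.sf(f, df1, df2))


def manova_partition(
    scores: pd.DataFrame,
    meta: pd.DataFrame,
    covariates: tuple[str, ...] = (
        "batch_set",
        "week",
        "location",
        "ethnicity",
        "sex",
        "cmv_status",
    ),
) -> list[VariancePartition]:
    """Type-II MANOVA of PC scores on clinical covariates (Pillai tests).

    For each covariate T the hypothesis SSCP is the drop in residual SSCP
    between the model without T and the full additive model (type-II sums,
    appropriate for an additive model with no interactions). Reported per
    covariate: Pillai trace V, partial eta^2 = V / s with
    s = min(df_T, n_responses), and the Pillai F-approximation p-value.
    """
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    meta = meta.loc[scores.index]
    covs = [c for c in covariates if c in meta.columns and meta[c].nunique() > 1]
    if not covs:
        raise ArgumentError("no usable covariates with more than one level")
    y = scores.to_numpy(dtype=float)
    n, p = y.shape
    blocks = _design_columns(meta, covs)

    def fit_sscp(cols: list[str]) -> tuple[np.ndarray, int]:
        x = np.hstack([np.ones((n, 1))] + [blocks[c] for c in cols])
        rank = np.linalg.matrix_rank(x)
        if rank < x.shape[1]:
            raise ArgumentError(
                f"collinear covariates in design: {cols} (rank {rank} < {x.shape[1]})"
            )
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        return resid.T @ resid, rank

    e_full, rank_full = fit_sscp(covs)
    df_e = n - rank_full
    if df_e <= 0:
        raise ArgumentError("not enough samples for the requested model")

    out: list[VariancePartition] = []
    for cov in covs:
        others = [c for c in covs if c != cov]
        if others:
            e_red, _ = fit_sscp(others)
        else:
            yc = y - y.mean(axis=0)
            e_red = yc.T @ yc
        h = e_red - e_full
        q = blocks[cov].shape[1]
        try:
            v = float(np.trace(h @ np.linalg.inv(h + e_full)))
        except np.linalg.LinAlgError:
            v = float(np.trace(np.linalg.lstsq(h + e_full, h, rcond=None)[0]))
        s = min(q, p)
        _, _, _, pval = _pillai_f(v, q, p, df_e)
        out.append(
            VariancePartition(
                covariate=cov,
                pillai=v,
                partial_eta2=float(np.clip(v / s, 0.0, 1.0)),
                p_value=pval,
                df_term=q,
            )
        )
    return out
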