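"""Permutation screen for associations between stunting and immune function.

Samples are split into three groups by height-for-age z-score (HAZ):
American children (group 0, HAZ imputed as 0), non-stunted Bangladeshi
children (group 1, HAZ > -1.5) and more-stunted Bangladeshi children
(group 2, HAZ <= -1.5). For each functional feature i (a cell-population x
marker positive fraction) the screen considers the event

    (mu_i0 - mu_i1) / s_i0 >= theta   and   (mu_i2 - mu_i1) / s_i2 >= theta

where mu_ij is the mean of feature i in group j and s_ij is the two-sample
pooled standard deviation of group j with group 1. The null distribution
comes from permuting HAZ scores among the Bangladeshi samples (the American
pseudo-HAZ of 0 is a constant and stays fixed) and re-deriving groups 1/2;
per-feature permutation p-values use the (1 + B) / (1 + N) estimator and
the per-theta FDR is the plug-in ratio of mean null event counts to
observed event counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from adjclust.errors import ArgumentError
from adjclust.io_prep import SampleMeta

__all__ = [
    "HazGroups",
    "ValidationResult",
    "STUNTING_HAZ_THRESHOLD",
    "condition_filter",
    "assign_groups",
    "pooled_sd",
    "event_statistic",
    "permutation_screen",
    "candidates",
    "validate_pc1",
    "validate_marker",
    "combine_pvalues",
]

#: HAZ at or below this value defines the "more stunted" group
STUNTING_HAZ_THRESHOLD = -1.5

DEFAULT_THETA_GRID = tuple(float(x) for x in np.round(np.arange(0.0, 2.0 + 1e-9, 0.1), 10))


@dataclass(frozen=True)
class HazGroups:
    """Disjoint screen groups: American / non-stunted / more-stunted."""

    group0: tuple[str, ...]  # American, HAZ treated as 0
    group1: tuple[str, ...]  # Bangladeshi, HAZ > -1.5
    group2: tuple[str, ...]  # Bangladeshi, HAZ <= -1.5
    haz: dict[str, float] | None = None


@dataclass(frozen=True)
class ValidationResult:
    marker: str
    pc1_variance_share: float
    p_train: float
    p_valid: float
    p_combined: float


def condition_filter(
    feature_table: pd.DataFrame, condition_labels: pd.Series, seed: int = 0
) -> list[str]:
    """Samples whose k-means (k=2) cluster matches their declared condition.

    Feature vectors are z-scored per feature before clustering; each of the
    two clusters is mapped to the stimulation condition of the majority of
    its members, and samples landing in the wrong cluster are dropped.
    """
    labels = condition_labels.loc[feature_table.index]
    x = feature_table.to_numpy(dtype=float)
    sd = x.std(axis=0)
    if not np.any(sd > 0):
        warnings.warn("feature vectors are identical; retaining all samples", stacklevel=2)
        return list(feature_table.index)
    xz = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    cl = km.fit_predict(xz)
    mapping = {}
    for c in (0, 1):
        members = labels[cl == c]
        if len(members) == 0:
            continue
        mapping[c] = members.mode().iloc[0]
    keep = [
        s for s, c, lab in zip(feature_table.index, cl, labels) if mapping.get(c) == lab
    ]
    return keep


def assign_groups(metas: list[SampleMeta] | pd.DataFrame) -> HazGroups:
    """Three-way HAZ grouping; Bangladeshi samples lacking HAZ are dropped."""
    if isinstance(metas, pd.DataFrame):
        records = metas.reset_index().to_dict("records")
    else:
        records = [vars(m) for m in metas]
    g0, g1, g2 = [], [], []
    haz_map: dict[str, float] = {}
    for rec in records:
        sid = str(rec["sample_id"])
        loc = rec["location"]
        haz = rec.get("haz")
        if loc == "USA":
            g0.append(sid)
            haz_map[sid] = 0.0
        elif loc == "Bangladesh":
            if haz is None or (isinstance(haz, float) and np.isnan(haz)):
                warnings.warn(f"Bangladeshi sample {sid} has no HAZ; excluded", stacklevel=2)
                continue
            haz = float(haz)
            haz_map[sid] = haz
            (g2 if haz <= STUNTING_HAZ_THRESHOLD else g1).append(sid)
    return HazGroups(group0=tuple(g0), group1=tuple(g1), group2=tuple(g2), haz=haz_map)


def pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample pooled SD with df weights."""
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ArgumentError("pooled SD needs >= 2 samples per group")
    va = np.var(a, ddof=1)
    vb = np.var(b, ddof=1)
    return float(np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)))


def event_statistic(
    values0: np.ndarray, values1: np.ndarray, values2: np.ndarray, theta: float
) -> dict:
    """Evaluate the two-sided standardized event for one feature.

    Returns means, pooled SDs, both standardized differences and the event
    flag (None when a pooled SD is zero, making the event undefined).
    """
    v0 = np.asarray(values0, dtype=float)
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    mu0, mu1, mu2 = v0.mean(), v1.mean(), v2.mean()
    s0 = pooled_sd(v0, v1)
    s2 = pooled_sd(v2, v1)
    if s0 == 0 or s2 == 0:
        return {
            "mu": (mu0, mu1, mu2),
            "s0": s0,
            "s2": s2,
            "d0": np.nan,
            "d2": np.nan,
            "event": None,
        }
    d0 = (mu0 - mu1) / s0
    d2 = (mu2 - mu1) / s2
    return {
        "mu": (mu0, mu1, mu2),
        "s0": s0,
        "s2": s2,
        "d0": d0,
        "d2": d2,
        "event": bool(d0 >= theta and d2 >= theta),
    }


def _group_moments(m: np.ndarray, x: np.ndarray, x2: np.ndarray, n: int):
    """Mean and unbiased variance per permutation row of membership matrix m."""
    mu = (m @ x) / n
    ss = m @ x2
    var = (ss - n * mu**2) / (n - 1)
    np.maximum(var, 0.0, out=var)
    return mu, var


def permutation_screen(
    features: pd.DataFrame,
    groups: HazGroups,
    theta_grid: tuple[float, ...] = DEFAULT_THETA_GRID,
    n_perm: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the HAZ permutation screen over all features and thresholds.

    Returns one row per (feature, theta) with the observed group means,
    pooled SDs, standardized differences, event flag, permutation p-value
    and the per-theta plug-in permutation FDR.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives unstable p/FDR estimates", stacklevel=2)
    idx0 = [s for s in groups.group0 if s in features.index]
    idx1 = [s for s in groups.group1 if s in features.index]
    idx2 = [s for s in groups.group2 if s in features.index]
    if len(idx0) < 2 or len(idx1) < 2 or len(idx2) < 2:
        raise ArgumentError("each screen group needs at least 2 samples with features")
    x0 = features.loc[idx0].to_numpy(dtype=float)
    bang = idx1 + idx2
    xb = features.loc[bang].to_numpy(dtype=float)
    haz_vals = np.array([groups.haz[s] for s in bang]) if groups.haz else None
    if haz_vals is None:
        raise ArgumentError("HazGroups must carry HAZ values for permutation")
    n0, n1, n2 = len(idx0), len(idx1), len(idx2)
    nb = n1 + n2
    n_feat = features.shape[1]

    # fixed group-0 moments
    mu0 = x0.mean(axis=0)
    var0 = x0.var(axis=0, ddof=1)

    rng = np.random.default_rng(seed)
    xb2 = xb**2
    # row 0 is the observed assignment; rows 1..n_perm are permutations
    member2 = np.zeros((n_perm + 1, nb), dtype=float)
    member2[0, n1:] = 1.0
    for b in range(1, n_perm + 1):
        perm = rng.permutation(nb)
        stunted = haz_vals[perm] <= STUNTING_HAZ_THRESHOLD
        member2[b, stunted] = 1.0
    member1 = 1.0 - member2

    mu1, var1 = _group_moments(member1, xb, xb2, n1)
    mu2, var2 = _group_moments(member2, xb, xb2, n2)
    s0 = np.sqrt(((n0 - 1) * var0[None, :] + (n1 - 1) * var1) / (n0 + n1 - 2))
    s2 = np.sqrt(((n2 - 1) * var2 + (n1 - 1) * var1) / (n2 + n1 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        d0 = (mu0[None, :] - mu1) / s0
        d2 = (mu2 - mu1) / s2

    rows = []
    names = list(features.columns)
    for theta in theta_grid:
        ev = (d0 >= theta) & (d2 >= theta)  # NaN comparisons are False
        obs = ev[0]
        null_counts = ev[1:].sum(axis=1)  # events per permutation
        per_feat = ev[1:].sum(axis=0)  # permutations where the feature fires
        perm_p = (1.0 + per_feat) / (1.0 + n_perm)
        n_obs = int(obs.sum())
        fdr_theta = (
            min(float(null_counts.mean()) / n_obs, 1.0) if n_obs > 0 else np.nan
        )
        undefined = ~np.isfinite(d0[0]) | ~np.isfinite(d2[0])
        for f in range(n_feat):
            rows.append(
                {
                    "feature": names[f],
                    "theta": float(theta),
                    "mu0": mu0[f],
                    "mu1": mu1[0, f],
                    "mu2": mu2[0, f],
                    "s0": s0[0, f],
                    "s2": s2[0, f],
                    "d0": d0[0, f],
                    "d2": d2[0, f],
                    "event": (None if undefined[f] else bool(obs[f])),
                    "perm_p": float(perm_p[f]),
                    "perm_fdr": fdr_theta,
                }
            )
    return pd.DataFrame(rows)


def candidates(
    screen: pd.DataFrame,
    p_cutoff: float = 0.05,
    fdr_cutoff: float = 0.2,
    theta: float | None = None,
) -> pd.DataFrame:
    """Features passing the event + p + FDR cuts.

    With ``theta`` given, the cut is applied at that threshold only; by
    default a feature qualifies if it passes at any threshold in the grid
    (best-over-grid mode), reported with the largest qualifying theta.
    """
    df = screen[screen["event"] == True]  # noqa: E712 - event may be None
    df = df[(df["perm_p"] <= p_cutoff) & (df["perm_fdr"] <= fdr_cutoff)]
    if theta is not None:
        return df[df["theta"] == theta].reset_index(drop=True)
    if df.empty:
        return df.reset_index(drop=True)
    best = df.sort_values("theta").groupby("feature", sort=True).tail(1)
    return best.sort_values("feature").reset_index(drop=True)


def validate_pc1(
    matrix: pd.DataFrame, stunted: pd.Series | np.ndarray
) -> tuple[float, float]:
    """One-sided PC1 regression: does the marker rise with stunting?

    ``matrix`` holds one column per cell population measuring the same
    marker. PC1 of the centered columns (oriented to correlate positively
    with the per-sample mean, so "higher" means higher expression) is
    regressed on the stunted indicator; returns (PC1 variance share,
    one-sided p for a positive group effect). A single column reduces to a
    one-sided two-sample t-test on that column.
    """
    x = matrix.to_numpy(dtype=float)
    g = np.asarray(stunted, dtype=float)
    if x.shape[0] != g.shape[0] or x.shape[0] < 3:
        raise ArgumentError("need >= 3 aligned samples for PC1 validation")
    xc = x - x.mean(axis=0)
    if x.shape[1] == 1:
        pc1 = xc[:, 0]
        share = 1.0
    else:
        u, sv, vt = np.linalg.svd(xc, full_matrices=False)
        pc1 = u[:, 0] * sv[0]
        share = float(sv[0] ** 2 / np.sum(sv**2))
        if np.corrcoef(pc1, xc.mean(axis=1))[0, 1] < 0:
            pc1 = -pc1
    # OLS of PC1 on the group indicator; one-sided t for beta > 0
    gc = g - g.mean()
    denom = np.sum(gc**2)
    if denom == 0:
        raise ArgumentError("stunted indicator is constant")
    beta = np.sum(gc * pc1) / denom
    resid = pc1 - beta * gc - pc1.mean()
    df = len(pc1) - 2
    se = np.sqrt(np.sum(resid**2) / df / denom)
    t = beta / se if se > 0 else np.inf
    p = float(stats.t.sf(t, df))
    return share, p


def validate_marker(
    marker: str,
    train: pd.DataFrame,
    train_stunted: pd.Series | np.ndarray,
    valid: pd.DataFrame,
    valid_stunted: pd.Series | np.ndarray,
) -> ValidationResult:
    """Train + validation PC1 tests for one marker, Fisher-combined."""
    share, p_train = validate_pc1(train, train_stunted)
    _, p_valid = validate_pc1(valid, valid_stunted)
    return ValidationResult(
        marker=marker,
        pc1_variance_share=share,
        p_train=p_train,
        p_valid=p_valid,
        p_combined=combine_pvalues(p_train, p_valid),
    )


def combine_pvalues(p_train: float, p_valid: float) -> float:
    """Fisher's method: -2(ln p1 + ln p2) ~ chi-square with 4 df."""
    ps = []
    for p in (p_train, p_valid):
        if not 0 <= p <= 1:
            raise ArgumentError(f"p-value out of range: {p}")
        if p == 0:
            warnings.warn("p-value of 0 clipped to float tiny", stacklevel=2)
            p = np.finfo(float).tiny
        ps.append(p)
    stat = -2.0 * (np.log(ps[0]) + np.log(ps[1]))
    return float(stats.chi2.sf(stat, df=4))
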