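"""Auxiliary statistics around the main model.

Moran's I (spatial autocorrelation diagnostic on per-region values, with a
seeded permutation p-value), Welch's two-sample t test, and the collinearity
screens applied to the region covariates before fitting: pairwise Pearson
correlation with an |r| > 0.6 flag, and variance inflation factors with a
VIF >= 4 flag.

Moran weights default to row-standardized inverse great-circle distance
between region centroids; a binary k-nearest-neighbour scheme is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CONTINUOUS_COVARIATES, CovariateTable

__all__ = [
    "SpatialWeights",
    "inverse_distance_weights",
    "knn_weights",
    "morans_i",
    "welch_t",
    "pearson_matrix",
    "vif",
]

_EARTH_RADIUS_KM = 6371.0


@dataclass
class SpatialWeights:
    """n x n non-negative weight matrix with zero diagonal."""

    w: np.ndarray
    scheme: str = "inverse-distance"
    row_standardized: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if np.any(np.diag(w) != 0):
            raise ValueError("weights must have a zero diagonal")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        self.w = w

    def row_standardize(self) -> "SpatialWeights":
        rs = self.w.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        return SpatialWeights(self.w / rs, scheme=self.scheme, row_standardized=True)


def _great_circle_km(lat, lon) -> np.ndarray:
    la = np.radians(np.asarray(lat, dtype=float))[:, None]
    lo = np.radians(np.asarray(lon, dtype=float))[:, None]
    dla = la - la.T
    dlo = lo - lo.T
    h = np.sin(dla / 2) ** 2 + np.cos(la) * np.cos(la.T) * np.sin(dlo / 2) ** 2
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def inverse_distance_weights(lat, lon, row_standardize: bool = True) -> SpatialWeights:
    """1/d great-circle weights between region centroids (default scheme)."""
    d = _great_circle_km(lat, lon)
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    w[~np.isfinite(w)] = 0.0
    sw = SpatialWeights(w, scheme="inverse-distance")
    return sw.row_standardize() if row_standardize else sw


def knn_weights(lat, lon, k: int = 4) -> SpatialWeights:
    """Binary k-nearest-neighbour weights, symmetrized."""
    d = _great_circle_km(lat, lon)
    n = d.shape[0]
    w = np.zeros((n, n))
    for i in range(n):
        order = np.argsort(d[i])
        nearest = [j for j in order if j != i][:k]
        w[i, nearest] = 1.0
    w = np.maximum(w, w.T)
    return SpatialWeights(w, scheme="binary-knn")


def morans_i(
    values, weights: SpatialWeights, n_perm: int = 9_999, seed: int = 0
) -> tuple[float, float]:
    """Moran's I with a one-sided (greater) permutation p-value.

    I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2.
    Returns (NaN, NaN) for constant values (undefined).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 values")
    w = weights.w
    if w.shape[0] != n:
        raise ValueError("weights dimension mismatch")
    dev = x - x.mean()
    denom = float(dev @ dev)
    if denom == 0.0:
        return float("nan"), float("nan")
    s0 = float(w.sum())

    def stat(d):
        return n / s0 * float(d @ w @ d) / float(d @ d)

    i_obs = stat(dev)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if stat(rng.permutation(dev)) >= i_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return i_obs, p


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's two-sample t test: (t, Welch–Satterthwaite df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("both samples are constant")
    res = stats.ttest_ind(x, y, equal_var=False)
    sx, sy = vx / x.size, vy / y.size
    df = (sx + sy) ** 2 / (sx**2 / (x.size - 1) + sy**2 / (y.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def pearson_matrix(
    covariates: CovariateTable | pd.DataFrame, threshold: float = 0.6
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Pairwise Pearson r between continuous covariates, flagging |r| > 0.6."""
    df = covariates.df if isinstance(covariates, CovariateTable) else covariates
    cols = [c for c in CONTINUOUS_COVARIATES if c in df.columns] or list(df.columns)
    sub = df[cols].astype(float)
    if len(sub) < 3:
        raise ValueError("need at least 3 regions")
    if (sub.std(ddof=1) == 0).any():
        raise ValueError("constant covariate in correlation screen")
    r = sub.corr(method="pearson")
    flags = [
        (cols[i], cols[j], float(r.iloc[i, j]))
        for i in range(len(cols))
        for j in range(i + 1, len(cols))
        if abs(r.iloc[i, j]) > threshold
    ]
    return r, flags


def vif(
    covariates: CovariateTable | pd.DataFrame, threshold: float = 4.0
) -> pd.DataFrame:
    """Variance inflation factor per covariate: 1 / (1 - R^2) from an
    intercept-augmented least-squares regression on the others. Perfect
    collinearity reports inf (flagged), not an error."""
    df = covariates.df if isinstance(covariates, CovariateTable) else covariates
    cols = [c for c in CONTINUOUS_COVARIATES if c in df.columns] or list(df.columns)
    X = df[cols].to_numpy(dtype=float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError("need more regions than covariates + 1")
    rows = []
    for j in range(k):
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        target = X[:, j]
        coef, *_ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        tss = float(((target - target.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / tss if tss > 0 else 1.0
        v = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"covariate": cols[j], "vif": v, "flag": v >= threshold})
    return pd.DataFrame(rows)
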