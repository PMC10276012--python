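"""Correlation screening and PCA of the size-normalized species trait table."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.decomposition import PCA as _SKPCA

__all__ = ["pearson_matrix", "pca", "PCAResult"]


def pearson_matrix(table: pd.DataFrame, min_n: int = 3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p (t transform, n-2 df).

    Pairwise deletion: each pair uses its complete rows. Pairs with fewer
    than ``min_n`` complete rows or a zero-variance column get NaN.
    """
    cols = list(table.columns)
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    for i in range(k):
        for j in range(i + 1, k):
            sub = table[[cols[i], cols[j]]].dropna()
            xi = sub.iloc[:, 0].to_numpy(float)
            xj = sub.iloc[:, 1].to_numpy(float)
            if len(sub) < min_n or np.ptp(xi) == 0 or np.ptp(xj) == 0:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = scipy.stats.pearsonr(xi, xj)
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
    return r, p


@dataclass
class PCAResult:
    """PCA of the trait table (listwise-complete rows).

    ``loadings`` is trait x component (orthonormal columns), ``scores`` is
    row x component, and scores @ loadings.T reconstructs the standardized
    (or merely centered) data. Component signs are fixed so each loading
    vector's largest-magnitude entry is positive.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    standardized: bool
    center: pd.Series
    scale: pd.Series | None


def pca(table: pd.DataFrame, standardize: bool = True) -> PCAResult:
    """PCA of the species trait table.

    With ``standardize`` (default) traits are z-scored first — i.e. the
    correlation-matrix PCA appropriate when traits mix units (s, cm, Hz,
    dimensionless). Rows with any missing value are dropped.
    """
    data = table.dropna()
    if data.shape[1] < 2:
        raise ValueError("need at least 2 traits")
    if data.shape[0] < 2:
        raise ValueError("need at least 2 complete rows")
    X = data.to_numpy(float)
    center = X.mean(axis=0)
    Xc = X - center
    scale = None
    if standardize:
        scale = X.std(axis=0, ddof=1)
        if np.any(scale == 0):
            raise ValueError("zero-variance trait; drop it or disable standardize")
        Xc = Xc / scale
    k = min(Xc.shape)
    sk = _SKPCA(n_components=k, svd_solver="full")
    scores = sk.fit_transform(Xc)
    load = sk.components_.T  # trait x component
    # deterministic sign: largest-|loading| entry of each component positive
    for c in range(load.shape[1]):
        jmax = int(np.argmax(np.abs(load[:, c])))
        if load[jmax, c] < 0:
            load[:, c] *= -1.0
            scores[:, c] *= -1.0
    ev = sk.explained_variance_
    ratio = ev / ev.sum()
    comp_names = [f"PC{i + 1}" for i in range(load.shape[1])]
    return PCAResult(
        loadings=pd.DataFrame(load, index=data.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=data.index, columns=comp_names),
        explained_variance=ev,
        explained_variance_ratio=ratio,
        standardized=standardize,
        center=pd.Series(center, index=data.columns),
        scale=pd.Series(scale, index=data.columns) if scale is not None else None,
    )
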