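"""Cell-population structure: MDS, PCA, and dispersion over time.

Ordination treats each cell's gene profile as a point; classical
(Torgerson) multidimensional scaling on correlation distance shows how the
cell population drifts through expression space over the time course, and
PCA attributes that drift to gene axes.  The coefficient of dispersion
(COD = median absolute deviation / median) of per-component scores,
computed per time point, summarises when the population is noisy and when
it is tight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalization import ExpressionMatrix

_MEDIAN_EPS = 1e-12


@dataclass
class OrdinationResult:
    """Low-dimensional cell coordinates with optional PCA extras.

    ``coords`` is cells x components; ``centroids`` the per-time-point mean
    coordinate.  ``var_explained`` and ``loadings`` are populated by PCA only.
    ``excluded`` lists cells dropped for constant profiles (undefined
    correlation).
    """

    coords: pd.DataFrame
    cell_meta: pd.DataFrame
    centroids: pd.DataFrame
    var_explained: np.ndarray | None = None
    loadings: pd.DataFrame | None = None
    excluded: list | None = None


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|entry| of each column positive."""
    flips = np.sign(vectors[np.abs(vectors).argmax(axis=0), np.arange(vectors.shape[1])])
    flips[flips == 0] = 1.0
    return flips


def _centroids(coords: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    return coords.groupby(meta["time_h"]).mean()


def classical_mds(distances: np.ndarray, n_dims: int = 2) -> np.ndarray:
    """Torgerson MDS of a symmetric distance matrix.

    Double-centers the squared distances, eigendecomposes the Gram matrix,
    and returns the top ``n_dims`` axes scaled by the square root of their
    (clipped-nonnegative) eigenvalues, with the deterministic sign
    convention.
    """
    D = np.asarray(distances, dtype=float)
    D2 = D**2
    n = D.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:n_dims]
    lam = np.clip(eigval[order], 0.0, None)
    coords = eigvec[:, order] * np.sqrt(lam)
    return coords * _fix_signs(coords)


def mds_embed(expr: ExpressionMatrix, n_dims: int = 2) -> OrdinationResult:
    """Classical MDS of cells under Pearson-correlation distance.

    Distance between two cells is 1 - Pearson correlation of their gene
    profiles.  The Torgerson double-centered Gram matrix is
    eigendecomposed and the top ``n_dims`` axes (scaled by sqrt eigenvalue)
    returned; coordinates are centered at the origin by construction.
    Cells with a constant profile have no defined correlation and are
    excluded (reported in ``excluded``).
    """
    X = expr.expr.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("MDS needs at least 3 cells")
    sd = X.std(axis=1)
    excluded = list(expr.expr.index[sd == 0])
    keep = sd > 0
    X = X[keep]
    index = expr.expr.index[keep]
    meta = expr.cell_meta.loc[index]

    D = 1.0 - np.corrcoef(X)
    coords = classical_mds(D, n_dims)
    cdf = pd.DataFrame(coords, index=index, columns=[f"MDS{i+1}" for i in range(n_dims)])
    return OrdinationResult(cdf, meta, _centroids(cdf, meta), excluded=excluded)


def pca(expr: ExpressionMatrix, k: int = 3) -> OrdinationResult:
    """Column-centered (unscaled) PCA of the cells x genes matrix.

    Genes share the unit expression scale, so no variance scaling is
    applied.  Returns scores, gene loadings, and the fraction of total
    variance per component, with the deterministic sign convention of
    :func:`mds_embed`.
    """
    X = expr.expr.to_numpy(dtype=float)
    n = X.shape[0]
    if n < k + 1:
        raise ValueError("need more cells than components")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((S > S[0] * 1e-12).sum()) if S.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    scores = U[:, :k] * S[:k]
    comps = Vt[:k].T  # genes x k
    flips = _fix_signs(scores)
    scores = scores * flips
    comps = comps * flips
    total_var = (S**2).sum()
    var_explained = (S[:k] ** 2) / total_var

    cols = [f"PC{i+1}" for i in range(k)]
    sdf = pd.DataFrame(scores, index=expr.expr.index, columns=cols)
    ldf = pd.DataFrame(comps, index=expr.expr.columns, columns=cols)
    return OrdinationResult(
        sdf,
        expr.cell_meta,
        _centroids(sdf, expr.cell_meta),
        var_explained=var_explained,
        loadings=ldf,
    )


def cod(values) -> float:
    """Coefficient of dispersion: MAD / |median| (MAD unscaled).

    Returns NaN (a flagged sentinel, never silently replaced) when the
    median is within 1e-12 of zero, where the ratio is undefined.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cod of empty vector")
    med = np.median(x)
    if abs(med) < _MEDIAN_EPS:
        return float("nan")
    mad = np.median(np.abs(x - med))
    return float(mad / abs(med))


def dispersion_by_time(ordination: OrdinationResult) -> pd.DataFrame:
    """COD of each component's score distribution at each time point.

    Rows are components, columns time points (hours).  Time points with a
    single cell are rejected.
    """
    meta = ordination.cell_meta
    times = np.sort(meta["time_h"].unique())
    out = pd.DataFrame(index=ordination.coords.columns, columns=times, dtype=float)
    for t in times:
        scores = ordination.coords.loc[meta["time_h"] == t]
        if len(scores) < 2:
            raise ValueError(f"time point {t} has fewer than 2 cells")
        for comp in scores.columns:
            out.loc[comp, t] = cod(scores[comp].to_numpy())
    return out
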