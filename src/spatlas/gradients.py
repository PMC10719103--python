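"""Cluster discreteness and spatial-gradient statistics.

Neighbourhood purity measures how discrete a cell cluster is: the fraction
of a cell's 50 nearest neighbours *in expression space* sharing its
cluster label.  Spatial gradients are quantified by correlating a 1-D
expression axis (PC1 or a diffusion pseudotime) with a per-cell spatial
coordinate such as cortical depth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse
import scipy.sparse.linalg
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import ExpressionMatrix


def _pca_embedding(expr: ExpressionMatrix, layer: str, n_dims: int) -> np.ndarray:
    x = expr.layer(layer)
    n_dims = min(n_dims, min(x.shape) - 1)
    if n_dims < 1:
        raise ValueError("need at least 2 cells and 2 genes")
    return PCA(n_components=n_dims, random_state=0).fit_transform(x - x.mean(axis=0))


def neighborhood_purity(expr: ExpressionMatrix, cluster_labels: pd.Series,
                        k: int = 50, layer: str = "lognorm",
                        n_pca: int = 50,
                        subclass_of: pd.Series | None = None) -> dict:
    """Per-cell purity plus cluster and subclass discreteness aggregates.

    Purity of a cell = fraction of its k expression-space nearest
    neighbours (in a PCA embedding) with the same cluster label.  Cluster
    discreteness = mean member purity; subclass discreteness = median of
    its clusters' discreteness.
    """
    if expr.n_cells < k + 1:
        k = expr.n_cells - 1
    emb = _pca_embedding(expr, layer, n_pca)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb)
    labels = cluster_labels.loc[expr.cells].to_numpy()
    purity = (labels[idx[:, 1:]] == labels[:, None]).mean(axis=1)
    purity = pd.Series(purity, index=expr.cells, name="purity")
    cluster_disc = purity.groupby(labels).mean()
    cluster_sizes = pd.Series(labels).value_counts()
    result = {
        "purity": purity,
        "cluster_discreteness": cluster_disc,
        "low_n_clusters": list(cluster_sizes[cluster_sizes < 2].index),
    }
    if subclass_of is not None:
        parents = subclass_of.loc[cluster_disc.index]
        result["subclass_discreteness"] = cluster_disc.groupby(parents.to_numpy()).median()
    return result


def expression_axis(expr: ExpressionMatrix, method: str = "pc1",
                    layer: str = "lognorm", n_pca: int = 50,
                    knn: int = 15, seed: int = 0) -> pd.Series:
    """One-dimensional expression axis per cell: PC1 score or pseudotime.

    PC1 orientation is fixed so the gene with the largest absolute loading
    has a positive loading.  Pseudotime is the first nontrivial diffusion
    component of a kNN transition kernel on the PCA embedding, oriented to
    correlate positively with PC1.  Both are centered.
    """
    x = expr.layer(layer)
    if np.allclose(x.var(axis=0), 0):
        raise ValueError("zero-variance expression data")
    pca = PCA(n_components=min(n_pca, min(x.shape) - 1), random_state=seed)
    emb = pca.fit_transform(x - x.mean(axis=0))
    loadings = pca.components_[0]
    sign = np.sign(loadings[np.argmax(np.abs(loadings))]) or 1.0
    pc1 = sign * emb[:, 0]
    if method == "pc1":
        axis = pc1
    elif method == "pseudotime":
        axis = _diffusion_component(emb, knn)
        r = np.corrcoef(axis, pc1)[0, 1]
        if np.isfinite(r) and r < 0:
            axis = -axis
    else:
        raise ValueError(f"unknown axis method {method!r}")
    axis = axis - axis.mean()
    return pd.Series(axis, index=expr.cells, name=method)


def _diffusion_component(emb: np.ndarray, knn: int) -> np.ndarray:
    """First nontrivial eigenvector of a symmetrized kNN diffusion kernel."""
    n = len(emb)
    k = min(knn, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    dist, idx = nn.kneighbors(emb)
    sigma = np.maximum(dist[:, -1], 1e-12)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()
    # adaptive Gaussian kernel on neighbour distances
    vals = np.exp(-(dist[:, 1:].ravel() ** 2) / (sigma[rows] * sigma[cols]))
    w = scipy.sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    w = (w + w.T) / 2
    d = np.asarray(w.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(np.maximum(d, 1e-12))
    m = scipy.sparse.diags(d_inv_sqrt) @ w @ scipy.sparse.diags(d_inv_sqrt)
    _, vecs = scipy.sparse.linalg.eigsh(m, k=2, which="LA")
    comp = vecs[:, 0] * d_inv_sqrt  # eigsh returns ascending order: [:,1] is trivial
    return comp


def gradient_correlation(axis_values: pd.Series | np.ndarray,
                         coordinate: pd.Series | np.ndarray) -> dict:
    """Pearson correlation of an expression axis with a spatial coordinate."""
    a = np.asarray(axis_values, dtype=float)
    c = np.asarray(coordinate, dtype=float)
    if a.size != c.size or a.size < 3:
        raise ValueError("need >= 3 aligned value pairs")
    if a.std() == 0 or c.std() == 0:
        return {"r": np.nan, "p": np.nan, "n": int(a.size)}
    r, p = sps.pearsonr(a, c)
    return {"r": float(r), "p": float(p), "n": int(a.size)}
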