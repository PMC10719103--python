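"""Anchor-based integration of an imaged query dataset with a labeled reference.

The pipeline follows the two-round scheme used for atlas-scale label
transfer: (i) subclasses of the reference are grouped into a configurable
number of integration partitions by balanced cuts of a subclass
connectivity graph; (ii) round one co-embeds reference and query by
diagonal-covariance CCA, finds mutual-nearest-neighbour anchors and
transfers partition labels with a plurality-fraction confidence; (iii)
round two repeats the embedding/anchor/transfer procedure within each
partition, on partition-specific highly variable genes, to transfer
subclass and cluster labels; confidences are multiplied by the partition
confidence.  Anchors also drive transcriptome-wide imputation as a
distance-weighted average over each query cell's nearest anchor reference
cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse.csgraph
import scipy.sparse
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.extmath import randomized_svd

from .config import AnalysisConfig
from .io import ExpressionMatrix

logger = logging.getLogger("spatlas")


# ---------------------------------------------------------------------------
# preprocessing

def preprocess_for_integration(expr: ExpressionMatrix, total: float = 1000.0
                               ) -> ExpressionMatrix:
    """Add ``lognorm`` (total -> 1000, log1p) and ``scaled`` (per-gene z) layers."""
    raw = expr.layer("raw")
    totals = raw.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if len(zero):
        raise ValueError(
            f"all-zero cells: {[expr.cells[i] for i in zero[:5]]}"
        )
    out = expr.copy()
    lognorm = np.log1p(raw / totals[:, None] * total)
    mu = lognorm.mean(axis=0)
    sd = lognorm.std(axis=0)
    # relative guard: float rounding gives constant genes sd ~ 1e-16 * mu
    varying = sd > 1e-12 * np.maximum(1.0, np.abs(mu))
    scaled = np.where(varying, (lognorm - mu) / np.where(varying, sd, 1.0), 0.0)
    out.layers["lognorm"] = lognorm
    out.layers["scaled"] = scaled
    return out


def select_hvg(expr: ExpressionMatrix, layer: str = "lognorm") -> list[str]:
    """Genes with positive normalized log dispersion (Seurat-style binning)."""
    import scanpy as sc
    import anndata

    if len(expr.genes) < 2:
        raise ValueError("need at least 2 genes")
    # flavor="seurat" expects log1p-transformed input
    adata = anndata.AnnData(
        X=expr.layer(layer).copy(),
        var=pd.DataFrame(index=pd.Index(expr.genes, name="gene")),
    )
    sc.pp.highly_variable_genes(
        adata, flavor="seurat", min_disp=0.0, max_disp=np.inf,
        min_mean=-np.inf, max_mean=np.inf,
    )
    return [g for g, hv in zip(expr.genes, adata.var["highly_variable"]) if hv]


# ---------------------------------------------------------------------------
# reference partitioning

@dataclass
class IntegrationPartitioning:
    assignment: dict[str, int]  # subclass -> partition id (0..K-1)
    graph: pd.DataFrame  # symmetric subclass x subclass edge-weight matrix
    cut_weight: float = 0.0

    @property
    def partitions(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for s, p in self.assignment.items():
            out.setdefault(p, []).append(s)
        return out


def subclass_connectivity(emb: np.ndarray, subclasses: np.ndarray, knn: int = 15
                          ) -> pd.DataFrame:
    """Subclass graph: edge weight = number of cross-subclass kNN edges."""
    names = sorted(set(subclasses))
    pos = {s: i for i, s in enumerate(names)}
    codes = np.array([pos[s] for s in subclasses])
    nn = NearestNeighbors(n_neighbors=min(knn, len(emb) - 1) + 1).fit(emb)
    _, idx = nn.kneighbors(emb)
    w = np.zeros((len(names), len(names)))
    for i, row in enumerate(idx):
        for j in row[1:]:
            a, b = codes[i], codes[j]
            if a != b:
                w[a, b] += 1
                w[b, a] += 1
    return pd.DataFrame(w, index=names, columns=names)


def _cut_weight(w: np.ndarray, side: np.ndarray) -> float:
    return float(w[np.ix_(side, ~side)].sum())


def _bisect(w: np.ndarray, weights: np.ndarray, n1: int, n2: int,
            frac: float, tol: float, rng: np.random.Generator) -> np.ndarray:
    """Split nodes into two sides holding >= n1 / n2 nodes, cell-weight
    fraction ~ ``frac`` on side one, minimizing the cut; spectral order +
    single-move refinement."""
    n = len(weights)
    if n == n1:  # forced: everything except n2 singles
        pass
    lap = scipy.sparse.csgraph.laplacian(scipy.sparse.csr_matrix(w))
    if n <= 2:
        order = np.arange(n)
    else:
        try:
            vals, vecs = scipy.sparse.linalg.eigsh(
                lap.asfptype(), k=2, which="SM",
                v0=rng.random(n),
            )
            fiedler = vecs[:, np.argsort(vals)[1]]
            order = np.argsort(fiedler, kind="stable")
        except Exception:  # tiny or ill-conditioned graphs
            order = np.argsort(weights)[::-1]
    total = weights.sum()
    target = frac * total
    # choose the split point along the spectral order closest to the target
    csum = np.cumsum(weights[order])
    valid = np.arange(n1, n - n2 + 1)
    split = valid[np.argmin(np.abs(csum[valid - 1] - target))]
    side = np.zeros(n, dtype=bool)
    side[order[:split]] = True

    # greedy refinement: move any node that lowers the cut within balance
    lo, hi = target * (1 - tol), target * (1 + tol)
    for _ in range(20):
        improved = False
        gains = w @ side - w @ ~side  # per-node preference for side one
        for i in np.argsort(-np.abs(gains)):
            new = side.copy()
            new[i] = not new[i]
            if new.sum() < n1 or (~new).sum() < n2:
                continue
            s1 = weights[new].sum()
            if not (lo <= s1 <= hi) and abs(s1 - target) >= abs(weights[side].sum() - target):
                continue
            if _cut_weight(w, new) < _cut_weight(w, side):
                side = new
                improved = True
        if not improved:
            break
    return side


def partition_reference(ref: ExpressionMatrix, subclasses: pd.Series,
                        k_partitions: int = 50, n_pca: int = 100,
                        knn: int = 15, balance_tol: float = 0.2,
                        seed: int = 0) -> IntegrationPartitioning:
    """Group subclasses into ``k_partitions`` balanced, low-cut partitions.

    PCA embedding of the scaled layer -> per-cell kNN graph -> subclass
    connectivity graph -> recursive spectral bisection with move
    refinement under a ±``balance_tol`` cell-count balance constraint.
    Deterministic under ``seed``.
    """
    from sklearn.decomposition import PCA

    labels = subclasses.loc[ref.cells].to_numpy()
    names = sorted(set(labels))
    if k_partitions > len(names):
        raise ValueError(
            f"k_partitions={k_partitions} exceeds {len(names)} subclasses"
        )
    x = ref.layer("scaled")
    n_pca = min(n_pca, min(x.shape) - 1)
    emb = PCA(n_components=n_pca, random_state=seed).fit_transform(x)
    graph = subclass_connectivity(emb, labels, knn=knn)
    w = graph.to_numpy()
    node_weights = pd.Series(labels).value_counts().reindex(names).to_numpy(float)
    rng = np.random.default_rng(seed)

    assignment = np.zeros(len(names), dtype=int)
    next_id = [0]

    def recurse(nodes: np.ndarray, k: int) -> None:
        if k == 1 or len(nodes) == 1:
            assignment[nodes] = next_id[0]
            next_id[0] += 1
            return
        k1 = k // 2
        k2 = k - k1
        side = _bisect(
            w[np.ix_(nodes, nodes)], node_weights[nodes],
            n1=k1, n2=k2, frac=k1 / k, tol=balance_tol, rng=rng,
        )
        recurse(nodes[side], k1)
        recurse(nodes[~side], k2)

    recurse(np.arange(len(names)), k_partitions)
    mapping = {s: int(assignment[i]) for i, s in enumerate(names)}
    part_of = np.array([mapping[s] for s in names])
    cut = float(sum(
        w[i, j] for i in range(len(names)) for j in range(i + 1, len(names))
        if part_of[i] != part_of[j]
    ))
    return IntegrationPartitioning(assignment=mapping, graph=graph, cut_weight=cut)


# ---------------------------------------------------------------------------
# CCA co-embedding and anchors

@dataclass
class CoEmbedding:
    ref: np.ndarray  # (n_ref, d) L2-normalized rows
    query: np.ndarray  # (n_query, d)


def cca_coembed(ref_scaled: np.ndarray, query_scaled: np.ndarray,
                n_dims: int = 100, max_fit_cells: int = 100000,
                seed: int = 0) -> CoEmbedding:
    """Co-embed two scaled cells-x-genes matrices by diagonal-covariance CCA.

    The canonical directions come from a truncated SVD of the cell-by-cell
    cross product of (possibly downsampled) matrices; all cells of both
    datasets are then projected through the induced linear maps from gene
    space, and each embedding row is L2-normalized.
    """
    a, b = np.asarray(ref_scaled, float), np.asarray(query_scaled, float)
    if a.shape[1] != b.shape[1]:
        raise ValueError("shared gene set mismatch between datasets")
    limit = min(a.shape[0], b.shape[0], a.shape[1])
    if n_dims > limit:
        raise ValueError(f"n_dims={n_dims} exceeds smallest dimension {limit}")
    rng = np.random.default_rng(seed)
    a_fit = a if len(a) <= max_fit_cells else a[rng.choice(len(a), max_fit_cells, replace=False)]
    b_fit = b if len(b) <= max_fit_cells else b[rng.choice(len(b), max_fit_cells, replace=False)]
    k = a_fit @ b_fit.T
    u, s, vt = randomized_svd(k, n_components=n_dims, random_state=seed)
    s = np.maximum(s, 1e-12)
    map_ref = b_fit.T @ vt.T / s  # genes -> CCA dims
    map_query = a_fit.T @ u / s

    def l2(x):
        norms = np.linalg.norm(x, axis=1, keepdims=True)
        return x / np.maximum(norms, 1e-12)

    return CoEmbedding(ref=l2(a @ map_ref), query=l2(b @ map_query))


@dataclass
class AnchorSet:
    pairs: np.ndarray  # (n_anchors, 2) of (ref index, query index)
    embedding: CoEmbedding

    @property
    def ref_cells(self) -> np.ndarray:
        """Unique anchor-participating reference cell indices."""
        return np.unique(self.pairs[:, 0])


def find_anchors(embedding: CoEmbedding, k: int = 5) -> AnchorSet:
    """Mutual cross-dataset nearest neighbours in the co-embedding."""
    r, q = embedding.ref, embedding.query
    if k >= len(r) or k >= len(q):
        raise ValueError(f"k={k} must be smaller than both dataset sizes")
    nn_q = NearestNeighbors(n_neighbors=k).fit(q)
    _, r_to_q = nn_q.kneighbors(r)  # for each ref cell: its k query neighbours
    nn_r = NearestNeighbors(n_neighbors=k).fit(r)
    _, q_to_r = nn_r.kneighbors(q)
    forward = {(i, j) for i, row in enumerate(r_to_q) for j in row}
    pairs = sorted(
        (i, j) for j, row in enumerate(q_to_r) for i in row if (i, j) in forward
    )
    return AnchorSet(pairs=np.array(pairs, dtype=int).reshape(-1, 2), embedding=embedding)


def transfer_labels(anchors: AnchorSet, ref_labels: np.ndarray,
                    k_anchor: int = 100) -> pd.DataFrame:
    """Plurality-vote label transfer over nearest anchor reference cells.

    For each query cell: take its ``k_anchor`` nearest anchor-participating
    reference cells in the co-embedding; the transferred label is the most
    frequent label among them and the confidence is that label's fraction.
    Ties break to the lexicographically smallest label.
    """
    if len(anchors.pairs) == 0:
        raise ValueError("no anchors found")
    ref_idx = anchors.ref_cells
    k_eff = min(k_anchor, len(ref_idx))
    nn = NearestNeighbors(n_neighbors=k_eff).fit(anchors.embedding.ref[ref_idx])
    _, idx = nn.kneighbors(anchors.embedding.query)
    labels = np.asarray(ref_labels)[ref_idx]
    out_label, out_conf = [], []
    for row in idx:
        counts = pd.Series(labels[row]).value_counts()
        top = counts[counts == counts.iloc[0]]
        best = sorted(top.index)[0]
        out_label.append(best)
        out_conf.append(counts.iloc[0] / k_eff)
    return pd.DataFrame({"label": out_label, "confidence": out_conf})


def impute_expression(anchors: AnchorSet, ref_full: ExpressionMatrix,
                      k_impute: int = 30, layer: str = "raw") -> ExpressionMatrix:
    """Anchor-weighted transcriptome imputation for each query cell.

    imputed[q] = sum_a w(q, a) ref[a] / sum_a w(q, a) over the k nearest
    anchor reference cells in the co-embedding, with Gaussian weights
    exp(-d^2 / sigma^2) where sigma is the distance to the k-th anchor.
    """
    if len(anchors.pairs) == 0:
        raise ValueError("no anchors available for imputation")
    ref_idx = anchors.ref_cells
    k_eff = min(k_impute, len(ref_idx))
    nn = NearestNeighbors(n_neighbors=k_eff).fit(anchors.embedding.ref[ref_idx])
    dist, idx = nn.kneighbors(anchors.embedding.query)
    sigma = np.maximum(dist[:, -1], 1e-12)
    w = np.exp(-((dist / sigma[:, None]) ** 2))
    w /= w.sum(axis=1, keepdims=True)
    ref_mat = ref_full.layer(layer)[ref_idx]
    imputed = np.einsum("qk,qkg->qg", w, ref_mat[idx])
    return ExpressionMatrix(
        cells=[f"q{i}" for i in range(len(imputed))],
        genes=list(ref_full.genes),
        layers={"raw": imputed},
    )


# ---------------------------------------------------------------------------
# two-round driver

@dataclass
class TransferResult:
    """Per-query-cell labels, confidences and pass flags from both rounds."""

    table: pd.DataFrame  # indexed by query cell id
    partitioning: IntegrationPartitioning
    anchors_round1: AnchorSet
    round2_anchors: dict[int, AnchorSet] = field(default_factory=dict)


def two_round_transfer(ref: ExpressionMatrix, ref_labels: pd.DataFrame,
                       query: ExpressionMatrix,
                       config: AnalysisConfig | None = None,
                       n_dims: int | None = None,
                       seed: int = 0) -> TransferResult:
    """Full two-round label transfer from a labeled reference to a query.

    ``ref_labels`` must carry ``subclass`` and ``cluster`` columns indexed
    by (or with a column of) reference cell ids.  The reference is subset
    to the query's gene panel for both rounds.  Cells pass when the
    adjusted subclass confidence is >= 0.8 and the adjusted cluster
    confidence is >= 0.5 (inclusive).
    """
    config = config or AnalysisConfig()
    if "cell_id" in ref_labels.columns:
        ref_labels = ref_labels.set_index("cell_id")
    ref_labels = ref_labels.loc[ref.cells]

    shared = [g for g in query.genes if g in set(ref.genes)]
    if not shared:
        raise ValueError("reference and query share no genes")
    ref_panel = preprocess_for_integration(ref.subset_genes(shared),
                                           total=config.integration_total)
    query_p = preprocess_for_integration(query.subset_genes(shared),
                                         total=config.integration_total)

    k_part = min(config.n_partitions, ref_labels["subclass"].nunique())
    partitioning = partition_reference(
        ref_panel, ref_labels["subclass"], k_partitions=k_part,
        n_pca=config.n_pca_dims, knn=config.knn_subclass_graph,
        balance_tol=config.partition_balance_tol, seed=seed,
    )
    part_of_cell = ref_labels["subclass"].map(partitioning.assignment).to_numpy()

    dims = n_dims or config.n_cca_dims
    dims = min(dims, len(shared), ref_panel.n_cells - 1, query_p.n_cells - 1)
    emb = cca_coembed(ref_panel.layer("scaled"), query_p.layer("scaled"),
                      n_dims=dims, max_fit_cells=config.max_fit_cells, seed=seed)
    anchors1 = find_anchors(emb, k=config.k_anchor_mnn)
    round1 = transfer_labels(anchors1, part_of_cell, k_anchor=config.k_anchor_transfer)

    out = pd.DataFrame(index=pd.Index(query.cells, name="cell_id"))
    out["partition"] = round1["label"].to_numpy()
    out["partition_conf"] = round1["confidence"].to_numpy()
    for col in ("subclass", "cluster"):
        out[col] = ""
        out[f"{col}_conf"] = np.nan

    round2_anchors: dict[int, AnchorSet] = {}
    for pid, members in partitioning.partitions.items():
        q_mask = (out["partition"] == pid).to_numpy()
        if not q_mask.any():
            logger.warning("two_round_transfer: partition %d has no query cells", pid)
            continue
        r_mask = np.isin(ref_labels["subclass"].to_numpy(), members)
        ref_sub = ref_panel.subset_cells(r_mask)
        query_sub = query_p.subset_cells(q_mask)
        try:
            hvg = select_hvg(ref_sub)
        except ValueError:
            hvg = []
        if len(hvg) < 2:
            logger.warning("partition %d: <2 HVGs, using all shared genes", pid)
            hvg = shared
        dims_p = min(dims, len(hvg), ref_sub.n_cells - 1, query_sub.n_cells - 1)
        emb_p = cca_coembed(
            ref_sub.subset_genes(hvg).layer("scaled"),
            query_sub.subset_genes(hvg).layer("scaled"),
            n_dims=dims_p, max_fit_cells=config.max_fit_cells, seed=seed,
        )
        anchors_p = find_anchors(emb_p, k=config.k_anchor_mnn)
        if len(anchors_p.pairs) == 0:
            logger.warning("partition %d: no anchors, cells left unlabeled", pid)
            continue
        round2_anchors[pid] = anchors_p
        sub_labels = ref_labels.loc[ref_sub.cells]
        for col in ("subclass", "cluster"):
            res = transfer_labels(anchors_p, sub_labels[col].to_numpy(),
                                  k_anchor=config.k_anchor_transfer)
            out.loc[q_mask, col] = res["label"].to_numpy()
            out.loc[q_mask, f"{col}_conf"] = res["confidence"].to_numpy()

    out["subclass_conf_adjusted"] = out["subclass_conf"] * out["partition_conf"]
    out["cluster_conf_adjusted"] = out["cluster_conf"] * out["partition_conf"]
    out["pass_subclass"] = out["subclass_conf_adjusted"] >= config.subclass_conf_threshold
    out["pass_cluster"] = out["cluster_conf_adjusted"] >= config.cluster_conf_threshold
    return TransferResult(
        table=out, partitioning=partitioning,
        anchors_round1=anchors1, round2_anchors=round2_anchors,
    )
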