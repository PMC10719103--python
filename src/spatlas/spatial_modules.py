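"""Molecularly defined brain regions from weighted neighbourhood composition.

Each cell gets a local cell-type-composition vector: over its 50 spatially
nearest neighbours (within section, 2D), neighbour j contributes weight
``exp(-(D_ij / D_i0)^2)`` to the entry of its cell type, where ``D_i0`` is
a per-cell bandwidth tied to local density — a multiple of the distance to
the cell's fifth nearest neighbour.  Vectors are L2-normalized and
clustered with Leiden over a kNN graph, pooling all sections.

Two levels are produced: level 1 over subclass compositions of all
non-vascular/non-immune cells (bandwidth x2), and level 2 within each
level-1 module over concatenated subclass+cluster compositions of neurons
only (bandwidth x1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger("spatlas")


@dataclass
class CompositionMatrix:
    """Cells x types weighted-composition matrix (dense)."""

    cell_ids: list[str]
    types: list[str]
    values: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.types)


def local_composition(cells: pd.DataFrame, types: str = "subclass", k: int = 50,
                      bandwidth_multiplier: float = 2.0,
                      bandwidth_neighbor: int = 5,
                      exclude: set[str] | None = None) -> CompositionMatrix:
    """Weighted local cell-type-composition vectors, per section.

    ``D_i0 = bandwidth_multiplier x`` (distance from cell i to its
    ``bandwidth_neighbor``-th nearest neighbour); neighbour weights follow
    ``exp(-(D/D_i0)^2)``.  Types in ``exclude`` are removed before the
    neighbour search (they contribute neither vectors nor weights).
    """
    pool = cells if not exclude else cells[~cells[types].isin(exclude)]
    type_names = sorted(pool[types].unique())
    type_pos = {t: i for i, t in enumerate(type_names)}
    values = np.zeros((len(pool), len(type_names)))
    cell_ids: list[str] = []
    row0 = 0
    for sec, section in pool.groupby("section_id", sort=True):
        n = len(section)
        if n < k + bandwidth_neighbor:
            raise ValueError(
                f"section {sec!r}: {n} cells after exclusion, need >= {k + bandwidth_neighbor}"
            )
        coords = section[["x", "y"]].to_numpy()
        nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
        dist, idx = nn.kneighbors(coords)
        d0 = bandwidth_multiplier * dist[:, bandwidth_neighbor]
        if (d0 == 0).any():
            bad = section["cell_id"].to_numpy()[d0 == 0]
            raise ValueError(f"zero bandwidth (coincident points) at cell {bad[0]!r}")
        weights = np.exp(-((dist[:, 1:] / d0[:, None]) ** 2))
        tcodes = section[types].map(type_pos).to_numpy()
        neighbor_types = tcodes[idx[:, 1:]]
        for t in range(len(type_names)):
            values[row0:row0 + n, t] = np.where(neighbor_types == t, weights, 0.0).sum(axis=1)
        cell_ids.extend(section["cell_id"])
        row0 += n
    return CompositionMatrix(cell_ids=cell_ids, types=type_names, values=values)


def cluster_compositions(comp: CompositionMatrix, resolution: float = 1.0,
                         knn: int = 15, seed: int = 0) -> pd.Series:
    """L2-normalize composition rows and Leiden-cluster their kNN graph."""
    norms = np.linalg.norm(comp.values, axis=1)
    if (norms == 0).any():
        raise ValueError("all-zero composition vector")
    x = comp.values / norms[:, None]
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 cells to cluster")
    k_eff = min(knn, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(x)
    _, idx = nn.kneighbors(x)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(idx) for j in row[1:]}
    graph = ig.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed, n_iterations=2,
    )
    return pd.Series(part.membership, index=comp.cell_ids, name="module")


def merge_indistinct_modules(comp: CompositionMatrix, labels: pd.Series,
                             cos_threshold: float = 0.98) -> pd.Series:
    """Merge modules whose mean composition profiles are indistinguishable.

    Leiden over-partitions regions of uniform composition into spatial
    chunks (composition-space neighbours are also spatial neighbours);
    atlas practice curates these away by merging clusters without clear
    compositional boundaries.  Here two modules merge when the cosine
    similarity of their centroid composition vectors is >=
    ``cos_threshold``; merging repeats until no pair qualifies.
    """
    labels = labels.copy()
    x = comp.values / np.maximum(np.linalg.norm(comp.values, axis=1, keepdims=True), 1e-12)
    frame = pd.DataFrame(x, index=comp.cell_ids)
    while True:
        centroids = frame.groupby(labels).mean()
        if len(centroids) < 2:
            break
        c = centroids.to_numpy()
        c = c / np.maximum(np.linalg.norm(c, axis=1, keepdims=True), 1e-12)
        sim = c @ c.T
        np.fill_diagonal(sim, -1)
        i, j = np.unravel_index(np.argmax(sim), sim.shape)
        if sim[i, j] < cos_threshold:
            break
        keep, drop = sorted((centroids.index[i], centroids.index[j]))
        labels[labels == drop] = keep
    return labels


def merge_small_modules(cells: pd.DataFrame, labels: pd.Series,
                        min_cells: int = 200, k: int = 15) -> pd.Series:
    """Absorb modules below ``min_cells`` into their spatially adjacent module.

    A small module's cells take the majority label among their spatial
    neighbours that belong to large-enough modules; iterates to a fixed
    point.  Programmatic surrogate for manual curation of modules without
    clear spatial boundaries.
    """
    labels = labels.copy()
    cells_idx = cells.set_index("cell_id")
    for _ in range(100):
        sizes = labels.value_counts()
        small = sizes[sizes < min_cells].index
        if len(small) == 0 or len(sizes) == 1:
            break
        changed = False
        for sec, section in cells_idx.loc[labels.index].groupby("section_id"):
            ids = section.index.to_numpy()
            lab = labels.loc[ids].to_numpy()
            big_mask = ~pd.Series(lab).isin(small).to_numpy()
            if not big_mask.any():
                continue
            k_eff = min(k, big_mask.sum())
            nn = NearestNeighbors(n_neighbors=k_eff).fit(
                section.loc[ids[big_mask], ["x", "y"]]
            )
            small_mask = ~big_mask
            if not small_mask.any():
                continue
            _, nbr = nn.kneighbors(section.loc[ids[small_mask], ["x", "y"]])
            big_lab = lab[big_mask]
            for cid, row in zip(ids[small_mask], nbr):
                votes = pd.Series(big_lab[row]).value_counts()
                labels.loc[cid] = votes.index[0]
                changed = True
        if not changed:
            break
    return labels


def two_level_modules(cells: pd.DataFrame, config=None, seed: int = 0,
                      neuronal_subclasses: set[str] | None = None,
                      exclude: set[str] | None = None) -> pd.DataFrame:
    """Level-1 and nested level-2 spatial module assignment.

    Level 1 clusters subclass-composition vectors of all cells except the
    excluded (vascular/immune) types, with the wide (x2) bandwidth.  Level 2
    reruns the analysis per level-1 module on neurons only, with the narrow
    (x1) bandwidth, on the concatenation of subclass- and cluster-level
    composition vectors; level-2 ids are nested as "L1.L2".
    """
    from .config import AnalysisConfig

    config = config or AnalysisConfig()
    comp1 = local_composition(
        cells, types="subclass", k=config.module_k,
        bandwidth_multiplier=config.level1_bandwidth_multiplier,
        bandwidth_neighbor=config.bandwidth_neighbor, exclude=exclude,
    )
    level1 = cluster_compositions(
        comp1, resolution=config.level1_resolution, knn=config.leiden_knn, seed=seed
    )
    level1 = merge_indistinct_modules(comp1, level1)
    level1 = merge_small_modules(
        cells[cells["cell_id"].isin(level1.index)], level1,
        min_cells=config.min_module_cells,
    )
    out = pd.DataFrame({"level1": level1.astype(str)})
    out["level2"] = ""

    neurons = (
        cells if neuronal_subclasses is None
        else cells[cells["subclass"].isin(neuronal_subclasses)]
    )
    neurons = neurons[neurons["cell_id"].isin(level1.index)]
    for mod, ids in level1.groupby(level1):
        members = neurons[neurons["cell_id"].isin(ids.index)]
        min_needed = config.module_k + config.bandwidth_neighbor
        if min(members.groupby("section_id").size(), default=0) < min_needed:
            logger.warning("two_level_modules: level-1 module %s skipped at level 2", mod)
            continue
        comp_sub = local_composition(
            members, types="subclass", k=config.module_k,
            bandwidth_multiplier=config.level2_bandwidth_multiplier,
            bandwidth_neighbor=config.bandwidth_neighbor,
        )
        comp_cl = local_composition(
            members, types="cluster", k=config.module_k,
            bandwidth_multiplier=config.level2_bandwidth_multiplier,
            bandwidth_neighbor=config.bandwidth_neighbor,
        )
        comp = CompositionMatrix(
            cell_ids=comp_sub.cell_ids,
            types=[f"sub:{t}" for t in comp_sub.types] + [f"cl:{t}" for t in comp_cl.types],
            values=np.hstack([comp_sub.values, comp_cl.values]),
        )
        level2 = cluster_compositions(
            comp, resolution=config.level2_resolution, knn=config.leiden_knn, seed=seed
        )
        level2 = merge_indistinct_modules(comp, level2)
        out.loc[level2.index, "level2"] = [f"{mod}.{m}" for m in level2]
    out.index.name = "cell_id"
    return out


def module_composition_summary(cells: pd.DataFrame, modules: pd.DataFrame,
                               level: str = "level1") -> pd.DataFrame:
    """Fraction of each module's cells belonging to each subclass."""
    merged = cells.set_index("cell_id").join(modules[level], how="inner")
    table = pd.crosstab(merged[level], merged["subclass"])
    return table.div(table.sum(axis=1), axis=0)
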