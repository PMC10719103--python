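"""Synthetic spatial-transcriptomics data with known ground truth.

Generates everything the analysis stages consume: per-section 2D point
patterns organised into spatial domains with distinct cell-type
compositions, negative-binomial cell-by-gene counts with cluster-specific
means, optional expression gradients along a spatial axis, pairwise
spatial attraction between designated type pairs, proximity-conditional
ligand-receptor upregulation, and a paired "dissociated" reference dataset
over a larger gene set.

Attraction is implemented by *relocating* a fraction of one type next to
the other rather than adding or removing cells, so per-type marginal
densities are untouched and proximity tests are driven purely by pairing.
Doublet scores are drawn directly (uniform below/above the calling
threshold) because doublet scoring itself is consumed, not computed, by
the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, LRDatabase, LRPair


@dataclass
class ClusterSpec:
    name: str
    mean_expression: np.ndarray  # length = number of reference genes
    dispersion: float = 10.0  # NB size parameter; np.inf -> Poisson
    proportion: float = 1.0  # within-subclass mixing weight


@dataclass
class SubclassSpec:
    name: str
    clusters: list[ClusterSpec]
    neuronal: bool = True


@dataclass
class DomainSpec:
    """Axis-aligned rectangular domain with a subclass mixture."""

    name: str
    x_range: tuple[float, float]
    y_range: tuple[float, float]
    composition: dict[str, float]  # subclass name -> mixture weight, sums to 1

    @property
    def area_um2(self) -> float:
        return (self.x_range[1] - self.x_range[0]) * (self.y_range[1] - self.y_range[0])


@dataclass
class AttractionRule:
    type_a: str
    type_b: str
    radius: float  # µm
    strength: float  # fraction of B cells relocated next to an A cell, in [0, 1]


@dataclass
class GradientRule:
    subclass: str
    axis: tuple[float, float]  # unit vector in the section plane
    genes: list[str]
    slope: float  # log-expression change per µm along the axis


@dataclass
class LRRule:
    type_a: str  # ligand-side subclass
    type_b: str  # receptor-side subclass
    lr_pair: LRPair
    fold: float  # >= 1
    radius: float  # µm


@dataclass
class SimulationConfig:
    genes: list[str]
    subclasses: list[SubclassSpec]
    domains: list[DomainSpec]
    n_sections: int = 1
    base_intensity: float = 1000.0  # cells per mm^2
    attraction_rules: list[AttractionRule] = field(default_factory=list)
    gradient_rules: list[GradientRule] = field(default_factory=list)
    lr_rules: list[LRRule] = field(default_factory=list)
    doublet_fraction: float = 0.0
    doublet_threshold: float = 0.25
    volume_mean: dict[int, float] = field(default_factory=lambda: {3: 400.0, 5: 600.0, 6: 800.0})
    volume_sd_fraction: float = 0.15
    n_zplanes: int = 5
    panel_genes: list[str] | None = None  # imaged subset; defaults to all genes
    seed: int = 0

    def __post_init__(self) -> None:
        for d in self.domains:
            if d.area_um2 <= 0:
                raise ValueError(f"domain {d.name!r} has zero area")
            total = sum(d.composition.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"domain {d.name!r} mixture weights sum to {total}, not 1")
        for r in self.attraction_rules:
            if r.radius <= 0:
                raise ValueError("attraction radius must be positive")
            if r.strength < 0:
                raise ValueError("attraction strength must be >= 0")
        for r in self.lr_rules:
            if r.fold < 1:
                raise ValueError("LR upregulation fold must be >= 1")
        if self.panel_genes is None:
            self.panel_genes = list(self.genes)
        unknown = set(self.panel_genes) - set(self.genes)
        if unknown:
            raise ValueError(f"panel genes absent from gene list: {sorted(unknown)}")

    def subclass(self, name: str) -> SubclassSpec:
        for s in self.subclasses:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass
class GroundTruth:
    """Per-cell truth plus the injected structure, keyed like the CellTable."""

    domain: pd.Series  # cell_id -> domain name
    subclass: pd.Series
    cluster: pd.Series
    gradient_coord: pd.Series  # coordinate along the (first) gradient axis
    attracted_pairs: list[tuple[str, str]]
    upregulated_lr: list[tuple[str, str, str]]  # (type_a, type_b, pair_name)
    doublet_ids: list[str] = field(default_factory=list)


def simulate_cells(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw per-domain homogeneous Poisson point patterns for each section.

    Within a domain, each subclass is an independent Poisson process with
    intensity ``base_intensity * weight``; clusters are drawn within the
    subclass by their configured proportions.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for s in range(config.n_sections):
        section_id = f"sec{s}"
        for dom in config.domains:
            area_mm2 = dom.area_um2 / 1e6
            for sub_name, weight in dom.composition.items():
                sub = config.subclass(sub_name)
                n = rng.poisson(config.base_intensity * weight * area_mm2)
                if n == 0:
                    continue
                xs = rng.uniform(*dom.x_range, size=n)
                ys = rng.uniform(*dom.y_range, size=n)
                props = np.array([c.proportion for c in sub.clusters], dtype=float)
                props /= props.sum()
                cl_idx = rng.choice(len(sub.clusters), size=n, p=props)
                for i in range(n):
                    rows.append((section_id, s, xs[i], ys[i], dom.name, sub_name,
                                 sub.clusters[cl_idx[i]].name))
    if not rows:
        raise ValueError("simulation produced zero cells; raise base_intensity")
    cells = pd.DataFrame(
        rows, columns=["section_id", "z_section_order", "x", "y",
                       "_domain", "subclass", "cluster"],
    )
    cells.insert(0, "cell_id", [f"c{i:06d}" for i in range(len(cells))])

    vol_mean = config.volume_mean[config.n_zplanes]
    cells["volume"] = np.maximum(
        rng.normal(vol_mean, config.volume_sd_fraction * vol_mean, size=len(cells)), 1.0
    )
    cells["n_zplanes"] = config.n_zplanes
    cells["region"] = cells["_domain"]

    n_doublets = rng.binomial(len(cells), config.doublet_fraction)
    doublet_idx = rng.choice(len(cells), size=n_doublets, replace=False)
    scores = rng.uniform(0.0, config.doublet_threshold, size=len(cells))
    scores[doublet_idx] = rng.uniform(config.doublet_threshold + 1e-6, 1.0, size=n_doublets)
    cells["doublet_score"] = scores

    axis = config.gradient_rules[0].axis if config.gradient_rules else (1.0, 0.0)
    coord = cells["x"].to_numpy() * axis[0] + cells["y"].to_numpy() * axis[1]

    truth = GroundTruth(
        domain=pd.Series(cells["_domain"].to_numpy(), index=cells["cell_id"]),
        subclass=pd.Series(cells["subclass"].to_numpy(), index=cells["cell_id"]),
        cluster=pd.Series(cells["cluster"].to_numpy(), index=cells["cell_id"]),
        gradient_coord=pd.Series(coord, index=cells["cell_id"]),
        attracted_pairs=[(r.type_a, r.type_b) for r in config.attraction_rules],
        upregulated_lr=[(r.type_a, r.type_b, r.lr_pair.pair_name) for r in config.lr_rules],
        doublet_ids=cells["cell_id"].iloc[doublet_idx].tolist(),
    )
    return cells.drop(columns=["_domain"]), truth


def apply_attraction(cells: pd.DataFrame, rule: AttractionRule, seed: int = 0) -> pd.DataFrame:
    """Relocate a ``strength`` fraction of type-B cells next to type-A cells.

    Each selected B cell moves to a uniform position within ``rule.radius``
    of a randomly chosen A cell in the same section; all other cells (and
    all per-type counts) are untouched.
    """
    if rule.radius <= 0:
        raise ValueError("attraction radius must be positive")
    rng = np.random.default_rng(seed)
    out = cells.copy()
    strength = min(rule.strength, 1.0)
    if strength == 0:
        return out
    for _, section in cells.groupby("section_id"):
        a_idx = section.index[section["subclass"] == rule.type_a]
        b_idx = section.index[section["subclass"] == rule.type_b]
        if len(a_idx) == 0 or len(b_idx) == 0:
            raise ValueError(
                f"both {rule.type_a!r} and {rule.type_b!r} must be present in each section"
            )
        move = rng.random(len(b_idx)) < strength
        moved = b_idx[move]
        # distinct A partners where possible, so the injected signal is
        # cross-type pairing rather than collision-induced B-B clumping
        if len(moved) <= len(a_idx):
            targets = a_idx[rng.choice(len(a_idx), size=len(moved), replace=False)]
        else:
            targets = a_idx[rng.integers(0, len(a_idx), size=len(moved))]
        # uniform over the disk of the rule radius
        r = rule.radius * np.sqrt(rng.random(len(moved)))
        theta = rng.uniform(0, 2 * np.pi, size=len(moved))
        out.loc[moved, "x"] = cells.loc[targets, "x"].to_numpy() + r * np.cos(theta)
        out.loc[moved, "y"] = cells.loc[targets, "y"].to_numpy() + r * np.sin(theta)
    return out


def _cluster_mean_lookup(config: SimulationConfig) -> dict[str, np.ndarray]:
    means = {}
    for sub in config.subclasses:
        for cl in sub.clusters:
            mean = np.asarray(cl.mean_expression, dtype=float)
            if mean.shape != (len(config.genes),):
                raise ValueError(
                    f"cluster {cl.name!r} mean vector has length {mean.shape}, "
                    f"expected {len(config.genes)}"
                )
            if (mean < 0).any():
                raise ValueError(f"cluster {cl.name!r} has a negative mean")
            means[cl.name] = mean
    return means


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial by gamma-Poisson mixing; Poisson in the dispersion -> inf limit."""
    if not np.isfinite(dispersion):
        return rng.poisson(mean)
    lam = np.where(mean > 0, rng.gamma(dispersion, 1.0, size=mean.shape) * mean / dispersion, 0.0)
    return rng.poisson(lam)


def simulate_expression(cells: pd.DataFrame, config: SimulationConfig,
                        seed: int | None = None) -> ExpressionMatrix:
    """Draw panel-gene counts for each cell from its cluster's NB model.

    The cluster mean is scaled by cell volume relative to the configured
    mean volume; gradient rules multiply the mean of their genes by
    ``exp(slope * (t - t_mid))`` where ``t`` is the cell's coordinate along
    the rule axis and ``t_mid`` the per-section midpoint.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    means = _cluster_mean_lookup(config)
    panel_idx = [config.genes.index(g) for g in config.panel_genes]
    dispersion = {cl.name: cl.dispersion for s in config.subclasses for cl in s.clusters}
    vol_mean = config.volume_mean[config.n_zplanes]

    # per-gene multiplicative gradient factors
    factors = np.ones((len(cells), len(config.genes)))
    for rule in config.gradient_rules:
        t = cells["x"].to_numpy() * rule.axis[0] + cells["y"].to_numpy() * rule.axis[1]
        t = t - 0.5 * (t.min() + t.max())
        in_sub = (cells["subclass"] == rule.subclass).to_numpy()
        gi = [config.genes.index(g) for g in rule.genes]
        factors[np.ix_(in_sub, gi)] *= np.exp(rule.slope * t[in_sub])[:, None]

    counts = np.zeros((len(cells), len(panel_idx)))
    vols = cells["volume"].to_numpy()
    clusters = cells["cluster"].to_numpy()
    for i in range(len(cells)):
        mean = means[clusters[i]][panel_idx] * factors[i, panel_idx] * (vols[i] / vol_mean)
        counts[i] = _nb_draw(rng, mean, dispersion[clusters[i]])
    return ExpressionMatrix(
        cells=list(cells["cell_id"]), genes=list(config.panel_genes), layers={"raw": counts}
    )


def apply_lr_upregulation(expr: ExpressionMatrix, cells: pd.DataFrame,
                          rule: LRRule) -> ExpressionMatrix:
    """Scale ligand genes in proximal A cells and receptor genes in proximal B cells.

    "Proximal" means within ``rule.radius`` of any cell of the partner type
    in the same section.  A fold of 1 is the exact identity.
    """
    from scipy.spatial import cKDTree

    for g in rule.lr_pair.ligand_components + rule.lr_pair.receptor_components:
        if g not in expr.genes:
            raise KeyError(f"LR rule gene {g!r} not in expression matrix")
    out = expr.copy()
    if rule.fold == 1.0:
        return out
    raw = out.layers["raw"]
    lig_idx = expr.gene_index(list(rule.lr_pair.ligand_components))
    rec_idx = expr.gene_index(list(rule.lr_pair.receptor_components))
    pos_of = {c: i for i, c in enumerate(expr.cells)}
    for _, section in cells.groupby("section_id"):
        a = section[section["subclass"] == rule.type_a]
        b = section[section["subclass"] == rule.type_b]
        if len(a) == 0 or len(b) == 0:
            continue
        tree_a = cKDTree(a[["x", "y"]].to_numpy())
        tree_b = cKDTree(b[["x", "y"]].to_numpy())
        a_prox = tree_b.query_ball_point(a[["x", "y"]].to_numpy(), rule.radius)
        b_prox = tree_a.query_ball_point(b[["x", "y"]].to_numpy(), rule.radius)
        a_rows = [pos_of[cid] for cid, hits in zip(a["cell_id"], a_prox) if hits]
        b_rows = [pos_of[cid] for cid, hits in zip(b["cell_id"], b_prox) if hits]
        if a_rows:
            raw[np.ix_(a_rows, lig_idx)] *= rule.fold
        if b_rows:
            raw[np.ix_(b_rows, rec_idx)] *= rule.fold
    return out


def simulate_reference(config: SimulationConfig, n_cells_per_cluster: int = 200,
                       seed: int | None = None) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Dissociated-reference stand-in: same cluster means, full gene set, no space.

    Returns the expression matrix and a label frame (cell_id, subclass,
    cluster).  Panel genes are a subset of the reference genes by
    construction.
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    means = _cluster_mean_lookup(config)
    rows, labels = [], []
    for sub in config.subclasses:
        for cl in sub.clusters:
            for _ in range(n_cells_per_cluster):
                rows.append(_nb_draw(rng, means[cl.name], cl.dispersion))
                labels.append((sub.name, cl.name))
    counts = np.asarray(rows, dtype=float)
    cell_ids = [f"ref{i:06d}" for i in range(len(rows))]
    label_df = pd.DataFrame(labels, columns=["subclass", "cluster"])
    label_df.insert(0, "cell_id", cell_ids)
    expr = ExpressionMatrix(cells=cell_ids, genes=list(config.genes), layers={"raw": counts})
    return expr, label_df


def make_lr_database(pairs: Sequence[LRPair]) -> LRDatabase:
    """Convenience wrapper to assemble an LR database from pair specs."""
    return LRDatabase(list(pairs))
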