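"""Proximity-based cell-cell interaction testing with local-randomization nulls.

Two cells interact candidate-wise when their centroids lie within
``R_proximal`` in the same section (15 µm, about one soma diameter, in the
strict regime; 30 µm in the relaxed regime, which additionally requires
ligand-receptor support).  The null distribution of proximal-pair counts
for every subclass pair is generated by repeatedly displacing *every* cell
to a uniform random position within ``R_randomization`` (100 µm) of its
original location — preserving local density while destroying fine-scale
pairing — then fitting the counts to a normal distribution.  Enrichment
p-values are one-sided (upper tail), Benjamini-Hochberg adjusted across
all (region x pair) tests, and a pair is called interacting when
p_adj < 0.05 with at least 50 observed proximal pairs.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial import cKDTree

from .stats import bh_adjust

logger = logging.getLogger("spatlas")


@dataclass
class InteractionConfig:
    r_proximal: float = 15.0
    r_randomization: float = 100.0
    n_rounds: int = 1000
    alpha: float = 0.05
    min_observed_pairs: int = 50
    enrichment_threshold_default: float = 2.0
    enrichment_threshold_stringent: float = 6.0
    enrichment_threshold_astrocyte: float = 1.0
    min_nonneuronal_cells: int = 50
    stringent_regions: tuple[str, ...] = (
        "anterior hypothalamus", "posterior hypothalamus",
        "anterior midbrain", "posterior midbrain", "pons", "medulla",
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r_proximal >= self.r_randomization:
            raise ValueError("R_proximal must be below R_randomization")
        if self.n_rounds < 100:
            raise ValueError("need at least 100 randomization rounds")


def split_regions(cells: pd.DataFrame,
                  hindbrain_sublabels: pd.Series | None = None) -> pd.Series:
    """Refine region labels for high-complexity regions.

    Hypothalamus and midbrain are each split into anterior/posterior at the
    midpoint of their cells' ccfx range (mean of min and max; cells exactly
    at the midpoint go anterior).  The hindbrain splits into pons and
    medulla using the supplied anatomical sub-annotations.
    """
    regions = cells["region"].copy()
    for region in ("hypothalamus", "midbrain"):
        mask = cells["region"] == region
        if not mask.any():
            continue
        ccfx = cells.loc[mask, "ccfx"]
        if ccfx.isna().any():
            raise ValueError(f"missing ccfx for cells in {region!r}")
        mid = 0.5 * (ccfx.min() + ccfx.max())
        regions.loc[mask] = np.where(
            ccfx <= mid, f"anterior {region}", f"posterior {region}"
        )
    hb = cells["region"] == "hindbrain"
    if hb.any():
        if hindbrain_sublabels is None:
            raise ValueError("hindbrain present but no pons/medulla sub-annotations given")
        regions.loc[hb] = hindbrain_sublabels.loc[cells.loc[hb, "cell_id"]].to_numpy()
    return regions


def select_region_subclasses(cells: pd.DataFrame, enrichment: pd.DataFrame,
                             config: InteractionConfig,
                             neuronal_subclasses: set[str] | None = None,
                             astrocyte_subclasses: set[str] | None = None,
                             min_confidence: float = 0.8) -> dict[str, list[str]]:
    """Per-region subclass shortlist by enrichment / abundance rules.

    Neuronal subclasses need an enrichment score above the region's
    threshold (6 for the six high-complexity split regions, else 2);
    astrocytes need enrichment >= 1; other non-neuronal subclasses need
    more than 50 cells in the region.  Only cells at subclass confidence
    >= ``min_confidence`` are counted.
    """
    conf = cells["subclass_confidence"].fillna(1.0)
    usable = cells[(conf >= min_confidence) & (cells["subclass"] != "")]
    neuronal_subclasses = neuronal_subclasses or set(enrichment.index)
    astrocyte_subclasses = astrocyte_subclasses or set()
    counts = pd.crosstab(usable["subclass"], usable["region"])
    out: dict[str, list[str]] = {}
    for region in sorted(usable["region"].unique()):
        if region not in enrichment.columns:
            raise ValueError(f"region {region!r} absent from enrichment table")
        thr_neuronal = (
            config.enrichment_threshold_stringent
            if region in config.stringent_regions
            else config.enrichment_threshold_default
        )
        selected = []
        for sub in counts.index:
            score = enrichment.at[sub, region] if sub in enrichment.index else 0.0
            n = counts.at[sub, region] if region in counts.columns else 0
            if sub in astrocyte_subclasses:
                keep = score >= config.enrichment_threshold_astrocyte
            elif sub in neuronal_subclasses:
                keep = score >= thr_neuronal
            else:
                keep = n > config.min_nonneuronal_cells
            if keep and n > 0:
                selected.append(sub)
        out[region] = selected
    return out


def _count_pairs(tree_a: cKDTree, tree_b: cKDTree | None, n_a: int, r: float) -> int:
    """Unordered cross-type (or within-type) centroid pairs within distance r."""
    if tree_b is None:  # within-type: subtract self pairs, halve
        total = tree_a.count_neighbors(tree_a, r)
        return int((total - n_a) // 2)
    return int(tree_a.count_neighbors(tree_b, r))


def count_proximal_pairs(cells: pd.DataFrame, type_a: str, type_b: str,
                         r_proximal: float, label: str = "subclass") -> int:
    """Observed proximal pairs between two subclasses, per section, summed."""
    total = 0
    for _, section in cells.groupby("section_id"):
        a = section.loc[section[label] == type_a, ["x", "y"]].to_numpy()
        b = section.loc[section[label] == type_b, ["x", "y"]].to_numpy()
        if len(a) == 0 or len(b) == 0:
            continue
        tree_a = cKDTree(a)
        if type_a == type_b:
            total += _count_pairs(tree_a, None, len(a), r_proximal)
        else:
            total += _count_pairs(tree_a, cKDTree(b), len(a), r_proximal)
    return total


def _displace(coords: np.ndarray, radius: float, rng: np.random.Generator,
              bounds: tuple[np.ndarray, np.ndarray] | None = None) -> np.ndarray:
    """Uniform displacement within a disk, reflected at the section bounds.

    Reflection at the bounding box of the observed pattern keeps the
    displaced pattern inside the imaged tissue; a uniform pattern stays
    exactly uniform under reflected displacement, so the null preserves
    local density rather than diluting it over a larger support.
    """
    r = radius * np.sqrt(rng.random(len(coords)))
    theta = rng.uniform(0, 2 * np.pi, size=len(coords))
    moved = coords + np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    if bounds is not None:
        lo, hi = bounds
        span = np.maximum(hi - lo, 1e-12)
        # fold into [lo, lo + 2*span) then mirror the upper half
        folded = np.mod(moved - lo, 2 * span)
        moved = lo + np.where(folded > span, 2 * span - folded, folded)
    return moved


def null_distribution(cells: pd.DataFrame, pairs: list[tuple[str, str]],
                      config: InteractionConfig, label: str = "subclass",
                      seed: int | None = None) -> pd.DataFrame:
    """Normal-fit null of proximal-pair counts under local randomization.

    Each round displaces every cell independently and uniformly within a
    disk of radius ``R_randomization`` (in its own section plane) and
    recounts proximal pairs for every requested subclass pair.  Returns the
    per-pair sample mean and standard deviation over rounds.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sections = [
        (sec[label].to_numpy(), sec[["x", "y"]].to_numpy())
        for _, sec in cells.groupby("section_id")
    ]
    counts = np.zeros((config.n_rounds, len(pairs)))
    for rnd in range(config.n_rounds):
        for labels, coords in sections:
            bounds = (coords.min(axis=0), coords.max(axis=0))
            moved = _displace(coords, config.r_randomization, rng, bounds=bounds)
            trees = {
                t: cKDTree(moved[labels == t])
                for t in {t for p in pairs for t in p}
                if (labels == t).any()
            }
            for pi, (ta, tb) in enumerate(pairs):
                if ta not in trees or tb not in trees:
                    continue
                if ta == tb:
                    counts[rnd, pi] += _count_pairs(
                        trees[ta], None, int((labels == ta).sum()), config.r_proximal
                    )
                else:
                    counts[rnd, pi] += _count_pairs(
                        trees[ta], trees[tb], 0, config.r_proximal
                    )
    return pd.DataFrame(
        {
            "type_a": [p[0] for p in pairs],
            "type_b": [p[1] for p in pairs],
            "permutation_mean": counts.mean(axis=0),
            "permutation_std": counts.std(axis=0, ddof=1),
        }
    )


def call_interactions(cells: pd.DataFrame,
                      region_subclasses: dict[str, list[str]],
                      config: InteractionConfig,
                      lr_support: set[tuple[str, str, str]] | None = None,
                      min_confidence: float = 0.8) -> pd.DataFrame:
    """Test every subclass pair in every region against its randomization null.

    z = (observed - null mean) / null std; one-sided upper-tail normal p;
    BH adjustment across all (region x pair) tests of the run.  A pair is
    significant when p_adj < alpha and the observed count is >= the
    minimum-pair threshold; when ``lr_support`` is given (relaxed regime)
    the pair must additionally appear in it as (region, subclass1,
    subclass2) in either orientation.
    """
    conf = cells["subclass_confidence"].fillna(1.0)
    usable = cells[(conf >= min_confidence) & (cells["subclass"] != "")]
    rows = []
    for region, subclasses in region_subclasses.items():
        in_region = usable[usable["region"] == region]
        pairs = [
            (a, b) for i, a in enumerate(subclasses) for b in subclasses[i:]
        ]
        if not pairs:
            continue
        null = null_distribution(
            in_region, pairs, config,
            seed=config.seed + zlib.crc32(region.encode()) % 2**20,
        )
        for (ta, tb), (_, nrow) in zip(pairs, null.iterrows()):
            observed = count_proximal_pairs(in_region, ta, tb, config.r_proximal)
            mean, std = nrow["permutation_mean"], nrow["permutation_std"]
            if std == 0:
                # permutation-style bound when the null degenerates
                pval = 1.0 / (config.n_rounds + 1) if observed > mean else 1.0
                z = np.nan
            else:
                z = (observed - mean) / std
                pval = float(sps.norm.sf(z))
            rows.append({
                "region": region, "subclass1": ta, "subclass2": tb,
                "proximal_count": observed, "permutation_mean": mean,
                "permutation_std": std, "z_score": z,
                "fold_change": observed / mean if mean > 0 else np.nan,
                "pval": pval,
            })
    result = pd.DataFrame(rows)
    if result.empty:
        return result
    result["pval-adjusted"] = bh_adjust(result["pval"].to_numpy())
    significant = (
        (result["pval-adjusted"] < config.alpha)
        & (result["proximal_count"] >= config.min_observed_pairs)
    )
    if lr_support is not None:
        supported = result.apply(
            lambda r: (r["region"], r["subclass1"], r["subclass2"]) in lr_support
            or (r["region"], r["subclass2"], r["subclass1"]) in lr_support,
            axis=1,
        )
        result["supported_by_LR_analysis"] = supported
        significant &= supported
    else:
        result["supported_by_LR_analysis"] = np.nan
    result["significant"] = significant
    return result
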