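"""Marker-gene panel selection from a clustered reference.

Candidates come from an all-pairs differential-expression screen: for
every ordered cluster pair a gene qualifies with fold change >= 2 at
p < 0.01 (two-sided Wilcoxon rank-sum), expressed in >= 50% of foreground
cells and with a > 3.3-fold enrichment of the expressing-cell fraction;
the 50 smallest-p qualifiers are kept per pair and direction.  Genes that
are impractical to image — fewer than 40 hybridization probes or more
than 3,000 mean counts in their top cluster — are excluded.  The panel is
then completed greedily: starting from curated seed genes, repeatedly add
the candidate covering the most (pair, direction) slots still below the
target of three discriminative genes, until every slot is satisfied or no
gene helps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ExpressionMatrix

logger = logging.getLogger("spatlas")


def screen_deg_candidates(ref: ExpressionMatrix, clusters: pd.Series,
                          layer: str = "raw", min_fold: float = 2.0,
                          max_p: float = 0.01, min_fg_fraction: float = 0.5,
                          min_fraction_ratio: float = 3.3,
                          top_per_pair: int = 50) -> pd.DataFrame:
    """All-ordered-pairs DEG screen returning the per-pair top candidates.

    A background expressing fraction of zero makes the enrichment ratio
    +inf (the limiting case passes).  Clusters need at least 2 cells.
    """
    labels = clusters.loc[ref.cells].to_numpy()
    names = sorted(set(labels))
    if len(names) < 2:
        raise ValueError("need at least 2 clusters")
    sizes = pd.Series(labels).value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(f"clusters with fewer than 2 cells: {list(small.index)}")
    mat = ref.layer(layer)
    by_cluster = {c: mat[labels == c] for c in names}
    means = {c: m.mean(axis=0) for c, m in by_cluster.items()}
    fractions = {c: (m > 0).mean(axis=0) for c, m in by_cluster.items()}

    rows = []
    for fg in names:
        for bg in names:
            if fg == bg:
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                fold = means[fg] / means[bg]
                ratio = fractions[fg] / fractions[bg]
            fold = np.where(means[bg] == 0,
                            np.where(means[fg] > 0, np.inf, np.nan), fold)
            ratio = np.where(fractions[bg] == 0,
                             np.where(fractions[fg] > 0, np.inf, np.nan), ratio)
            passing = np.flatnonzero(
                (fold >= min_fold)
                & (fractions[fg] >= min_fg_fraction)
                & (ratio > min_fraction_ratio)
            )
            if len(passing) == 0:
                continue
            pvals = np.array([
                sps.ranksums(by_cluster[fg][:, g], by_cluster[bg][:, g]).pvalue
                for g in passing
            ])
            ok = pvals < max_p
            passing, pvals = passing[ok], pvals[ok]
            order = np.argsort(pvals, kind="stable")[:top_per_pair]
            for g, p in zip(passing[order], pvals[order]):
                rows.append({
                    "gene": ref.genes[g], "foreground": fg, "background": bg,
                    "direction": f"{fg}>{bg}", "fold_change": fold[g],
                    "p_value": p, "fg_fraction": fractions[fg][g],
                    "fraction_ratio": ratio[g],
                })
    return pd.DataFrame(
        rows, columns=["gene", "foreground", "background", "direction",
                       "fold_change", "p_value", "fg_fraction", "fraction_ratio"],
    )


def filter_panel_constraints(candidates: pd.DataFrame, gene_meta: pd.DataFrame,
                             min_probe_capacity: int = 40,
                             max_cluster_mean: float = 3000.0
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop genes too short or too abundant for imaging.

    ``gene_meta`` must carry ``probe_capacity`` and ``max_cluster_mean``
    indexed by gene (or with a ``gene`` column).  Exclusion is strict:
    capacity 40 and mean 3,000 are retained.  Returns (filtered
    candidates, exclusion log).
    """
    if "gene" in gene_meta.columns:
        gene_meta = gene_meta.set_index("gene")
    genes = candidates["gene"].unique()
    missing = [g for g in genes if g not in gene_meta.index]
    if missing:
        raise ValueError(f"gene_meta lacks entries for: {missing[:10]}")
    reasons = []
    for g in genes:
        cap = gene_meta.at[g, "probe_capacity"]
        mx = gene_meta.at[g, "max_cluster_mean"]
        if cap < min_probe_capacity:
            reasons.append({"gene": g, "reason": f"probe_capacity {cap} < {min_probe_capacity}"})
        elif mx > max_cluster_mean:
            reasons.append({"gene": g, "reason": f"max_cluster_mean {mx} > {max_cluster_mean}"})
    excluded = pd.DataFrame(reasons, columns=["gene", "reason"])
    keep = ~candidates["gene"].isin(set(excluded["gene"]))
    return candidates[keep].copy(), excluded


@dataclass
class PanelReport:
    selected: list[str]
    coverage: pd.DataFrame  # per (foreground, background): selected gene count
    uncoverable: list[tuple[str, str]] = field(default_factory=list)
    added: list[str] = field(default_factory=list)


def _coverage(candidates: pd.DataFrame, genes: set[str]) -> pd.Series:
    chosen = candidates[candidates["gene"].isin(genes)]
    return chosen.groupby(["foreground", "background"]).size()


def greedy_complete_panel(candidates: pd.DataFrame, seed_genes: list[str],
                          target_per_pair: int = 3) -> PanelReport:
    """Greedy completion: add the gene covering the most deficient slots.

    A slot is an ordered (foreground, background) cluster pair with fewer
    than ``target_per_pair`` selected discriminative genes.  Ties break by
    smallest aggregate candidate p-value, then gene name.  Pairs with no
    candidates at all are reported as uncoverable.
    """
    if candidates.empty:
        raise ValueError("empty candidate table")
    all_pairs = set(map(tuple, candidates[["foreground", "background"]].drop_duplicates().to_numpy()))
    selected = set(seed_genes)
    added: list[str] = []
    pair_genes = candidates.groupby(["foreground", "background"])["gene"].apply(set)
    gene_pairs = candidates.groupby("gene").apply(
        lambda d: set(map(tuple, d[["foreground", "background"]].to_numpy())),
        include_groups=False,
    )
    gene_p = candidates.groupby("gene")["p_value"].sum()

    def deficits() -> dict[tuple[str, str], int]:
        cov = _coverage(candidates, selected)
        return {
            pair: target_per_pair - int(cov.get(pair, 0))
            for pair in all_pairs
            if target_per_pair - int(cov.get(pair, 0)) > 0
        }

    while True:
        need = deficits()
        if not need:
            break
        best_gene, best_key = None, None
        for gene in gene_pairs.index:
            if gene in selected:
                continue
            gain = sum(1 for pair in gene_pairs[gene] if pair in need)
            if gain == 0:
                continue
            key = (-gain, gene_p[gene], gene)
            if best_key is None or key < best_key:
                best_gene, best_key = gene, key
        if best_gene is None:
            break
        selected.add(best_gene)
        added.append(best_gene)

    cov = _coverage(candidates, selected)
    coverage = pd.DataFrame(
        [
            {"foreground": fg, "background": bg,
             "n_selected": int(cov.get((fg, bg), 0)),
             "deficit": max(0, target_per_pair - int(cov.get((fg, bg), 0)))}
            for fg, bg in sorted(all_pairs)
        ]
    )
    uncoverable = [
        pair for pair in sorted(all_pairs)
        if len(pair_genes.get(pair, set())) == 0
    ]
    return PanelReport(
        selected=sorted(selected), coverage=coverage,
        uncoverable=uncoverable, added=added,
    )


def panel_overlap(panel_a: list[str], panel_b: list[str]) -> int:
    """Number of genes shared by two imaging panels."""
    return len(set(panel_a) & set(panel_b))
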