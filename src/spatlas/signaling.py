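"""Ligand-receptor scoring and upregulation screens for interacting pairs.

For a ligand-receptor pair k and cells i (ligand side) and j (receptor
side) the expression score is ``S = log(1 + prod_{p,q} L_p * R_q)`` over
all ligand and receptor component genes (natural log; imputed expression
is the intended input, so multi-gene complexes score zero whenever any
component is absent).  Proximal cell pairs are compared with an
equal-size random sample of non-proximal pairs by a one-sided Welch test;
candidate LR pairs must show >= 2-fold score enrichment, BH-adjusted
p < 0.01, and nonzero scores in >= 40% of proximal pairs.  A parallel
screen tests, per highly variable gene, whether cells proximal to the
partner type upregulate the gene relative to non-proximal cells of the
same type.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import ExpressionMatrix, LRDatabase
from .stats import bh_adjust, welch_t_one_sided

logger = logging.getLogger("spatlas")


def lr_score(ligand_expr, receptor_expr) -> float:
    """log(1 + product over all ligand x receptor component expression)."""
    lig = np.asarray(ligand_expr, dtype=float)
    rec = np.asarray(receptor_expr, dtype=float)
    if (lig < 0).any() or (rec < 0).any():
        raise ValueError("component expression must be nonnegative")
    return float(np.log1p(np.prod(lig) * np.prod(rec)))


def _lr_scores_vectorized(lig_mat: np.ndarray, rec_mat: np.ndarray) -> np.ndarray:
    """Scores for aligned arrays of ligand-cell and receptor-cell components."""
    return np.log1p(np.prod(lig_mat, axis=1) * np.prod(rec_mat, axis=1))


def _cross_pairs(cells: pd.DataFrame, type_a: str, type_b: str,
                 r_proximal: float) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """(proximal, non-proximal) unordered A-B cell-id pairs, per section."""
    proximal, nonproximal = [], []
    for _, section in cells.groupby("section_id"):
        a = section[section["subclass"] == type_a]
        b = section[section["subclass"] == type_b]
        if len(a) == 0 or len(b) == 0:
            continue
        if type_a == type_b:
            coords = a[["x", "y"]].to_numpy()
            tree = cKDTree(coords)
            close = {(i, j) for i, j in tree.query_pairs(r_proximal)}
            ids = a["cell_id"].to_numpy()
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    (proximal if (i, j) in close else nonproximal).append((ids[i], ids[j]))
        else:
            dist = cKDTree(a[["x", "y"]].to_numpy()).sparse_distance_matrix(
                cKDTree(b[["x", "y"]].to_numpy()), r_proximal, output_type="coo_matrix"
            )
            close = set(zip(dist.row, dist.col))
            ids_a, ids_b = a["cell_id"].to_numpy(), b["cell_id"].to_numpy()
            for i in range(len(ids_a)):
                for j in range(len(ids_b)):
                    (proximal if (i, j) in close else nonproximal).append(
                        (ids_a[i], ids_b[j])
                    )
    return proximal, nonproximal


def lr_upregulation_test(cells: pd.DataFrame, expr: ExpressionMatrix,
                         type_a: str, type_b: str, lr_db: LRDatabase,
                         r_proximal: float = 30.0, seed: int = 0,
                         region: str = "", layer: str = "raw",
                         min_fold: float = 2.0, max_padj: float = 0.01,
                         min_nonzero_fraction: float = 0.4) -> pd.DataFrame:
    """Screen every LR pair for upregulation in proximal A-B cell pairs.

    Both orientations are tested (A as ligand sender to B, and B to A).
    Control pairs are sampled uniformly without replacement from the
    non-proximal cross pairs (with replacement, flagged, if too few).
    """
    rng = np.random.default_rng(seed)
    proximal, nonproximal = _cross_pairs(cells, type_a, type_b, r_proximal)
    if not proximal:
        raise ValueError(f"no proximal pairs between {type_a!r} and {type_b!r}")
    n = len(proximal)
    with_replacement = len(nonproximal) < n
    if with_replacement:
        logger.warning("lr_upregulation_test: sampling controls with replacement")
        pick = rng.integers(0, len(nonproximal), size=n)
    else:
        pick = rng.choice(len(nonproximal), size=n, replace=False)
    controls = [nonproximal[i] for i in pick]

    pos = {c: i for i, c in enumerate(expr.cells)}
    mat = expr.layer(layer)
    rows = []
    orientations = [(type_a, type_b, 0, 1), (type_b, type_a, 1, 0)]
    for sub_lig, sub_rec, li, ri in orientations:
        for entry in lr_db:
            lig_idx = expr.gene_index(list(entry.ligand_components))
            rec_idx = expr.gene_index(list(entry.receptor_components))

            def scores(pairs):
                lig_rows = [pos[p[li]] for p in pairs]
                rec_rows = [pos[p[ri]] for p in pairs]
                return _lr_scores_vectorized(
                    mat[np.ix_(lig_rows, lig_idx)], mat[np.ix_(rec_rows, rec_idx)]
                )

            s_prox = scores(proximal)
            s_ctrl = scores(controls)
            _, pval = welch_t_one_sided(s_prox, s_ctrl)
            ctrl_mean = s_ctrl.mean()
            rows.append({
                "subclass_ligand": sub_lig, "subclass_receptor": sub_rec,
                "LR_pair": entry.pair_name, "N_proximal_pairs": n,
                "mean_proximal_lr_exp": s_prox.mean(),
                "exp_fraction": float((s_prox > 0).mean()),
                "fold_change": s_prox.mean() / ctrl_mean if ctrl_mean > 0 else np.inf,
                "pval": pval, "region": region,
                "pathway_name": entry.pathway,
                "control_with_replacement": with_replacement,
            })
    result = pd.DataFrame(rows)
    result["pval-adjusted"] = bh_adjust(result["pval"].to_numpy())
    result["significant"] = (
        (result["fold_change"] >= min_fold)
        & (result["pval-adjusted"] < max_padj)
        & (result["exp_fraction"] >= min_nonzero_fraction)
    )
    return result


def gene_upregulation_test(cells: pd.DataFrame, expr: ExpressionMatrix,
                           type_a: str, type_b: str, hvg: list[str],
                           r_proximal: float = 30.0, region: str = "",
                           layer: str = "raw", min_fold: float = 2.0,
                           max_padj: float = 0.01) -> pd.DataFrame:
    """Per-HVG screen: do type-A cells near type B upregulate the gene?

    Type-A cells split into proximal (within ``r_proximal`` of any B cell,
    same section) and non-proximal groups; one-sided Welch test per gene,
    BH adjusted; significant when fold >= 2 and p_adj < 0.01.
    """
    a_cells = cells[cells["subclass"] == type_a]
    prox_ids: list[str] = []
    for _, section in cells.groupby("section_id"):
        a = section[section["subclass"] == type_a]
        b = section[section["subclass"] == type_b]
        if len(a) == 0 or len(b) == 0:
            continue
        tree_b = cKDTree(b[["x", "y"]].to_numpy())
        hits = tree_b.query_ball_point(a[["x", "y"]].to_numpy(), r_proximal)
        prox_ids.extend(cid for cid, h in zip(a["cell_id"], hits) if h)
    prox_set = set(prox_ids)
    group1 = [c for c in a_cells["cell_id"] if c in prox_set]
    group2 = [c for c in a_cells["cell_id"] if c not in prox_set]
    pos = {c: i for i, c in enumerate(expr.cells)}
    mat = expr.layer(layer)
    rows = []
    for gene in hvg:
        gi = expr.gene_index(gene)[0]
        x1 = mat[[pos[c] for c in group1], gi]
        x2 = mat[[pos[c] for c in group2], gi]
        if len(x1) < 2 or len(x2) < 2:
            logger.warning("gene_upregulation_test: %s skipped (empty group)", gene)
            continue
        _, pval = welch_t_one_sided(x1, x2)
        rows.append({
            "subclass_gene_exp": type_a, "subclass_interacting": type_b,
            "gene": gene, "proximal_mean": x1.mean(), "control_mean": x2.mean(),
            "fold_change": x1.mean() / x2.mean() if x2.mean() > 0 else np.inf,
            "pval": pval, "region": region,
        })
    result = pd.DataFrame(rows)
    if result.empty:
        return result
    result["pval-adjusted"] = bh_adjust(result["pval"].to_numpy())
    result["significant"] = (
        (result["fold_change"] >= min_fold) & (result["pval-adjusted"] < max_padj)
    )
    return result


def pathway_summary(lr_results: pd.DataFrame, top: int = 10) -> pd.DataFrame:
    """Per-pathway summary: the significant pair with the highest fold change."""
    sig = lr_results[lr_results["significant"]]
    if sig.empty:
        return pd.DataFrame(columns=["pathway_name", "LR_pair", "fold_change"])
    best = sig.loc[sig.groupby("pathway_name")["fold_change"].idxmax()]
    best = best.sort_values("fold_change", ascending=False).head(top)
    return best[["pathway_name", "LR_pair", "fold_change"]].reset_index(drop=True)
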