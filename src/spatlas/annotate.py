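"""Per-cell and per-region annotations.

Neurotransmitter identity is called from canonical transporter/synthesis
marker counts at a fixed MERFISH count threshold; regional enrichment is
the fold change of a subclass's cell density in a region over its
whole-brain density; local complexity counts distinct neuronal subclasses
among a cell's spatial nearest neighbours.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .io import ExpressionMatrix

logger = logging.getLogger("spatlas")

#: Marker genes per neurotransmitter flag; glutamatergic uses any of three
#: vesicular transporter paralogs, the others a single transporter (or Hdc
#: for histamine synthesis).
NEUROTRANSMITTER_MARKERS: dict[str, list[str]] = {
    "glut": ["Slc17a7", "Slc17a6", "Slc17a8"],
    "gaba": ["Slc32a1"],
    "sero": ["Slc6a4"],
    "dopa": ["Slc6a3"],
    "choli": ["Slc18a3"],
    "glycine": ["Slc6a5"],
    "nora": ["Slc6a2"],
    "hist": ["Hdc"],
}


def assign_neurotransmitters(expr: ExpressionMatrix, threshold: int = 2,
                             layer: str = "raw") -> pd.DataFrame:
    """Flag each cell's neurotransmitter identities from marker RNA counts.

    A flag is set iff any of its marker genes has count >= ``threshold``
    (default 2 counts per cell).  Flags are independent: cells may carry
    several (for example glutamate/GABA co-release).
    """
    all_markers = [g for gs in NEUROTRANSMITTER_MARKERS.values() for g in gs]
    missing = [g for g in all_markers if g not in expr.genes]
    if missing:
        raise KeyError(f"marker genes absent from matrix: {missing}")
    mat = expr.layer(layer)
    out = pd.DataFrame(index=pd.Index(expr.cells, name="cell_id"))
    for flag, markers in NEUROTRANSMITTER_MARKERS.items():
        counts = mat[:, expr.gene_index(markers)]
        out[flag] = (counts >= threshold).any(axis=1)
        out[f"{flag}_max_count"] = counts.max(axis=1)
    return out


def enrichment_score(cells: pd.DataFrame,
                     region_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Subclass-by-region density-enrichment table.

    score(s, r) = [n(s, r) / N(r)] / [n(s) / N], the fold change of the
    subclass's average density in region r over its whole-brain average.
    With cell counts as the size proxy the region volume cancels; a
    per-region volume table may be supplied to weight instead.
    """
    labeled = cells[(cells["region"] != "") & (cells["subclass"] != "")]
    if labeled.empty:
        raise ValueError("no cells with both region and subclass labels")
    counts = pd.crosstab(labeled["subclass"], labeled["region"])
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("empty region in enrichment computation")
    region_total = (
        counts.sum(axis=0).astype(float) if region_sizes is None
        else region_sizes.reindex(counts.columns).astype(float)
    )
    n_total = region_total.sum()
    subclass_rate = counts.sum(axis=1) / n_total  # n(s) / N
    density = counts.div(region_total, axis=1)  # n(s, r) / N(r)
    return density.div(subclass_rate, axis=0)


def local_complexity(cells: pd.DataFrame, k: int = 50,
                     label: str = "subclass",
                     neuronal_subclasses: set[str] | None = None) -> pd.Series:
    """Distinct neuronal subclass count among each cell's k spatial neighbours.

    Neighbours are found within the cell's own section (2D).  If
    ``neuronal_subclasses`` is given, both the neighbour pool and the label
    counting are restricted to those subclasses.  Sections with fewer than
    ``k + 1`` cells use all available neighbours, with a warning.
    """
    out = pd.Series(np.nan, index=cells["cell_id"], name="local_complexity")
    pool = cells if neuronal_subclasses is None else cells[
        cells[label].isin(neuronal_subclasses)
    ]
    for sec, section in pool.groupby("section_id"):
        if len(section) < 2:
            continue
        k_eff = min(k, len(section) - 1)
        if k_eff < k:
            logger.warning(
                "local_complexity: section %s has only %d neighbours (< %d)",
                sec, k_eff, k,
            )
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(section[["x", "y"]])
        _, idx = nn.kneighbors(section[["x", "y"]])
        labels = section[label].to_numpy()
        vals = [len(set(labels[row[1:]])) for row in idx]
        out.loc[section["cell_id"]] = vals
    return out
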