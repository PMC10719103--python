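"""Five-step QC/normalization for segmented cell-by-gene matrices.

The pipeline order is: (1) volume filter by z-plane count, (2) per-cell
volume normalization, (3) rescaling of mean total counts per experiment to
a common target, (4) removal of the top/bottom total-count quantiles, and
(5) doublet removal by thresholding precomputed doublet scores.  All
boundary values are retained ("less than" / "more than" / "higher than"
are strict comparisons).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .io import ExpressionMatrix

logger = logging.getLogger("spatlas")


@dataclass
class QCReport:
    """Per-step removed-cell accounting and per-group scaling factors."""

    n_input: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    scale_factors: dict[str, float] = field(default_factory=dict)

    @property
    def n_output(self) -> int:
        return self.n_input - sum(self.removed.values())

    def record(self, step: str, n_removed: int) -> None:
        self.removed[step] = self.removed.get(step, 0) + n_removed

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"step": step, "removed": n, "fraction": n / self.n_input if self.n_input else 0.0}
            for step, n in self.removed.items()
        ]
        return pd.DataFrame(rows, columns=["step", "removed", "fraction"])


VOLUME_BOUNDS = {3: (50.0, 1500.0), 5: (80.0, 2500.0), 6: (100.0, 3000.0)}


def volume_filter(cells: pd.DataFrame,
                  bounds: dict[int, tuple[float, float]] | None = None
                  ) -> tuple[pd.DataFrame, QCReport]:
    """Drop cells whose imaged volume falls outside the per-z-plane window.

    Windows are [50, 1500], [80, 2500] and [100, 3000] µm³ for 3-, 5- and
    6-z-plane measurements; boundary volumes are retained.
    """
    bounds = VOLUME_BOUNDS if bounds is None else bounds
    bad_z = set(cells["n_zplanes"]) - set(bounds)
    if bad_z:
        raise ValueError(f"unsupported n_zplanes values: {sorted(bad_z)}")
    lo = cells["n_zplanes"].map(lambda z: bounds[z][0])
    hi = cells["n_zplanes"].map(lambda z: bounds[z][1])
    keep = (cells["volume"] >= lo) & (cells["volume"] <= hi)
    report = QCReport(n_input=len(cells))
    report.record("volume_filter", int((~keep).sum()))
    logger.info("volume_filter: removed %d of %d cells", (~keep).sum(), len(cells))
    return cells[keep].copy(), report


def volume_normalize(expr: ExpressionMatrix, cells: pd.DataFrame) -> ExpressionMatrix:
    """Divide each cell's counts by its imaged volume -> ``volnorm`` layer."""
    vols = cells.set_index("cell_id").loc[expr.cells, "volume"].to_numpy()
    if (vols <= 0).any():
        raise ValueError("zero or negative cell volume")
    out = expr.copy()
    out.layers["volnorm"] = out.layer("raw") / vols[:, None]
    return out


def rescale_mean_total(expr: ExpressionMatrix, groups: pd.Series | np.ndarray,
                       target: float = 250.0, layer: str = "volnorm"
                       ) -> tuple[ExpressionMatrix, QCReport]:
    """Scale each experiment group so its mean per-cell total equals ``target``.

    Idempotent: reapplying to its own output is the identity up to floating
    point.
    """
    groups = np.asarray(groups)
    if len(groups) != expr.n_cells:
        raise ValueError("group labels must align with cells")
    out = expr.copy()
    mat = out.layer(layer)
    report = QCReport(n_input=expr.n_cells)
    for g in pd.unique(groups):
        rows = np.flatnonzero(groups == g)
        mean_total = mat[rows].sum(axis=1).mean()
        if mean_total == 0:
            raise ValueError(f"group {g!r} has all-zero totals")
        factor = target / mean_total
        mat[rows] *= factor
        report.scale_factors[str(g)] = float(factor)
    return out, report


def total_count_quantile_filter(expr: ExpressionMatrix, cells: pd.DataFrame,
                                q: float = 0.01, layer: str = "volnorm",
                                groups: pd.Series | np.ndarray | None = None
                                ) -> tuple[ExpressionMatrix, pd.DataFrame, QCReport]:
    """Remove cells in the top and bottom ``q`` total-count quantiles.

    Quantiles use linear interpolation and are computed per experiment
    group (matching the granularity of the mean-total normalization);
    removal is strict (< low or > high), so with ``q = 0`` this is the
    identity.
    """
    if q >= 0.5:
        raise ValueError("quantile fraction must be < 0.5")
    if expr.n_cells < 3:
        raise ValueError("need at least 3 cells")
    totals = expr.layer(layer).sum(axis=1)
    groups = np.zeros(expr.n_cells) if groups is None else np.asarray(groups)
    keep = np.ones(expr.n_cells, dtype=bool)
    for g in pd.unique(groups):
        rows = np.flatnonzero(groups == g)
        lo = np.quantile(totals[rows], q)
        hi = np.quantile(totals[rows], 1 - q)
        keep[rows] = (totals[rows] >= lo) & (totals[rows] <= hi)
    report = QCReport(n_input=expr.n_cells)
    report.record("total_count_quantile_filter", int((~keep).sum()))
    kept_ids = [c for c, k in zip(expr.cells, keep) if k]
    cells_out = cells[cells["cell_id"].isin(kept_ids)].copy()
    return expr.subset_cells(keep), cells_out, report


def doublet_filter(cells: pd.DataFrame, threshold: float = 0.25
                   ) -> tuple[pd.DataFrame, QCReport]:
    """Remove cells with doublet score strictly above ``threshold``.

    Cells without a score pass through with a warning (scoring is an
    upstream, external step).
    """
    report = QCReport(n_input=len(cells))
    if "doublet_score" not in cells.columns or cells["doublet_score"].isna().all():
        logger.warning("doublet_filter: no doublet scores present; passing through")
        report.record("doublet_filter", 0)
        return cells.copy(), report
    remove = cells["doublet_score"] > threshold
    report.record("doublet_filter", int(remove.sum()))
    return cells[~remove].copy(), report


def run_preprocessing(cells: pd.DataFrame, expr: ExpressionMatrix,
                      config: AnalysisConfig | None = None
                      ) -> tuple[pd.DataFrame, ExpressionMatrix, QCReport]:
    """Run QC steps 1-5 in order and return the combined accounting."""
    config = config or AnalysisConfig()
    bounds = {3: config.volume_bounds_3z, 5: config.volume_bounds_5z,
              6: config.volume_bounds_6z}
    report = QCReport(n_input=len(cells))

    cells1, r1 = volume_filter(cells, bounds)
    report.record("volume_filter", r1.removed["volume_filter"])
    expr1 = expr.subset_cells(list(cells1["cell_id"]))

    expr2 = volume_normalize(expr1, cells1)
    groups = cells1.set_index("cell_id").loc[expr2.cells, "section_id"]
    expr3, r3 = rescale_mean_total(expr2, groups, target=config.mean_total_target)
    report.scale_factors.update(r3.scale_factors)

    expr4, cells4, r4 = total_count_quantile_filter(
        expr3, cells1, q=config.total_count_quantile,
        groups=groups.to_numpy(),
    )
    report.record("total_count_quantile_filter",
                  r4.removed["total_count_quantile_filter"])

    cells5, r5 = doublet_filter(cells4, threshold=config.doublet_threshold)
    report.record("doublet_filter", r5.removed["doublet_filter"])
    expr5 = expr4.subset_cells(list(cells5["cell_id"]))
    return cells5, expr5, report
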