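"""Shared data types and readers/writers for the pipeline's on-disk formats.

Cell tables are plain :class:`pandas.DataFrame` objects with a documented
column set (one row per segmented cell); expression data live in
:class:`ExpressionMatrix`, a minimal named-layer container that converts to
and from :class:`anndata.AnnData`; ligand-receptor databases follow the
CellChat column layout with receptor complexes underscore-joined.

All delimited files are comma-separated with "." decimals, mandatory
headers and empty fields for missing values, so that write -> read
round-trips are value-exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("spatlas")

#: Columns a cell table must provide.
CELL_TABLE_REQUIRED = ["cell_id", "section_id", "x", "y", "volume", "n_zplanes"]

#: Optional per-cell columns, absent ones are filled with missing values.
CELL_TABLE_OPTIONAL = [
    "z_section_order",
    "region",
    "subclass",
    "cluster",
    "subclass_confidence",
    "cluster_confidence",
    "doublet_score",
    "ccfx",
    "ccfy",
    "ccfz",
]

_NUMERIC_CELL_COLUMNS = [
    "x", "y", "volume", "subclass_confidence", "cluster_confidence",
    "doublet_score", "ccfx", "ccfy", "ccfz",
]
_STRING_CELL_COLUMNS = ["section_id", "region", "subclass", "cluster"]


def validate_cell_table(cells: pd.DataFrame) -> None:
    """Raise ``ValueError`` on any violated cell-table invariant."""
    missing = [c for c in CELL_TABLE_REQUIRED if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table lacks required columns: {missing}")
    dup = cells["cell_id"][cells["cell_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate cell_id values: {sorted(set(dup))}")
    if (cells["volume"] <= 0).any():
        bad = cells.loc[cells["volume"] <= 0, "cell_id"].tolist()
        raise ValueError(f"non-positive volume for cells {bad[:5]}")
    for col in ("subclass_confidence", "cluster_confidence", "doublet_score"):
        if col in cells.columns:
            vals = cells[col].dropna()
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"{col} outside [0, 1]")
    # every cluster label must map to exactly one subclass label
    if "cluster" in cells.columns and "subclass" in cells.columns:
        labeled = cells.dropna(subset=["cluster", "subclass"])
        labeled = labeled[labeled["cluster"] != ""]
        n_parents = labeled.groupby("cluster")["subclass"].nunique()
        multi = n_parents[n_parents > 1]
        if len(multi):
            raise ValueError(
                f"clusters mapping to multiple subclasses: {list(multi.index)}"
            )


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read a cell table CSV, validate it, and fill absent optional columns.

    Column order in the file is irrelevant.  Non-numeric coordinate entries
    raise with the offending row number; duplicate ``cell_id`` values raise
    naming the ids.
    """
    cells = pd.read_csv(path, dtype={"cell_id": str, "section_id": str})
    missing = [c for c in CELL_TABLE_REQUIRED if c not in cells.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in ("x", "y", "volume"):
        numeric = pd.to_numeric(cells[col], errors="coerce")
        bad = cells.index[numeric.isna() & cells[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} at row {bad[0] + 2}"
            )
        cells[col] = numeric
    cells["n_zplanes"] = pd.to_numeric(cells["n_zplanes"]).astype(int)
    for col in CELL_TABLE_OPTIONAL:
        if col not in cells.columns:
            cells[col] = "" if col in _STRING_CELL_COLUMNS else np.nan
    for col in _STRING_CELL_COLUMNS:
        cells[col] = cells[col].fillna("").astype(str)
    validate_cell_table(cells)
    logger.info("read_cell_table: %d cells from %s", len(cells), path)
    return cells


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    cols = CELL_TABLE_REQUIRED + [c for c in CELL_TABLE_OPTIONAL if c in cells.columns]
    cells.loc[:, cols].to_csv(path, index=False, float_format="%.17g")


@dataclass
class ExpressionMatrix:
    """Cells x genes matrix with named layers (at least ``"raw"``).

    Layers are dense float64 arrays of identical shape.  Raw values must be
    nonnegative and all values finite.
    """

    cells: list[str]
    genes: list[str]
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cells = list(map(str, self.cells))
        self.genes = list(map(str, self.genes))
        for name, arr in list(self.layers.items()):
            arr = np.asarray(arr, dtype=np.float64)
            if arr.shape != self.shape:
                raise ValueError(
                    f"layer {name!r} has shape {arr.shape}, expected {self.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"layer {name!r} contains non-finite values")
            self.layers[name] = arr
        if "raw" in self.layers and (self.layers["raw"] < 0).any():
            raise ValueError("raw layer contains negative values")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.cells), len(self.genes))

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def layer(self, name: str = "raw") -> np.ndarray:
        if name not in self.layers:
            raise KeyError(f"layer {name!r} not present; have {sorted(self.layers)}")
        return self.layers[name]

    def gene_index(self, genes: str | Sequence[str]) -> np.ndarray:
        """Integer indices for one gene name or a sequence of names."""
        lookup = {g: i for i, g in enumerate(self.genes)}
        names = [genes] if isinstance(genes, str) else list(genes)
        missing = [g for g in names if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return np.array([lookup[g] for g in names], dtype=int)

    def subset_cells(self, mask_or_ids: np.ndarray | Sequence[str]) -> "ExpressionMatrix":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype != object:
            idx = np.flatnonzero(mask_or_ids) if mask_or_ids.dtype == bool else mask_or_ids
        else:
            pos = {c: i for i, c in enumerate(self.cells)}
            idx = np.array([pos[c] for c in mask_or_ids], dtype=int)
        return ExpressionMatrix(
            cells=[self.cells[i] for i in idx],
            genes=list(self.genes),
            layers={k: v[idx] for k, v in self.layers.items()},
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(
            cells=list(self.cells),
            genes=[self.genes[i] for i in idx],
            layers={k: v[:, idx] for k, v in self.layers.items()},
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            cells=list(self.cells),
            genes=list(self.genes),
            layers={k: v.copy() for k, v in self.layers.items()},
        )

    def to_anndata(self):
        import anndata

        adata = anndata.AnnData(
            X=self.layer("raw").copy(),
            obs=pd.DataFrame(index=pd.Index(self.cells, name="cell_id")),
            var=pd.DataFrame(index=pd.Index(self.genes, name="gene")),
        )
        for name, arr in self.layers.items():
            if name != "raw":
                adata.layers[name] = arr.copy()
        return adata

    @classmethod
    def from_anndata(cls, adata) -> "ExpressionMatrix":
        def dense(x):
            return np.asarray(x.todense() if scipy.sparse.issparse(x) else x, dtype=np.float64)

        layers = {"raw": dense(adata.X)}
        for name in adata.layers:
            layers[name] = dense(adata.layers[name])
        return cls(cells=list(adata.obs_names), genes=list(adata.var_names), layers=layers)


def read_expression(path: str | Path, format: str = "mtx-triplet") -> ExpressionMatrix:
    """Read an expression matrix into the ``raw`` layer.

    Parameters
    ----------
    path
        For ``mtx-triplet``: the ``.mtx`` file, with ``cells.txt`` and
        ``genes.txt`` sidecars next to it.  For ``dense-delimited``: a CSV
        with cell ids in the first column and gene names in the header.
        For ``hdf5-container``: an ``.h5ad`` file.
    """
    path = Path(path)
    if format == "mtx-triplet":
        cells = path.parent.joinpath("cells.txt").read_text().split()
        genes = path.parent.joinpath("genes.txt").read_text().split()
        mat = scipy.io.mmread(path)
        if mat.shape != (len(cells), len(genes)):
            raise ValueError(
                f"{path}: matrix shape {mat.shape} does not match sidecars "
                f"({len(cells)} cells, {len(genes)} genes)"
            )
        raw = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=np.float64)
    elif format == "dense-delimited":
        df = pd.read_csv(path, index_col=0)
        cells, genes, raw = list(df.index.astype(str)), list(df.columns), df.to_numpy(np.float64)
    elif format == "hdf5-container":
        import anndata

        return ExpressionMatrix.from_anndata(anndata.read_h5ad(path))
    else:
        raise ValueError(f"unknown expression format {format!r}")
    logger.info("read_expression: %s matrix %s", format, raw.shape)
    return ExpressionMatrix(cells=cells, genes=genes, layers={"raw": raw})


def write_expression(expr: ExpressionMatrix, path: str | Path, format: str = "mtx-triplet",
                     layer: str = "raw") -> None:
    path = Path(path)
    if format == "mtx-triplet":
        path.parent.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(expr.layer(layer)))
        path.parent.joinpath("cells.txt").write_text("\n".join(expr.cells) + "\n")
        path.parent.joinpath("genes.txt").write_text("\n".join(expr.genes) + "\n")
    elif format == "dense-delimited":
        pd.DataFrame(expr.layer(layer), index=expr.cells, columns=expr.genes).to_csv(
            path, float_format="%.17g"
        )
    elif format == "hdf5-container":
        expr.to_anndata().write_h5ad(path)
    else:
        raise ValueError(f"unknown expression format {format!r}")


@dataclass(frozen=True)
class LRPair:
    """One ligand-receptor interaction; complexes carry >1 component gene."""

    pair_name: str
    ligand_components: tuple[str, ...]
    receptor_components: tuple[str, ...]
    pathway: str = ""
    category: str = ""


@dataclass
class LRDatabase:
    """Ligand-receptor interaction table in the CellChat column layout."""

    entries: list[LRPair]

    def __post_init__(self) -> None:
        names = [e.pair_name for e in self.entries]
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise ValueError(f"duplicate pair_name values: {sorted(dup)}")
        for e in self.entries:
            if not e.ligand_components or not e.receptor_components:
                raise ValueError(f"pair {e.pair_name!r} has an empty component list")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def read_lr_database(path: str | Path) -> LRDatabase:
    """Read an LR table CSV; complex components are underscore-joined."""
    df = pd.read_csv(path).fillna("")
    required = {"pair_name", "ligand", "receptor"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: LR table needs columns {sorted(required)}")
    entries = []
    for _, row in df.iterrows():
        lig = tuple(g for g in str(row["ligand"]).split("_") if g)
        rec = tuple(g for g in str(row["receptor"]).split("_") if g)
        if not lig or not rec:
            raise ValueError(
                f"pair {row['pair_name']!r}: empty ligand or receptor field"
            )
        entries.append(
            LRPair(
                pair_name=str(row["pair_name"]),
                ligand_components=lig,
                receptor_components=rec,
                pathway=str(row.get("pathway", "")),
                category=str(row.get("category", "")),
            )
        )
    return LRDatabase(entries)


def write_lr_database(db: LRDatabase, path: str | Path) -> None:
    pd.DataFrame(
        {
            "pair_name": [e.pair_name for e in db],
            "ligand": ["_".join(e.ligand_components) for e in db],
            "receptor": ["_".join(e.receptor_components) for e in db],
            "pathway": [e.pathway for e in db],
            "category": [e.category for e in db],
        }
    ).to_csv(path, index=False)


# Stable column orders for the result tables written by write_results.
RESULT_SCHEMAS: Mapping[str, list[str]] = {
    "interactions": [
        "subclass1", "subclass2", "pval", "pval-adjusted", "z_score",
        "proximal_count", "permutation_mean", "permutation_std",
        "fold_change", "region", "supported_by_LR_analysis",
    ],
    "lr": [
        "subclass_ligand", "subclass_receptor", "LR_pair", "N_proximal_pairs",
        "mean_proximal_lr_exp", "exp_fraction", "fold_change", "pval",
        "pval-adjusted", "region", "pathway_name",
    ],
    "gene_upregulation": [
        "subclass_gene_exp", "subclass_interacting", "gene", "proximal_mean",
        "control_mean", "fold_change", "pval", "pval-adjusted", "region",
    ],
}


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write one CSV per result table with a stable, documented column order.

    Known table kinds (keys of :data:`RESULT_SCHEMAS`) are reordered to their
    schema; other tables keep their own column order.  Values round-trip to
    full precision.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        schema = RESULT_SCHEMAS.get(name)
        if schema is not None:
            cols = [c for c in schema if c in df.columns]
            cols += [c for c in df.columns if c not in cols]
            df = df.loc[:, cols]
        dest = out_dir / f"{name}.csv"
        df.to_csv(dest, index=False, float_format="%.17g")
        logger.info("write_results: %s (%d rows)", dest, len(df))
        written.append(dest)
    return written


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
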