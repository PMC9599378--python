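"""Expression and marker-database input handling.

Loads a genes x cells expression matrix (dense CSV/TSV or MatrixMarket
triplet), a CellMatch-style marker table, log-normalizes counts, restricts
the matrix to marker genes and flags cells that cannot be annotated at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

#: label given to cells with zero expression across every marker gene
UNKNOWN_LABEL = "unknown"


@dataclass
class RawCounts:
    """A genes x cells matrix of non-negative values with identifiers.

    ``values`` may hold raw counts or already-normalized expression;
    downstream code does not care which until :func:`lognormalize`.
    """

    values: np.ndarray  # genes x cells
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if (self.values < 0).any():
            raise ValueError("expression values must be non-negative")
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name} identifiers")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class ExpressionMatrix:
    """Log-scale marker-gene x cell matrix, the working matrix of the method.

    ``normalization`` records how the values were produced
    (``"size-factor-log"`` or ``"passthrough"``) so runs are auditable.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    normalization: str = "size-factor-log"

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def cell_index(self, cells: set[str] | list[str]) -> np.ndarray:
        """Column indices of the given cell ids, in matrix order."""
        wanted = set(cells)
        return np.array(
            [i for i, c in enumerate(self.cell_ids) if c in wanted], dtype=int
        )


@dataclass
class MarkerDB:
    """Marker-gene sets per cell type for one species/tissue.

    A gene may legitimately belong to several types' sets; scoring sums a
    gene's importance into every set containing it.
    """

    cell_types: list[str]
    gene_sets: dict[str, set[str]]
    species: str = ""
    tissue: str = ""

    def __post_init__(self) -> None:
        if len(self.cell_types) < 2:
            raise ValueError("need at least 2 cell types with markers")
        for t in self.cell_types:
            if not self.gene_sets.get(t):
                raise ValueError(f"cell type {t!r} has an empty marker set")

    @property
    def all_markers(self) -> set[str]:
        out: set[str] = set()
        for s in self.gene_sets.values():
            out |= s
        return out

    def restricted_to(self, genes: set[str]) -> "MarkerDB":
        """Drop marker genes absent from ``genes``; drop emptied types."""
        kept_sets = {
            t: self.gene_sets[t] & genes
            for t in self.cell_types
            if self.gene_sets[t] & genes
        }
        dropped = [t for t in self.cell_types if t not in kept_sets]
        if dropped:
            logger.warning(
                "dropping %d cell type(s) with no markers in the data: %s",
                len(dropped), ", ".join(dropped),
            )
        return MarkerDB(
            cell_types=[t for t in self.cell_types if t in kept_sets],
            gene_sets=kept_sets,
            species=self.species,
            tissue=self.tissue,
        )


# default column names follow the CellMatch table layout
MARKER_COLUMNS = {
    "species": "speciesType",
    "tissue": "tissueType",
    "resource": "markerResource",
    "cell_type": "shortname",
    "gene": "cellMarker",
}


def load_marker_db(
    path: str | Path,
    species: str,
    tissue: str,
    columns: dict[str, str] | None = None,
    case_fold: bool = False,
) -> MarkerDB:
    """Read a marker table (TSV) and filter it to one species and tissue.

    When a marker-resource column is present, only single-cell derived
    entries (``Single-cell sequencing``/``scRNA-seq``, case-insensitive
    substring ``single``) are kept. Gene symbols are deduplicated per cell
    type; types left without genes are dropped with a warning.
    """
    cols = dict(MARKER_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = [cols["species"], cols["tissue"], cols["cell_type"], cols["gene"]]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"marker table is missing required columns: {missing}")

    mask = (df[cols["species"]] == species) & (df[cols["tissue"]] == tissue)
    if cols["resource"] in df.columns:
        mask &= df[cols["resource"]].str.contains("single", case=False, na=False)
    sub = df.loc[mask].dropna(subset=[cols["gene"], cols["cell_type"]])
    if sub.empty:
        raise ValueError(
            f"no markers for species={species!r} tissue={tissue!r} after filtering"
        )

    gene_sets: dict[str, set[str]] = {}
    for t, grp in sub.groupby(cols["cell_type"], sort=True):
        genes = set(grp[cols["gene"]])
        if case_fold:
            genes = {g.upper() for g in genes}
        if genes:
            gene_sets[str(t)] = genes
    empty = [t for t in gene_sets if not gene_sets[t]]
    for t in empty:
        logger.warning("cell type %r has no marker genes after filtering; dropped", t)
        del gene_sets[t]
    return MarkerDB(
        cell_types=sorted(gene_sets), gene_sets=gene_sets,
        species=species, tissue=tissue,
    )


def read_expression(
    path: str | Path,
    orientation: str = "genes-by-cells",
    genes_file: str | Path | None = None,
    cells_file: str | Path | None = None,
) -> RawCounts:
    """Read dense CSV/TSV (first column gene ids, header cell ids) or a
    MatrixMarket ``.mtx`` with side files listing row/column names.

    ``orientation`` declares the layout on disk explicitly
    (``genes-by-cells`` or ``cells-by-genes``) rather than guessing from
    shape.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        if genes_file is None or cells_file is None:
            raise ValueError(".mtx input requires genes and cells name files")
        mat = scipy.io.mmread(path)
        genes = [ln.split("\t")[0].strip() for ln in Path(genes_file).read_text().splitlines() if ln.strip()]
        cells = [ln.split("\t")[0].strip() for ln in Path(cells_file).read_text().splitlines() if ln.strip()]
        values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
    else:
        sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        genes = [str(g) for g in df.index]
        cells = [str(c) for c in df.columns]
        values = df.to_numpy(dtype=float)
    if orientation == "cells-by-genes":
        values = values.T
        genes, cells = cells, genes
    elif orientation != "genes-by-cells":
        raise ValueError(f"unknown orientation {orientation!r}")
    return RawCounts(values=values, gene_ids=genes, cell_ids=cells)


def lognormalize(raw: RawCounts, mode: str = "size-factor-log") -> RawCounts:
    """Size-factor normalize each cell to the median library size, then log1p.

    Each cell's column is rescaled so its total equals the median of the
    per-cell totals, correcting for read depth, before log(1+x). Cells with
    zero total have no defined size factor and are dropped with a warning —
    they cannot be annotated anyway. ``mode="passthrough"`` returns the
    input unchanged for data that is already normalized.
    """
    if mode == "passthrough":
        return raw
    if mode != "size-factor-log":
        raise ValueError(f"unknown normalization mode {mode!r}")
    totals = raw.values.sum(axis=0)
    keep = totals > 0
    if not keep.all():
        dropped = [c for c, k in zip(raw.cell_ids, keep) if not k]
        logger.warning("dropping %d zero-total cell(s): %s", len(dropped), dropped[:10])
    values = raw.values[:, keep]
    totals = totals[keep]
    if values.shape[1] == 0:
        raise ValueError("all cells have zero total counts")
    median_total = float(np.median(totals))
    scaled = values * (median_total / totals)
    return RawCounts(
        values=np.log1p(scaled),
        gene_ids=raw.gene_ids,
        cell_ids=[c for c, k in zip(raw.cell_ids, keep) if k],
    )


def restrict_to_markers(
    expr: RawCounts, db: MarkerDB
) -> tuple[ExpressionMatrix, set[str]]:
    """Keep only marker-gene rows; identify unannotatable cells.

    Rows are the union of all marker sets present in the data, minus rows
    that are zero in every cell. Cells whose restricted column is entirely
    zero express no marker at all and are returned separately as the
    ``unknown`` set — the pipeline labels them "unknown" and excludes them
    from all downstream stages.
    """
    marker_rows = [i for i, g in enumerate(expr.gene_ids) if g in db.all_markers]
    if not marker_rows:
        raise ValueError("no marker genes found in the expression data")
    values = expr.values[marker_rows, :]
    genes = [expr.gene_ids[i] for i in marker_rows]

    nonzero_gene = (values != 0).any(axis=1)
    values = values[nonzero_gene, :]
    genes = [g for g, k in zip(genes, nonzero_gene) if k]
    if not genes:
        raise ValueError("every marker gene is zero across all cells")

    nonzero_cell = (values != 0).any(axis=0)
    unknown = {c for c, k in zip(expr.cell_ids, nonzero_cell) if not k}
    if unknown:
        logger.info("%d cell(s) express no marker gene; labeled %s",
                    len(unknown), UNKNOWN_LABEL)
    values = values[:, nonzero_cell]
    cells = [c for c, k in zip(expr.cell_ids, nonzero_cell) if k]
    return (
        ExpressionMatrix(values=values, gene_ids=genes, cell_ids=cells),
        unknown,
    )
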