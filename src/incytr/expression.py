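"""Single-cell expression handling: normalization and robust group averages.

Counts are normalized per cell to a fixed library size (10,000) and
log1p-transformed — the standard library-size normalization used throughout
the single-cell ecosystem.  The per-group, per-condition average expression
AE of a gene is Tukey's trimean of its normalized values,

    AE = Q2/2 + (Q1 + Q3)/4,

a location estimate robust to the heavy-tailed noise of droplet data.
Quartiles use linear interpolation of the order statistics (the NumPy
default), fixed for reproducibility and configurable via ``method``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

logger = logging.getLogger(__name__)

NORMALIZE_SCALE = 10_000.0


@dataclass
class ExpressionMatrix:
    """A genes-by-cells matrix of counts or normalized expression."""

    genes: list[str]
    cells: list[str]
    values: np.ndarray  # shape (n_genes, n_cells), float
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite")
        if (self.values < 0).any():
            raise ValueError("expression values must be nonnegative")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols")
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("duplicate cell ids")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    def gene_row(self, gene: str) -> np.ndarray:
        return self.values[self._gene_index[gene]]

    def __contains__(self, gene: str) -> bool:
        return gene in self._gene_index


@dataclass
class CellAnnotation:
    """Per-cell group and condition labels."""

    table: pd.DataFrame = field(repr=False)  # columns cell_id, group, condition

    def __post_init__(self) -> None:
        for col in ("cell_id", "group", "condition"):
            if col not in self.table.columns:
                raise ValueError(f"cell annotation missing column {col!r}")
        if self.table["cell_id"].duplicated().any():
            raise ValueError("duplicate cell ids in annotation")
        self.table = self.table.reset_index(drop=True)

    @property
    def groups(self) -> list[str]:
        return sorted(self.table["group"].unique())

    @property
    def conditions(self) -> list[str]:
        return sorted(self.table["condition"].unique())

    def cells_of(self, group: str | None = None, condition: str | None = None) -> list[str]:
        t = self.table
        if group is not None:
            t = t[t["group"] == group]
        if condition is not None:
            t = t[t["condition"] == condition]
        return list(t["cell_id"])

    def group_sizes(self, condition: str | None = None) -> dict[str, int]:
        t = self.table
        if condition is not None:
            t = t[t["condition"] == condition]
        return t.groupby("group").size().to_dict()


def normalize_counts(raw: ExpressionMatrix, scale: float = NORMALIZE_SCALE) -> ExpressionMatrix:
    """Library-size normalize and log1p-transform a count matrix.

    Each cell's counts are divided by the cell total, multiplied by
    ``scale`` and log1p-transformed.  Cells with zero total counts are kept
    as all-zero columns (with a warning).
    """
    if raw.normalized:
        raise ValueError("matrix is already normalized")
    totals = raw.values.sum(axis=0)
    zero = totals == 0
    if zero.any():
        logger.warning("%d cells have zero total counts", int(zero.sum()))
    safe = np.where(zero, 1.0, totals)
    vals = np.log1p(raw.values / safe * scale)
    return ExpressionMatrix(
        genes=list(raw.genes), cells=list(raw.cells), values=vals, normalized=True
    )


def trimean(values, method: str = "linear") -> float:
    """Tukey's trimean Q2/2 + (Q1+Q3)/4 of a nonempty sample."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("trimean of empty input")
    q1, q2, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method=method)
    return float(0.5 * q2 + 0.25 * (q1 + q3))


def _trimean_rows(mat: np.ndarray, method: str = "linear") -> np.ndarray:
    """Row-wise trimean of a 2-D array (genes x cells)."""
    q = np.quantile(mat, [0.25, 0.5, 0.75], axis=1, method=method)
    return 0.5 * q[1] + 0.25 * (q[0] + q[2])


@dataclass
class GroupExpression:
    """Trimean average expression AE per gene, cell group and condition.

    ``table`` is a long DataFrame (gene, group, condition, AE).  Entries for
    empty group-condition combinations are absent.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self._lookup = {
            (r.gene, r.group, r.condition): r.AE
            for r in self.table.itertuples(index=False)
        }

    def ae(self, gene: str, group: str, condition: str, default: float | None = None) -> float:
        key = (gene, group, condition)
        if key in self._lookup:
            return self._lookup[key]
        if default is not None:
            return default
        raise KeyError(key)

    def ae_by_group(self, gene: str, condition: str) -> dict[str, float]:
        """AE of one gene across every group of a condition."""
        sub = self.table[
            (self.table["gene"] == gene) & (self.table["condition"] == condition)
        ]
        return dict(zip(sub["group"], sub["AE"]))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def group_average_expression(
    expr: ExpressionMatrix,
    ann: CellAnnotation,
    genes: list[str] | None = None,
    method: str = "linear",
) -> GroupExpression:
    """Compute AE for every (gene, group, condition) with at least one cell.

    Every cell of ``expr`` must carry an annotation row; a missing label is
    a hard error rather than a silent drop.
    """
    if not expr.normalized:
        raise ValueError("group averages are computed on normalized expression")
    ann_cells = set(ann.table["cell_id"])
    missing = [c for c in expr.cells if c not in ann_cells]
    if missing:
        raise ValueError(
            f"{len(missing)} cells lack annotation rows (first: {missing[0]!r})"
        )
    if genes is None:
        genes = list(expr.genes)
    gene_rows = np.array([expr._gene_index[g] for g in genes])
    col_of = {c: j for j, c in enumerate(expr.cells)}

    rows = []
    for condition in ann.conditions:
        for group in ann.groups:
            cells = ann.cells_of(group=group, condition=condition)
            cols = [col_of[c] for c in cells if c in col_of]
            if not cols:
                logger.info("no cells for group=%s condition=%s", group, condition)
                continue
            sub = expr.values[np.ix_(gene_rows, cols)]
            aes = _trimean_rows(sub, method=method)
            for g, ae in zip(genes, aes):
                rows.append((g, group, condition, float(ae)))
    return GroupExpression(
        table=pd.DataFrame(rows, columns=["gene", "group", "condition", "AE"])
    )


# ---------------------------------------------------------------------------
# I/O


def read_counts_mtx(
    matrix_path: str | Path, genes_path: str | Path, barcodes_path: str | Path
) -> ExpressionMatrix:
    """Read an MTX triplet (matrix + gene list + barcode list), genes as rows."""
    mat = np.asarray(mmread(str(matrix_path)).todense(), dtype=float)
    genes = read_gene_list(genes_path)
    cells = read_gene_list(barcodes_path)
    return ExpressionMatrix(genes=genes, cells=cells, values=mat, normalized=False)


def read_counts_csv(path: str | Path) -> ExpressionMatrix:
    """Read a dense genes-by-cells CSV (first column gene symbols)."""
    df = pd.read_csv(path, index_col=0)
    return ExpressionMatrix(
        genes=[str(g) for g in df.index],
        cells=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
        normalized=False,
    )


def read_cell_metadata(path: str | Path) -> CellAnnotation:
    """Read the cell metadata CSV (cell_id, group, condition)."""
    return CellAnnotation(table=pd.read_csv(path, dtype=str))


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text list, one symbol per line; '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out
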