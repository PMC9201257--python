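"""Core in-memory container for labeled single-cell expression matrices.

The whole pipeline operates on one object: a dense cells x genes matrix of
non-negative expression values (RPKM-like units) together with gene
identifiers, cell identifiers and a binary class label per cell (positive
class = cells from type-2-diabetic donors by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ExpressionDataset"]


@dataclass
class ExpressionDataset:
    """Cells x genes expression matrix with per-cell binary labels.

    Parameters
    ----------
    values
        Dense ``(n_cells, n_genes)`` float array of non-negative, finite
        expression values on the RPKM scale (no log transform).
    gene_ids
        Unique gene identifier per column (Entrez-style numeric id as a
        string).
    cell_ids
        Identifier per row.
    labels
        Per-cell class label; ``None`` for an unlabeled matrix.
    symbols
        Optional gene symbol per column, aligned with ``gene_ids``.
    positive_class
        Which label value counts as the positive class in confusion
        summaries; configurable, "T2D" by default.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    labels: np.ndarray | None = None
    symbols: list[str] | None = None
    positive_class: str = "T2D"
    log1p: bool = False  # expression values are used raw unless this is set

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-dimensional")
        n_cells, n_genes = self.values.shape
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            dupes = sorted(
                g for g in set(self.gene_ids) if self.gene_ids.count(g) > 1
            )
            raise ValueError(f"duplicate gene ids: {dupes}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("expression matrix contains negative values")
        if self.symbols is not None and len(self.symbols) != n_genes:
            raise ValueError("symbols length does not match gene count")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape[0] != n_cells:
                raise ValueError("labels length does not match cell count")
            if len(set(self.labels)) > 2:
                raise ValueError(
                    f"more than two classes: {sorted(set(self.labels))}"
                )
        if self.log1p:
            self.values = np.log1p(self.values)

    # -- basic introspection -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> list[str]:
        if self.labels is None:
            raise ValueError("dataset is unlabeled")
        return sorted(set(self.labels))

    def require_two_classes(self) -> None:
        """Raise unless both classes are present (needed for training)."""
        if self.labels is None:
            raise ValueError("dataset is unlabeled")
        if len(set(self.labels)) != 2:
            raise ValueError(
                "both classes must be present; got "
                f"{sorted(set(self.labels))}"
            )

    def y(self) -> np.ndarray:
        """Labels as a 0/1 integer vector (1 = positive class)."""
        if self.labels is None:
            raise ValueError("dataset is unlabeled")
        return (self.labels == self.positive_class).astype(int)

    # -- derived views -------------------------------------------------------

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionDataset":
        """Restrict to the given genes, preserving the requested order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"genes absent from dataset: {missing}")
        cols = [index[g] for g in gene_ids]
        return ExpressionDataset(
            values=self.values[:, cols],
            gene_ids=list(gene_ids),
            cell_ids=list(self.cell_ids),
            labels=None if self.labels is None else self.labels.copy(),
            symbols=None
            if self.symbols is None
            else [self.symbols[c] for c in cols],
            positive_class=self.positive_class,
        )

    def subset_cells(self, rows: np.ndarray) -> "ExpressionDataset":
        rows = np.asarray(rows)
        return ExpressionDataset(
            values=self.values[rows],
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in np.atleast_1d(rows)],
            labels=None if self.labels is None else self.labels[rows],
            symbols=None if self.symbols is None else list(self.symbols),
            positive_class=self.positive_class,
        )

    def with_labels(self, labels: np.ndarray) -> "ExpressionDataset":
        return ExpressionDataset(
            values=self.values,
            gene_ids=list(self.gene_ids),
            cell_ids=list(self.cell_ids),
            labels=np.asarray(labels, dtype=object),
            symbols=None if self.symbols is None else list(self.symbols),
            positive_class=self.positive_class,
        )
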