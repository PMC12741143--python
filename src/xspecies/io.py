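"""Data containers and readers/writers for the external formats used across the
pipeline: 10x-style MTX triplets, tab-separated metadata tables, GMT gene-set
collections, plus the shared depth-normalization step.

In-memory orientation is always cells x genes; MTX on disk follows the 10x
convention (genes x cells) and is transposed on load/write. Counts are held
dense: the package targets desk-scale synthetic and downsampled data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "CountMatrix",
    "OrthologTable",
    "GeneSetCollection",
    "load_counts",
    "write_counts",
    "load_gene_sets",
    "load_table",
    "normalize_log1p",
]


@dataclass
class CountMatrix:
    """Cells x genes integer count matrix with an optional log-normalized layer.

    Attributes
    ----------
    counts : ndarray of shape (n_cells, n_genes)
        Non-negative integer UMI counts.
    gene_ids, cell_ids : ndarray of str
        Ordered, duplicate-free identifiers for columns and rows.
    normalized : ndarray or None
        log1p of depth-scaled counts, same shape as ``counts``.
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    normalized: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-dimensional (cells x genes)")
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells or len(self.gene_ids) != n_genes:
            raise ValueError(
                f"shape mismatch: counts {self.counts.shape} vs "
                f"{len(self.cell_ids)} cells / {len(self.gene_ids)} genes"
            )
        if pd.Index(self.gene_ids).has_duplicates:
            raise ValueError("gene_ids contain duplicates")
        if pd.Index(self.cell_ids).has_duplicates:
            raise ValueError("cell_ids contain duplicates")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if self.counts.size and not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if self.normalized is not None:
            self.normalized = np.asarray(self.normalized, dtype=float)
            if self.normalized.shape != self.counts.shape:
                raise ValueError("normalized layer shape differs from counts")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def normalize(self, scale_per_cell: float = 10_000.0) -> "CountMatrix":
        """Attach the log1p depth-normalized layer (in place); returns self."""
        self.normalized = normalize_log1p(self.counts, scale_per_cell)
        return self

    def subset_cells(self, mask_or_ids) -> "CountMatrix":
        idx = _as_row_index(mask_or_ids, self.cell_ids)
        return CountMatrix(
            counts=self.counts[idx],
            gene_ids=self.gene_ids.copy(),
            cell_ids=self.cell_ids[idx],
            normalized=None if self.normalized is None else self.normalized[idx],
        )

    def subset_genes(self, genes) -> "CountMatrix":
        pos = pd.Index(self.gene_ids).get_indexer(list(genes))
        if (pos < 0).any():
            missing = [g for g, p in zip(genes, pos) if p < 0]
            raise KeyError(f"genes not found: {missing[:10]}")
        return CountMatrix(
            counts=self.counts[:, pos],
            gene_ids=np.asarray(list(genes), dtype=object),
            cell_ids=self.cell_ids.copy(),
            normalized=None if self.normalized is None else self.normalized[:, pos],
        )


def _as_row_index(mask_or_ids, cell_ids: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask_or_ids)
    if arr.dtype == bool:
        if arr.shape[0] != len(cell_ids):
            raise ValueError("boolean mask length differs from n_cells")
        return np.flatnonzero(arr)
    if np.issubdtype(arr.dtype, np.integer):
        return arr
    pos = pd.Index(cell_ids).get_indexer(arr)
    if (pos < 0).any():
        raise KeyError("some cell ids not present in matrix")
    return pos


@dataclass
class OrthologTable:
    """n:m ortholog pairs (source_gene -> target_gene), duplicate-free."""

    pairs: pd.DataFrame  # columns: source_gene, target_gene

    def __post_init__(self) -> None:
        required = {"source_gene", "target_gene"}
        if not required.issubset(self.pairs.columns):
            raise ValueError("ortholog table needs source_gene/target_gene columns")
        self.pairs = self.pairs[["source_gene", "target_gene"]].astype(str).reset_index(drop=True)
        if self.pairs.duplicated().any():
            raise ValueError("duplicate ortholog pairs")

    def __len__(self) -> int:
        return len(self.pairs)

    def targets_of(self, source: str) -> list[str]:
        sel = self.pairs.loc[self.pairs["source_gene"] == source, "target_gene"]
        return sorted(sel.tolist())

    def sources_of(self, target: str) -> list[str]:
        sel = self.pairs.loc[self.pairs["target_gene"] == target, "source_gene"]
        return sorted(sel.tolist())


@dataclass
class GeneSetCollection:
    """Named gene sets (pathway -> member genes) from one source database."""

    sets: dict[str, set[str]]
    source_db: str = "unknown"

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def load_counts(matrix_path, genes_path, cells_path) -> CountMatrix:
    """Read a 10x-style MTX triplet (matrix genes x cells, gene TSV, cell TSV).

    The first column of each TSV is taken as the identifier. Non-integer
    matrix entries and header/TSV dimension mismatches are fatal.
    """
    mat = spio.mmread(str(matrix_path))
    mat = sparse.coo_matrix(mat)
    dense = np.asarray(mat.todense())
    if not np.allclose(dense, np.round(dense)):
        raise ValueError(f"{matrix_path}: non-integer entries in count matrix")
    dense = np.round(dense).astype(np.int64)
    genes = _read_id_column(genes_path)
    cells = _read_id_column(cells_path)
    if dense.shape != (len(genes), len(cells)):
        raise ValueError(
            f"dimension mismatch: MTX is {dense.shape} (genes x cells) but TSVs "
            f"declare {len(genes)} genes / {len(cells)} cells"
        )
    return CountMatrix(counts=dense.T, gene_ids=np.asarray(genes, dtype=object),
                       cell_ids=np.asarray(cells, dtype=object))


def _read_id_column(path) -> list[str]:
    ids = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def write_counts(cm: CountMatrix, out_dir, prefix: str = "") -> dict[str, Path]:
    """Write the MTX triplet (genes x cells on disk) under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / f"{prefix}matrix.mtx",
        "genes": out_dir / f"{prefix}genes.tsv",
        "cells": out_dir / f"{prefix}barcodes.tsv",
    }
    spio.mmwrite(str(paths["matrix"]), sparse.coo_matrix(cm.counts.T), field="integer")
    paths["genes"].write_text("".join(f"{g}\n" for g in cm.gene_ids), encoding="utf-8")
    paths["cells"].write_text("".join(f"{c}\n" for c in cm.cell_ids), encoding="utf-8")
    return paths


def load_gene_sets(gmt_path, source_db: str = "unknown") -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> gene2 ...

    Lines with fewer than 3 fields are skipped with a warning; a duplicated
    set name is fatal. Duplicate genes within a line collapse to one.
    """
    sets: dict[str, set[str]] = {}
    with open(gmt_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                warnings.warn(f"{gmt_path}:{lineno}: fewer than 3 fields, skipped")
                continue
            name = fields[0]
            if name in sets:
                raise ValueError(f"{gmt_path}: duplicate gene-set name {name!r}")
            members = {g for g in fields[2:] if g}
            if members:
                sets[name] = members
    return GeneSetCollection(sets=sets, source_db=source_db)


def load_table(path, required: list[str] | None = None) -> pd.DataFrame:
    """Read a headered TSV; missing required columns are fatal (named)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in required or []:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df


def normalize_log1p(counts: np.ndarray, scale_per_cell: float = 10_000.0) -> np.ndarray:
    """log(1 + count * scale / cell_total) per cell; all-zero cells stay zero."""
    if scale_per_cell <= 0:
        raise ValueError("scale_per_cell must be positive")
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    safe = np.where(totals > 0, totals, 1.0)
    return np.log1p(counts * (scale_per_cell / safe))
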