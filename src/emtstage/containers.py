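"""Shared data containers used across the pipeline.

Matrices are stored genes x observations (cells, samples or AOIs), mirroring
the layout of the 10x MTX deposit format.  Annotation tables are pandas
DataFrames indexed by the corresponding axis labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass
class CountMatrix:
    """Sparse non-negative integer counts, genes x cells (or samples/AOIs).

    Attributes
    ----------
    X : scipy.sparse.csr_matrix
        genes x observations count matrix.
    genes : pd.Index
        Gene symbols (unique).
    cells : pd.Index
        Observation barcodes / sample ids (unique).
    gene_meta : pd.DataFrame
        Per-gene annotations, indexed like ``genes``; carries at least a
        boolean ``mito`` column when mitochondrial genes are flagged.
    cell_meta : pd.DataFrame
        Per-observation annotations indexed like ``cells``.
    """

    X: sp.spmatrix
    genes: pd.Index
    cells: pd.Index
    gene_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    cell_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        self.genes = pd.Index(self.genes, name="gene")
        self.cells = pd.Index(self.cells, name="cell")
        if self.X.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if not self.genes.is_unique:
            raise ValueError("gene identifiers must be unique")
        if not self.cells.is_unique:
            raise ValueError("cell identifiers must be unique")
        if self.gene_meta.empty:
            self.gene_meta = pd.DataFrame(index=self.genes)
        if self.cell_meta.empty:
            self.cell_meta = pd.DataFrame(index=self.cells)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def mito_flags(self) -> np.ndarray:
        """Boolean per-gene mitochondrial flags (all False if unannotated)."""
        if "mito" in self.gene_meta.columns:
            return self.gene_meta["mito"].to_numpy(dtype=bool)
        return np.zeros(self.n_genes, dtype=bool)

    def subset(self, gene_mask=None, cell_mask=None) -> "CountMatrix":
        X = self.X
        genes, cells = self.genes, self.cells
        gmeta, cmeta = self.gene_meta, self.cell_meta
        if gene_mask is not None:
            X = X[gene_mask, :]
            genes = genes[gene_mask]
            gmeta = gmeta.loc[genes]
        if cell_mask is not None:
            X = X[:, cell_mask]
            cells = cells[cell_mask]
            cmeta = cmeta.loc[cells]
        return CountMatrix(X, genes, cells, gmeta.copy(), cmeta.copy())

    def to_dense(self) -> pd.DataFrame:
        return pd.DataFrame(self.X.toarray(), index=self.genes, columns=self.cells)


@dataclass
class NormalizedMatrix:
    """Dense genes x cells matrix on a stated log2 scale.

    ``values[g, c] = log2(1 + count * target_sum / library_size)``; zero
    counts map to exactly zero.  Provenance fields record the transform.
    """

    values: pd.DataFrame  # genes x cells, float
    target_sum: float
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("normalized values must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def cells(self) -> pd.Index:
        return self.values.columns


@dataclass
class PairedSegmentsMatrix:
    """Gene x AOI matrix with paired ROI segment annotations.

    Each ROI contributes exactly one ``vim_pos`` and one ``vim_neg`` AOI.
    """

    values: pd.DataFrame  # genes x AOIs, non-negative
    annotations: pd.DataFrame  # index = AOI ids; columns roi_id, segment

    SEGMENTS = ("vim_pos", "vim_neg")

    def __post_init__(self) -> None:
        if list(self.annotations.index) != list(self.values.columns):
            raise ValueError("annotation index must match AOI columns")
        bad = set(self.annotations["segment"]) - set(self.SEGMENTS)
        if bad:
            raise ValueError(f"unknown segment labels: {sorted(bad)}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("segment values must be non-negative")
        counts = self.annotations.groupby("roi_id")["segment"].apply(
            lambda s: sorted(s) == sorted(self.SEGMENTS)
        )
        if not counts.all():
            missing = counts.index[~counts].tolist()
            raise ValueError(f"ROIs without both segments: {missing}")

    @property
    def roi_ids(self) -> list:
        return sorted(self.annotations["roi_id"].unique().tolist())

    def segment_columns(self, segment: str) -> pd.DataFrame:
        """Columns of one segment, ordered by ROI id."""
        ann = self.annotations[self.annotations["segment"] == segment]
        ann = ann.sort_values("roi_id")
        return self.values[ann.index]
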