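"""Shared domain containers.

All expression containers are thin wrappers around pandas objects so that
gene and cell-type labels travel with the numbers. Matrices are oriented
genes x (cells | types | samples | spots) throughout, matching the layout
of 10x-style count matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

CP10K = 1.0e4


@dataclass
class ReferenceCounts:
    """Annotated single-cell count matrix.

    Parameters
    ----------
    counts
        genes x cells matrix of non-negative read/UMI counts.
    gene_ids
        Gene identifiers, one per row of ``counts``.
    cell_types
        Per-cell cell-type label (at least two distinct types).
    sample_ids
        Per-cell donor/sample label.
    ercc_mask
        Per-gene boolean marking spike-in rows. Spike-in rows are excluded
        from the endogenous gene set used for signatures and markers.
    """

    counts: np.ndarray
    gene_ids: pd.Index
    cell_types: np.ndarray
    sample_ids: np.ndarray
    ercc_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = pd.Index(self.gene_ids)
        self.cell_types = np.asarray(self.cell_types)
        self.sample_ids = np.asarray(self.sample_ids)
        if self.ercc_mask is None:
            self.ercc_mask = np.zeros(self.counts.shape[0], dtype=bool)
        self.ercc_mask = np.asarray(self.ercc_mask, dtype=bool)
        g, n = self.counts.shape
        if len(self.gene_ids) != g:
            raise ValueError(
                f"gene_ids has {len(self.gene_ids)} entries for {g} rows"
            )
        if len(self.cell_types) != n or len(self.sample_ids) != n:
            raise ValueError("per-cell annotations must match the cell count")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(self.type_names) < 2:
            raise ValueError("reference must contain at least two cell types")

    @property
    def type_names(self) -> list:
        return sorted(pd.unique(self.cell_types))

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def endogenous(self) -> tuple[np.ndarray, pd.Index]:
        """Counts and gene ids with spike-in rows removed."""
        keep = ~self.ercc_mask
        return self.counts[keep], self.gene_ids[keep]

    def spikeins(self) -> tuple[np.ndarray, pd.Index]:
        keep = self.ercc_mask
        return self.counts[keep], self.gene_ids[keep]


@dataclass
class FullSignature:
    """Genes x cell-types pseudobulk profile matrix on the CP10K scale.

    Every column sums to 10^4: each entry is the expected expression of a
    gene in 10,000 transcripts drawn from one cell type.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        colsums = self.values.to_numpy().sum(axis=0)
        if (self.values.to_numpy() < 0).any():
            raise ValueError("signature entries must be non-negative")
        if not np.allclose(colsums, CP10K, rtol=1e-6):
            raise ValueError("each FullSignature column must sum to 10^4")

    @property
    def cell_type_names(self) -> list:
        return list(self.values.columns)


@dataclass
class SignatureMatrix:
    """Marker-restricted signature matrix S (genes x cell types, CP10K scale).

    ``marker_sets`` maps each cell type to its ordered marker genes; a gene
    that is a top marker for several types occupies a single row but is
    recorded in every owning set.
    """

    values: pd.DataFrame
    marker_sets: dict[str, list[str]]
    top_n: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("signature entries must be non-negative")
        rows = set(self.values.index)
        for ct, genes in self.marker_sets.items():
            missing = set(genes) - rows
            if missing:
                raise ValueError(
                    f"marker genes of {ct!r} absent from matrix rows: "
                    f"{sorted(missing)[:5]}"
                )

    @property
    def cell_type_names(self) -> list:
        return list(self.values.columns)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def restrict_types(self, types: list[str]) -> "SignatureMatrix":
        """Keep only ``types`` columns and the union of their markers."""
        keep_genes = []
        seen = set()
        for ct in types:
            for g in self.marker_sets[ct]:
                if g not in seen:
                    seen.add(g)
                    keep_genes.append(g)
        keep_genes = [g for g in self.values.index if g in seen]
        return SignatureMatrix(
            values=self.values.loc[keep_genes, list(types)],
            marker_sets={ct: list(self.marker_sets[ct]) for ct in types},
            top_n=self.top_n,
        )


@dataclass
class MixtureProfile:
    """A single bulk sample or spatial spot on the CP10K scale.

    ``values`` is indexed by gene and is expected to sum to 10^4 over the
    full shared gene set before restriction to marker genes.
    """

    values: pd.Series
    id: str = "mixture"
    coords: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("mixture values must be non-negative")


@dataclass
class CellSizeVector:
    """Per-cell-type RNA-content coefficients c_j.

    ``method`` records provenance: ``ercc`` (spike-in derived),
    ``computational`` (residual-driven estimate), or ``uniform`` (all ones).
    """

    c: pd.Series
    method: str = "uniform"
    per_cell_content: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if (self.c.to_numpy() <= 0).any():
            raise ValueError("cell size coefficients must be positive")
        if self.method == "uniform" and not np.allclose(self.c.to_numpy(), 1.0):
            raise ValueError("uniform cell sizes must all equal 1")

    @classmethod
    def uniform(cls, cell_types: list) -> "CellSizeVector":
        return cls(c=pd.Series(1.0, index=list(cell_types)), method="uniform")

    def relative(self) -> "CellSizeVector":
        """Rescale to mean one: only size ratios matter for deconvolution,
        and a mean-one c keeps the reconstruction on the CP10K scale."""
        return CellSizeVector(
            c=self.c / self.c.mean(),
            method=self.method,
            per_cell_content=self.per_cell_content,
        )

    def aligned(self, cell_types: list) -> np.ndarray:
        return self.c.reindex(list(cell_types)).to_numpy(dtype=float)


@dataclass
class DeconvolutionFit:
    """Result of deconvolving one mixture.

    ``proportions`` are cell-number fractions on the simplex;
    ``reconstruction`` is the inferred mixture sum_j c_j x_j s_ij on the
    marker genes, whose Spearman correlation with the observed mixture is
    ``score``.
    """

    proportions: pd.Series
    weights: np.ndarray
    beta: float
    reconstruction: pd.Series
    n_iter: int
    converged: bool
    score: float
    capped_weights: Optional[np.ndarray] = None
    cap_quantile: Optional[float] = None
    delta: Optional[pd.Series] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        x = self.proportions.to_numpy(dtype=float)
        if (x < -1e-8).any() or abs(x.sum() - 1.0) > 1e-8:
            raise ValueError("proportions must lie on the simplex")
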