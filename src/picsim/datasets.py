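"""The peak-by-cell count container used throughout the package.

A :class:`CountDataset` holds a sparse non-negative integer matrix with peaks
as rows and cells as columns, plus aligned annotation tables. It is the
universal input (estimation, diagnostics) and output (simulation) type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["CountDataset"]


def _default_peaks(n: int) -> pd.DataFrame:
    return pd.DataFrame(index=pd.Index([f"peak{i + 1}" for i in range(n)], name="peak_id"))


def _default_cells(n: int) -> pd.DataFrame:
    return pd.DataFrame(index=pd.Index([f"cell{j + 1}" for j in range(n)], name="cell_id"))


@dataclass
class CountDataset:
    """Peak-by-cell integer count matrix with peak and cell annotations.

    Parameters
    ----------
    counts
        Sparse or dense matrix, peaks x cells, non-negative integers.
    peaks
        Per-peak annotation; index = peak ids. Optional columns include
        genomic coordinates (``chrom``, ``start``, ``end``) and truth columns.
    cells
        Per-cell annotation; index = barcodes. Optional columns include
        ``group``, ``batch``, ``individual``.
    """

    counts: sp.csr_matrix
    peaks: pd.DataFrame = None  # type: ignore[assignment]
    cells: pd.DataFrame = None  # type: ignore[assignment]
    uns: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        else:
            self.counts = self.counts.tocsr()
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        data = self.counts.data
        if data.size and not np.allclose(data, np.round(data)):
            raise ValueError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        if self.peaks is None:
            self.peaks = _default_peaks(self.n_peaks)
        if self.cells is None:
            self.cells = _default_cells(self.n_cells)
        if len(self.peaks) != self.n_peaks:
            raise ValueError(
                f"peak annotation length {len(self.peaks)} != matrix rows {self.n_peaks}"
            )
        if len(self.cells) != self.n_cells:
            raise ValueError(
                f"cell annotation length {len(self.cells)} != matrix columns {self.n_cells}"
            )

    # -- basic geometry -------------------------------------------------
    @property
    def n_peaks(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    # -- summaries ------------------------------------------------------
    def library_sizes(self) -> np.ndarray:
        """Total counts per cell (column sums)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def peak_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def cells_detected_per_peak(self) -> np.ndarray:
        """Number of cells with a nonzero count, per peak."""
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def zero_fraction_per_cell(self) -> np.ndarray:
        nz = np.asarray((self.counts > 0).sum(axis=0)).ravel()
        return 1.0 - nz / self.n_peaks

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    # -- subsetting -----------------------------------------------------
    def subset_peaks(self, mask: np.ndarray) -> "CountDataset":
        mask = np.asarray(mask)
        return CountDataset(
            self.counts[mask, :], self.peaks.iloc[mask].copy(), self.cells.copy(), dict(self.uns)
        )

    def subset_cells(self, mask: np.ndarray) -> "CountDataset":
        mask = np.asarray(mask)
        return CountDataset(
            self.counts[:, mask], self.peaks.copy(), self.cells.iloc[mask].copy(), dict(self.uns)
        )
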