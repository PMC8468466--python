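"""Core data containers for sparse per-omics matrices and cell labels.

Orientation convention: omics matrices are features x cells throughout the
package (rows = genes / methylation sites / accessibility bins, columns =
single cells). Per-cell operations therefore act on columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

OMICS_KINDS = ("expression", "methylation", "accessibility")


def _check_unique(ids: np.ndarray, what: str) -> None:
    uniq, counts = np.unique(ids, return_counts=True)
    dup = uniq[counts > 1]
    if dup.size:
        raise ValueError(f"duplicate {what}: {', '.join(map(str, dup[:10]))}")


@dataclass
class SparseOmicsMatrix:
    """One omics layer: sparse features x cells matrix plus identifiers.

    Parameters
    ----------
    values : scipy.sparse matrix, shape (n_features, n_cells)
        Explicitly stored entries only; absent entries are structural zeros
        (missing observations for methylation/accessibility).
    feature_ids : sequence of str
        Gene symbols, site keys ``chrom:pos`` (0-based) or bin keys
        ``chrom:start-end`` (0-based, half-open).
    cell_ids : sequence of str
    omics_kind : {"expression", "methylation", "accessibility"}
        Methylation entries must be ternary-coded (+1 methylated,
        -1 unmethylated, implicit 0 missing); accessibility entries must be
        nonnegative.
    """

    values: sp.spmatrix
    feature_ids: np.ndarray
    cell_ids: np.ndarray
    omics_kind: str

    def __post_init__(self) -> None:
        self._validate_structure()
        self._validate_entries()

    def _validate_structure(self) -> None:
        if self.omics_kind not in OMICS_KINDS:
            raise ValueError(
                f"omics_kind must be one of {OMICS_KINDS}, got {self.omics_kind!r}"
            )
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values, dtype=float))
        self.values = self.values.tocsr()
        n, m = self.values.shape
        if n != len(self.feature_ids):
            raise ValueError(
                f"matrix has {n} rows but {len(self.feature_ids)} feature_ids"
            )
        if m != len(self.cell_ids):
            raise ValueError(f"matrix has {m} columns but {len(self.cell_ids)} cell_ids")
        _check_unique(self.feature_ids, "feature_ids")
        _check_unique(self.cell_ids, "cell_ids")

    def _validate_entries(self) -> None:
        data = self.values.data
        if self.omics_kind == "methylation":
            bad = data[(data != 1.0) & (data != -1.0)]
            if bad.size:
                raise ValueError(
                    "methylation entries must be ternary (+1/-1 stored, 0 implicit); "
                    f"found {bad[:5]}"
                )
        elif self.omics_kind == "accessibility":
            if data.size and data.min() < 0:
                raise ValueError("accessibility entries must be nonnegative")

    @classmethod
    def unchecked(cls, values, feature_ids, cell_ids, omics_kind) -> "SparseOmicsMatrix":
        """Construct without the per-kind entry-range check.

        For matrices whose entries are no longer raw measurements (e.g.
        normalized ternary layers); structural invariants still apply.
        """
        out = cls.__new__(cls)
        out.values = values
        out.feature_ids = feature_ids
        out.cell_ids = cell_ids
        out.omics_kind = omics_kind
        out._validate_structure()
        return out

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def toarray(self) -> np.ndarray:
        return self.values.toarray()

    def subset_cells(self, cell_ids: Sequence[str]) -> "SparseOmicsMatrix":
        """Return a copy restricted to ``cell_ids`` in the given order."""
        index = pd.Index(self.cell_ids)
        locs = index.get_indexer(list(cell_ids))
        if (locs < 0).any():
            missing = np.asarray(cell_ids, dtype=object)[locs < 0]
            raise KeyError(f"cells not in matrix: {missing[:5]}")
        return SparseOmicsMatrix(
            values=self.values[:, locs],
            feature_ids=self.feature_ids,
            cell_ids=np.asarray(cell_ids, dtype=object),
            omics_kind=self.omics_kind,
        )


@dataclass
class ClassLabels:
    """Cell classification: one categorical label per cell."""

    cell_ids: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.cell_ids) != len(self.labels):
            raise ValueError("cell_ids and labels must have equal length")
        _check_unique(self.cell_ids, "cell_ids")
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def for_cells(self, cell_ids: Sequence[str]) -> np.ndarray:
        """Label array aligned to ``cell_ids``; error on any unlabeled cell."""
        series = pd.Series(self.labels, index=pd.Index(self.cell_ids))
        wanted = pd.Index(list(cell_ids))
        missing = wanted.difference(series.index)
        if len(missing):
            raise KeyError(f"no label for cells: {list(missing[:5])}")
        return series.loc[wanted].to_numpy(dtype=object)

    def indicator(self) -> np.ndarray:
        """Cells x classes 0/1 indicator matrix (delta_js)."""
        classes = self.classes
        return (self.labels[:, None] == classes[None, :]).astype(float)


@dataclass
class ReducedTensor:
    """L x M x K array of SVD-projected layers over shared cells."""

    values: np.ndarray
    cell_ids: np.ndarray
    layer_kinds: tuple

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.ndim != 3:
            raise ValueError("tensor must be 3-way (L x M x K)")
        if self.values.shape[1] != len(self.cell_ids):
            raise ValueError("cell_ids length must match tensor mode-2 dimension")
        if self.values.shape[2] != len(self.layer_kinds):
            raise ValueError("layer_kinds length must match tensor mode-3 dimension")
        if self.values.shape[2] < 2:
            raise ValueError("need at least 2 omics layers to integrate")
        if not np.isfinite(self.values).all():
            raise ValueError("tensor entries must be finite")

    @property
    def shape(self) -> tuple:
        return self.values.shape
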