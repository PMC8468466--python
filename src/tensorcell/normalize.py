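"""Per-cell normalizations applied before the per-layer SVD.

Two schemes are used, mirroring how sparse missing-value-heavy layers and the
dense-ish expression layer are treated differently:

* L1: each cell column is rescaled so that sum_i |x_ij| = N (the number of
  features). Zeros stay zero, so sparsity is preserved. Used for ternary
  methylation and binned accessibility when per-cell coverage is comparable
  across cells; skipped when some cells have very few observations, because
  rescaling would give those cells enormous weight.
* center+scale: each cell column is shifted to mean zero and rescaled so that
  sum_i x_ij^2 = N. Used for expression counts; this densifies the layer.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .types import SparseOmicsMatrix

_SCHEMES = ("l1", "center_scale", "none")


def l1_normalize_columns(X: sp.spmatrix, copy: bool = True) -> sp.spmatrix:
    """Scale each column of sparse ``X`` so its absolute sum equals n_rows."""
    X = sp.csc_matrix(X, copy=copy)
    n = X.shape[0]
    colsums = np.abs(X).sum(axis=0).A1
    zero = np.where(colsums == 0)[0]
    if zero.size:
        raise ValueError(f"all-zero columns at indices {zero[:10].tolist()}")
    X.data *= np.repeat(n / colsums, np.diff(X.indptr))
    return X.tocsr()


def center_scale_columns(X) -> np.ndarray:
    """Center each column to mean 0 and scale so sum of squares equals n_rows."""
    X = np.asarray(X.toarray() if sp.issparse(X) else X, dtype=float)
    n = X.shape[0]
    X = X - X.mean(axis=0, keepdims=True)
    ss = (X**2).sum(axis=0)
    zero = np.where(ss == 0)[0]
    if zero.size:
        raise ValueError(f"constant columns at indices {zero[:10].tolist()}")
    return X * np.sqrt(n / ss)


def normalize_l1(matrix: SparseOmicsMatrix) -> SparseOmicsMatrix:
    """L1-normalize every cell column of a layer (sum_i |x'_ij| = N_k)."""
    try:
        values = l1_normalize_columns(matrix.values)
    except ValueError as exc:
        cols = _offending_cells(matrix)
        raise ValueError(f"all-zero cells cannot be L1-normalized: {cols}") from exc
    # scaled entries are no longer ternary, so skip the raw-entry validation
    return SparseOmicsMatrix.unchecked(
        values, matrix.feature_ids, matrix.cell_ids, matrix.omics_kind
    )


def _offending_cells(matrix: SparseOmicsMatrix) -> list:
    colsums = np.abs(matrix.values).sum(axis=0).A1
    return [str(c) for c in matrix.cell_ids[colsums == 0][:10]]


def normalize_center_scale(matrix: SparseOmicsMatrix) -> np.ndarray:
    """Center+scale every cell column; returns a dense features x cells array."""
    try:
        return center_scale_columns(matrix.values)
    except ValueError:
        dense = matrix.values.toarray()
        const = np.ptp(dense, axis=0) == 0
        cells = [str(c) for c in matrix.cell_ids[const][:10]]
        raise ValueError(f"constant cells cannot be standardized: {cells}") from None


def normalization_plan(dataset_mode: str, custom: dict | None = None) -> dict:
    """Per-omics normalization scheme for a dataset style.

    ``dataset1``: expression center+scale, methylation and accessibility L1
    (per-cell coverage comparable). ``dataset2``: expression center+scale,
    methylation and accessibility untouched (some cells have too few
    observations for L1 to be safe). ``custom``: caller-specified mapping.
    """
    plans = {
        "dataset1": {
            "expression": "center_scale",
            "methylation": "l1",
            "accessibility": "l1",
        },
        "dataset2": {
            "expression": "center_scale",
            "methylation": "none",
            "accessibility": "none",
        },
    }
    if dataset_mode in plans:
        return plans[dataset_mode]
    if dataset_mode == "custom":
        custom = dict(custom or {})
        base = plans["dataset1"].copy()
        for kind, scheme in custom.items():
            if kind not in base:
                raise ValueError(f"unknown omics kind in custom plan: {kind!r}")
            if scheme not in _SCHEMES:
                raise ValueError(f"unknown scheme {scheme!r}; use one of {_SCHEMES}")
            base[kind] = scheme
        return base
    raise ValueError(
        f"unknown dataset_mode {dataset_mode!r}; use dataset1, dataset2 or custom"
    )


def apply_normalization(matrix: SparseOmicsMatrix, scheme: str):
    """Apply one scheme; returns sparse matrix (l1/none) or dense array."""
    if scheme == "l1":
        return normalize_l1(matrix).values
    if scheme == "center_scale":
        return normalize_center_scale(matrix)
    if scheme == "none":
        return matrix.values
    raise ValueError(f"unknown scheme {scheme!r}")
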