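"""Per-layer truncated SVD and stacking of projected layers into a tensor.

Each normalized layer X_k (N_k features x M cells) is reduced to a common
rank L via its top-L singular triplets, X_k ~= sum_l lambda_l u_l v_l^T.
Projecting features through the left vectors, row l of U^T X_k, gives an
L x M representation per layer; the K layers stacked over their shared cells
form the L x M x K tensor handed to the HOSVD.

Sign convention: for every singular pair (u_l, v_l) the pair is flipped so
that the maximum-magnitude entry of u_l is positive (ties broken by first
index), making outputs reproducible across solvers and runs.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .types import ReducedTensor


def fix_signs(U: np.ndarray, *others: np.ndarray):
    """Flip column signs so each column of U has a positive max-|.| entry.

    Any companion matrices in ``others`` (e.g. the right singular vectors)
    get the same flips. Ties on |.| are broken by the first index.
    """
    flips = np.ones(U.shape[1])
    for col in range(U.shape[1]):
        u = U[:, col]
        idx = int(np.argmax(np.abs(u)))
        if u[idx] < 0:
            flips[col] = -1.0
    U = U * flips
    flipped = [o * flips for o in others]
    return (U, *flipped) if others else U


class LayerSVD(BaseEstimator):
    """Truncated SVD of one omics layer (features x cells).

    Parameters
    ----------
    n_components : int
        Common rank L shared across layers (default 10).
    tol : float
        Solver tolerance for the Lanczos iteration.
    max_iter : int
        Iteration cap for the sparse solver.
    random_state : int or None
        Seeds the Lanczos start vector; fixed seed gives fixed output.

    Attributes
    ----------
    singular_values_ : (L,) nonincreasing nonnegative array
    feature_components_ : (N_k, L) orthonormal-column left vectors
    cell_components_ : (M, L) orthonormal-column right vectors
    """

    def __init__(self, n_components=10, tol=1e-8, max_iter=1000, random_state=None):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        L = self.n_components
        n, m = X.shape
        if L > min(n, m):
            raise ValueError(
                f"n_components={L} exceeds min(matrix shape)={min(n, m)}"
            )
        small = min(n, m)
        dense_path = (not sp.issparse(X)) and max(n, m) <= 2000
        if L >= small - 1 or small <= 3:
            dense_path = True
        if dense_path:
            Xd = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
            U, s_full, Vt = scipy.linalg.svd(Xd, full_matrices=False)
            U, s, V = U[:, :L], s_full[:L], Vt[:L].T
            s_after = float(s_full[L]) if len(s_full) > L else None
        else:
            k = min(L + 1, small - 1)
            rng = np.random.default_rng(self.random_state)
            v0 = rng.standard_normal(min(n, m))
            U, s, Vt = spla.svds(
                X, k=k, tol=self.tol, maxiter=self.max_iter, v0=v0
            )
            order = np.argsort(s)[::-1]
            U, s, Vt = U[:, order], s[order], Vt[order]
            s_after = s[L] if len(s) > L else None
            U, s, V = U[:, :L], s[:L], Vt[:L].T
        if s_after is not None and s[-1] > 0:
            gap = (s[-1] - s_after) / s[-1]
            if gap < 1e-10:
                warnings.warn(
                    "trailing singular values are (near-)degenerate; the "
                    "retained subspace is not unique",
                    stacklevel=2,
                )
        U, V = fix_signs(U, V)
        self.singular_values_ = s
        self.feature_components_ = U
        self.cell_components_ = V
        self.n_features_in_ = n
        return self

    def transform(self, X):
        """Project features: row l of the output is u_l^T X (L x M)."""
        check_is_fitted(self, "feature_components_")
        if X.shape[0] != self.feature_components_.shape[0]:
            raise ValueError(
                f"matrix has {X.shape[0]} features; SVD was fitted on "
                f"{self.feature_components_.shape[0]}"
            )
        out = self.feature_components_.T @ X
        return np.asarray(out)

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


def truncated_svd(X, L, seed=None, tol=1e-8, max_iter=1000) -> LayerSVD:
    """Functional wrapper around :class:`LayerSVD`."""
    return LayerSVD(
        n_components=L, tol=tol, max_iter=max_iter, random_state=seed
    ).fit(X)


def project_features(svd: LayerSVD, X) -> np.ndarray:
    """Eq.-style contraction x_lj = sum_i u_li x_ij over the layer's features."""
    return svd.transform(X)


def stack_tensor(
    projections: Sequence[np.ndarray],
    cell_ids: Sequence[Sequence[str]],
    layer_kinds: Sequence[str],
) -> ReducedTensor:
    """Stack per-layer L x M_k projections into an L x M x K tensor.

    Cells are restricted to the intersection of all layers' cell sets, in the
    canonical order of the first layer (the expression layer by convention);
    layers missing a cell are dropped via intersection, never imputed.
    """
    if len(projections) < 2:
        raise ValueError("need at least 2 layers to stack")
    if len(projections) != len(cell_ids) or len(projections) != len(layer_kinds):
        raise ValueError("projections, cell_ids and layer_kinds must align")
    id_sets = [set(ids) for ids in cell_ids]
    shared = set.intersection(*id_sets)
    if not shared:
        raise ValueError("no cells are shared across all layers")
    canon = [c for c in cell_ids[0] if c in shared]
    L = projections[0].shape[0]
    slices = []
    for proj, ids in zip(projections, cell_ids):
        if proj.shape[0] != L:
            raise ValueError("all layers must share the same rank L")
        lookup = {c: j for j, c in enumerate(ids)}
        cols = [lookup[c] for c in canon]
        slices.append(np.asarray(proj)[:, cols])
    values = np.stack(slices, axis=2)
    return ReducedTensor(values=values, cell_ids=canon, layer_kinds=tuple(layer_kinds))
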