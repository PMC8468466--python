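"""Higher-order SVD (Tucker form) of the L x M x K reduced tensor.

The factor matrix of mode n holds the left singular vectors of the mode-n
unfolding; the core tensor is the input contracted with the factor
transposes,

    T(l, j, k) = sum_{l1, l2, l3} G(l1, l2, l3) U1[l, l1] U2[j, l2] U3[k, l3].

Unfolding convention: mode-n matricization puts mode n on the rows and the
remaining modes on the columns in ascending mode order (numpy moveaxis +
reshape, C order). Factor columns are ordered by decreasing unfolding
singular value and sign-fixed as in :mod:`tensorcell.svd`.

Economy sizes: mode n keeps r_n = min(d_n, prod of other dims) columns. For
the cell mode that is min(M, L*K); columns beyond the unfolding rank are not
unique, and with the full economy core the reconstruction is still exact.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .svd import fix_signs
from .types import ReducedTensor


def unfold(T: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n matricization: mode on rows, other modes ascending on columns."""
    return np.moveaxis(T, mode, 0).reshape(T.shape[mode], -1)


class HOSVD(BaseEstimator):
    """Higher-order SVD of a 3-way tensor.

    Attributes
    ----------
    core_ : ndarray, shape (r1, r2, r3)
        Core tensor G; squared entries measure the energy each triple of
        factor columns contributes.
    factors_ : list of 3 ndarrays
        Orthonormal-column factor matrices, one per mode
        (feature mode L x r1, cell mode M x r2, omics mode K x r3).
    singular_values_ : list of 3 ndarrays
        Unfolding singular values per mode (nonincreasing).
    """

    def fit(self, T, y=None):
        T = T.values if isinstance(T, ReducedTensor) else np.asarray(T, dtype=float)
        if T.ndim != 3:
            raise ValueError("input must be a 3-way tensor")
        if not np.isfinite(T).all():
            raise ValueError("tensor entries must be finite")
        factors, svals = [], []
        for mode in range(3):
            M = unfold(T, mode)
            U, s, _ = scipy.linalg.svd(M, full_matrices=False)
            r = min(M.shape)
            U = fix_signs(U[:, :r])
            factors.append(U)
            svals.append(s[:r])
        core = np.einsum(
            "abc,ai,bj,ck->ijk", T, factors[0], factors[1], factors[2],
            optimize=True,
        )
        self.factors_ = factors
        self.singular_values_ = svals
        self.core_ = core
        self.shape_ = T.shape
        return self

    def inverse_transform(self, core: np.ndarray | None = None) -> np.ndarray:
        """Contract the core with the factors back to an L x M x K tensor."""
        check_is_fitted(self, "core_")
        G = self.core_ if core is None else np.asarray(core, dtype=float)
        U1, U2, U3 = self.factors_
        if G.shape != (U1.shape[1], U2.shape[1], U3.shape[1]):
            raise ValueError(
                f"core shape {G.shape} does not match factor column counts "
                f"({U1.shape[1]}, {U2.shape[1]}, {U3.shape[1]})"
            )
        return np.einsum("ijk,ai,bj,ck->abc", G, U1, U2, U3, optimize=True)

    @property
    def feature_factors_(self) -> np.ndarray:
        return self.factors_[0]

    @property
    def cell_factors_(self) -> np.ndarray:
        return self.factors_[1]

    @property
    def omics_factors_(self) -> np.ndarray:
        return self.factors_[2]


def hosvd(tensor) -> HOSVD:
    """Functional wrapper: fit a :class:`HOSVD` on a tensor."""
    return HOSVD().fit(tensor)


def reconstruct(result: HOSVD) -> np.ndarray:
    """Rebuild the tensor from core and factors (exact with the full core)."""
    return result.inverse_transform()
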