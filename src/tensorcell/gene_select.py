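"""Back-projection of feature-mode components to genes and chi2 selection.

A selected feature-mode HOSVD component lives in the reduced L-space; it is
mapped back to the original features of a layer through that layer's SVD left
vectors, u[l1, i] = sum_l U1[l, l1] * u[l, i]. Under the null hypothesis that
the back-projected loadings are Gaussian, the statistic
sum_{l1} (u[l1, i] / sigma_{l1})^2 follows a chi-squared distribution with as
many degrees of freedom as there are selected components; its upper-tail
probability is the per-feature p-value, BH-adjusted across features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator

from .association import bh_adjust


def backproject(mode1_factors: np.ndarray, feature_left_vectors: np.ndarray, l1: int) -> np.ndarray:
    """Map HOSVD feature-mode component ``l1`` back to original features.

    ``mode1_factors`` is the L x r1 mode-1 factor matrix (columns =
    components); ``feature_left_vectors`` is the layer's N_k x L left
    singular-vector matrix.
    """
    U1 = np.asarray(mode1_factors, dtype=float)
    U = np.asarray(feature_left_vectors, dtype=float)
    if U.shape[1] != U1.shape[0]:
        raise ValueError(
            f"left vectors have L={U.shape[1]} but mode-1 factors have "
            f"{U1.shape[0]} rows"
        )
    if not 0 <= l1 < U1.shape[1]:
        raise ValueError(f"component index {l1} out of range")
    return U @ U1[:, l1]


def estimate_scales(loadings: np.ndarray, method: str = "sample_sd") -> np.ndarray:
    """Per-component scale sigma_{l1} of the loading columns.

    ``sample_sd``: standard deviation about the column mean (ddof=1, default).
    ``rms``: zero-mean variant sqrt(mean(u^2)), matching a mean-zero Gaussian
    null exactly.
    """
    loadings = np.atleast_2d(np.asarray(loadings, dtype=float))
    if method == "sample_sd":
        sigma = loadings.std(axis=0, ddof=1)
    elif method == "rms":
        sigma = np.sqrt(np.mean(loadings**2, axis=0))
    else:
        raise ValueError(f"unknown scale method {method!r}")
    if np.any(sigma <= 0):
        raise ValueError("estimated scale is zero for at least one component")
    return sigma


def chi2_pvalues(loadings, scales="estimate", scale_method: str = "sample_sd"):
    """Upper-tail chi-squared p-value per feature.

    ``loadings``: features x selected-components array (a 1-D array is one
    component). ``scales``: per-component sigma, or ``"estimate"`` to use
    :func:`estimate_scales` over all features.
    """
    loadings = np.asarray(loadings, dtype=float)
    if loadings.ndim == 1:
        loadings = loadings[:, None]
    if loadings.shape[1] < 1:
        raise ValueError("need at least one selected component")
    if isinstance(scales, str) and scales == "estimate":
        sigma = estimate_scales(loadings, method=scale_method)
    else:
        sigma = np.asarray(scales, dtype=float)
        if sigma.ndim == 0:
            sigma = sigma[None]
        if np.any(sigma <= 0):
            raise ValueError("scales must be positive")
        if len(sigma) != loadings.shape[1]:
            raise ValueError("one scale per loading column required")
    stat = np.sum((loadings / sigma) ** 2, axis=1)
    df = loadings.shape[1]
    return scipy.stats.chi2.sf(stat, df), stat, sigma


class GeneSelector(BaseEstimator):
    """Chi-squared feature selection from back-projected loadings.

    Parameters
    ----------
    alpha : float
        BH-adjusted threshold (default 0.01).
    scales : "estimate" or array
        Per-component sigma; estimated from the loading columns by default.
    scale_method : {"sample_sd", "rms"}
        How sigma is estimated (see :func:`estimate_scales`).

    Attributes
    ----------
    results_ : DataFrame with feature_id, per-component loadings, statistic,
        pvalue, adjusted_pvalue, selected.
    selected_features_ : feature IDs with adjusted p < alpha, sorted by
        adjusted p then ID.
    """

    def __init__(self, alpha=0.01, scales="estimate", scale_method="sample_sd"):
        self.alpha = alpha
        self.scales = scales
        self.scale_method = scale_method

    def fit(self, X, y=None, feature_ids=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        pvals, stat, sigma = chi2_pvalues(
            X, scales=self.scales, scale_method=self.scale_method
        )
        adjusted = bh_adjust(pvals)
        selected = adjusted < self.alpha
        if feature_ids is None:
            feature_ids = np.array([str(i) for i in range(X.shape[0])], dtype=object)
        feature_ids = np.asarray(feature_ids, dtype=object)
        frame = {"feature_id": feature_ids}
        for c in range(X.shape[1]):
            frame[f"loading_{c + 1}"] = X[:, c]
        frame.update(
            statistic=stat, pvalue=pvals, adjusted_pvalue=adjusted, selected=selected
        )
        self.results_ = pd.DataFrame(frame)
        self.scales_ = sigma
        self.pvalues_ = pvals
        self.adjusted_pvalues_ = adjusted
        sel = self.results_[selected].sort_values(
            ["adjusted_pvalue", "feature_id"], kind="mergesort"
        )
        self.selected_features_ = sel["feature_id"].to_numpy(dtype=object)
        return self


def select_features(raw_p, alpha: float = 0.01, feature_ids=None) -> pd.DataFrame:
    """BH-adjust raw p-values and flag features with adjusted p < alpha."""
    raw_p = np.asarray(raw_p, dtype=float)
    adjusted = bh_adjust(raw_p)
    if feature_ids is None:
        feature_ids = np.array([str(i) for i in range(len(raw_p))], dtype=object)
    df = pd.DataFrame(
        {
            "feature_id": np.asarray(feature_ids, dtype=object),
            "pvalue": raw_p,
            "adjusted_pvalue": adjusted,
            "selected": adjusted < alpha,
        }
    )
    return df
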