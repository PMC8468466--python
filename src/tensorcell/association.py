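"""Testing cell-mode singular vectors against the known cell classification.

Each cell-mode vector v (one component per cell) is regressed on the class
indicator variables, v_j = a_s delta_js + b, and tested with the F statistic
comparing the class model to the intercept-only model (df1 = S-1,
df2 = M-S) — equivalently a one-way ANOVA of v across classes. The family of
raw p-values (all vectors of one analysis) is Benjamini-Hochberg adjusted;
vectors with adjusted p below alpha are "coincident" with the classification.

Feature-mode components are then ranked by how much core-tensor energy they
share with the coincident cell-mode components:
score(l1) = sum over selected l2, all l3 of G(l1, l2, l3)^2.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .types import ClassLabels


def categorical_regression_p(vector, labels) -> tuple:
    """OLS fit of the class-indicator model and its F-test p-value.

    Returns ``(coefficients, intercept, pvalue)``: the intercept is the mean
    of the reference class (lexicographically first), coefficients are the
    per-class mean offsets from it (reference coefficient 0). A zero-variance
    vector has no explainable variance and gets p = 1 by convention, so
    constant components are never selected.
    """
    v = np.asarray(vector, dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("vector must be finite")
    y = labels.labels if isinstance(labels, ClassLabels) else np.asarray(labels)
    if len(y) != len(v):
        raise ValueError("vector and labels must have equal length")
    classes, inverse, counts = np.unique(y, return_inverse=True, return_counts=True)
    S, M = len(classes), len(v)
    if S < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        small = classes[counts < 2]
        raise ValueError(f"classes with fewer than 2 cells: {list(small)}")
    if M <= S:
        raise ValueError(f"need more cells ({M}) than classes ({S})")

    grand = v.mean()
    group_sums = np.bincount(inverse, weights=v, minlength=S)
    group_means = group_sums / counts
    ssb = float(np.sum(counts * (group_means - grand) ** 2))
    sst = float(np.sum((v - grand) ** 2))
    ssw = sst - ssb
    coefs = group_means - group_means[0]
    intercept = float(group_means[0])
    if sst <= 0 or sst < 1e-300:
        return coefs, intercept, 1.0
    df1, df2 = S - 1, M - S
    if ssw <= 0:
        return coefs, intercept, 0.0
    F = (ssb / df1) / (ssw / df2)
    p = float(scipy.stats.f.sf(F, df1, df2))
    return coefs, intercept, p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class ClassAssociation(BaseEstimator):
    """Coincidence test of cell-mode components with the classification.

    Parameters
    ----------
    alpha : float
        BH-adjusted significance threshold (default 0.01).

    Attributes
    ----------
    results_ : DataFrame with columns component, pvalue, adjusted_pvalue,
        selected — one row per component.
    coefficients_ : (C, S) per-class mean offsets per component.
    selected_ : indices of coincident components.
    """

    def __init__(self, alpha: float = 0.01):
        self.alpha = alpha

    def fit(self, X, y):
        """X: cells x components matrix; y: ClassLabels or label array."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 1:
            raise ValueError("X must be a cells x components matrix")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        coefs, intercepts, pvals = [], [], []
        for c in range(X.shape[1]):
            a, b, p = categorical_regression_p(X[:, c], y)
            coefs.append(a)
            intercepts.append(b)
            pvals.append(p)
        pvals = np.asarray(pvals)
        adjusted = bh_adjust(pvals)
        selected = adjusted < self.alpha
        self.results_ = pd.DataFrame(
            {
                "component": np.arange(X.shape[1]),
                "pvalue": pvals,
                "adjusted_pvalue": adjusted,
                "selected": selected,
            }
        )
        self.coefficients_ = np.vstack(coefs)
        self.intercepts_ = np.asarray(intercepts)
        self.pvalues_ = pvals
        self.adjusted_pvalues_ = adjusted
        self.selected_ = np.where(selected)[0]
        return self


def select_coincident(vectors, labels, alpha: float = 0.01) -> ClassAssociation:
    """Test a components x cells matrix of cell-mode vectors (rows)."""
    vectors = np.asarray(vectors, dtype=float)
    return ClassAssociation(alpha=alpha).fit(vectors.T, labels)


def rank_l1_by_core(core: np.ndarray, selected_l2: Sequence[int]):
    """Rank feature-mode components by core energy over coincident l2.

    Returns ``(order, scores)``: scores[l1] = sum over selected l2 and all l3
    of G(l1, l2, l3)^2; order lists l1 indices by descending score, ties
    broken by the smaller index.
    """
    G = core.core_ if isinstance(core, BaseEstimator) else np.asarray(core)
    selected_l2 = np.asarray(list(selected_l2), dtype=int)
    if selected_l2.size == 0:
        raise ValueError("no coincident cell-mode vectors to rank against")
    if selected_l2.min() < 0 or selected_l2.max() >= G.shape[1]:
        raise ValueError("selected_l2 indices out of range")
    scores = np.sum(G[:, selected_l2, :] ** 2, axis=(1, 2))
    order = np.lexsort((np.arange(len(scores)), -scores))
    return order, scores
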