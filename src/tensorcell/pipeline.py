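"""End-to-end tensor-decomposition unsupervised feature extraction.

Stages: per-cell normalization -> per-layer truncated SVD to a common rank L
-> stack the projected layers into an L x M x K tensor over shared cells ->
HOSVD -> categorical regression of the cell-mode factor columns on the known
classification (BH-adjusted) -> rank feature-mode components by core energy
over the coincident cell-mode components -> back-project the top components
to the target layer's features -> chi-squared p-values -> BH selection.
The fitted cell-mode factors also feed the 2-D UMAP embedding.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import io as tio
from .association import ClassAssociation, rank_l1_by_core, select_coincident
from .embed import CellEmbedding, export_embedding
from .gene_select import GeneSelector, backproject
from .hosvd import HOSVD
from .normalize import apply_normalization, normalization_plan
from .svd import LayerSVD, stack_tensor
from .types import ClassLabels, SparseOmicsMatrix

logger = logging.getLogger(__name__)

LAYER_ORDER = ("expression", "methylation", "accessibility")


class TensorFeatureExtraction(BaseEstimator):
    """Unsupervised multiomics integration with supervised read-out.

    The decomposition itself never sees the labels; they are used only to
    identify which cell-mode components coincide with the classification and
    to read out class-informative features.

    Parameters
    ----------
    n_components : int
        Common SVD rank L per layer (default 10).
    alpha : float
        BH-adjusted significance threshold for both the cell-mode coincidence
        test and the feature selection (default 0.01).
    n_top_components : int
        How many top core-energy feature-mode components are back-projected
        (default 1).
    normalization : str or dict
        ``"dataset1"`` (L1 for methylation/accessibility, center+scale for
        expression), ``"dataset2"`` (sparse layers untouched) or a custom
        per-omics mapping.
    target_layer : str
        Layer whose features are selected (default ``"expression"``).
    scale_method : {"sample_sd", "rms"}
        Scale estimator for the chi-squared statistic.
    random_state : int or None
        Seeds the truncated-SVD start vectors.
    """

    def __init__(
        self,
        n_components: int = 10,
        alpha: float = 0.01,
        n_top_components: int = 1,
        normalization="dataset1",
        target_layer: str = "expression",
        scale_method: str = "sample_sd",
        svd_tol: float = 1e-8,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.alpha = alpha
        self.n_top_components = n_top_components
        self.normalization = normalization
        self.target_layer = target_layer
        self.scale_method = scale_method
        self.svd_tol = svd_tol
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X: Mapping[str, SparseOmicsMatrix], y: ClassLabels):
        """Fit on a mapping of omics kind -> layer matrix plus cell labels."""
        layers = {k: X[k] for k in LAYER_ORDER if k in X}
        if len(layers) < 2:
            raise ValueError("need at least 2 omics layers to integrate")
        if self.target_layer in layers:
            target = self.target_layer
        else:
            target = next(iter(layers))
            logger.warning(
                "target layer %r absent; selecting features of %r instead",
                self.target_layer, target,
            )
        if isinstance(self.normalization, str):
            plan = normalization_plan(self.normalization)
        else:
            plan = normalization_plan("custom", dict(self.normalization))

        svds, projections, cell_id_lists, kinds = {}, [], [], []
        for kind, layer in layers.items():
            normalized = apply_normalization(layer, plan[kind])
            svd = LayerSVD(
                n_components=self.n_components,
                tol=self.svd_tol,
                random_state=self.random_state,
            ).fit(normalized)
            svds[kind] = svd
            projections.append(svd.transform(normalized))
            cell_id_lists.append(list(layer.cell_ids))
            kinds.append(kind)
        tensor = stack_tensor(projections, cell_id_lists, kinds)

        decomposition = HOSVD().fit(tensor)
        cell_factors = decomposition.cell_factors_  # M x min(M, L*K)

        labels_aligned = ClassLabels(
            cell_ids=tensor.cell_ids, labels=y.for_cells(tensor.cell_ids)
        )
        association = ClassAssociation(alpha=self.alpha).fit(
            cell_factors, labels_aligned
        )
        self.layer_association_ = {
            kind: select_coincident(
                svds[kind].cell_components_.T,
                ClassLabels(
                    cell_ids=layers[kind].cell_ids,
                    labels=y.for_cells(layers[kind].cell_ids),
                ),
                alpha=self.alpha,
            )
            for kind in kinds
        }

        selected_l2 = association.selected_
        self.svd_ = svds
        self.tensor_ = tensor
        self.hosvd_ = decomposition
        self.association_ = association
        self.labels_ = labels_aligned
        self.cell_factors_ = cell_factors
        self.target_layer_ = target
        self.selected_components_ = selected_l2

        if selected_l2.size == 0:
            logger.warning(
                "no cell-mode component coincides with the classification; "
                "no features selected"
            )
            self.component_ranking_ = None
            self.core_scores_ = None
            self.gene_selector_ = None
            self.feature_results_ = None
            self.selected_features_ = np.array([], dtype=object)
            return self

        order, scores = rank_l1_by_core(decomposition.core_, selected_l2)
        top = order[: self.n_top_components]
        loadings = np.column_stack(
            [
                backproject(
                    decomposition.feature_factors_,
                    svds[target].feature_components_,
                    l1,
                )
                for l1 in top
            ]
        )
        selector = GeneSelector(
            alpha=self.alpha, scale_method=self.scale_method
        ).fit(loadings, feature_ids=layers[target].feature_ids)

        self.component_ranking_ = order
        self.core_scores_ = scores
        self.top_components_ = top
        self.gene_loadings_ = loadings
        self.gene_selector_ = selector
        self.feature_results_ = selector.results_
        self.selected_features_ = selector.selected_features_
        return self

    # ------------------------------------------------------------------
    def embed(self, n_neighbors: int = 100, seed: int | None = None) -> np.ndarray:
        """UMAP-embed all cell-mode factor columns into 2-D."""
        check_is_fitted(self, "cell_factors_")
        return CellEmbedding(
            n_neighbors=n_neighbors,
            random_state=self.random_state if seed is None else seed,
        ).fit_transform(self.cell_factors_)

    def summary(self) -> dict:
        check_is_fitted(self, "association_")
        return {
            "n_cells": len(self.tensor_.cell_ids),
            "layers": list(self.svd_.keys()),
            "tensor_shape": list(self.tensor_.shape),
            "n_cell_components": int(self.cell_factors_.shape[1]),
            "n_coincident_components": int(self.selected_components_.size),
            "coincident_per_layer_svd": {
                k: int(a.selected_.size) for k, a in self.layer_association_.items()
            },
            "top_feature_components": (
                [int(i) for i in self.top_components_]
                if self.selected_components_.size
                else []
            ),
            "n_selected_features": int(len(self.selected_features_)),
            "target_layer": self.target_layer_,
        }


def run_pipeline(
    layers: Mapping[str, SparseOmicsMatrix],
    labels: ClassLabels,
    outdir,
    n_components: int = 10,
    alpha: float = 0.01,
    n_top_components: int = 1,
    normalization="dataset1",
    target_layer: str = "expression",
    scale_method: str = "sample_sd",
    n_neighbors: int = 100,
    seed: int | None = 0,
    embed: bool = True,
) -> dict:
    """Run the full pipeline and write all artifacts under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = TensorFeatureExtraction(
        n_components=n_components,
        alpha=alpha,
        n_top_components=n_top_components,
        normalization=normalization,
        target_layer=target_layer,
        scale_method=scale_method,
        random_state=seed,
    ).fit(layers, labels)

    model.association_.results_.to_csv(
        outdir / "cell_component_association.tsv", sep="\t", index=False
    )
    if model.feature_results_ is not None:
        model.feature_results_.to_csv(
            outdir / "feature_selection.tsv", sep="\t", index=False
        )
        Path(outdir / "selected_features.txt").write_text(
            "\n".join(map(str, model.selected_features_)) + "\n"
        )
    np.savez(
        outdir / "hosvd.npz",
        core=model.hosvd_.core_,
        feature_factors=model.hosvd_.feature_factors_,
        cell_factors=model.hosvd_.cell_factors_,
        omics_factors=model.hosvd_.omics_factors_,
    )
    if embed and model.cell_factors_.shape[0] > n_neighbors:
        coords = model.embed(n_neighbors=n_neighbors)
        export_embedding(
            coords,
            model.tensor_.cell_ids,
            labels,
            outdir / "embedding.tsv",
            plot_path=outdir / "embedding.png",
        )
    summary = model.summary()
    config = {
        "n_components": n_components,
        "alpha": alpha,
        "n_top_components": n_top_components,
        "normalization": normalization,
        "target_layer": target_layer,
        "scale_method": scale_method,
        "n_neighbors": n_neighbors,
        "seed": seed,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    (outdir / "config.json").write_text(json.dumps(config, indent=1))
    return summary
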