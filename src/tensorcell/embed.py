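"""2-D UMAP embedding of cells from the cell-mode HOSVD factors."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .types import ClassLabels


class CellEmbedding(BaseEstimator):
    """UMAP embedding of the cell-mode factor columns.

    All cell-mode columns are embedded (not only the coincident ones);
    hyperparameters are library defaults except ``n_neighbors`` (default 100).
    """

    def __init__(self, n_neighbors: int = 100, random_state: int | None = None):
        self.n_neighbors = n_neighbors
        self.random_state = random_state

    def fit_transform(self, X, y=None) -> np.ndarray:
        import umap  # deferred: numba-jitted import is slow

        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("X must be cells x components with >= 2 columns")
        if X.shape[0] <= self.n_neighbors:
            raise ValueError(
                f"{X.shape[0]} cells <= n_neighbors={self.n_neighbors}; "
                "choose a smaller n_neighbors"
            )
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=self.n_neighbors,
            random_state=self.random_state,
        )
        coords = np.asarray(reducer.fit_transform(X), dtype=float)
        self.embedding_ = coords
        return coords

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self


def embed_cells(cell_factors, n_neighbors: int = 100, seed: int | None = None) -> np.ndarray:
    """Embed an M x C cell-factor matrix into M x 2 coordinates."""
    return CellEmbedding(n_neighbors=n_neighbors, random_state=seed).fit_transform(
        cell_factors
    )


def export_embedding(coords, cell_ids, labels: ClassLabels, path, plot_path=None) -> pd.DataFrame:
    """Write cell_id/x/y/class TSV; optionally render a class-colored scatter."""
    coords = np.asarray(coords, dtype=float)
    cell_ids = np.asarray(cell_ids, dtype=object)
    if coords.shape != (len(cell_ids), 2):
        raise ValueError("coords must be cells x 2 aligned with cell_ids")
    classes = labels.for_cells(cell_ids)
    df = pd.DataFrame(
        {"cell_id": cell_ids, "x": coords[:, 0], "y": coords[:, 1], "class": classes}
    )
    df.to_csv(path, sep="\t", index=False)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        for cls, sub in df.groupby("class"):
            ax.scatter(sub["x"], sub["y"], s=8, label=str(cls), alpha=0.8)
        ax.set_xlabel("UMAP 1")
        ax.set_ylabel("UMAP 2")
        ax.legend(markerscale=2, fontsize=8)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return df
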