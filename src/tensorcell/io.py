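"""Reading raw single-cell omics files and building sparse layer matrices.

Input dialects
--------------
* expression: TSV (optionally gzipped) with a header row of cell IDs and a
  first column of gene IDs, values = nonnegative counts.
* per-cell site files: headerless 3-column TSV ``chrom <tab> pos <tab> value``,
  one file per cell, positions 1-based in files (converted to 0-based
  internally).
* labels: TSV ``cell_id <tab> class`` with a header row.

Persistence uses MatrixMarket coordinate files plus TSV sidecars for the
feature and cell identifiers, so every artifact stays plain text.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Tuple

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .types import ClassLabels, SparseOmicsMatrix

logger = logging.getLogger(__name__)

#: default width of an accessibility aggregation bin, approximating one
#: nucleosome (~147 nt wrapped DNA plus linker)
NUCLEOSOME_BIN = 200


def read_expression_matrix(path) -> SparseOmicsMatrix:
    """Read a genes x cells count TSV into a sparse expression matrix.

    The file must carry a header row of cell IDs and a first column of gene
    IDs; row and column order are preserved.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0:
        raise ValueError(f"no rows in expression file {path}")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique()
        raise ValueError(f"duplicate gene IDs: {list(dup[:10])}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique()
        raise ValueError(f"duplicate cell IDs: {list(dup[:10])}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any() and not df[col].isna().any():
                i = int(np.where(coerced.isna())[0][0])
                raise ValueError(
                    f"non-numeric value at gene {df.index[i]!r}, cell {col!r}"
                ) from None
        raise
    if np.isnan(values).any():
        i, j = map(int, np.argwhere(np.isnan(values))[0])
        raise ValueError(f"missing value at gene {df.index[i]!r}, cell {df.columns[j]!r}")
    if values.min() < 0:
        raise ValueError("expression counts must be nonnegative")
    return SparseOmicsMatrix(
        values=sp.csr_matrix(values),
        feature_ids=df.index.to_numpy(dtype=object),
        cell_ids=df.columns.to_numpy(dtype=object),
        omics_kind="expression",
    )


def read_site_file(path, one_based: bool = True) -> pd.DataFrame:
    """Read one cell's ``chrom pos value`` TSV into a DataFrame (0-based pos)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "pos", "value"],
        dtype={"chrom": str, "pos": np.int64, "value": float},
    )
    if one_based:
        df["pos"] = df["pos"] - 1
    if (df["pos"] < 0).any():
        raise ValueError(f"negative position in {path}")
    return df


def _sites_to_frame(per_cell_sites: Mapping[str, Iterable]) -> pd.DataFrame:
    """Flatten {cell_id -> iterable of (chrom, pos, value)} to one DataFrame."""
    frames = []
    for cell_id, sites in per_cell_sites.items():
        if isinstance(sites, pd.DataFrame):
            df = sites[["chrom", "pos", "value"]].copy()
        else:
            rows = [
                (s.chrom, s.pos, s.value) if hasattr(s, "chrom") else tuple(s)
                for s in sites
            ]
            df = pd.DataFrame(rows, columns=["chrom", "pos", "value"])
        df["cell"] = cell_id
        frames.append(df)
    if not frames:
        raise ValueError("no cells provided")
    out = pd.concat(frames, ignore_index=True)
    out["chrom"] = out["chrom"].astype(str)
    out["pos"] = out["pos"].astype(np.int64)
    out["value"] = out["value"].astype(float)
    if (out["pos"] < 0).any():
        raise ValueError("positions must be >= 0")
    return out


def _warn_empty_cells(cell_order, observed_cells) -> None:
    empty = [c for c in cell_order if c not in observed_cells]
    if empty:
        warnings.warn(
            f"{len(empty)} cell(s) have zero observations and yield all-zero "
            f"columns (e.g. {empty[:3]}); downstream normalization may reject them",
            stacklevel=3,
        )


def build_ternary_methylation(
    per_cell_sites: Mapping[str, Iterable], call_threshold: float = 0.5
) -> SparseOmicsMatrix:
    """Build the ternary methylation matrix over the union of observed sites.

    The feature set is the union of genomic positions observed in at least one
    cell, sorted by (chrom, pos). An observed site is coded +1 when its level
    is >= ``call_threshold`` (methylated) and -1 otherwise; unobserved
    (cell, site) pairs stay implicit zeros so missingness never has to be
    imputed.
    """
    if not 0.0 < call_threshold < 1.0:
        raise ValueError("call_threshold must be in (0, 1)")
    df = _sites_to_frame(per_cell_sites)
    if df.empty:
        raise ValueError("no sites observed in any cell")
    bad = (df["value"] < 0) | (df["value"] > 1)
    if bad.any():
        row = df[bad].iloc[0]
        raise ValueError(
            f"methylation level outside [0, 1]: {row['value']} at "
            f"{row['chrom']}:{row['pos']} (cell {row['cell']})"
        )
    dup = df.duplicated(subset=["cell", "chrom", "pos"], keep=False)
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate site within one cell: {row['chrom']}:{row['pos']} "
            f"in cell {row['cell']}"
        )

    sites = (
        df[["chrom", "pos"]]
        .drop_duplicates()
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    site_index = pd.MultiIndex.from_frame(sites)
    row_of = pd.Series(np.arange(len(sites)), index=site_index)
    cell_order = list(per_cell_sites.keys())
    col_of = {c: j for j, c in enumerate(cell_order)}
    _warn_empty_cells(cell_order, set(df["cell"]))

    rows = row_of.loc[pd.MultiIndex.from_frame(df[["chrom", "pos"]])].to_numpy()
    cols = df["cell"].map(col_of).to_numpy()
    data = np.where(df["value"].to_numpy() >= call_threshold, 1.0, -1.0)
    mat = sp.coo_matrix(
        (data, (rows, cols)), shape=(len(sites), len(cell_order))
    ).tocsr()
    feature_ids = [f"{c}:{p}" for c, p in zip(sites["chrom"], sites["pos"])]
    return SparseOmicsMatrix(mat, feature_ids, cell_order, "methylation")


def bin_accessibility(
    per_cell_sites: Mapping[str, Iterable], bin_size: int = NUCLEOSOME_BIN
) -> SparseOmicsMatrix:
    """Sum accessibility values into fixed-width genomic bins per cell.

    Bins are half-open intervals ``[m*bin_size, (m+1)*bin_size)`` per
    chromosome; only bins with at least one observation in at least one cell
    become features, sorted by (chrom, start).
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    df = _sites_to_frame(per_cell_sites)
    if df.empty:
        raise ValueError("no sites observed in any cell")
    if (df["value"] < 0).any():
        row = df[df["value"] < 0].iloc[0]
        raise ValueError(
            f"negative accessibility value {row['value']} at "
            f"{row['chrom']}:{row['pos']} (cell {row['cell']})"
        )
    df["start"] = (df["pos"] // bin_size) * bin_size

    bins = (
        df[["chrom", "start"]]
        .drop_duplicates()
        .sort_values(["chrom", "start"], kind="mergesort")
        .reset_index(drop=True)
    )
    row_of = pd.Series(np.arange(len(bins)), index=pd.MultiIndex.from_frame(bins))
    cell_order = list(per_cell_sites.keys())
    col_of = {c: j for j, c in enumerate(cell_order)}
    _warn_empty_cells(cell_order, set(df["cell"]))

    rows = row_of.loc[pd.MultiIndex.from_frame(df[["chrom", "start"]])].to_numpy()
    cols = df["cell"].map(col_of).to_numpy()
    mat = sp.coo_matrix(
        (df["value"].to_numpy(), (rows, cols)),
        shape=(len(bins), len(cell_order)),
    ).tocsr()
    mat.sum_duplicates()
    feature_ids = [
        f"{c}:{s}-{s + bin_size}" for c, s in zip(bins["chrom"], bins["start"])
    ]
    return SparseOmicsMatrix(mat, feature_ids, cell_order, "accessibility")


def read_labels(path) -> ClassLabels:
    """Read a ``cell_id <tab> class`` TSV (header row) into ClassLabels."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("labels file needs two columns: cell_id, class")
    return ClassLabels(
        cell_ids=df.iloc[:, 0].to_numpy(dtype=object),
        labels=df.iloc[:, 1].to_numpy(dtype=object),
    )


def write_labels(labels: ClassLabels, path) -> None:
    pd.DataFrame({"cell_id": labels.cell_ids, "class": labels.labels}).to_csv(
        path, sep="\t", index=False
    )


def save_sparse(matrix: SparseOmicsMatrix, prefix, normalized: bool = False) -> None:
    """Persist a layer as ``<prefix>.mtx`` + ID sidecars + JSON metadata.

    ``normalized`` marks bundles whose entries are no longer raw measurements
    (loading then skips the per-kind entry-range check).
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(prefix.parent / (prefix.name + ".mtx")), matrix.values.tocoo())
    pd.Series(matrix.feature_ids).to_csv(
        prefix.parent / (prefix.name + ".features.tsv"),
        sep="\t", index=False, header=False,
    )
    pd.Series(matrix.cell_ids).to_csv(
        prefix.parent / (prefix.name + ".cells.tsv"),
        sep="\t", index=False, header=False,
    )
    (prefix.parent / (prefix.name + ".json")).write_text(
        json.dumps({"omics_kind": matrix.omics_kind, "normalized": normalized})
    )


def load_sparse(prefix) -> SparseOmicsMatrix:
    """Load a layer written by :func:`save_sparse`."""
    prefix = Path(prefix)
    mtx = prefix.parent / (prefix.name + ".mtx")
    feats = prefix.parent / (prefix.name + ".features.tsv")
    cells = prefix.parent / (prefix.name + ".cells.tsv")
    meta = prefix.parent / (prefix.name + ".json")
    for p in (mtx, feats, cells, meta):
        if not p.exists():
            raise FileNotFoundError(f"missing bundle file: {p}")
    values = sp.csr_matrix(scipy.io.mmread(str(mtx)))
    feature_ids = pd.read_csv(feats, sep="\t", header=None, dtype=str)[0].to_numpy(
        dtype=object
    )
    cell_ids = pd.read_csv(cells, sep="\t", header=None, dtype=str)[0].to_numpy(
        dtype=object
    )
    info = json.loads(meta.read_text())
    if info.get("normalized", False):
        return SparseOmicsMatrix.unchecked(
            values, feature_ids, cell_ids, info["omics_kind"]
        )
    return SparseOmicsMatrix(values, feature_ids, cell_ids, info["omics_kind"])
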