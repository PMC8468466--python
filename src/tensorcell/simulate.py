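"""Synthetic single-cell multiomics worlds with planted class structure.

The generator emulates the statistical shape of trimodal single-cell data
(scNMT / scChaRM style): a counts expression layer with ~28% nonzero
entries, a ternary methylation layer and a binned accessibility layer that
are observed at only a few percent of (cell, site) pairs. Class structure is
planted in a known subset of features of every layer so that recovery can be
scored. Two output paths share one set of sampled observations:

* :func:`simulate_matrices` assembles the three sparse layer matrices
  directly (fast path for simulation studies);
* :func:`generate_multiomics` writes the exact file dialects the I/O module
  reads (expression TSV, per-cell ``chrom pos value`` site files, labels
  TSV) so ingestion round-trips are testable.

Generative model (documented choices, not fit to any real dataset): the
classes are successive developmental stages with equally spaced stage scores
t_s in [-1, 1], mirroring the ordered biology (oocyte maturation, embryonic
time points) this kind of trimodal data comes from. Every planted feature
follows the stage axis monotonically with a random sign g in {-1, +1}:

* expression: Gamma-Poisson counts (negative binomial, dispersion r = 2)
  with log-normal gene means calibrated so the expected nonzero fraction is
  0.28; planted genes are drawn from the expressed top third of base means
  and reassigned a common moderate marker scale (markers must be detectably
  and comparably expressed to be class-informative in the count domain).
  Their mean is ``mu_i * exp(effect_size * g * t_s)``, renormalized per
  class so the summed marker expression is exactly stage-independent
  (stages change marker composition, not marker mass), which keeps the
  class signal out of the per-cell mean profile.
* methylation: sites observed Bernoulli(p_obs) per cell; levels are Beta
  draws around a per-site methylation probability, which for planted sites
  is ``sigmoid(effect_size * g * t_s)`` (progressive gain/loss along the
  stages). The planted fraction is large (30% of sites by default) because
  genome-wide demethylation/remethylation waves move a large share of the
  methylome monotonically across developmental stages.
* accessibility: one candidate site per 200-nt bin, observed
  Bernoulli(p_obs), values 1 + Poisson(rate) with a planted rate factor
  ``exp(effect_size * g * t_s)`` on 15% of bins by default (chromatin
  opening/closing tracking the same stage axis), renormalized per class so
  overall accessibility is stage-neutral.

Concentrating the planted signal on one stage axis keeps the class variation
the dominant non-constant component of every layer, which is the regime the
decomposition's cross-layer component indexing relies on.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import write_labels
from .types import ClassLabels, SparseOmicsMatrix

# base scale of the log-normal gene-mean distribution (sigma = 1.5,
# mean-preserving), calibrated so E[P(count > 0)] = 0.28 under NB(r = 2)
_EXPR_BASE_MEAN = 0.704
_EXPR_LOG_SIGMA = 1.5
_EXPR_DISPERSION = 2.0
#: baseline mean count of planted marker genes: strongly expressed
#: stage-defining regulators (the compositional balance caps their maximum
#: up-fold at ~2x, so the absolute contrast scales with this baseline)
_MARKER_BASE_MEAN = 8.0
_CHROMS = ("chr1", "chr2", "chr3", "chr4", "chr5")


@dataclass
class SimulationSpec:
    """Stated world for the synthetic multiomics generator."""

    n_cells: int = 300
    class_sizes: tuple = (100, 100, 100)
    n_genes: int = 2000
    n_meth_sites: int = 50000
    n_acc_sites: int = 50000
    planted_genes: int = 50
    planted_meth: int = 15000
    planted_acc: int = 7500
    effect_size: float = 2.0
    obs_expression: float = 0.28  # target nonzero fraction, via the count model
    obs_meth: float = 0.03
    obs_acc: float = 0.05
    bin_size: int = 200
    seed: int = 0

    def __post_init__(self):
        if sum(self.class_sizes) != self.n_cells:
            raise ValueError("class sizes must sum to n_cells")
        if len(self.class_sizes) < 2:
            raise ValueError("need at least 2 classes")
        for planted, total, name in (
            (self.planted_genes, self.n_genes, "genes"),
            (self.planted_meth, self.n_meth_sites, "methylation sites"),
            (self.planted_acc, self.n_acc_sites, "accessibility sites"),
        ):
            if planted > total:
                raise ValueError(f"more planted {name} ({planted}) than total ({total})")
        for p in (self.obs_expression, self.obs_meth, self.obs_acc):
            if not 0 < p <= 1:
                raise ValueError("observation probabilities must be in (0, 1]")

    @property
    def n_classes(self) -> int:
        return len(self.class_sizes)


def _site_coords(n_sites: int, spacing: int, rng=None, jitter: int = 0):
    """Deterministic genome layout: sites spread over _CHROMS, fixed spacing."""
    per_chrom = int(np.ceil(n_sites / len(_CHROMS)))
    chrom_idx = np.arange(n_sites) // per_chrom
    within = np.arange(n_sites) % per_chrom
    pos = within * spacing
    if jitter and rng is not None:
        pos = pos + rng.integers(0, jitter, size=n_sites)
    chroms = np.array(_CHROMS, dtype=object)[chrom_idx]
    return chroms, pos.astype(np.int64)


def _make_labels(spec: SimulationSpec):
    cells = np.array(
        [f"cell{j:04d}" for j in range(spec.n_cells)], dtype=object
    )
    labels = np.repeat(
        [f"class{s + 1}" for s in range(spec.n_classes)], spec.class_sizes
    ).astype(object)
    return ClassLabels(cell_ids=cells, labels=labels), labels


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class _Draws:
    """All sampled observations of one world; shared by both output paths."""

    def __init__(self, spec: SimulationSpec):
        rng = np.random.default_rng(spec.seed)
        self.spec = spec
        self.class_labels, label_arr = _make_labels(spec)
        class_of_cell = np.repeat(np.arange(spec.n_classes), spec.class_sizes)
        # equally spaced stage scores: classes are ordered developmental stages
        stage = np.linspace(-1.0, 1.0, spec.n_classes)

        # --- expression -------------------------------------------------
        mu = _EXPR_BASE_MEAN * np.exp(
            _EXPR_LOG_SIGMA * rng.standard_normal(spec.n_genes)
            - _EXPR_LOG_SIGMA**2 / 2
        )
        expressed = np.where(mu >= np.quantile(mu, 2.0 / 3.0))[0]
        planted_genes = rng.choice(expressed, spec.planted_genes, replace=False)
        # markers share a common moderate expression scale (a curated marker
        # panel), so their count-domain effects are comparable
        mu[planted_genes] = _MARKER_BASE_MEAN * np.exp(
            0.25 * rng.standard_normal(spec.planted_genes)
        )
        gene_sign = rng.choice([-1.0, 1.0], size=spec.planted_genes)
        marker_factor = np.exp(
            spec.effect_size * gene_sign[:, None] * stage[None, :]
        )
        # compositional balance: stages redistribute marker expression but
        # leave the summed marker mass unchanged per cell
        w = mu[planted_genes]
        marker_factor *= (w.sum() / (w @ marker_factor))[None, :]
        factor = np.ones((spec.n_genes, spec.n_classes))
        factor[planted_genes] = marker_factor
        mean = mu[:, None] * factor[:, class_of_cell]
        r = _EXPR_DISPERSION
        gamma = rng.gamma(shape=r, scale=1.0 / r, size=mean.shape)
        self.expression_counts = rng.poisson(mean * gamma).astype(float)
        self.gene_ids = np.array(
            [f"gene{i:05d}" for i in range(spec.n_genes)], dtype=object
        )
        self.planted_gene_ids = self.gene_ids[np.sort(planted_genes)]

        # --- methylation ------------------------------------------------
        m_chrom, m_pos = _site_coords(spec.n_meth_sites, spacing=50)
        base_p = rng.beta(0.8, 0.8, size=spec.n_meth_sites)
        planted_meth = np.sort(
            rng.choice(spec.n_meth_sites, spec.planted_meth, replace=False)
        )
        meth_sign = rng.choice([-1.0, 1.0], size=spec.planted_meth)
        cell_rows, site_cols, levels = [], [], []
        for j in range(spec.n_cells):
            n_obs = rng.binomial(spec.n_meth_sites, spec.obs_meth)
            idx = rng.choice(spec.n_meth_sites, size=n_obs, replace=False)
            t_j = stage[class_of_cell[j]]
            p = base_p[idx].copy()
            hit = np.isin(idx, planted_meth)
            if hit.any():
                g = meth_sign[np.searchsorted(planted_meth, idx[hit])]
                p[hit] = _sigmoid(spec.effect_size * g * t_j)
            conc = 10.0
            lv = rng.beta(conc * p + 0.25, conc * (1 - p) + 0.25)
            cell_rows.append(np.full(n_obs, j))
            site_cols.append(idx)
            levels.append(lv)
        self.meth = (
            np.concatenate(cell_rows),
            np.concatenate(site_cols),
            np.concatenate(levels),
        )
        self.meth_chrom, self.meth_pos = m_chrom, m_pos
        self.planted_meth_keys = [
            f"{m_chrom[i]}:{m_pos[i]}" for i in planted_meth
        ]

        # --- accessibility (one candidate site per bin) ------------------
        a_chrom, a_start = _site_coords(spec.n_acc_sites, spacing=spec.bin_size)
        a_offset = rng.integers(0, spec.bin_size, size=spec.n_acc_sites)
        a_pos = a_start + a_offset
        planted_acc = np.sort(
            rng.choice(spec.n_acc_sites, spec.planted_acc, replace=False)
        )
        acc_sign = rng.choice([-1.0, 1.0], size=spec.planted_acc)
        base_rate = 0.5
        acc_factor = np.exp(
            spec.effect_size * acc_sign[:, None] * stage[None, :]
        )
        acc_factor *= (spec.planted_acc / acc_factor.sum(axis=0))[None, :]
        cell_rows, site_cols, values = [], [], []
        for j in range(spec.n_cells):
            n_obs = rng.binomial(spec.n_acc_sites, spec.obs_acc)
            idx = rng.choice(spec.n_acc_sites, size=n_obs, replace=False)
            t_j = stage[class_of_cell[j]]
            rate = np.full(n_obs, base_rate)
            hit = np.isin(idx, planted_acc)
            if hit.any():
                which = np.searchsorted(planted_acc, idx[hit])
                rate[hit] = base_rate * acc_factor[which, class_of_cell[j]]
            vals = 1.0 + rng.poisson(rate)
            cell_rows.append(np.full(n_obs, j))
            site_cols.append(idx)
            values.append(vals.astype(float))
        self.acc = (
            np.concatenate(cell_rows),
            np.concatenate(site_cols),
            np.concatenate(values),
        )
        self.acc_chrom, self.acc_pos, self.acc_start = a_chrom, a_pos, a_start
        self.planted_acc_keys = [
            f"{a_chrom[i]}:{a_start[i]}-{a_start[i] + spec.bin_size}"
            for i in planted_acc
        ]

    def manifest(self) -> dict:
        return {
            "spec": asdict(self.spec),
            "planted_genes": list(map(str, self.planted_gene_ids)),
            "planted_methylation_sites": self.planted_meth_keys,
            "planted_accessibility_bins": self.planted_acc_keys,
        }


def _site_matrix(cells, sites, values, chroms, pos, n_cells, kind, key_fmt, binary_call):
    """Assemble a sparse layer over the union of observed sites, sorted."""
    observed = np.unique(sites)
    # site index is already ordered by (chrom, pos) by construction
    remap = np.searchsorted(observed, sites)
    data = np.where(values >= 0.5, 1.0, -1.0) if binary_call else values
    mat = sp.coo_matrix(
        (data, (remap, cells)), shape=(len(observed), n_cells)
    ).tocsr()
    feature_ids = [key_fmt(chroms[i], pos[i]) for i in observed]
    cell_ids = [f"cell{j:04d}" for j in range(n_cells)]
    return SparseOmicsMatrix(mat, feature_ids, cell_ids, kind)


def simulate_matrices(spec: SimulationSpec | None = None, **kwargs):
    """Generate the three layer matrices, labels and planted-feature manifest.

    Returns ``(layers, labels, manifest)`` where ``layers`` maps omics kind
    to a :class:`SparseOmicsMatrix`. Equivalent to writing the files with
    :func:`generate_multiomics` and ingesting them, but without touching disk.
    """
    if spec is None:
        spec = SimulationSpec(**kwargs)
    d = _Draws(spec)
    cell_ids = d.class_labels.cell_ids
    expression = SparseOmicsMatrix(
        sp.csr_matrix(d.expression_counts), d.gene_ids, cell_ids, "expression"
    )
    methylation = _site_matrix(
        d.meth[0], d.meth[1], d.meth[2], d.meth_chrom, d.meth_pos,
        spec.n_cells, "methylation",
        lambda c, p: f"{c}:{p}", binary_call=True,
    )
    accessibility = _site_matrix(
        d.acc[0], d.acc[1], d.acc[2], d.acc_chrom, d.acc_start,
        spec.n_cells, "accessibility",
        lambda c, s: f"{c}:{s}-{s + spec.bin_size}", binary_call=False,
    )
    layers = {
        "expression": expression,
        "methylation": methylation,
        "accessibility": accessibility,
    }
    return layers, d.class_labels, d.manifest()


def generate_multiomics(spec: SimulationSpec | None = None, outdir=".", **kwargs):
    """Write a synthetic world to disk in the dialects the I/O module reads.

    Produces ``expression.tsv``, ``labels.tsv``, ``manifest.json`` and
    per-cell site files ``methylation/<cell>.tsv`` and
    ``accessibility/<cell>.tsv`` (1-based positions, as on disk). Same seed
    gives byte-identical output.
    """
    if spec is None:
        spec = SimulationSpec(**kwargs)
    d = _Draws(spec)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cell_ids = d.class_labels.cell_ids

    expr = pd.DataFrame(
        d.expression_counts.astype(int), index=d.gene_ids, columns=cell_ids
    )
    expr.to_csv(outdir / "expression.tsv", sep="\t")
    write_labels(d.class_labels, outdir / "labels.tsv")
    (outdir / "manifest.json").write_text(json.dumps(d.manifest(), indent=1))

    for name, (cells, sites, values), chroms, pos in (
        ("methylation", d.meth, d.meth_chrom, d.meth_pos),
        ("accessibility", d.acc, d.acc_chrom, d.acc_pos),
    ):
        sub = outdir / name
        sub.mkdir(exist_ok=True)
        order = np.lexsort((sites, cells))
        cells_o, sites_o, values_o = cells[order], sites[order], values[order]
        bounds = np.searchsorted(cells_o, np.arange(spec.n_cells + 1))
        for j, cell in enumerate(cell_ids):
            lo, hi = bounds[j], bounds[j + 1]
            df = pd.DataFrame(
                {
                    "chrom": chroms[sites_o[lo:hi]],
                    "pos": pos[sites_o[lo:hi]] + 1,  # 1-based on disk
                    "value": values_o[lo:hi],
                }
            )
            df.to_csv(sub / f"{cell}.tsv", sep="\t", header=False, index=False)
    return outdir


def toy_worked_example() -> dict:
    """Tiny fixed dataset (6 cells, 2 classes) with hand-checkable values.

    The expected ternary methylation entries and accessibility bin sums in
    the returned manifest were derived by hand from the listed sites
    (threshold 0.5, 200-nt half-open bins).
    """
    cells = ["c1", "c2", "c3", "c4", "c5", "c6"]
    labels = ClassLabels(cell_ids=cells, labels=["A", "A", "A", "B", "B", "B"])
    expression = pd.DataFrame(
        [
            [10, 12, 11, 1, 0, 2],
            [8, 9, 10, 0, 1, 0],
            [5, 4, 6, 5, 6, 4],
            [0, 1, 0, 1, 0, 1],
            [3, 0, 2, 0, 3, 1],
            [7, 6, 8, 9, 7, 8],
            [1, 2, 1, 2, 1, 2],
            [0, 0, 1, 1, 0, 0],
        ],
        index=[f"g{i}" for i in range(1, 9)],
        columns=cells,
    )
    meth_sites = {
        "c1": [("chr1", 100, 1.0), ("chr1", 300, 0.2)],
        "c2": [("chr1", 100, 0.9), ("chr2", 50, 0.5)],
        "c3": [("chr1", 300, 0.0)],
        "c4": [("chr2", 50, 0.1)],
        "c5": [("chr1", 100, 0.0), ("chr2", 50, 1.0)],
        "c6": [("chr1", 300, 0.8)],
    }
    acc_sites = {
        "c1": [("chr1", 50, 2.0), ("chr1", 150, 3.0), ("chr1", 250, 1.0)],
        "c2": [("chr1", 10, 4.0)],
        "c3": [("chr2", 400, 2.0), ("chr2", 410, 5.0)],
        "c4": [("chr1", 250, 2.0)],
        "c5": [("chr2", 430, 1.0)],
        "c6": [("chr1", 0, 1.0), ("chr2", 599, 2.0)],
    }
    manifest = {
        "expected_ternary": {
            "chr1:100": {"c1": 1, "c2": 1, "c5": -1},
            "chr1:300": {"c1": -1, "c3": -1, "c6": 1},
            "chr2:50": {"c2": 1, "c4": -1, "c5": 1},
        },
        "expected_bins": {
            "chr1:0-200": {"c1": 5.0, "c2": 4.0, "c6": 1.0},
            "chr1:200-400": {"c1": 1.0, "c4": 2.0},
            "chr2:400-600": {"c3": 7.0, "c5": 1.0, "c6": 2.0},
        },
        "tensor_shape": (3, 6, 3),
    }
    return {
        "cells": cells,
        "labels": labels,
        "expression": expression,
        "methylation_sites": meth_sites,
        "accessibility_sites": acc_sites,
        "manifest": manifest,
    }
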