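"""Synthetic multiomics generator: dialect fidelity, sparsity targets,
determinism, toy worked example."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from tensorcell import (
    SimulationSpec,
    bin_accessibility,
    build_ternary_methylation,
    generate_multiomics,
    hosvd,
    read_expression_matrix,
    read_labels,
    reconstruct,
    simulate_matrices,
    stack_tensor,
    truncated_svd,
)
from tensorcell.io import read_site_file
from tensorcell.normalize import apply_normalization, normalization_plan

from .conftest import SMALL_SPEC


def _dir_digest(root: Path) -> str:
    h = hashlib.sha256()
    for path in sorted(root.rglob("*")):
        if path.is_file():
            h.update(path.relative_to(root).as_posix().encode())
            h.update(path.read_bytes())
    return h.hexdigest()


class TestGenerator:
    def test_seeded_determinism_byte_identical(self, tmp_path):
        spec = dict(SMALL_SPEC, n_meth_sites=800, n_acc_sites=800, planted_meth=240,
                    planted_acc=120, n_cells=30, class_sizes=(10, 10, 10),
                    planted_genes=6, n_genes=100)
        a = generate_multiomics(SimulationSpec(seed=5, **spec), tmp_path / "a")
        b = generate_multiomics(SimulationSpec(seed=5, **spec), tmp_path / "b")
        assert _dir_digest(a) == _dir_digest(b)

    def test_default_world_sparsity(self):
        layers, labels, _ = simulate_matrices(seed=3)
        fracs = {
            k: m.values.nnz / (m.n_features * m.n_cells) for k, m in layers.items()
        }
        assert abs(fracs["expression"] - 0.28) / 0.28 < 0.2
        assert abs(fracs["methylation"] - 0.03) / 0.03 < 0.2
        assert abs(fracs["accessibility"] - 0.05) / 0.05 < 0.2
        assert len(labels.cell_ids) == 300 and labels.n_classes == 3

    def test_value_domains(self, small_world):
        layers, labels, manifest = small_world
        assert set(np.unique(layers["methylation"].values.data)) <= {-1.0, 1.0}
        assert layers["accessibility"].values.data.min() >= 0
        assert (layers["expression"].values.data >= 0).all()
        assert len(manifest["planted_genes"]) == SMALL_SPEC["planted_genes"]

    def test_file_and_matrix_paths_agree(self, tmp_path):
        spec = SimulationSpec(
            seed=23, n_cells=24, class_sizes=(8, 8, 8), n_genes=80,
            n_meth_sites=600, n_acc_sites=600, planted_genes=6,
            planted_meth=180, planted_acc=90,
        )
        layers, labels, _ = simulate_matrices(spec)
        out = generate_multiomics(spec, tmp_path)

        expr = read_expression_matrix(out / "expression.tsv")
        np.testing.assert_array_equal(expr.toarray(), layers["expression"].toarray())

        cells = list(read_labels(out / "labels.tsv").cell_ids)
        assert cells == list(labels.cell_ids)

        meth_files = {c: read_site_file(out / "methylation" / f"{c}.tsv") for c in cells}
        meth = build_ternary_methylation(meth_files)
        assert list(meth.feature_ids) == list(layers["methylation"].feature_ids)
        np.testing.assert_array_equal(
            meth.toarray(), layers["methylation"].toarray()
        )

        acc_files = {c: read_site_file(out / "accessibility" / f"{c}.tsv") for c in cells}
        acc = bin_accessibility(acc_files)
        assert list(acc.feature_ids) == list(layers["accessibility"].feature_ids)
        np.testing.assert_allclose(acc.toarray(), layers["accessibility"].toarray())

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError, match="planted"):
            SimulationSpec(n_genes=10, planted_genes=20)
        with pytest.raises(ValueError, match="sum"):
            SimulationSpec(n_cells=10, class_sizes=(4, 4, 4))

    def test_null_world_has_no_class_moment_differences(self):
        # with effect 0 the per-class mean expression of planted genes matches
        # the background: nothing distinguishes planted from non-planted
        layers, labels, manifest = simulate_matrices(
            seed=8, effect_size=0.0, **SMALL_SPEC
        )
        X = layers["expression"].toarray()
        planted = np.isin(layers["expression"].feature_ids, manifest["planted_genes"])
        y = labels.labels
        classes = np.unique(y)
        means = np.array([X[np.ix_(planted, y == c)].mean() for c in classes])
        assert np.ptp(means) < 0.15 * means.mean() + 0.5


class TestToyWorkedExample:
    def test_ternary_matches_manifest(self, toy):
        m = build_ternary_methylation(toy["methylation_sites"])
        expected = toy["manifest"]["expected_ternary"]
        assert list(m.feature_ids) == list(expected.keys())
        arr = m.toarray()
        cells = toy["cells"]
        for i, (site, entries) in enumerate(expected.items()):
            for j, cell in enumerate(cells):
                assert arr[i, j] == entries.get(cell, 0), (site, cell)

    def test_bins_match_manifest(self, toy):
        m = bin_accessibility(toy["accessibility_sites"])
        expected = toy["manifest"]["expected_bins"]
        assert list(m.feature_ids) == list(expected.keys())
        arr = m.toarray()
        for i, (_, entries) in enumerate(expected.items()):
            for j, cell in enumerate(toy["cells"]):
                assert arr[i, j] == pytest.approx(entries.get(cell, 0.0))

    def test_tensor_shape_and_hosvd_round_trip(self, toy):
        from tensorcell import read_expression_matrix  # noqa: F401 (parity)
        from tensorcell.types import SparseOmicsMatrix
        import scipy.sparse as sp

        expr = SparseOmicsMatrix(
            sp.csr_matrix(toy["expression"].to_numpy(float)),
            toy["expression"].index.to_numpy(object),
            toy["cells"],
            "expression",
        )
        meth = build_ternary_methylation(toy["methylation_sites"])
        acc = bin_accessibility(toy["accessibility_sites"])
        plan = normalization_plan("dataset1")
        projections, cid = [], []
        for m in (expr, meth, acc):
            X = apply_normalization(m, plan[m.omics_kind])
            svd = truncated_svd(X, L=3, seed=0)
            projections.append(svd.transform(X))
            cid.append(list(m.cell_ids))
        tensor = stack_tensor(
            projections, cid, ["expression", "methylation", "accessibility"]
        )
        assert tensor.shape == tuple(toy["manifest"]["tensor_shape"])
        model = hosvd(tensor)
        np.testing.assert_allclose(
            reconstruct(model), tensor.values,
            atol=1e-10 * max(1.0, np.linalg.norm(tensor.values)),
        )
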