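import numpy as np
import pytest

from tensorcell import SimulationSpec, simulate_matrices, toy_worked_example

#: scaled-down world with the same proportions as the defaults, for unit
#: tests that need a full multiomics dataset but not desk-scale statistics
SMALL_SPEC = dict(
    n_cells=120,
    class_sizes=(40, 40, 40),
    n_genes=400,
    n_meth_sites=4000,
    n_acc_sites=4000,
    planted_genes=12,
    planted_meth=1200,
    planted_acc=600,
)


@pytest.fixture(scope="session")
def toy():
    return toy_worked_example()


@pytest.fixture(scope="session")
def small_world():
    layers, labels, manifest = simulate_matrices(
        SimulationSpec(seed=17, **SMALL_SPEC)
    )
    return layers, labels, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
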