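import numpy as np
import pytest

from morphomod.hypotheses import builtin_ledger
from morphomod.io import LandmarkDataset
from morphomod.synthetic import make_template, simulate_tree, paperlike_simulation


@pytest.fixture(scope="session")
def template():
    return make_template(seed=1)


@pytest.fixture(scope="session")
def ledger(template):
    return builtin_ledger(template.organ_of)


@pytest.fixture(scope="session")
def small_tree():
    return simulate_tree(8, 11.5, seed=3)


@pytest.fixture(scope="session")
def study_sim():
    """One study-scale simulated dataset shared across tests (read-only)."""
    dataset, tree, tpl, ledger_, generating = paperlike_simulation(seed=0)
    return {
        "dataset": dataset,
        "tree": tree,
        "template": tpl,
        "ledger": ledger_,
        "generating": generating,
    }


@pytest.fixture
def random_dataset():
    """Small random landmark dataset (no structure)."""
    rng = np.random.default_rng(7)
    coords = rng.normal(size=(6, 5, 3))
    return LandmarkDataset(
        [f"s{i}" for i in range(6)], [f"L{j}" for j in range(5)], coords
    )
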