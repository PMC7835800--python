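import numpy as np
import pytest

from crnmf import AssociationMatrix, EntityIndex, WeightedNetwork
from crnmf.simulate import SimulationConfig, generate


def make_association(values, row_kind="lincRNA", col_kind="disease",
                     row_prefix=None, col_prefix=None):
    """Build an AssociationMatrix with auto-generated ids."""
    values = np.asarray(values, dtype=float)
    rp = row_prefix or row_kind[0]
    cp = col_prefix or col_kind[0]
    rows = EntityIndex(row_kind, tuple(f"{rp}{i:03d}" for i in range(values.shape[0])))
    cols = EntityIndex(col_kind, tuple(f"{cp}{j:03d}" for j in range(values.shape[1])))
    return AssociationMatrix(rows, cols, values)


def make_network(weights, kind="gene"):
    weights = np.asarray(weights, dtype=float)
    nodes = EntityIndex(kind, tuple(f"{kind[0]}{i:03d}" for i in range(weights.shape[0])))
    return WeightedNetwork(nodes, weights)


def random_network(n, seed, kind="lincRNA", density=0.4):
    """A random symmetric non-negative weighted graph (zero diagonal)."""
    rng = np.random.default_rng(seed)
    upper = np.triu((rng.random((n, n)) < density) * rng.random((n, n)), k=1)
    return make_network(upper + upper.T, kind=kind)


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic study conditions (seed 0)."""
    bundle, truth = generate(SimulationConfig(seed=0))
    return bundle, truth


@pytest.fixture(scope="session")
def small_bundle():
    """A miniature bundle for fast protocol-structure tests."""
    bundle, truth = generate(SimulationConfig(
        n_lincrnas=20, n_genes=60, n_diseases=8, r_true=2,
        density_x=0.1, density_y=0.03, seed=11))
    return bundle, truth
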