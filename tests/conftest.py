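import numpy as np
import pytest

from sdtrace import (
    LeafLocations,
    PMMParams,
    SDParams,
    SimConfig,
    parse_newick,
    simulate_locations,
    simulate_sequences,
    simulate_topology,
)


@pytest.fixture
def cherry():
    """The smallest proper lineage tree: root - u - (A, B)."""
    return parse_newick("((A:1,B:1)u:1)r;")


@pytest.fixture
def single_leaf():
    return parse_newick("(A:1)r;")


@pytest.fixture
def five_leaf():
    return parse_newick(
        "((((A:2,B:2)a:3,C:5)b:2,(D:4,E:4)c:3)d:1)r;"
    )


def random_tree(rng, n_leaves=None, tau=None):
    """A random ultrametric lineage tree (deterministic per rng state)."""
    n = n_leaves or int(rng.integers(3, 12))
    tau = tau or float(rng.uniform(0.5, 20.0))
    seed_rng = np.random.default_rng(rng.integers(2 ** 31))
    return simulate_topology(n, tau, seed_rng), tau


def random_sd_params(rng, tree, r_max=10.0):
    theta = {u: float(rng.uniform(0, 2 * np.pi))
             for u in tree.bifurcations()}
    return SDParams(
        sigma=float(rng.uniform(0.2, 3.0)),
        r=float(rng.uniform(0.0, r_max)),
        theta=theta,
        x0=float(rng.normal(0, 5)),
        y0=float(rng.normal(0, 5)),
    )


def random_locations(rng, tree, params=None):
    params = params or random_sd_params(rng, tree)
    return simulate_locations(
        tree, params, np.random.default_rng(rng.integers(2 ** 31)))
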