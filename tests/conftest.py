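"""Shared fixtures: default synthetic ground truth and panels."""

import numpy as np
import pytest

from panelnet.estimation import EstimatorConfig
from panelnet.synthetic import SyntheticConfig, generate_truth, simulate_panel


@pytest.fixture(scope="session")
def default_truth():
    return generate_truth(SyntheticConfig())


@pytest.fixture(scope="session")
def default_panel(default_truth):
    """n=2000 two-wave panel from the default ground truth."""
    return simulate_panel(default_truth, n=2000, seed=20260101)


@pytest.fixture(scope="session")
def null_truth():
    """Ground truth with no edges and no cross-lagged structure."""
    cfg = SyntheticConfig(
        within_edge_weight=0.0,
        bridge_edges=[],
        cross_lagged=[],
        autoregressive_coeff=0.0,
    )
    return generate_truth(cfg)


@pytest.fixture
def fast_estimator():
    return EstimatorConfig(seed=7)


def random_network(p: int, density: float, seed: int, negative_frac: float = 0.0):
    """Random symmetric weighted network used by brute-force oracle tests."""
    from panelnet.estimation import WeightedNetwork

    rng = np.random.default_rng(seed)
    W = np.zeros((p, p))
    iu = np.triu_indices(p, 1)
    mask = rng.random(len(iu[0])) < density
    mags = rng.uniform(0.02, 0.5, size=len(iu[0]))
    signs = np.where(rng.random(len(iu[0])) < negative_frac, -1.0, 1.0)
    vals = np.where(mask, mags * signs, 0.0)
    W[iu] = vals
    W = W + W.T
    return WeightedNetwork(
        weights=W, node_labels=[f"V{i}" for i in range(p)]
    )
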