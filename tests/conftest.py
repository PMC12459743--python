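"""Shared fixtures: benchmark simulations and trained models (session scope).

The heavy artifacts — the 3-channel benchmark at L=8000 with its fully
cross-validated network fit, and a purely linear reference system with its
fit — are built once per session and shared across unit, property, and
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from eegconn import syndata
from eegconn.ncreann import (
    NCREANNConfig,
    build_regressors,
    decompose_connectivity,
    fit_ncreann,
)


@pytest.fixture(scope="session")
def b1_system():
    return syndata.benchmark_b1()


@pytest.fixture(scope="session")
def b1_run(b1_system):
    """Benchmark sources (L=8000, seed 1), regressors (p=10), trained model."""
    src, edges = syndata.simulate_nmvar(b1_system, 8000, seed=1)
    reg = build_regressors(src, order=10, window_ms=None)
    model = fit_ncreann(reg, NCREANNConfig(seed=1))
    return {"sources": src, "edges": edges, "regressors": reg, "model": model}


@pytest.fixture(scope="session")
def b1_connectivity(b1_run):
    return decompose_connectivity(b1_run["model"], b1_run["regressors"])


def linear_chain_system() -> syndata.GroundTruthSystem:
    """Purely linear 3-channel chain: 0 -> 1 (lag 1), 1 -> 2 (lag 2)."""
    coeffs = np.zeros((2, 3, 3))
    coeffs[0, 0, 0], coeffs[1, 0, 0] = 1.2, -0.5
    coeffs[0, 1, 1] = 0.5
    coeffs[0, 2, 2] = 0.5
    coeffs[0, 1, 0] = 0.6
    coeffs[1, 2, 1] = 0.5
    return syndata.GroundTruthSystem(
        n_channels=3,
        order=2,
        linear_coeffs=coeffs,
        innovation_sd=np.array([1.0, 0.3, 0.3]),
        burn_in=500,
    )


@pytest.fixture(scope="session")
def linear_run():
    """Linear MVAR data (L=8000), regressors, and a trained network."""
    system = linear_chain_system()
    src, edges = syndata.simulate_nmvar(system, 8000, seed=5)
    reg = build_regressors(src, order=10, window_ms=None)
    model = fit_ncreann(reg, NCREANNConfig(folds=2, seed=5))
    return {"system": system, "sources": src, "edges": edges,
            "regressors": reg, "model": model}
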