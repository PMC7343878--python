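"""Shared test fixtures and the brute-force cascade reference."""

from __future__ import annotations

import numpy as np
import pytest

from tipcascade.cascade import CERTAIN, CONTINGENT, NEVER
from tipcascade.fixtures import builtin_fixtures
from tipcascade.network import SocialNetwork


def brute_force_cascade(net: SocialNetwork, labels: np.ndarray, rho: float):
    """Reference cascade: recompute every node's active share from scratch.

    Pure-python set arithmetic, independent of the sparse-matrix
    implementation under test.  Returns (R series, final active set).
    """
    N = net.n_nodes
    neigh = {i: set() for i in range(N)}
    for u, v in net.graph.edges:
        neigh[u].add(v)
        neigh[v].add(u)
    active = {i for i in range(N) if labels[i] == CERTAIN}
    R = [len(active)]
    while True:
        new = set()
        for i in range(N):
            if labels[i] == CONTINGENT and i not in active:
                k = len(neigh[i])
                if k > 0 and len(neigh[i] & active) / k > rho:
                    new.add(i)
        active |= new
        R.append(len(active))
        if not new:
            break
    return R, active


def random_small_instance(rng: np.random.Generator, max_nodes: int = 8):
    """A random small graph with random labels and threshold fraction."""
    N = int(rng.integers(2, max_nodes + 1))
    prob = rng.uniform(0.1, 0.9)
    edges = [
        (u, v)
        for u in range(N)
        for v in range(u + 1, N)
        if rng.random() < prob
    ]
    net = SocialNetwork.from_edges(N, edges)
    labels = rng.choice([NEVER, CONTINGENT, CERTAIN], size=N).astype(np.int8)
    rho = float(rng.uniform(0.0, 1.0))
    return net, labels, rho


@pytest.fixture(scope="session")
def fixture_set():
    return builtin_fixtures()
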