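"""Shared fixtures: toy networks and small random suites."""

from __future__ import annotations

import numpy as np
import pytest

from quantweb import QuantNetwork


def make_net(a, network_id="net", study_id="study", hosts=None, parasitoids=None, **kw):
    a = np.asarray(a)
    if hosts is None:
        hosts = [f"h{i}" for i in range(a.shape[0])]
    if parasitoids is None:
        parasitoids = [f"p{j}" for j in range(a.shape[1])]
    return QuantNetwork(network_id=network_id, study_id=study_id,
                        hosts=hosts, parasitoids=parasitoids, a=a, **kw)


@pytest.fixture
def net_diag():
    """Perfectly specialised 2x2 web: [[2,0],[0,2]]."""
    return make_net(np.array([[2, 0], [0, 2]]))


@pytest.fixture
def net_uniform():
    """Fully generalised 2x2 web: [[1,1],[1,1]]."""
    return make_net(np.array([[1, 1], [1, 1]]))


@pytest.fixture
def net_mixed():
    """Asymmetric 2x2 web: [[2,1],[0,1]]."""
    return make_net(np.array([[2, 1], [0, 1]]))


@pytest.fixture
def net_single():
    """Single-cell web: [[5]]."""
    return make_net(np.array([[5]]))


@pytest.fixture
def small_random_nets():
    """A seeded suite of small valid integer networks (R + C <= 8)."""
    rng = np.random.default_rng(20240915)
    nets = []
    while len(nets) < 8:
        shape = (rng.integers(1, 5), rng.integers(1, 4))
        a = rng.integers(0, 4, size=shape)
        if a.sum() == 0 or (a.sum(axis=0) == 0).any():
            continue
        nets.append(make_net(a, network_id=f"rand{len(nets)}"))
    return nets


@pytest.fixture
def medium_random_nets():
    """Seeded denser integer networks for invariant checks."""
    rng = np.random.default_rng(7)
    nets = []
    for k in range(5):
        a = rng.multinomial(200, np.ones(6 * 4) / 24).reshape(6, 4)
        if (a.sum(axis=0) == 0).any():
            a[:, a.sum(axis=0) == 0] += 1
        nets.append(make_net(a, network_id=f"med{k}"))
    return nets
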