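"""Shared fixtures: canonical topologies and hand-constructed parameter sets.

The hand-picked kinetics realize the intended physiology analytically:
degradation ~1e-9 freezes outputs between conditions (slow-dilution memory),
half-max constants ~1e-3 saturate Hill terms at physiological levels, and the
recall edges use small V with a high half-max on the memory link so the
untrained memory level (0.1) leaks only negligibly into salivation.
"""

from __future__ import annotations

import numpy as np
import pytest

from pavnet.dynamics import EdgeParams, NodeParams, ParameterSet, SignalEdge
from pavnet.sampling import derive_signal_edges
from pavnet.topology import Topology


def make_params(
    t: Topology,
    signal_edges: list[SignalEdge] | None = None,
    V: float = 1.0,
    k: float = 1e-3,
    K: float = 1.0,
    alpha: float = 0.5,
    n: float = 2.0,
    eta: float = 1e-9,
    sig_V: float = 10.0,
    sig_k: float = 0.01,
    sig_n: float = 1.0,
    edge_overrides: dict[tuple[int, int], EdgeParams] | None = None,
) -> ParameterSet:
    """Uniform hand-picked kinetics with optional per-edge overrides."""
    if signal_edges is None:
        signal_edges = derive_signal_edges(t)
    edge_overrides = edge_overrides or {}
    edge_params = {}
    for i, j, _s in t.edges():
        edge_params[(i, j)] = edge_overrides.get(
            (i, j), EdgeParams(V=V, k=k, K=K, alpha=alpha, n=n)
        )
    node_params = {i: NodeParams(eta=eta) for i in range(t.n_nodes)}
    signal_params = {
        (e.signal, e.node): EdgeParams(V=sig_V, k=sig_k, K=1.0, alpha=0.0, n=sig_n)
        for e in signal_edges
    }
    return ParameterSet(edge_params, node_params, signal_params)


#: Recall-edge kinetics: small V so untrained leak stays inside the off band,
#: high half-max on the memory link to discriminate trained vs untrained memory.
RECALL_EDGE_WEAK = EdgeParams(V=0.02, k=0.01, K=1.0, alpha=0.5, n=3.0)
RECALL_MEMORY_LINK = EdgeParams(V=0.02, k=1.0, K=1.0, alpha=0.5, n=3.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20160)
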