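"""Post-hoc statistics on robust pools and combination results.

Regulation entropy quantifies sign-mixing among the regulations converging
on each node: a node whose incoming edges all activate (or all inhibit)
scores 0 bits, a node with an even activation/inhibition mix scores 1 bit;
a network's score is the mean over its regulated nodes.  Logically valid
combined networks are expected to sit well below unconstrained random
networks of the same size — the no-contradiction merge rule suppresses
mixed-sign convergence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

from .combination import MergeMap, all_merge_maps, check_sign_compatibility, role_legal
from .topology import RegulationSign, Topology

__all__ = [
    "EntropyReport",
    "regulation_entropy",
    "random_network_baseline",
    "pool_entropy",
    "cluster_pool",
    "legal_map_count",
    "combination_space_size",
    "q_histogram",
]


@dataclass(frozen=True)
class EntropyReport:
    """Per-network regulation entropies (bits) and their mean."""

    entropies: np.ndarray
    mean: float


def regulation_entropy(t: Topology) -> float:
    """Mean per-node entropy (bits) of incoming regulation signs.

    Self-edges count toward a node's in-edge profile.  Nodes without
    incoming edges are excluded from the mean; a network with no edges
    scores 0.
    """
    per_node = []
    for j in range(t.n_nodes):
        col = t.adjacency[:, j]
        a = int(np.count_nonzero(col == RegulationSign.ACTIVATION))
        b = int(np.count_nonzero(col == RegulationSign.INHIBITION))
        total = a + b
        if total == 0:
            continue
        h = 0.0
        for c in (a, b):
            if c:
                p = c / total
                h -= p * np.log2(p)
        per_node.append(h)
    return float(np.mean(per_node)) if per_node else 0.0


def random_network_baseline(
    n_nodes: int, n_samples: int, seed: int
) -> EntropyReport:
    """Entropy of unconstrained random networks of a given size.

    Each ordered node pair draws independently and uniformly among the three
    regulation states.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    ent = np.empty(n_samples)
    for s in range(n_samples):
        adj = rng.integers(0, 3, size=(n_nodes, n_nodes))
        ent[s] = regulation_entropy(Topology(n_nodes, adj.astype(np.int8)))
    return EntropyReport(ent, float(ent.mean()))


def pool_entropy(pool: Sequence[Topology]) -> EntropyReport:
    """Entropy report over an explicit pool of topologies."""
    ent = np.array([regulation_entropy(t) for t in pool])
    return EntropyReport(ent, float(ent.mean()) if len(ent) else 0.0)


def cluster_pool(
    pool: Sequence[Topology],
) -> tuple[list[int], np.ndarray | None]:
    """Average-linkage hierarchical clustering of sign vectors.

    Each topology flattens to its row-major vector of regulation signs;
    distances are Hamming counts (number of differing entries).  Returns the
    dendrogram leaf order (indices into the pool) and the SciPy linkage
    matrix (None for a singleton pool).
    """
    if not pool:
        raise ValueError("pool must be nonempty")
    if len(pool) == 1:
        return [0], None
    vectors = np.array([t.adjacency.ravel() for t in pool], dtype=float)
    n_entries = vectors.shape[1]
    dist = pdist(vectors, metric="hamming") * n_entries
    linkage = average(dist)
    return [int(i) for i in leaves_list(linkage)], linkage


def combination_space_size(
    poolL: int | Sequence[Topology],
    poolR: int | Sequence[Topology],
    arity: int,
    map_counter: Callable[[MergeMap], bool] | None = None,
) -> int:
    """Exact size of the combination candidate space at a given arity.

    With plain pool sizes, counts all (pair, map) candidates before any
    filtering: ``|poolL| * |poolR| * n_maps(arity)`` with 9 / 18 / 6 maps at
    arity 1 / 2 / 3 (optionally restricted by ``map_counter``).  With actual
    pools, counts the role-legal, sign-compatible combinations — the length
    of the :func:`~pavnet.combination.enumerate_combinations` stream.
    """
    maps = all_merge_maps(arity)
    if map_counter is not None:
        maps = [m for m in maps if map_counter(m)]
    if isinstance(poolL, int) and isinstance(poolR, int):
        return poolL * poolR * len(maps)
    count = 0
    for tL in poolL:  # type: ignore[union-attr]
        for tR in poolR:  # type: ignore[union-attr]
            for m in maps:
                if check_sign_compatibility(tL, tR, m):
                    count += 1
    return count


def legal_map_count(tL: Topology, tR: Topology, arity: int) -> int:
    """Role-legal merge maps at an arity, before sign filtering."""
    return sum(1 for m in all_merge_maps(arity) if role_legal(tL, tR, m))


def q_histogram(
    qs: Sequence[float], bin_width: float = 0.0005
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of Q-values at the screen's reporting granularity."""
    qs = np.asarray(qs, dtype=float)
    top = max(float(qs.max()) if len(qs) else 0.0, bin_width)
    edges = np.arange(0.0, top + bin_width, bin_width)
    counts, edges = np.histogram(qs, bins=edges)
    return counts, edges
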