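"""Signed directed regulatory network topologies with node roles.

A topology is an ``n × n`` matrix over three regulation states — none,
activation, inhibition — where entry ``(i, j)`` is the effect of node *i* on
node *j* (self-regulation allowed).  For three nodes this gives the classic
``3**9 = 19683`` candidate space.  Each topology has a canonical integer ID:
the adjacency read row-major as a base-3 number with entry ``(0, 0)`` as the
most significant digit (0 = none, 1 = activation, 2 = inhibition).

Node roles tie matrix indices to the biological wiring of the conditioning
function: the learning module uses ``ring_input`` (R), ``food_input`` (F) and
``memory_output`` (M) at indices 0, 1, 2; the recall module uses
``memory_input`` (M), ``ring_input`` (R) and ``output_fs`` (F&S, the node that
both receives the food signal and reports salivation) at indices 0, 1, 2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "RegulationSign",
    "NodeRole",
    "Topology",
    "LEARNING_ROLES",
    "RECALL_ROLES",
    "enumerate_topologies",
    "encode_id",
    "decode_id",
    "swap_nodes",
    "topology_to_json",
    "topology_from_json",
]


class RegulationSign(IntEnum):
    """Regulation state of one ordered node pair; the base-3 digit values."""

    NONE = 0
    ACTIVATION = 1
    INHIBITION = 2


class NodeRole(str, Enum):
    RING_INPUT = "ring_input"
    FOOD_INPUT = "food_input"
    MEMORY_OUTPUT = "memory_output"
    MEMORY_INPUT = "memory_input"
    OUTPUT_FS = "output_fs"
    INTERNAL = "internal"


#: Canonical role layout of the learning module: R, F, M.
LEARNING_ROLES: dict[int, NodeRole] = {
    0: NodeRole.RING_INPUT,
    1: NodeRole.FOOD_INPUT,
    2: NodeRole.MEMORY_OUTPUT,
}

#: Canonical role layout of the recall module: M, R, F&S.
RECALL_ROLES: dict[int, NodeRole] = {
    0: NodeRole.MEMORY_INPUT,
    1: NodeRole.RING_INPUT,
    2: NodeRole.OUTPUT_FS,
}


@dataclass(frozen=True)
class Topology:
    """A signed directed network over roled nodes.

    Parameters
    ----------
    n_nodes
        Number of nodes.
    adjacency
        ``n_nodes × n_nodes`` integer matrix of :class:`RegulationSign`
        values; entry ``(i, j)`` is the regulation of node *i* on node *j*.
    roles
        Mapping node index → :class:`NodeRole`.  Non-internal roles must be
        assigned to at most one node each.
    """

    n_nodes: int
    adjacency: np.ndarray
    roles: Mapping[int, NodeRole] = field(default_factory=dict)

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=np.int8)
        if adj.shape != (self.n_nodes, self.n_nodes):
            raise ValueError(
                f"adjacency shape {adj.shape} != ({self.n_nodes}, {self.n_nodes})"
            )
        if not np.isin(adj, (0, 1, 2)).all():
            raise ValueError("adjacency entries must be 0 (none), 1 (activation) or 2 (inhibition)")
        adj.setflags(write=False)
        object.__setattr__(self, "adjacency", adj)
        roles = {int(i): NodeRole(r) for i, r in self.roles.items()}
        non_internal = [r for r in roles.values() if r is not NodeRole.INTERNAL]
        if len(non_internal) != len(set(non_internal)):
            raise ValueError("non-internal roles must be injective")
        for i in roles:
            if not 0 <= i < self.n_nodes:
                raise IndexError(f"role index {i} out of range")
        object.__setattr__(self, "roles", roles)

    # hashing/equality by structure, not array identity
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Topology):
            return NotImplemented
        return (
            self.n_nodes == other.n_nodes
            and np.array_equal(self.adjacency, other.adjacency)
            and self.roles == other.roles
        )

    def __hash__(self) -> int:
        return hash((self.n_nodes, self.adjacency.tobytes(), tuple(sorted(self.roles.items()))))

    # ------------------------------------------------------------------
    def sign(self, i: int, j: int) -> RegulationSign:
        """Regulation of node *i* on node *j*."""
        return RegulationSign(int(self.adjacency[i, j]))

    def node_with_role(self, role: NodeRole) -> int:
        """Index of the unique node carrying *role* (KeyError if absent)."""
        for i, r in self.roles.items():
            if r is role:
                return i
        raise KeyError(f"no node with role {role.value!r}")

    def edges(self) -> list[tuple[int, int, RegulationSign]]:
        """Non-none edges as ``(source, target, sign)`` triples, row-major order."""
        ii, jj = np.nonzero(self.adjacency)
        return [(int(i), int(j), RegulationSign(int(self.adjacency[i, j]))) for i, j in zip(ii, jj)]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.adjacency))


# ----------------------------------------------------------------------
# Canonical IDs and enumeration


def encode_id(t: Topology) -> int:
    """Canonical base-3 ID of a topology (row-major, entry (0,0) most significant)."""
    digits = t.adjacency.ravel()
    out = 0
    for d in digits:
        out = out * 3 + int(d)
    return out


def decode_id(topo_id: int, n_nodes: int, roles: Mapping[int, NodeRole] | None = None) -> Topology:
    """Topology of a canonical ID (inverse of :func:`encode_id`)."""
    n_digits = n_nodes * n_nodes
    if not 0 <= topo_id < 3**n_digits:
        raise ValueError(f"id {topo_id} out of range [0, {3**n_digits - 1}] for {n_nodes} nodes")
    digits = np.zeros(n_digits, dtype=np.int8)
    rem = topo_id
    for pos in range(n_digits - 1, -1, -1):
        digits[pos] = rem % 3
        rem //= 3
    return Topology(n_nodes, digits.reshape(n_nodes, n_nodes), roles or {})


def enumerate_topologies(
    n_nodes: int, roles: Mapping[int, NodeRole] | None = None
) -> Iterator[Topology]:
    """Yield every ``3**(n_nodes**2)`` topology in ascending canonical-ID order.

    For three nodes this materializes the full 19683-topology candidate space;
    larger spaces stream lazily (the four-node space of 43046721 is supported
    by the API but normally counted analytically, not materialized).
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    n_digits = n_nodes * n_nodes
    roles = dict(roles or {})
    digits = np.zeros(n_digits, dtype=np.int8)
    total = 3**n_digits
    for _ in range(total):
        yield Topology(n_nodes, digits.reshape(n_nodes, n_nodes).copy(), roles)
        # increment base-3 counter, least-significant digit last
        for pos in range(n_digits - 1, -1, -1):
            if digits[pos] < 2:
                digits[pos] += 1
                break
            digits[pos] = 0


def topology_space_size(n_nodes: int) -> int:
    """Number of candidate topologies on *n_nodes* nodes: ``3**(n_nodes**2)``."""
    return 3 ** (n_nodes * n_nodes)


# ----------------------------------------------------------------------
# Transformations


def swap_nodes(t: Topology, a: int, b: int) -> Topology:
    """Exchange nodes *a* and *b* (rows, columns and roles); an involution."""
    if a == b:
        raise ValueError("swap requires two distinct nodes")
    for idx in (a, b):
        if not 0 <= idx < t.n_nodes:
            raise IndexError(f"node index {idx} out of range")
    perm = list(range(t.n_nodes))
    perm[a], perm[b] = perm[b], perm[a]
    adj = t.adjacency[np.ix_(perm, perm)]
    roles = {perm.index(i): r for i, r in t.roles.items()}
    return Topology(t.n_nodes, adj, roles)


# ----------------------------------------------------------------------
# JSON network format

_SIGN_TO_STR = {RegulationSign.ACTIVATION: "+", RegulationSign.INHIBITION: "-"}
_STR_TO_SIGN = {"+": RegulationSign.ACTIVATION, "-": RegulationSign.INHIBITION}


def topology_to_json(t: Topology) -> str:
    """Serialize to the network JSON format (none edges omitted)."""
    doc = {
        "n_nodes": t.n_nodes,
        "roles": {str(i): r.value for i, r in sorted(t.roles.items())},
        "edges": [
            {"from": i, "to": j, "sign": _SIGN_TO_STR[s]} for i, j, s in t.edges()
        ],
    }
    return json.dumps(doc, indent=2)


def topology_from_json(text: str) -> Topology:
    """Parse the network JSON format, or a bare base-3 digit string for 3-node IDs."""
    stripped = text.strip()
    if stripped and all(c in "012" for c in stripped):
        n_digits = len(stripped)
        n = int(round(n_digits**0.5))
        if n * n != n_digits:
            raise ValueError(f"digit string length {n_digits} is not a square")
        return decode_id(int(stripped, 3), n)
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed network JSON at line {exc.lineno}: {exc.msg}") from exc
    n = int(doc["n_nodes"])
    adj = np.zeros((n, n), dtype=np.int8)
    for e in doc.get("edges", []):
        adj[int(e["from"]), int(e["to"])] = _STR_TO_SIGN[e["sign"]]
    roles = {int(i): NodeRole(r) for i, r in doc.get("roles", {}).items()}
    return Topology(n, adj, roles)
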