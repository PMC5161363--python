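"""Merging learning and recall sub-networks into whole Pavlovian candidates.

A merge identifies 1–3 nodes of a learning-module network with nodes of a
recall-module network; the combined network keeps the union of both edge
sets.  A merge is logically possible only when

* no identified pair of slots carries contradictory regulation (an edge that
  is activation in one module and inhibition in the other — including
  self-edges and edges between two merged nodes);
* the food-receiving and ring-receiving roles are never fused (one physical
  receptor cannot take both signals), and the learning memory output is
  never fused with the recall salivation output.

When the learning memory output is not merged with the recall memory input,
an activating edge from the former to the latter is added so the trained
memory state can drive recall; if the union already carries inhibition on
that slot the combination is rejected as contradictory.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .dynamics import CompiledSystem, ParameterSet, SignalEdge, SimulationError
from .evaluation import (
    DEFAULT_SETTINGS,
    EvalSettings,
    QResult,
    StageFailure,
    Verdict,
    _require_state,
    draw_inits,
    unique_steady_outputs,
)
from .sampling import DEFAULT_RANGES, ParameterRanges, sample_parameters, topology_seed
from .topology import NodeRole, RegulationSign, Topology, encode_id

__all__ = [
    "MergeMap",
    "CombinedNetwork",
    "all_merge_maps",
    "role_legal",
    "check_sign_compatibility",
    "combine_networks",
    "enumerate_combinations",
    "combined_signal_edges",
    "test_pavlovian",
    "compute_q_combined",
]


@dataclass(frozen=True)
class MergeMap:
    """Identification of learning nodes with recall nodes.

    ``pairs`` is a set of ``(learning index, recall index)`` tuples forming a
    partial injective matching; the arity (1, 2 or 3) is the number of fused
    node pairs.
    """

    pairs: frozenset[tuple[int, int]]

    def __init__(self, pairs: Iterable[tuple[int, int]]):
        object.__setattr__(self, "pairs", frozenset((int(a), int(b)) for a, b in pairs))
        left = [a for a, _ in self.pairs]
        right = [b for _, b in self.pairs]
        if len(set(left)) != len(left) or len(set(right)) != len(right):
            raise ValueError("merge map must be injective on both sides")
        if not 1 <= len(self.pairs) <= 3:
            raise ValueError("arity must be 1, 2 or 3")

    @property
    def arity(self) -> int:
        return len(self.pairs)

    def recall_partner(self, learning_node: int) -> int | None:
        for a, b in self.pairs:
            if a == learning_node:
                return b
        return None

    def learning_partner(self, recall_node: int) -> int | None:
        for a, b in self.pairs:
            if b == recall_node:
                return a
        return None

    def __repr__(self) -> str:  # stable order for manifests
        inner = ",".join(f"{a}:{b}" for a, b in sorted(self.pairs))
        return f"MergeMap({inner})"


@dataclass(frozen=True)
class CombinedNetwork:
    """A merged whole network with provenance and multi-role bookkeeping.

    ``roles`` maps each combined node to the *set* of roles it inherited —
    a merged node may, e.g., be both the learning memory output and the
    recall memory input; both modules' ring receivers remain distinct nodes
    in low-arity merges, so a single role can also appear on two nodes.
    """

    topology: Topology
    learning_id: int
    recall_id: int
    merge: MergeMap
    roles: dict[int, frozenset[NodeRole]]
    added_memory_edge: bool

    @property
    def arity(self) -> int:
        return self.merge.arity

    @property
    def n_nodes(self) -> int:
        return self.topology.n_nodes

    def nodes_with_role(self, role: NodeRole) -> list[int]:
        return sorted(i for i, rs in self.roles.items() if role in rs)

    def node_with_role(self, role: NodeRole) -> int:
        nodes = self.nodes_with_role(role)
        if len(nodes) != 1:
            raise KeyError(f"role {role.value!r} not unique: {nodes}")
        return nodes[0]

    def validate(self) -> None:
        """Check the structural invariants of a legal combination."""
        if self.n_nodes != 6 - self.arity:
            raise ValueError("node count must be 6 - arity")
        food = set(self.nodes_with_role(NodeRole.FOOD_INPUT)) | set(
            self.nodes_with_role(NodeRole.OUTPUT_FS)
        )
        ring = set(self.nodes_with_role(NodeRole.RING_INPUT))
        if food & ring:
            raise ValueError("a node receives both food and ring signals")
        mem_out = self.node_with_role(NodeRole.MEMORY_OUTPUT)
        fs = self.node_with_role(NodeRole.OUTPUT_FS)
        if mem_out == fs:
            raise ValueError("memory output fused with recall output")
        mem_in = self.node_with_role(NodeRole.MEMORY_INPUT)
        if mem_out != mem_in:
            if not self.added_memory_edge:
                raise ValueError("unmerged memory nodes require the added link")
            if self.topology.sign(mem_out, mem_in) is not RegulationSign.ACTIVATION:
                raise ValueError("memory link edge must be activating")
        elif self.added_memory_edge:
            raise ValueError("merged memory nodes must not flag an added link")


# ----------------------------------------------------------------------
# Merge-map enumeration and legality


def all_merge_maps(arity: int, n_nodes: int = 3) -> list[MergeMap]:
    """Every injective matching of the given arity, before any filtering.

    For three-node modules this yields 9 / 18 / 6 maps at arity 1 / 2 / 3.
    """
    if arity not in (1, 2, 3):
        raise ValueError("arity must be 1, 2 or 3")
    maps = []
    for left in itertools.combinations(range(n_nodes), arity):
        for right in itertools.permutations(range(n_nodes), arity):
            maps.append(MergeMap(zip(left, right)))
    return maps


def _receives_food(role: NodeRole) -> bool:
    return role in (NodeRole.FOOD_INPUT, NodeRole.OUTPUT_FS)


def _receives_ring(role: NodeRole) -> bool:
    return role is NodeRole.RING_INPUT


def role_legal(tL: Topology, tR: Topology, m: MergeMap) -> bool:
    """Whether a merge map violates no input/output role constraint."""
    for a, b in m.pairs:
        rL = tL.roles.get(a, NodeRole.INTERNAL)
        rR = tR.roles.get(b, NodeRole.INTERNAL)
        if _receives_food(rL) and _receives_ring(rR):
            return False
        if _receives_ring(rL) and _receives_food(rR):
            return False
        if rL is NodeRole.MEMORY_OUTPUT and rR is NodeRole.OUTPUT_FS:
            return False
    return True


def _memory_link_slot(tL: Topology, tR: Topology, m: MergeMap) -> tuple[int, int] | None:
    """Learning/recall node pair of the added memory link, if one is needed."""
    mem_out = tL.node_with_role(NodeRole.MEMORY_OUTPUT)
    mem_in = tR.node_with_role(NodeRole.MEMORY_INPUT)
    if m.recall_partner(mem_out) == mem_in:
        return None
    return mem_out, mem_in


def check_sign_compatibility(tL: Topology, tR: Topology, m: MergeMap) -> bool:
    """True iff the merge has no sign conflict and no role violation.

    For every ordered pair of fused slots (including a slot with itself,
    i.e. self-edges) the two modules' signs must agree or at least one must
    be absent.  The added memory link counts as an activation requirement on
    its slot when both of its endpoints are fused nodes.
    """
    if not role_legal(tL, tR, m):
        return False
    pairs = sorted(m.pairs)
    for aL, aR in pairs:
        for bL, bR in pairs:
            sL = tL.adjacency[aL, bL]
            sR = tR.adjacency[aR, bR]
            if sL and sR and sL != sR:
                return False
    slot = _memory_link_slot(tL, tR, m)
    if slot is not None:
        mem_out, mem_in = slot
        # the link's slot may already carry a sign in the union when either
        # memory node is fused with some other node; inhibition there
        # contradicts the required activating link
        partnerL = m.learning_partner(mem_in)
        if partnerL is not None and tL.adjacency[mem_out, partnerL] == RegulationSign.INHIBITION:
            return False
        partnerR = m.recall_partner(mem_out)
        if partnerR is not None and tR.adjacency[partnerR, mem_in] == RegulationSign.INHIBITION:
            return False
    return True


# ----------------------------------------------------------------------
# Merging


def combine_networks(tL: Topology, tR: Topology, m: MergeMap) -> CombinedNetwork:
    """Union-merge two sub-networks under a compatible merge map.

    Learning nodes keep their indices; unmerged recall nodes are appended in
    ascending recall order.  The merged adjacency is the union of both edge
    sets (compatible by precondition), plus the activating memory link when
    the two memory nodes are not fused.
    """
    if not check_sign_compatibility(tL, tR, m):
        raise ValueError("incompatible merge (sign conflict or role violation)")
    nL = tL.n_nodes
    index_of_recall: dict[int, int] = {}
    next_idx = nL
    for j in range(tR.n_nodes):
        partner = m.learning_partner(j)
        if partner is not None:
            index_of_recall[j] = partner
        else:
            index_of_recall[j] = next_idx
            next_idx += 1
    n = next_idx
    adj = np.zeros((n, n), dtype=np.int8)
    adj[:nL, :nL] = tL.adjacency
    for i, j, s in tR.edges():
        ci, cj = index_of_recall[i], index_of_recall[j]
        if adj[ci, cj] and adj[ci, cj] != int(s):
            raise ValueError("sign conflict surfaced during merge")
        adj[ci, cj] = int(s)

    roles: dict[int, set[NodeRole]] = {i: set() for i in range(n)}
    for i, r in tL.roles.items():
        roles[i].add(r)
    for j, r in tR.roles.items():
        roles[index_of_recall[j]].add(r)

    added = False
    slot = _memory_link_slot(tL, tR, m)
    if slot is not None:
        mem_out, mem_in = slot
        ci, cj = mem_out, index_of_recall[mem_in]
        if adj[ci, cj] == RegulationSign.INHIBITION:
            raise ValueError("memory link slot carries inhibition")
        if adj[ci, cj] == RegulationSign.NONE:
            adj[ci, cj] = RegulationSign.ACTIVATION
        added = True

    combined = CombinedNetwork(
        topology=Topology(n, adj, {}),
        learning_id=encode_id(tL),
        recall_id=encode_id(tR),
        merge=m,
        roles={i: frozenset(rs - {NodeRole.INTERNAL}) for i, rs in roles.items()},
        added_memory_edge=added,
    )
    combined.validate()
    return combined


def enumerate_combinations(
    poolL: Sequence[Topology], poolR: Sequence[Topology], arity: int
) -> Iterator[CombinedNetwork]:
    """All logically possible combinations of two pools at the given arity.

    Every (learning network, recall network, merge map) triple passing the
    sign/role check is emitted; identical merged graphs arising from
    different provenances are *not* deduplicated — counts are counts of
    combinations, not of unique graphs.
    """
    maps = all_merge_maps(arity)
    for tL in poolL:
        for tR in poolR:
            for m in maps:
                if check_sign_compatibility(tL, tR, m):
                    yield combine_networks(tL, tR, m)


# ----------------------------------------------------------------------
# Whole-network (Pavlovian) screening


def combined_signal_edges(c: CombinedNetwork) -> list[SignalEdge]:
    """Signal wiring of a combined network.

    Food and ring fan out multiplicatively to every node carrying the
    corresponding input role (a fused receptor node receives a single term);
    the food signal additionally drives the salivation output additively.
    There is no external memory signal: the learning module supplies it.
    """
    edges: list[SignalEdge] = []
    for i in c.nodes_with_role(NodeRole.RING_INPUT):
        edges.append(SignalEdge("ring", i, additive=False))
    for i in c.nodes_with_role(NodeRole.FOOD_INPUT):
        edges.append(SignalEdge("food", i, additive=False))
    edges.append(SignalEdge("food", c.node_with_role(NodeRole.OUTPUT_FS), additive=True))
    return edges


def test_pavlovian(
    c: CombinedNetwork,
    params: ParameterSet,
    settings: EvalSettings | None = None,
    init_rng: np.random.Generator | None = None,
) -> Verdict:
    """Whole-network conditioning protocol (thresholds 5/10), early exit.

    (1) no-signal baseline: unique steady memory and salivation outputs;
    (2) food alone: memory off, salivation on; (3) ring alone: both off;
    (4) food+ring training: memory on with a steady plateau; (5) signals
    removed: memory retains >= 80% of the plateau at the checkpoint;
    (6) from that persistent state, ring alone turns salivation on.
    """
    settings = (settings or DEFAULT_SETTINGS).for_combined()
    rng = init_rng if init_rng is not None else np.random.default_rng(0)
    on = settings.s_on
    try:
        mem = c.node_with_role(NodeRole.MEMORY_OUTPUT)
        sal = c.node_with_role(NodeRole.OUTPUT_FS)
        system = CompiledSystem(c.topology, params, combined_signal_edges(c))
        inits = draw_inits(
            c.n_nodes, [mem, sal], settings.n_inits, rng,
            settings.init_high, settings.output_init,
        )
        outs = [mem, sal]
        base, _ = unique_steady_outputs(system, {}, inits, outs, settings)
        # (2) food alone: salivation with no training
        v, _ = unique_steady_outputs(
            system, {"food": on}, inits, outs, settings, band_nodes=[mem]
        )
        _require_state(v[mem], base[mem], settings.ratios, "off")
        _require_state(v[sal], base[sal], settings.ratios, "on")
        # (3) ring alone, untrained: nothing happens
        v, _ = unique_steady_outputs(system, {"ring": on}, inits, outs, settings)
        _require_state(v[mem], base[mem], settings.ratios, "off")
        _require_state(v[sal], base[sal], settings.ratios, "off")
        # (4) training: food and ring together switch the memory on
        v, trained = unique_steady_outputs(
            system, {"food": on, "ring": on}, inits, [mem], settings, band_nodes=[]
        )
        _require_state(v[mem], base[mem], settings.ratios, "on")
        plateau = v[mem]
        # (5) persistence of the memory after signal removal
        rule = settings.persistence
        try:
            tail = system.integrate(
                {}, trained[None, :], np.array([rule.t_check]),
                t_span=(0.0, rule.t_check),
            )
        except SimulationError as exc:
            raise StageFailure("sim-failed") from exc
        persistent = tail[0, -1, :]
        if persistent[mem] < rule.retain_frac * plateau:
            raise StageFailure("persistence")
        # (6) recall after training: ring alone from the persistent state
        grid = np.arange(
            settings.steady.window[0], settings.steady.window[1] + 0.5, 1.0
        )
        try:
            post = system.integrate(
                {"ring": on}, persistent[None, :], grid,
                t_span=(0.0, settings.t_end),
            )
        except SimulationError as exc:
            raise StageFailure("sim-failed") from exc
        from .evaluation import _steady_value

        y_post = _steady_value(post[0, :, sal], settings.steady, require_band=False)
        if y_post is None:
            raise StageFailure("no-steady-state")
        _require_state(y_post, base[sal], settings.ratios, "on")
    except StageFailure as f:
        return Verdict(False, f.stage)
    return Verdict(True)


def compute_q_combined(
    c: CombinedNetwork,
    n_sets: int,
    seed: int,
    settings: EvalSettings | None = None,
    ranges: ParameterRanges = DEFAULT_RANGES,
) -> QResult:
    """Q-value of a combined network under the Pavlovian protocol."""
    t = c.topology
    param_sets = sample_parameters(
        t, n_sets, seed, ranges, signal_edges=combined_signal_edges(c)
    )
    base = topology_seed(seed, t)
    n_pass = 0
    for idx, params in enumerate(param_sets):
        rng = np.random.default_rng([base, idx])
        if test_pavlovian(c, params, settings, rng).passed:
            n_pass += 1
    return QResult(encode_id(t), n_sets, n_pass)
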