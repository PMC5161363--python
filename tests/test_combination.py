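"""Merge maps, sign-compatibility logic, network merging and the combined
Pavlovian protocol, cross-checked against a brute-force oracle."""

import itertools

import numpy as np
import pytest

from pavnet.cli_io import simplest_learning_topology, simplest_recall_topology
from pavnet.combination import (
    CombinedNetwork,
    MergeMap,
    all_merge_maps,
    check_sign_compatibility,
    combine_networks,
    combined_signal_edges,
    compute_q_combined,
    enumerate_combinations,
    role_legal,
)
from pavnet.combination import test_pavlovian as run_pavlovian_test
from pavnet.evaluation import Verdict
from pavnet.topology import (
    LEARNING_ROLES,
    RECALL_ROLES,
    NodeRole,
    RegulationSign,
    Topology,
    decode_id,
)

from conftest import RECALL_EDGE_WEAK, RECALL_MEMORY_LINK, make_params


# ----------------------------------------------------------------------
# Independent brute-force oracle

#: role pairs that may never be fused: (learning role, recall role)
FORBIDDEN_ROLE_PAIRS = {
    (NodeRole.FOOD_INPUT, NodeRole.RING_INPUT),
    (NodeRole.RING_INPUT, NodeRole.OUTPUT_FS),
    (NodeRole.MEMORY_OUTPUT, NodeRole.OUTPUT_FS),
}


def oracle_maps(arity):
    """All injective matchings, written independently of the implementation."""
    out = []
    for left in itertools.permutations(range(3), arity):
        for right in itertools.permutations(range(3), arity):
            pairs = frozenset(zip(left, right))
            if len(pairs) == arity:
                out.append(pairs)
    return sorted(set(out), key=sorted)


def oracle_compatible(tL, tR, pairs):
    """Edge-by-edge compatibility re-check by direct matrix comparison."""
    for aL, aR in pairs:
        rL = tL.roles.get(aL, NodeRole.INTERNAL)
        rR = tR.roles.get(aR, NodeRole.INTERNAL)
        if (rL, rR) in FORBIDDEN_ROLE_PAIRS:
            return False
    for (aL, aR) in pairs:
        for (bL, bR) in pairs:
            sL, sR = int(tL.adjacency[aL, bL]), int(tR.adjacency[aR, bR])
            if sL != 0 and sR != 0 and sL != sR:
                return False
    # the added memory link must not meet inhibition on its slot
    mem_out, mem_in = 2, 0  # canonical role positions
    if (mem_out, mem_in) not in pairs:
        for (aL, aR) in pairs:
            if aR == mem_in and int(tL.adjacency[mem_out, aL]) == 2:
                return False
            if aL == mem_out and int(tR.adjacency[aR, mem_in]) == 2:
                return False
    return True


def random_pool(roles, n, rng):
    ids = rng.integers(0, 3**9, size=n)
    return [decode_id(int(i), 3, roles) for i in ids]


# ----------------------------------------------------------------------


class TestMergeMaps:
    def test_total_map_counts(self):
        assert len(all_merge_maps(1)) == 9
        assert len(all_merge_maps(2)) == 18
        assert len(all_merge_maps(3)) == 6

    def test_maps_match_oracle(self):
        for arity in (1, 2, 3):
            got = sorted({m.pairs for m in all_merge_maps(arity)}, key=sorted)
            assert got == oracle_maps(arity)

    def test_role_legal_counts_for_canonical_modules(self):
        tL = decode_id(0, 3, LEARNING_ROLES)
        tR = decode_id(0, 3, RECALL_ROLES)
        legal = {
            arity: sum(role_legal(tL, tR, m) for m in all_merge_maps(arity))
            for arity in (1, 2, 3)
        }
        oracle = {
            arity: sum(
                all(
                    (tL.roles[a], tR.roles[b]) not in FORBIDDEN_ROLE_PAIRS
                    for a, b in pairs
                )
                for pairs in oracle_maps(arity)
            )
            for arity in (1, 2, 3)
        }
        assert legal == oracle == {1: 6, 2: 8, 3: 2}

    def test_injectivity_enforced(self):
        with pytest.raises(ValueError):
            MergeMap({(0, 0), (0, 1)})
        with pytest.raises(ValueError):
            MergeMap({(0, 0), (1, 0)})


class TestSignCompatibility:
    def _with_self_edge(self, roles, node, sign):
        adj = np.zeros((3, 3), dtype=np.int8)
        adj[node, node] = sign
        return Topology(3, adj, roles)

    def test_conflicting_self_regulation_blocks_merge(self):
        # learning F self-activates, recall F&S self-inhibits; F merged with F&S
        tL = self._with_self_edge(LEARNING_ROLES, 1, 1)
        tR = self._with_self_edge(RECALL_ROLES, 2, 2)
        assert not check_sign_compatibility(tL, tR, MergeMap({(1, 2)}))

    def test_missing_regulation_is_compatible(self):
        tL = self._with_self_edge(LEARNING_ROLES, 1, 1)
        tR = decode_id(0, 3, RECALL_ROLES)
        assert check_sign_compatibility(tL, tR, MergeMap({(1, 2)}))

    def test_food_ring_fusion_always_forbidden(self):
        tL = decode_id(0, 3, LEARNING_ROLES)
        tR = decode_id(0, 3, RECALL_ROLES)
        assert not check_sign_compatibility(tL, tR, MergeMap({(1, 1)}))  # F with R
        assert not check_sign_compatibility(tL, tR, MergeMap({(0, 2)}))  # R with F&S
        assert not check_sign_compatibility(tL, tR, MergeMap({(2, 2)}))  # M with F&S

    def test_cross_edge_conflict_at_arity_two(self):
        # F1->R1 positive but F2->R2 negative: fusing both pairs is impossible
        aL = np.zeros((3, 3), dtype=np.int8)
        aL[1, 0] = 1
        tL = Topology(3, aL, LEARNING_ROLES)
        aR = np.zeros((3, 3), dtype=np.int8)
        aR[2, 1] = 2  # F&S -> ring, negative
        tR = Topology(3, aR, RECALL_ROLES)
        m = MergeMap({(1, 2), (0, 1)})  # F with F&S, R with ring
        assert not check_sign_compatibility(tL, tR, m)
        tR_pos = Topology(3, np.where(aR == 2, 1, 0).astype(np.int8), RECALL_ROLES)
        assert check_sign_compatibility(tL, tR_pos, m)


class TestCombineNetworks:
    def test_memory_merge_needs_no_added_edge(self):
        c = combine_networks(
            simplest_learning_topology(), simplest_recall_topology(), MergeMap({(2, 0)})
        )
        assert c.n_nodes == 5
        assert not c.added_memory_edge
        c.validate()
        assert c.roles[2] == frozenset({NodeRole.MEMORY_OUTPUT, NodeRole.MEMORY_INPUT})

    def test_ring_merge_adds_memory_link(self):
        # learning memory fused with the recall ring receiver
        c = combine_networks(
            simplest_learning_topology(), simplest_recall_topology(), MergeMap({(2, 1)})
        )
        assert c.n_nodes == 5
        assert c.added_memory_edge
        mem_out = c.node_with_role(NodeRole.MEMORY_OUTPUT)
        mem_in = c.node_with_role(NodeRole.MEMORY_INPUT)
        assert c.topology.sign(mem_out, mem_in) is RegulationSign.ACTIVATION
        c.validate()

    def test_arity_three_memory_aligned_merge_of_empty_modules(self):
        tL = decode_id(0, 3, LEARNING_ROLES)
        tR = decode_id(0, 3, RECALL_ROLES)
        c = combine_networks(tL, tR, MergeMap({(0, 1), (1, 2), (2, 0)}))
        assert c.n_nodes == 3
        assert c.topology.n_edges == 0
        assert not c.added_memory_edge

    def test_edge_union(self):
        c = combine_networks(
            simplest_learning_topology(), simplest_recall_topology(), MergeMap({(2, 0)})
        )
        got = {(i, j, int(s)) for i, j, s in c.topology.edges()}
        # learning edges keep indices; recall ring->F&S and M->F&S map to 3->4, 2->4
        assert got == {(0, 2, 1), (1, 2, 1), (2, 4, 1), (3, 4, 1)}

    def test_incompatible_merge_rejected(self):
        tL = decode_id(0, 3, LEARNING_ROLES)
        tR = decode_id(0, 3, RECALL_ROLES)
        with pytest.raises(ValueError):
            combine_networks(tL, tR, MergeMap({(1, 1)}))


class TestEnumerateCombinations:
    @pytest.mark.parametrize("arity", [1, 2, 3])
    def test_matches_brute_force_oracle(self, arity, rng):
        poolL = random_pool(LEARNING_ROLES, 5, rng)
        poolR = random_pool(RECALL_ROLES, 5, rng)
        got = [
            (c.learning_id, c.recall_id, tuple(sorted(c.merge.pairs)))
            for c in enumerate_combinations(poolL, poolR, arity)
        ]
        expected = []
        for tL in poolL:
            for tR in poolR:
                for pairs in oracle_maps(arity):
                    if oracle_compatible(tL, tR, pairs):
                        expected.append(
                            (
                                int("".join(str(d) for d in tL.adjacency.ravel()), 3),
                                int("".join(str(d) for d in tR.adjacency.ravel()), 3),
                                tuple(sorted(pairs)),
                            )
                        )
        assert sorted(got) == sorted(expected)

    def test_all_emitted_networks_satisfy_invariants(self, rng):
        poolL = random_pool(LEARNING_ROLES, 3, rng)
        poolR = random_pool(RECALL_ROLES, 3, rng)
        for arity in (1, 2, 3):
            for c in enumerate_combinations(poolL, poolR, arity):
                c.validate()
                assert c.n_nodes == 6 - arity
                # edge union: every edge traces back to a source or the link
                mem_out = c.node_with_role(NodeRole.MEMORY_OUTPUT)
                mem_in = c.node_with_role(NodeRole.MEMORY_INPUT)
                for i, j, s in c.topology.edges():
                    if (i, j) == (mem_out, mem_in) and c.added_memory_edge:
                        continue
                    assert _edge_has_source(c, poolL, poolR, i, j, s)


def _edge_has_source(c, poolL, poolR, i, j, s):
    tL = next(t for t in poolL if _tid(t) == c.learning_id)
    tR = next(t for t in poolR if _tid(t) == c.recall_id)
    recall_index = {}
    nxt = 3
    for rj in range(3):
        partner = c.merge.learning_partner(rj)
        if partner is not None:
            recall_index[rj] = partner
        else:
            recall_index[rj] = nxt
            nxt += 1
    if i < 3 and j < 3 and tL.sign(i, j) is s:
        return True
    for ri in range(3):
        for rj in range(3):
            if recall_index[ri] == i and recall_index[rj] == j and tR.sign(ri, rj) is s:
                return True
    return False


def _tid(t):
    return int("".join(str(d) for d in t.adjacency.ravel()), 3)


class TestPavlovianProtocol:
    def _combined_hand_params(self, c):
        mem = c.node_with_role(NodeRole.MEMORY_OUTPUT)
        sal = c.node_with_role(NodeRole.OUTPUT_FS)
        overrides = {}
        for i, j, s in c.topology.edges():
            if j == sal:
                overrides[(i, j)] = (
                    RECALL_MEMORY_LINK if i == mem else RECALL_EDGE_WEAK
                )
        return make_params(
            c.topology, signal_edges=combined_signal_edges(c), edge_overrides=overrides
        )

    def test_hand_picked_memory_merge_passes_all_stages(self):
        c = combine_networks(
            simplest_learning_topology(), simplest_recall_topology(), MergeMap({(2, 0)})
        )
        params = self._combined_hand_params(c)
        v = run_pavlovian_test(c, params, init_rng=np.random.default_rng(7))
        assert v == Verdict(True)

    def test_recall_output_without_memory_path_fails_post_training_stage(self):
        # an empty recall module leaves salivation driven by food alone:
        # training works, but the conditioned ring response never appears
        c = combine_networks(
            simplest_learning_topology(), decode_id(0, 3, RECALL_ROLES), MergeMap({(2, 0)})
        )
        params = make_params(c.topology, signal_edges=combined_signal_edges(c))
        from pavnet.dynamics import NodeParams

        sal = c.node_with_role(NodeRole.OUTPUT_FS)
        params.node_params[sal] = NodeParams(eta=0.01)  # salivation relaxes
        v = run_pavlovian_test(c, params, init_rng=np.random.default_rng(7))
        assert not v.passed
        assert v.failure_stage == "truth-table"

    def test_compute_q_combined_deterministic(self):
        c = combine_networks(
            simplest_learning_topology(), simplest_recall_topology(), MergeMap({(2, 0)})
        )
        a = compute_q_combined(c, 15, seed=8)
        b = compute_q_combined(c, 15, seed=8)
        assert a == b
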