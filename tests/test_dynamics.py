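"""Boolean network model, synchronous dynamics, attractors, state completion."""

import numpy as np
import pytest

from stabcore import (
    Attractor,
    BooleanState,
    PartialState,
    SignedNetwork,
    complete_partial_state,
    find_attractors,
    fixed_points,
    synchronous_step,
)
from conftest import code_to_values, naive_attractors, naive_step, random_signed_network


def net_of(*edges, extra=()):
    return SignedNetwork.from_edges(list(edges), extra_nodes=extra)


def state(net, **values):
    return BooleanState.from_mapping(net, values)


class TestSignedNetwork:
    def test_nodes_sorted_and_deduplicated(self):
        net = SignedNetwork(["b", "a", "a", "c"], [("c", "a", 1)])
        assert net.nodes == ("a", "b", "c")

    def test_parallel_opposite_edges_coexist(self):
        net = net_of(("A", "B", 1), ("A", "B", -1))
        assert len(net.edges) == 2
        assert net.activators("B") == ("A",) and net.inhibitors("B") == ("A",)

    def test_edge_endpoint_must_be_node(self):
        with pytest.raises(ValueError, match="not a declared node"):
            SignedNetwork(["A"], [("A", "B", 1)])

    def test_subnetwork_keeps_nodes_drops_edges(self):
        net = net_of(("A", "B", 1), ("B", "A", 1))
        sub = net.subnetwork([("A", "B", 1)])
        assert sub.nodes == net.nodes and sub.edges == frozenset({("A", "B", 1)})
        with pytest.raises(ValueError):
            net.subnetwork([("A", "A", 1)])


class TestSynchronousStep:
    def test_unregulated_gene_holds_and_inhibition_wins(self):
        net = net_of(("A", "B", -1))
        nxt = synchronous_step(net, state(net, A=1, B=1))
        assert nxt.as_dict() == {"A": 1, "B": 0}

    def test_mutual_activation_fixed_point(self):
        net = net_of(("A", "B", 1), ("B", "A", 1))
        s = state(net, A=1, B=1)
        assert synchronous_step(net, s) == s

    def test_activation_inhibition_orbit(self):
        # full orbit (0,0)->(1,0)->(1,1)->(0,1)->(0,0): A has only an
        # inhibitor, so it is vacuously activated while B stays OFF
        net = net_of(("A", "B", 1), ("B", "A", -1))
        s = state(net, A=0, B=0)
        orbit = [s.as_dict()]
        for _ in range(4):
            s = synchronous_step(net, s)
            orbit.append(s.as_dict())
        assert orbit == [
            {"A": 0, "B": 0},
            {"A": 1, "B": 0},
            {"A": 1, "B": 1},
            {"A": 0, "B": 1},
            {"A": 0, "B": 0},
        ]

    def test_unknown_gene_in_state_is_named(self):
        net = net_of(("A", "B", 1))
        other = SignedNetwork(["A", "Z"])
        bad = BooleanState.from_mapping(other, {"A": 1, "Z": 0})
        with pytest.raises((KeyError, ValueError), match="Z"):
            synchronous_step(net, bad)

    def test_decay_rule_zeroes_unregulated_genes(self):
        net = net_of(("A", "B", 1), extra=["C"])
        s = state(net, A=1, B=0, C=1)
        nxt = synchronous_step(net, s, rule="decay")
        assert nxt.as_dict() == {"A": 0, "B": 1, "C": 0}

    @pytest.mark.parametrize("rule", ["hold", "decay"])
    def test_matches_naive_rule_on_random_networks(self, rng, rule):
        for _ in range(25):
            net = random_signed_network(rng, max_nodes=8, max_edges=16)
            code = int(rng.integers(1 << len(net.nodes)))
            s = BooleanState(net.nodes, code)
            expect = naive_step(net, code_to_values(net, code), rule)
            assert synchronous_step(net, s, rule=rule).as_dict() == expect


class TestAttractors:
    def test_mutual_activation_fixed_points_and_swap_cycle(self):
        net = net_of(("A", "B", 1), ("B", "A", 1))
        assert {s.code for s in fixed_points(net)} == {0, 0b11}
        ats = find_attractors(net)
        assert sum(a.basin_size for a in ats) == 4
        # besides the two fixed points the antiphase pair swaps with period 2
        lengths = sorted(a.length for a in ats)
        assert lengths == [1, 1, 2]

    def test_edgeless_network_every_state_holds(self):
        net = SignedNetwork(["A", "B", "C"])
        ats = find_attractors(net)
        assert len(ats) == 8
        assert all(a.is_fixed_point and a.basin_size == 1 for a in ats)

    def test_activation_inhibition_single_four_cycle(self):
        net = net_of(("A", "B", 1), ("B", "A", -1))
        ats = find_attractors(net)
        assert len(ats) == 1
        (a,) = ats
        assert a.length == 4 and a.basin_size == 4

    def test_canonical_rotation_starts_at_minimal_code(self):
        net = net_of(("A", "B", 1), ("B", "A", -1))
        (a,) = find_attractors(net)
        assert a.states[0].code == min(s.code for s in a.states)
        # one synchronous step maps states[i] to states[i+1 mod L]
        for i, s in enumerate(a.states):
            assert synchronous_step(net, s) == a.states[(i + 1) % a.length]

    def test_exhaustive_cap_suggests_sampled_mode(self):
        net = SignedNetwork([f"g{i}" for i in range(6)])
        with pytest.raises(ValueError, match="sampled"):
            find_attractors(net, max_nodes_exhaustive=5)

    def test_sampled_mode_reaches_the_right_attractor(self):
        net = net_of(("A", "B", 1), ("B", "A", 1))
        start = state(net, A=1, B=1)
        ats = find_attractors(net, mode="sampled", start_states=[start])
        assert len(ats) == 1 and next(iter(ats)).states[0] == start
        with pytest.raises(ValueError, match="start_states"):
            find_attractors(net, mode="sampled")

    @pytest.mark.parametrize("rule", ["hold", "decay"])
    def test_oracle_equivalence_on_random_networks(self, rng, rule):
        """Exhaustive search equals brute-force cycle extraction from the
        full transition map, including basin sizes."""
        for _ in range(30):
            net = random_signed_network(rng, max_nodes=9, max_edges=22)
            expected = naive_attractors(net, rule)
            got = {
                tuple(s.code for s in a.states): a.basin_size
                for a in find_attractors(net, rule=rule)
            }
            assert got == expected
            assert sum(got.values()) == 1 << len(net.nodes)

    def test_all_activating_regulated_network_has_extreme_fixed_points(self, rng):
        # every node regulated, every edge activating: all-OFF and all-ON hold
        for _ in range(10):
            n = int(rng.integers(3, 7))
            nodes = [f"g{i}" for i in range(n)]
            edges = {(nodes[i], nodes[(i + 1) % n], 1) for i in range(n)}
            for _ in range(int(rng.integers(0, 5))):
                edges.add((nodes[int(rng.integers(n))], nodes[int(rng.integers(n))], 1))
            net = SignedNetwork(nodes, edges)
            codes = {s.code for s in fixed_points(net)}
            assert 0 in codes and (1 << n) - 1 in codes


class TestCompletePartialState:
    def test_completes_from_known_half(self):
        net = net_of(("A", "B", 1), ("B", "A", 1))
        done = complete_partial_state(net, PartialState({"A": 1, "B": None}))
        assert {s.as_dict()["B"] for s in done} == {1} and len(done) == 1

    def test_rejects_all_unknown_and_all_known(self):
        net = net_of(("A", "B", 1), ("B", "A", 1))
        with pytest.raises(ValueError, match="known"):
            complete_partial_state(net, PartialState({"A": None, "B": None}))
        with pytest.raises(ValueError, match="unknown"):
            complete_partial_state(net, PartialState({"A": 1, "B": 0}))

    def test_edgeless_network_yields_all_consistent_states(self):
        net = SignedNetwork(["A", "B"])
        done = complete_partial_state(net, PartialState({"A": 1, "B": None}))
        assert {s.as_dict()["B"] for s in done} == {0, 1}

    def test_infeasible_observation_yields_empty_set(self):
        # A -| A has the single fixed point A=0 ... with B free
        net = net_of(("A", "A", -1), extra=["B"])
        done = complete_partial_state(net, PartialState({"A": 1, "B": None}))
        assert done == set()
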