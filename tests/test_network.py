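"""Dynamics engine: local rule, schemes, transition graphs, attractors, basins."""

import numpy as np
import pytest

from conftest import random_network
from pombenet.network import (
    ThresholdNetwork,
    UpdateScheme,
    basin_size,
    build_transition_graph,
    estimate_async_basin,
    find_attractors,
    index_to_state,
    local_update,
    scheme_step,
    simulate,
    state_to_index,
)


def net1(w, t):
    return ThresholdNetwork.from_theta(("a",), [[w]], [t])


NET2_MUTUAL = ThresholdNetwork.from_theta(("a", "b"), [[0, 1], [1, 0]], [0.5, 0.5])


class TestLocalUpdate:
    @pytest.mark.parametrize(
        "w,theta,state,expected",
        [
            (1, 0.5, [1], 1),   # weighted sum above threshold -> on
            (1, 0.5, [0], 0),   # below -> off
            (0, 0, [1], 1),     # tie -> hold previous value
            (0, 0, [0], 0),
            (-1, -0.5, [1], 0),
        ],
    )
    def test_threshold_rule(self, w, theta, state, expected):
        assert local_update(net1(w, theta), state, 0) == expected

    def test_errors(self):
        with pytest.raises(IndexError):
            local_update(net1(1, 0), [1], 2)
        with pytest.raises(ValueError):
            local_update(NET2_MUTUAL, [1], 0)


class TestValueSets:
    def test_weight_outside_set_rejected(self):
        with pytest.raises(ValueError, match="weight"):
            ThresholdNetwork.from_theta(("a",), [[3]], [0])

    def test_threshold_outside_set_rejected(self):
        with pytest.raises(ValueError):
            ThresholdNetwork.from_theta(("a",), [[1]], [0.25])
        with pytest.raises(ValueError):
            ThresholdNetwork.from_theta(("a",), [[1]], [3])

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            ThresholdNetwork.from_theta(("a", "a"), [[0, 0], [0, 0]], [0, 0])


class TestStateEncoding:
    def test_roundtrip_all_states(self):
        for idx in range(16):
            assert state_to_index(index_to_state(idx, 4)) == idx

    def test_first_node_is_most_significant(self):
        assert state_to_index((1, 0, 0, 0)) == 8


class TestSchemeStep:
    def test_wildtype_first_transition(self, wt, sequence, parallel):
        assert scheme_step(wt, sequence[0], parallel) == sequence[1]

    @pytest.mark.parametrize("mode", ["parallel", "sequential", "block_sequential", "async_deterministic"])
    def test_g1_fixed_under_every_deterministic_scheme(self, wt, sequence, mode):
        g1 = sequence[9]
        scheme = (
            UpdateScheme(mode, blocks=((0, 1, 2), (3, 4, 5, 6), (7, 8, 9)))
            if mode == "block_sequential"
            else UpdateScheme(mode, order=tuple(range(10)))
            if mode != "parallel"
            else UpdateScheme(mode)
        )
        assert scheme_step(wt, g1, scheme) == g1

    def test_fully_async_changes_at_most_one_bit(self, wt, sequence):
        rng = np.random.default_rng(7)
        state = sequence[0]
        for _ in range(50):
            nxt = scheme_step(wt, state, UpdateScheme("fully_async"), rng=rng)
            assert sum(a != b for a, b in zip(state, nxt)) <= 1
            state = nxt

    def test_fully_async_requires_rng(self, wt, sequence):
        with pytest.raises(ValueError, match="rng"):
            scheme_step(wt, sequence[0], UpdateScheme("fully_async"))

    def test_missing_order_rejected(self, wt, sequence):
        with pytest.raises(ValueError, match="order"):
            scheme_step(wt, sequence[0], UpdateScheme("sequential"))
        with pytest.raises(ValueError, match="blocks"):
            scheme_step(wt, sequence[0], UpdateScheme("block_sequential"))


class TestSimulate:
    def test_wildtype_reproduces_cell_cycle(self, wt, sequence, parallel):
        assert simulate(wt, sequence[0], 9, parallel) == list(sequence.states)

    def test_fixed_point_stays(self, wt, sequence, parallel):
        traj = simulate(wt, sequence[9], 5, parallel)
        assert traj == [sequence[9]] * 6

    def test_zero_steps(self, wt, sequence, parallel):
        assert simulate(wt, sequence[0], 0, parallel) == [sequence[0]]


class TestTransitionGraph:
    def test_one_node_identity(self):
        tg = build_transition_graph(net1(1, 0.5), UpdateScheme("parallel"))
        assert tg.successor.tolist() == [0, 1]

    def test_two_node_mutual_activation(self):
        # hand enumeration: 00->00, 01->10, 10->01, 11->11
        tg = build_transition_graph(NET2_MUTUAL, UpdateScheme("parallel"))
        assert tg.successor.tolist() == [0, 2, 1, 3]

    def test_wildtype_total_map(self, wt, parallel):
        tg = build_transition_graph(wt, parallel)
        assert tg.successor.shape == (1024,)
        assert ((tg.successor >= 0) & (tg.successor < 1024)).all()

    def test_nondeterministic_scheme_rejected(self, wt):
        with pytest.raises(ValueError, match="deterministic"):
            build_transition_graph(wt, UpdateScheme("fully_async"))


def naive_attractors(tg):
    """Independent oracle: iterate every state 2**n steps, then walk its cycle."""
    n_states = tg.n_states
    assignment = {}
    cycles = set()
    for s in range(n_states):
        cur = s
        for _ in range(n_states):
            cur = int(tg.successor[cur])
        cycle = [cur]
        nxt = int(tg.successor[cur])
        while nxt != cur:
            cycle.append(nxt)
            nxt = int(tg.successor[nxt])
        canon = tuple(sorted(cycle))
        cycles.add(canon)
        assignment[s] = canon
    return cycles, assignment


class TestAttractors:
    def test_two_node_example(self):
        att = find_attractors(build_transition_graph(NET2_MUTUAL, UpdateScheme("parallel")))
        assert sorted(att.fixed_points) == [0, 3]
        assert [sorted(c) for c in att.limit_cycles] == [[1, 2]]
        assert all(len(c) > 1 for c in att.limit_cycles)

    def test_g1_among_wildtype_fixed_points(self, wt, sequence, parallel):
        att = find_attractors(build_transition_graph(wt, parallel))
        assert state_to_index(sequence[9]) in att.fixed_points

    def test_identity_graph_all_fixed(self):
        net = ThresholdNetwork.from_theta(("a", "b"), [[1, 0], [0, 1]], [0.5, 0.5])
        att = find_attractors(build_transition_graph(net, UpdateScheme("parallel")))
        assert sorted(att.fixed_points) == [0, 1, 2, 3]
        assert all(s == 1 for s in att.basin_sizes().values())

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_oracle_on_random_networks(self, seed):
        rng = np.random.default_rng(seed)
        net = random_network(rng, 4)
        tg = build_transition_graph(net, UpdateScheme("parallel"))
        att = find_attractors(tg)
        oracle_cycles, oracle_assignment = naive_attractors(tg)
        assert {tuple(sorted(a)) for a in att.attractors} == oracle_cycles
        for s in range(16):
            aid = int(att.attractor_of[s])
            assert tuple(sorted(att.attractors[aid])) == oracle_assignment[s]

    @pytest.mark.parametrize("seed", range(25))
    def test_fixed_points_invariant_across_deterministic_schemes(self, seed):
        rng = np.random.default_rng(100 + seed)
        net = random_network(rng, 4)
        schemes = [
            UpdateScheme("parallel"),
            UpdateScheme("sequential", order=(2, 0, 3, 1)),
            UpdateScheme("block_sequential", blocks=((0, 2), (1, 3))),
            UpdateScheme("async_deterministic", order=(3, 1, 0, 2)),
        ]
        fp_sets = []
        for scheme in schemes:
            att = find_attractors(build_transition_graph(net, scheme))
            fp_sets.append(frozenset(att.fixed_points))
        assert len(set(fp_sets)) == 1


class TestBasins:
    def test_wildtype_g1_basin_is_762(self, wt, sequence, parallel):
        att = find_attractors(build_transition_graph(wt, parallel))
        assert basin_size(att, state_to_index(sequence[9])) == 762

    def test_basins_partition_state_space(self, wt, parallel):
        att = find_attractors(build_transition_graph(wt, parallel))
        assert sum(att.basin_sizes().values()) == 1024

    def test_contraction_map_single_basin(self):
        # zero weights with positive thresholds force every node off: all -> 0
        net = ThresholdNetwork.from_theta(("a", "b", "c"), np.zeros((3, 3), int), [1, 1, 1])
        att = find_attractors(build_transition_graph(net, UpdateScheme("parallel")))
        assert att.fixed_points == [0]
        assert basin_size(att, 0) == 8

    def test_non_attractor_state_rejected(self, wt, parallel):
        att = find_attractors(build_transition_graph(wt, parallel))
        transient = next(
            s for s in range(1024) if all(s not in a for a in att.attractors)
        )
        with pytest.raises(ValueError, match="attractor"):
            basin_size(att, transient)


class TestAsyncBasin:
    def test_target_state_absorbs_immediately(self, wt, sequence):
        g1 = state_to_index(sequence[9])
        probs, mass = estimate_async_basin(wt, g1, runs=3, seed=5)
        assert probs[g1] == 1.0
        assert 0 < mass <= 1024

    def test_probabilities_are_run_fractions(self, wt, sequence):
        g1 = state_to_index(sequence[9])
        probs, _ = estimate_async_basin(wt, g1, runs=4, seed=5)
        assert np.all((probs * 4) == np.round(probs * 4))
        assert probs.min() >= 0 and probs.max() <= 1

    def test_one_node_decay_converges_exactly(self):
        # 1 always maps to 0, 0 holds on the tie: basin of 0 is both states
        net = net1(-1, 0)
        probs, mass = estimate_async_basin(net, 0, runs=10, seed=0)
        assert probs.tolist() == [1.0, 1.0]
        assert mass == 2.0

    def test_seed_reproducible(self, wt, sequence):
        g1 = state_to_index(sequence[9])
        a = estimate_async_basin(wt, g1, runs=5, seed=11)
        b = estimate_async_basin(wt, g1, runs=5, seed=11)
        assert np.array_equal(a[0], b[0])

    def test_non_fixed_point_rejected(self, wt, sequence):
        with pytest.raises(ValueError, match="fixed point"):
            estimate_async_basin(wt, state_to_index(sequence[0]), runs=1, seed=0)
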