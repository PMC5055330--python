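"""Triad revision rules, schedule, engines and absorbing-state behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from bcpf.core import (
    OpinionMatrix,
    Params,
    SignedNetwork,
    SystemState,
    Triad,
    count_unbalanced,
    init_random_state,
    is_balanced,
)
from bcpf.dynamics import (
    build_neighborhood,
    fixedpoint_residual,
    revise_opinion,
    revise_triad,
    revise_triad_ctd,
    revise_triad_ltd,
    run,
    run_bc_baseline,
    step,
)

from .conftest import ScriptedRNG, brute_force_unbalanced, network_from_signs


def make_state(n, sign_assignments, opinions):
    net = network_from_signs(n, sign_assignments)
    return SystemState.create(net, OpinionMatrix(np.asarray(opinions, dtype=float)))


class TestNeighborhood:
    def test_zero_confidence_only_self(self):
        state = make_state(3, {}, [[0.1], [0.2], [0.3]])
        nb = build_neighborhood(state, 0, epsilon=0.0)
        assert list(nb.members) == [0]
        assert nb.size == 1

    def test_enemies_never_influence(self):
        # enemy at distance 0 excluded; friend at 0.1 included
        state = make_state(3, {(0, 2): -1}, [[0.5], [0.6], [0.5]])
        nb = build_neighborhood(state, 0, epsilon=0.2)
        assert list(nb.members) == [0, 1]

    def test_full_confidence_all_friends(self):
        state = make_state(4, {}, [[0.0], [0.3], [0.6], [1.0]])
        nb = build_neighborhood(state, 2, epsilon=1.0)
        assert list(nb.members) == [0, 1, 2, 3]


class TestOpinionRevision:
    def test_mean_over_confidence_set(self):
        # friend at 0.4 within eps=0.2, friend at 0.9 outside -> mean {0.5, 0.4}
        state = make_state(3, {}, [[0.5], [0.4], [0.9]])
        revise_opinion(state, 0, Params(n_agents=3, epsilon=0.2))
        assert state.opinions.values[0, 0] == pytest.approx(0.45)
        assert state.opinions.values[1, 0] == 0.4  # others untouched

    def test_isolated_agent_unchanged(self):
        state = make_state(3, {(0, 1): -1, (0, 2): -1}, [[0.5], [0.5], [0.5]])
        revise_opinion(state, 0, Params(n_agents=3, epsilon=1.0))
        assert state.opinions.values[0, 0] == 0.5

    def test_consensus_is_fixed_point(self):
        state = make_state(4, {}, [[0.3]] * 4)
        for i in range(4):
            revise_opinion(state, i, Params(n_agents=4, epsilon=1.0))
        assert np.all(state.opinions.values == 0.3)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        x=hnp.arrays(np.float64, (5, 2), elements=st.floats(0, 1)),
        eps=st.floats(0, 1),
        pair_signs=st.lists(st.sampled_from([-1, 1]), min_size=10, max_size=10),
    )
    def test_revision_is_convex_combination(self, x, eps, pair_signs):
        # the revised opinion lies, per issue, inside the hull of the
        # confidence set's opinions — hence opinions can never leave [0,1]
        pairs = [(i, j) for i in range(5) for j in range(i + 1, 5)]
        state = make_state(5, dict(zip(pairs, pair_signs)), x)
        nb = build_neighborhood(state, 0, eps)
        lo = state.opinions.values[nb.members].min(axis=0)
        hi = state.opinions.values[nb.members].max(axis=0)
        revise_opinion(state, 0, Params(n_agents=5, n_issues=2, epsilon=eps))
        new = state.opinions.values[0]
        assert np.all(new >= lo - 1e-12) and np.all(new <= hi + 1e-12)

    def test_update_is_issue_by_issue(self):
        state = make_state(
            3, {(0, 2): -1, (1, 2): -1}, [[0.2, 0.8], [0.4, 0.6], [0.9, 0.1]]
        )
        revise_opinion(state, 0, Params(n_agents=3, n_issues=2, epsilon=1.0))
        assert state.opinions.values[0] == pytest.approx([0.3, 0.7])


class TestPreferentialFlip:
    def test_minus_minus_minus_befriends_closest(self):
        state = make_state(
            3, {(0, 1): -1, (0, 2): -1, (1, 2): -1}, [[0.0], [0.1], [0.6]]
        )
        # pair distances: (0,1)=0.1, (0,2)=0.6, (1,2)=0.5 -> befriend (0,1)
        ev = revise_triad(state, Triad(0, 1, 2), Params(n_agents=3, p=0.5), ScriptedRNG())
        assert ev.pair == (0, 1) and ev.new_sign == 1
        assert ev.branch == "smallest-delta"
        assert state.unbalanced_count == 0

    def test_minus_plus_plus_breaks_farthest_on_failure(self):
        # positive pairs (0,2) delta 0.8 and (1,2) delta 0.7; Bernoulli fails
        state = make_state(3, {(0, 1): -1}, [[0.0], [0.1], [0.8]])
        ev = revise_triad(
            state, Triad(0, 1, 2), Params(n_agents=3, p=0.3), ScriptedRNG(randoms=[0.9])
        )
        assert ev.pair == (0, 2) and ev.new_sign == -1
        assert ev.branch == "largest-delta"

    def test_minus_plus_plus_befriends_on_success(self):
        state = make_state(3, {(0, 1): -1}, [[0.0], [0.1], [0.8]])
        ev = revise_triad(
            state, Triad(0, 1, 2), Params(n_agents=3, p=0.3), ScriptedRNG(randoms=[0.1])
        )
        assert ev.pair == (0, 1) and ev.new_sign == 1
        assert ev.branch == "negative-to-positive"

    def test_balanced_triads_untouched(self):
        state = make_state(3, {(0, 1): -1, (0, 2): -1}, [[0.0], [0.5], [1.0]])
        assert revise_triad(state, Triad(0, 1, 2), Params(n_agents=3), ScriptedRNG()) is None

    def test_revised_triad_always_balanced_afterwards(self, rng):
        from bcpf.core import triad_type

        params = Params(n_agents=8, p=0.4)
        for _ in range(100):
            state = init_random_state(params, rng)
            tri = Triad.make(*rng.choice(8, 3, replace=False))
            revise_triad(state, tri, params, rng)
            assert triad_type(state, tri) in ("+++", "+--")


class TestRandomFlip:
    def test_all_negative_uniform_over_pairs(self, rng):
        counts = {pair: 0 for pair in Triad(0, 1, 2).pairs}
        n_trials = 10_000
        for _ in range(n_trials):
            state = make_state(
                3, {(0, 1): -1, (0, 2): -1, (1, 2): -1}, [[0.0], [0.1], [0.6]]
            )
            ev = revise_triad_ltd(state, Triad(0, 1, 2), Params(n_agents=3, p=0.5), rng)
            counts[ev.pair] += 1
        sigma = np.sqrt(n_trials * (1 / 3) * (2 / 3))
        for c in counts.values():
            assert abs(c - n_trials / 3) < 3 * sigma

    def test_break_branch_uniform_over_positive_pairs(self, rng):
        counts = {(0, 2): 0, (1, 2): 0}
        n_trials = 10_000
        hits = 0
        for _ in range(n_trials):
            state = make_state(3, {(0, 1): -1}, [[0.0], [0.1], [0.8]])
            ev = revise_triad_ltd(state, Triad(0, 1, 2), Params(n_agents=3, p=0.01), rng)
            if ev.branch == "random":
                counts[ev.pair] += 1
                hits += 1
        sigma = np.sqrt(hits * 0.25)
        assert abs(counts[0, 2] - hits / 2) < 3 * sigma

    def test_balanced_untouched(self, rng):
        state = make_state(3, {}, [[0.0], [0.5], [1.0]])
        assert revise_triad_ltd(state, Triad(0, 1, 2), Params(n_agents=3), rng) is None


class TestConstrainedFlip:
    def test_single_triad_always_applied(self):
        state = make_state(
            3, {(0, 1): -1, (0, 2): -1, (1, 2): -1}, [[0.0], [0.1], [0.6]]
        )
        ev = revise_triad_ctd(
            state, Triad(0, 1, 2), Params(n_agents=3, flip_rule="constrained"),
            ScriptedRNG(integers=[0]),
        )
        assert ev.applied and state.unbalanced_count == 0

    def test_count_increasing_candidate_rejected(self):
        # bipolar {0,1} vs {2,3,4} with the (0,1) link broken: flipping
        # (0,2) to + would raise the global count from 3 to 4 -> rejected
        net = SignedNetwork.two_cliques(5, [0, 1])
        net.flip(0, 1)
        state = SystemState.create(net, OpinionMatrix(np.zeros((5, 1))))
        before = state.unbalanced_count
        signs_before = state.network.signs.copy()
        ev = revise_triad_ctd(
            state, Triad(0, 1, 2), Params(n_agents=5, flip_rule="constrained"),
            ScriptedRNG(integers=[1]),  # candidate pair (0, 2)
        )
        assert ev.branch == "rejected-by-constraint"
        assert not ev.applied
        assert state.unbalanced_count == before
        assert np.array_equal(state.network.signs, signs_before)

    def test_count_decreasing_candidate_applied(self):
        net = SignedNetwork.two_cliques(5, [0, 1])
        net.flip(0, 1)
        state = SystemState.create(net, OpinionMatrix(np.zeros((5, 1))))
        ev = revise_triad_ctd(
            state, Triad(0, 1, 2), Params(n_agents=5, flip_rule="constrained"),
            ScriptedRNG(integers=[0]),  # candidate pair (0, 1): repairs the clique
        )
        assert ev.applied and state.unbalanced_count == 0

    def test_jammed_three_clique_state_terminates(self):
        # three mutually hostile triangles: every candidate flip raises the
        # unbalanced count, so constrained dynamics can never move
        net = SignedNetwork.two_cliques(9, [0, 1, 2])
        s = net.signs.copy()
        for grp in ([0, 1, 2], [3, 4, 5], [6, 7, 8]):
            for a in grp:
                for b in grp:
                    if a != b:
                        s[a, b] = 1
        s[np.ix_([3, 4, 5], [6, 7, 8])] = -1
        s[np.ix_([6, 7, 8], [3, 4, 5])] = -1
        state = SystemState.create(SignedNetwork(s), OpinionMatrix(np.zeros((9, 1))))
        assert state.unbalanced_count == 27
        res = run(
            Params(n_agents=9, flip_rule="constrained", epsilon=0.0, seed=1,
                   max_rounds=500),
            initial_state=state,
            record_series=False,
        )
        assert res.termination == "jammed"
        assert res.final_state.unbalanced_count == 27


class TestSchedule:
    def test_opinion_updates_every_period(self, rng):
        # N=6 -> M=3: over one round (N*M=18 steps) exactly 6 revisions occur
        params = Params(n_agents=6, epsilon=1.0, p=0.5)
        assert params.update_period == 3
        state = init_random_state(params, rng)
        changes = 0
        for _ in range(params.steps_per_round):
            before = state.opinions.values.copy()
            step(state, params, rng)
            if not np.array_equal(before, state.opinions.values):
                changes += 1
                assert state.t % 3 == 0  # revisions only on the cadence
        assert 1 <= changes <= 6
        assert state.t == 18

    def test_time_advances_one_per_step(self, rng):
        params = Params(n_agents=5)
        state = init_random_state(params, rng)
        for k in range(10):
            step(state, params, rng)
        assert state.t == 10


class TestRun:
    def test_three_agent_hand_simulation(self):
        # a single (-++) triad resolves at its first revision; the network is
        # frozen from then on
        state = make_state(3, {(0, 1): -1}, [[0.1], [0.2], [0.9]])
        res = run(
            Params(n_agents=3, p=0.01, epsilon=0.0, seed=0, max_rounds=50),
            initial_state=state,
            engine="reference",
        )
        assert res.absorbed
        assert res.t_balance >= 1
        assert is_balanced(res.final_state.network)
        # exactly one flip resolved the triad; in the (overwhelmingly likely
        # at p=0.01) break branch it must be the largest-delta pair (0,2)
        assert sum(res.flip_counts.values()) == 1
        if res.flip_counts["largest-delta"] == 1:
            assert res.final_state.network.signs[0, 2] == -1

    def test_zero_confidence_freezes_opinions(self):
        for engine, n, cap in (("fast", 12, 400), ("reference", 8, 120)):
            params = Params(n_agents=n, p=0.1, epsilon=0.0, seed=3, max_rounds=cap)
            state = init_random_state(params)
            x0 = state.opinions.values.copy()
            res = run(params, initial_state=state, engine=engine, record_series=False)
            assert np.array_equal(res.final_state.opinions.values, x0)

    def test_high_p_reaches_all_friends(self):
        for seed in range(20):
            res = run(
                Params(n_agents=20, p=0.9, epsilon=0.2, seed=seed, max_rounds=500),
                record_series=False,
            )
            assert res.absorbed
            assert res.clique_sizes[1] == 0

    def test_bit_identical_reproducibility(self):
        for engine in ("fast", "reference"):
            n = 14 if engine == "fast" else 8
            params = Params(n_agents=n, p=0.2, epsilon=0.3, seed=99, max_rounds=300)
            a = run(params, engine=engine)
            b = run(params, engine=engine)
            assert a.t_balance == b.t_balance and a.t_end == b.t_end
            assert np.array_equal(
                a.final_state.opinions.values, b.final_state.opinions.values
            )
            assert np.array_equal(a.final_state.network.signs, b.final_state.network.signs)
            assert a.flip_counts == b.flip_counts
            assert a.series.equals(b.series)

    def test_balance_is_absorbing(self, rng):
        # once unbalanced_count hits zero no flip can ever fire again
        res = run(
            Params(n_agents=10, p=0.2, epsilon=0.5, seed=5, max_rounds=300),
            engine="reference",
        )
        assert res.absorbed
        state = res.final_state
        signs = state.network.signs.copy()
        params = Params(n_agents=10, p=0.2, epsilon=0.5, seed=5, max_rounds=300)
        for _ in range(300):
            ev = step(state, params, rng)
            assert ev is None
        assert np.array_equal(state.network.signs, signs)

    def test_opinions_confined_to_unit_box(self):
        for seed in range(5):
            res = run(
                Params(n_agents=15, n_issues=2, p=0.3, epsilon=0.4, seed=seed,
                       max_rounds=300),
                record_series=False,
            )
            x = res.final_state.opinions.values
            assert x.min() >= 0.0 and x.max() <= 1.0

    def test_series_schema_and_flip_log_consistency(self):
        # not every seed absorbs (metastable multi-clique states); take the
        # first that does
        for seed in range(20):
            res = run(Params(n_agents=10, p=0.2, epsilon=0.3, seed=seed, max_rounds=300))
            if res.absorbed:
                break
        assert res.absorbed
        assert list(res.series.columns) == ["round", "t", "F_unbal", "D_plus", "D_minus", "N_op"]
        assert res.series["F_unbal"].iloc[-1] == 0.0
        applied = sum(
            v for k, v in res.flip_counts.items() if k != "rejected-by-constraint"
        )
        assert applied >= 1
        rec = res.to_record()
        assert rec["seed"] == seed and rec["termination"] == "absorbed"

    def test_cached_count_matches_brute_force_at_end(self):
        for seed in range(5):
            res = run(
                Params(n_agents=11, p=0.2, epsilon=0.2, seed=seed, max_rounds=100),
                record_series=False,
            )
            assert res.final_state.unbalanced_count == brute_force_unbalanced(
                res.final_state.network
            )

    def test_ltd_absorbing_classes_small_n(self):
        # random-flip dynamics: p < 1/2 ends bipolar, p > 1/2 all-friends
        for seed in range(8):
            lo = run(
                Params(n_agents=12, p=0.1, epsilon=0.0, flip_rule="random",
                       seed=seed, max_rounds=20_000),
                record_series=False,
            )
            if lo.absorbed:
                assert lo.clique_sizes[1] > 0
            hi = run(
                Params(n_agents=12, p=0.9, epsilon=0.0, flip_rule="random",
                       seed=seed, max_rounds=20_000),
                record_series=False,
            )
            assert hi.absorbed and hi.clique_sizes[1] == 0

    def test_stochastic_schedule_runs_and_reproduces(self):
        params = Params(n_agents=12, p=0.2, epsilon=0.3, seed=21, max_rounds=500,
                        stochastic_schedule=True)
        a = run(params, record_series=False)
        b = run(params, record_series=False)
        assert a.absorbed
        assert np.array_equal(a.final_state.opinions.values, b.final_state.opinions.values)

    def test_fixedpoint_residual_zero_at_absorption(self):
        res = run(Params(n_agents=12, p=0.2, epsilon=0.4, seed=2, max_rounds=300),
                  record_series=False)
        assert res.absorbed
        assert fixedpoint_residual(res.final_state, res.params) < 1e-9


class TestBCBaseline:
    def test_full_confidence_reaches_consensus(self):
        res = run_bc_baseline(Params(n_agents=40, epsilon=1.0, seed=2, max_rounds=5000),
                              record_series=False)
        assert res.absorbed and res.n_op == 1

    def test_zero_confidence_preserves_distinct_opinions(self):
        res = run_bc_baseline(Params(n_agents=30, epsilon=0.0, seed=4, max_rounds=100),
                              record_series=False)
        assert res.absorbed and res.n_op == 30
        assert res.t_balance == 0  # all-friends from the start

    def test_small_confidence_clusters_gap_exceeds_epsilon(self):
        res = run_bc_baseline(Params(n_agents=40, epsilon=0.05, seed=6, max_rounds=5000),
                              record_series=False)
        assert res.absorbed and res.n_op > 1
        centers = np.sort([c[0] for c in res.clustering.centroids])
        assert np.all(np.diff(centers) > 0.05)

    def test_network_never_revised(self):
        res = run_bc_baseline(Params(n_agents=15, epsilon=0.3, seed=1, max_rounds=2000),
                              record_series=False)
        assert res.final_state.network.n_negative == 0
        assert sum(res.flip_counts.values()) == 0
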