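import numpy as np
import pandas as pd
import pytest

from nhejevo.mk import marginal_node_posteriors
from nhejevo.simmap import (StochasticMap, call_node_states, find_primary_gains,
                            stochastic_map, summarize_maps, _sample_path)
from nhejevo.trees import Phylogeny

from _oracles import expected_jumps_conditioned
from conftest import random_tree


def er2(q):
    return np.array([[-q, q], [q, -q]])


class TestStochasticMap:
    def test_zero_rate_limit_single_segments(self):
        tree = random_tree(8, seed=1)
        tips = {lb: 1 for lb in tree.tip_labels}
        Q = er2(1e-12)
        m = stochastic_map(tree, tips, Q, root_prior=np.array([0.0, 1.0]), seed=0)
        assert all(len(segs) == 1 for segs in m.segments.values())
        assert m.transition_counts().sum() == 0

    def test_segment_invariants(self):
        from nhejevo.simulate import default_nhej_generator, simulate_mk_history

        tree = random_tree(15, seed=2, height=2.0)
        Q = default_nhej_generator()
        tips, _ = simulate_mk_history(tree, Q, root_state=0, seed=3)
        m = stochastic_map(tree, tips, Q, seed=4)
        for node, segs in m.segments.items():
            assert sum(d for _, d in segs) == pytest.approx(
                max(tree.blen[node], 1e-12), abs=1e-9)
            # first state equals parent node state, last equals child state
            assert segs[0][0] == m.node_states[tree.parent[node]]
            assert segs[-1][0] == m.node_states[node]
            for (s0, _), (s1, _) in zip(segs, segs[1:]):
                assert s0 != s1
        # sampled tip states equal observed tip states
        for t in tree.tip_indices():
            assert m.node_states[t] == tips[tree.labels[t]]

    def test_path_sampler_expected_jumps(self):
        """Endpoint-conditioned jump counts match the analytic expectation."""
        q01, q10 = 0.7, 1.3
        Q = np.array([[-q01, q01], [q10, -q10]])
        t = 1.4
        omega = max(-np.diag(Q))
        R = np.eye(2) + Q / omega
        rng = np.random.default_rng(5)
        n = 20000
        for (a, b) in [(0, 0), (0, 1)]:
            counts01 = []
            Rpows = [np.eye(2)]
            for _ in range(n):
                segs = _sample_path(Q, R, Rpows, omega, t, a, b, rng)
                counts01.append(sum(1 for (s0, _), (s1, _) in zip(segs, segs[1:])
                                    if s0 == 0 and s1 == 1))
            expected = expected_jumps_conditioned(Q, t, a, b, 0, 1)
            se = np.std(counts01, ddof=1) / np.sqrt(n)
            assert abs(np.mean(counts01) - expected) < 3 * se + 1e-3

    def test_node_frequencies_match_marginals_small_tree(self):
        from nhejevo.simulate import default_nhej_generator, simulate_mk_history

        tree = random_tree(8, seed=6, height=2.0)
        Q = default_nhej_generator()
        tips, _ = simulate_mk_history(tree, Q, root_state=0, seed=7)
        marg = marginal_node_posteriors(tree, tips, Q, "fitzjohn").values
        rng = np.random.default_rng(8)
        n = 3000
        maps = [stochastic_map(tree, tips, Q, "fitzjohn", rng=rng) for _ in range(n)]
        freq = summarize_maps(maps).node_posteriors.values
        internal = [i for i in range(tree.n_nodes) if not tree.is_tip(i)]
        se = np.sqrt(marg * (1 - marg) / n)
        assert np.all(np.abs(freq - marg)[internal] <= 3 * se[internal] + 2.0 / n)


class TestSummaries:
    @staticmethod
    def hand_built_map():
        tree = Phylogeny.from_newick("(A:2,B:2);")
        a, b = tree.tip_indices()
        node_states = np.zeros(tree.n_nodes, dtype=np.int64)
        node_states[b] = 1
        segments = {a: [(0, 2.0)], b: [(0, 0.5), (1, 1.0), (0, 0.25), (1, 0.25)]}
        return StochasticMap(tree=tree, node_states=node_states, segments=segments, k=2)

    def test_exact_bookkeeping(self):
        summ = summarize_maps([self.hand_built_map()])
        assert summ.mean_transition_counts[0, 1] == 2
        assert summ.mean_transition_counts[1, 0] == 1
        assert summ.time_in_state[0] == pytest.approx(2.75)
        assert summ.time_in_state[1] == pytest.approx(1.25)

    def test_time_conservation(self):
        from nhejevo.simulate import default_nhej_generator, simulate_mk_history

        tree = random_tree(10, seed=9, height=1.5)
        Q = default_nhej_generator()
        tips, _ = simulate_mk_history(tree, Q, root_state=0, seed=1)
        maps = [stochastic_map(tree, tips, Q, seed=s) for s in range(5)]
        summ = summarize_maps(maps)
        assert summ.time_in_state.sum() == pytest.approx(tree.total_length(),
                                                         rel=1e-6)

    def test_four_states_have_twelve_transition_types(self):
        from nhejevo.simulate import default_nhej_generator, simulate_mk_history

        tree = random_tree(6, seed=3)
        Q = default_nhej_generator()
        tips, _ = simulate_mk_history(tree, Q, root_state=0, seed=2)
        summ = summarize_maps([stochastic_map(tree, tips, Q, seed=0)])
        off = ~np.eye(4, dtype=bool)
        assert summ.transition_rel_freq.shape == (4, 4)
        assert off.sum() == 12

    def test_maps_on_different_trees_rejected(self):
        m1 = self.hand_built_map()
        tree2 = Phylogeny.from_newick("(A:1,C:1);")
        m2 = StochasticMap(tree=tree2, node_states=np.zeros(3, dtype=np.int64),
                           segments={1: [(0, 1.0)], 2: [(0, 1.0)]}, k=2)
        with pytest.raises(ValueError):
            summarize_maps([m1, m2])


class TestNodeCalls:
    @staticmethod
    def summary_with(posteriors):
        tree = random_tree(len(posteriors) + 1, seed=0)
        df = pd.DataFrame(np.tile([1.0, 0, 0, 0], (tree.n_nodes, 1)))
        for i, pp in enumerate(posteriors):
            df.iloc[i] = pp
        from nhejevo.simmap import MapSummary

        return MapSummary(tree=tree, k=4, n_maps=1,
                          mean_transition_counts=np.zeros((4, 4)),
                          transition_rel_freq=np.zeros((4, 4)),
                          time_in_state=np.zeros(4), node_posteriors=df)

    def test_threshold_is_exclusive(self):
        summ = self.summary_with([[0.8, 0.1, 0.05, 0.05],
                                  [0.5, 0.5, 0.0, 0.0],
                                  [0.7, 0.3, 0.0, 0.0]])
        calls = call_node_states(summ, threshold=0.7)
        assert calls.iloc[0] == 0
        assert calls.iloc[1] == -1
        assert calls.iloc[2] == -1


class TestPrimaryGains:
    """Hand-built 8-tip tree; states: 0 NHEJ-, 1 Ku_only, 2 LigD_only, 3 NHEJ+."""

    @staticmethod
    def build_tree():
        return Phylogeny.from_newick(
            "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);")

    def setup_calls(self, tree, gain_node_states):
        calls = pd.Series(-1, index=range(tree.n_nodes))
        post = np.zeros((tree.n_nodes, 4))
        post[:, 0] = 1.0
        for i in range(tree.n_nodes):
            if not tree.is_tip(i):
                calls[i] = 0
        for node, (state, pp) in gain_node_states.items():
            post[node] = 0.0
            post[node, state] = pp
            post[node, 0] = 1 - pp
            calls[node] = state if pp > 0.7 else -1
        return calls, pd.DataFrame(post)

    def find_mrca(self, tree, labels):
        below = tree.tips_below()
        want = {t for t in tree.tip_indices() if tree.labels[t] in labels}
        candidates = [i for i in range(tree.n_nodes) if below[i] >= want]
        return min(candidates, key=lambda i: len(below[i]))

    def test_gain_with_enough_descendants_reported(self):
        tree = self.build_tree()
        node = self.find_mrca(tree, {"A", "B", "C", "D"})
        calls, post = self.setup_calls(tree, {node: (3, 0.85)})
        gains = find_primary_gains(tree, calls, post, absent_state=0,
                                   gain_states=(1, 2), full_state=3)
        assert [g.node_id for g in gains] == [node]
        assert gains[0].n_descendant_tips == 4
        assert gains[0].pp_at_node == pytest.approx(0.85)

    def test_two_descendants_not_reported(self):
        tree = self.build_tree()
        node = self.find_mrca(tree, {"A", "B"})
        calls, post = self.setup_calls(tree, {node: (3, 0.9)})
        gains = find_primary_gains(tree, calls, post, absent_state=0,
                                   gain_states=(1, 2), full_state=3)
        assert gains == []

    def test_partial_gain_requires_completion_below(self):
        tree = self.build_tree()
        node = self.find_mrca(tree, {"A", "B", "C", "D"})
        calls, post = self.setup_calls(tree, {node: (2, 0.9)})
        gains = find_primary_gains(tree, calls, post, absent_state=0,
                                   gain_states=(1, 2), full_state=3)
        assert gains == []
        # a called NHEJ+ node below the LigD-only gain completes it
        child = self.find_mrca(tree, {"A", "B"})
        calls2, post2 = self.setup_calls(tree, {node: (2, 0.9), child: (3, 0.8)})
        gains2 = find_primary_gains(tree, calls2, post2, absent_state=0,
                                    gain_states=(1, 2), full_state=3)
        assert node in [g.node_id for g in gains2]

    def test_unrooted_tree_rejected(self):
        tree = self.build_tree()
        tree.rooted = False
        calls, post = self.setup_calls(tree, {})
        with pytest.raises(ValueError):
            find_primary_gains(tree, calls, post, absent_state=0,
                               gain_states=(1, 2), full_state=3)
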