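import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nhejevo.classify import FIVE_STATES, assign_states
from nhejevo.simulate import (SimulationConfig, default_nhej_generator,
                              generate_genome_tables, simulate_all,
                              simulate_brownian, simulate_mk_history,
                              simulate_tree)
from nhejevo.trees import Phylogeny


class TestYuleTree:
    def test_two_tips_is_cherry(self):
        tree = simulate_tree(2, seed=0)
        assert tree.n_tips == 2
        assert len(tree.children(tree.root)) == 2

    @pytest.mark.parametrize("n", [5, 20, 77])
    def test_internal_node_count(self, n):
        tree = simulate_tree(n, seed=1)
        internal = sum(1 for i in range(tree.n_nodes) if not tree.is_tip(i))
        assert internal == n - 1

    def test_ultrametric(self):
        tree = simulate_tree(40, seed=2)
        depths = tree.depths()
        tip_depths = [depths[t] for t in tree.tip_indices()]
        assert np.ptp(tip_depths) < 1e-9

    def test_seed_reproducibility(self):
        assert (simulate_tree(25, seed=7).to_newick()
                == simulate_tree(25, seed=7).to_newick())

    def test_mean_depth_matches_yule_expectation(self):
        """E[height] for a Yule tree stopped at n tips, MC-checked."""
        lam, n, reps = 1.0, 8, 400
        heights = [simulate_tree(n, birth_rate=lam, seed=s).height()
                   for s in range(reps)]
        # waiting times are Exp(k*lam) for k = 2..n, plus the pendant Exp(n*lam)
        expected = sum(1.0 / (k * lam) for k in range(2, n + 1)) + 1.0 / (n * lam)
        se = np.std(heights, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(heights) - expected) < 3 * se


class TestMkHistory:
    def test_zero_generator_keeps_root_state(self):
        tree = simulate_tree(10, seed=3)
        tips, hist = simulate_mk_history(tree, np.zeros((3, 3)), root_state=2, seed=0)
        assert (tips == 2).all()
        assert hist.transition_counts().sum() == 0

    def test_single_branch_flip_probability(self):
        q, t, reps = 0.6, 1.2, 20000
        tree = Phylogeny([-1, 0, 0], [0.0, t, 1e-9], [None, "A", "B"])
        Q = np.array([[-q, q], [q, -q]])
        rng = np.random.default_rng(0)
        flips = 0
        for _ in range(reps):
            tips, _ = simulate_mk_history(tree, Q, root_state=0, rng=rng)
            flips += tips["A"] != 0
        expect = 0.5 - 0.5 * np.exp(-2 * q * t)
        se = np.sqrt(expect * (1 - expect) / reps)
        assert abs(flips / reps - expect) < 3 * se

    def test_long_branch_time_in_state_reaches_stationarity(self):
        Q = np.array([[-0.2, 0.2], [0.8, -0.8]])
        pi = np.array([0.8, 0.2])  # stationary for these rates
        tree = Phylogeny([-1, 0, 0], [0.0, 400.0, 1e-9], [None, "A", "B"])
        _, hist = simulate_mk_history(tree, Q, root_state=0, seed=5)
        occupancy = hist.time_in_state() / hist.time_in_state().sum()
        f_obs = occupancy * 400.0
        chi2 = (((f_obs - pi * 400.0) ** 2) / (pi * 400.0)).sum()
        assert stats.chi2.sf(chi2, df=1) > 0.01

    def test_history_is_consistent_with_tips(self):
        tree = simulate_tree(30, seed=6)
        Q = default_nhej_generator()
        tips, hist = simulate_mk_history(tree, Q, root_state=0, seed=7)
        for t in tree.tip_indices():
            assert hist.node_states[t] == tips[tree.labels[t]]
            segs = hist.segments[t]
            assert segs[-1][0] == tips[tree.labels[t]]
            assert sum(d for _, d in segs) == pytest.approx(tree.blen[t])


class TestBrownian:
    def test_zero_rate_collapses_to_root(self):
        tree = simulate_tree(12, seed=8)
        x = simulate_brownian(tree, 0.0, root=3.14, seed=0)
        assert np.allclose(x, 3.14)

    def test_sister_covariance_matches_shared_depth(self):
        tree = Phylogeny.from_newick("((A:1,B:1):2,C:3);")
        reps = 4000
        rng = np.random.default_rng(1)
        draws = np.array([simulate_brownian(tree, 1.0, rng=rng)[["A", "B"]]
                          for _ in range(reps)])
        cov = np.cov(draws.T)[0, 1]
        se = np.sqrt(2.0 / reps) * 3.0  # rough SE of a covariance of BM tips
        assert abs(cov - 2.0) < 3 * se

    def test_lambda_zero_gives_iid_tips_with_depth_variance(self):
        tree = simulate_tree(6, seed=9)
        tree = tree.scale(1.0 / tree.height())
        reps = 3000
        rng = np.random.default_rng(2)
        draws = np.array([simulate_brownian(tree, 1.0, lam=0.0, rng=rng).values
                          for _ in range(reps)])
        C = np.cov(draws.T)
        assert np.allclose(np.diag(C), 1.0, atol=0.12)
        off = C[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.1


class TestGenomeTables:
    def test_round_trip_recovers_generating_states(self):
        rng = np.random.default_rng(3)
        states = pd.Series(rng.choice(FIVE_STATES, size=300),
                           index=[f"g{i:03d}" for i in range(300)])
        hits, genes, traits, _ = generate_genome_tables(states,
                                                        SimulationConfig(), seed=4)
        kept = hits[hits["evalue"] <= 1e-4]
        called = assign_states(kept, genome_ids=states.index)
        assert (called.loc[states.index] == states).all()

    def test_forced_operonic_placement(self):
        cfg = SimulationConfig(p_operonic=1.0, p_proximal_opposite=0.0)
        states = pd.Series("conventional_plus", index=[f"g{i}" for i in range(40)])
        _, genes, traits, truth = generate_genome_tables(states, cfg, seed=5)
        from nhejevo.classify import neighborhood_table

        sizes = {g: {"chr": int(traits.loc[g, "cds_count"])} for g in states.index}
        nb = neighborhood_table(genes, states, window=cfg.neighborhood_window,
                                replicon_sizes_by_genome=sizes)
        assert (nb["category"] == "operonic").all()
        assert all(v == "operonic" for v in truth.values())

    def test_configured_size_shift_recovered(self):
        cfg = SimulationConfig()
        rng = np.random.default_rng(6)
        states = pd.Series(rng.choice(["NHEJ_minus", "conventional_plus"], size=600),
                           index=[f"g{i:03d}" for i in range(600)])
        _, _, traits, _ = generate_genome_tables(states, cfg, seed=7)
        logs = np.log10(traits["genome_size_bp"].astype(float))
        diff = (logs[states == "conventional_plus"].mean()
                - logs[states == "NHEJ_minus"].mean())
        expected = (cfg.log10_size_mean["conventional_plus"]
                    - cfg.log10_size_mean["NHEJ_minus"])
        n1 = (states == "conventional_plus").sum()
        n2 = (states == "NHEJ_minus").sum()
        se = cfg.log10_size_sd * np.sqrt(1 / n1 + 1 / n2)
        assert abs(diff - expected) < 3 * se

    def test_decoys_are_above_threshold(self):
        cfg = SimulationConfig(domain_noise=2.0)
        states = pd.Series("NHEJ_minus", index=[f"g{i}" for i in range(50)])
        hits, _, _, _ = generate_genome_tables(states, cfg, seed=8)
        decoys = hits[hits["evalue"] > cfg.evalue_threshold]
        assert len(decoys) > 0


class TestSimulateAll:
    def test_outputs_byte_identical_for_same_seed(self, tmp_path):
        cfg = SimulationConfig(n_tips=40)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_all(cfg, d1, seed=11)
        simulate_all(cfg, d2, seed=11)
        for name in ["tree.nwk", "states.tsv", "domain_hits.tsv", "genes.tsv",
                     "traits.tsv", "truth.json"]:
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name

    def test_bundle_passes_consumer_preconditions(self, tmp_path):
        from nhejevo.classify import parse_domain_table
        from nhejevo.trees import read_newick

        cfg = SimulationConfig(n_tips=40)
        simulate_all(cfg, tmp_path, seed=12)
        tree = read_newick(str(tmp_path / "tree.nwk"))
        states = pd.read_csv(tmp_path / "states.tsv", sep="\t",
                             index_col="genome_id")["state"]
        assert sorted(tree.tip_labels) == sorted(states.index)
        hits = parse_domain_table(tmp_path / "domain_hits.tsv")
        called = assign_states(hits, genome_ids=states.index)
        assert (called.loc[states.index] == states).all()
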