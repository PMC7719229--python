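import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nhejevo.mk import (aic_weights, build_generator, fit_mk, fit_mk_models,
                        mk_loglik, rate_index_matrix, n_free_rates,
                        sample_q_posterior)
from nhejevo.trees import Phylogeny

from _oracles import loglik_by_enumeration
from conftest import random_tree


def er2(q):
    return np.array([[-q, q], [q, -q]])


def random_generator(k, seed, lo=0.2, hi=1.5):
    rng = np.random.default_rng(seed)
    idx = rate_index_matrix(k, "ARD")
    return build_generator(idx, rng.uniform(lo, hi, n_free_rates(idx)))


class TestLoglik:
    @pytest.mark.parametrize("q", [0.1, 0.7, 2.0])
    @pytest.mark.parametrize("t", [0.2, 1.0, 3.0])
    def test_two_state_cherry_closed_form(self, q, t):
        tree = Phylogeny.from_newick(f"(A:{t},B:{t});")
        p00 = 0.5 + 0.5 * np.exp(-2 * q * t)
        expected = np.log(0.5 * (p00 ** 2 + (1 - p00) ** 2))
        ll = mk_loglik(tree, {"A": 0, "B": 0}, er2(q), root_prior=np.array([0.5, 0.5]))
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_rate_to_zero_limit_gives_log_prior(self):
        tree = Phylogeny.from_newick("(A:1,(B:1,C:1):1);")
        prior = np.array([0.3, 0.7])
        ll = mk_loglik(tree, {"A": 1, "B": 1, "C": 1}, er2(1e-12), root_prior=prior)
        assert ll == pytest.approx(np.log(0.7), abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_on_five_tips(self, seed):
        tree = random_tree(5, seed=seed)
        Q = random_generator(4, seed)
        rng = np.random.default_rng(seed)
        tips = {lb: int(rng.integers(4)) for lb in tree.tip_labels}
        prior = np.full(4, 0.25)
        assert mk_loglik(tree, tips, Q, prior) == pytest.approx(
            loglik_by_enumeration(tree, tips, Q, prior), abs=1e-10)

    def test_invariant_to_tip_order_and_reread(self):
        tree = random_tree(12, seed=9)
        Q = random_generator(3, 3)
        rng = np.random.default_rng(1)
        tips = pd.Series({lb: int(rng.integers(3)) for lb in tree.tip_labels})
        ll = mk_loglik(tree, tips, Q, "flat")
        shuffled = tips.sample(frac=1.0, random_state=0)
        assert mk_loglik(tree, shuffled, Q, "flat") == pytest.approx(ll, abs=1e-12)
        reread = Phylogeny.from_newick(tree.to_newick())
        assert mk_loglik(reread, tips, Q, "flat") == pytest.approx(ll, abs=1e-9)

    def test_unassigned_tip_raises(self):
        tree = Phylogeny.from_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="B"):
            mk_loglik(tree, {"A": 0}, er2(1.0))

    def test_non_generator_raises(self):
        tree = Phylogeny.from_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            mk_loglik(tree, {"A": 0, "B": 0}, np.array([[0.5, 0.5], [1.0, -1.0]]))


class TestStructures:
    def test_free_parameter_counts(self):
        assert n_free_rates(rate_index_matrix(4, "ER")) == 1
        assert n_free_rates(rate_index_matrix(4, "SYM")) == 6
        assert n_free_rates(rate_index_matrix(4, "ARD")) == 12

    def test_generator_rows_sum_to_zero(self):
        Q = random_generator(4, 0)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12


class TestFit:
    def test_er_rate_recovery(self):
        tree = random_tree(300, seed=11, height=3.0)
        from nhejevo.simulate import simulate_mk_history

        tips, _ = simulate_mk_history(tree, er2(1.0), root_state=0, seed=5)
        fit = fit_mk(tree, tips, "ER", k=2, seed=0)
        assert abs(fit.rates[0] - 1.0) < 0.25
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik)

    def test_nested_models_ordered(self):
        tree = random_tree(80, seed=21, height=3.0)
        from nhejevo.simulate import simulate_mk_history

        Q = random_generator(3, 2, lo=0.3, hi=1.0)
        tips, _ = simulate_mk_history(tree, Q, root_state=0, seed=3)
        fits = fit_mk_models(tree, tips, k=3, seed=0, n_starts=3)
        assert fits["ARD"].loglik >= fits["SYM"].loglik - 1e-6
        assert fits["SYM"].loglik >= fits["ER"].loglik - 1e-6

    def test_constant_tips_drive_rate_to_floor(self):
        tree = random_tree(30, seed=4)
        tips = {lb: 0 for lb in tree.tip_labels}
        fit = fit_mk(tree, tips, "ER", k=2, seed=0, n_starts=2)
        assert fit.rates[0] < 1e-4


class TestAicWeights:
    def test_equal_aics_uniform(self):
        class F:  # minimal stand-in with an aic attribute
            aic = 10.0

        w = aic_weights([F(), F(), F()])
        assert np.allclose(w, 1 / 3)

    def test_delta_two_formula(self):
        w = aic_weights([0.0, 2.0])
        e = np.exp(1.0)
        assert np.allclose(w, [e / (e + 1), 1 / (e + 1)])

    def test_dominance(self):
        w = aic_weights([0.0, 100.0])
        assert w[0] == pytest.approx(1.0, abs=1e-10)

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.floats(min_value=-50, max_value=50), min_size=2, max_size=6),
           st.randoms(use_true_random=False))
    def test_sums_to_one_and_permutation_equivariant(self, aics, rnd):
        w = aic_weights(aics)
        assert w.sum() == pytest.approx(1.0)
        perm = list(range(len(aics)))
        rnd.shuffle(perm)
        w2 = aic_weights([aics[i] for i in perm])
        assert np.allclose(w2, w[perm])


class TestQPosterior:
    def test_same_seed_identical_chains(self):
        tree = random_tree(40, seed=6, height=2.0)
        from nhejevo.simulate import simulate_mk_history

        tips, _ = simulate_mk_history(tree, er2(0.8), root_state=0, seed=1)
        fit = fit_mk(tree, tips, "ER", k=2, seed=0, n_starts=2)
        a = sample_q_posterior(tree, tips, "ER", n_samples=100, seed=7, mle=fit)
        b = sample_q_posterior(tree, tips, "ER", n_samples=100, seed=7, mle=fit)
        assert np.array_equal(a.rates, b.rates)
        assert 0.05 <= a.acceptance_rate <= 0.8

    def test_posterior_mean_tracks_mle(self):
        tree = random_tree(150, seed=8, height=3.0)
        from nhejevo.simulate import simulate_mk_history

        tips, _ = simulate_mk_history(tree, er2(0.8), root_state=0, seed=2)
        fit = fit_mk(tree, tips, "ER", k=2, seed=0, n_starts=2)
        post = sample_q_posterior(tree, tips, "ER", n_samples=400, seed=3, mle=fit)
        assert post.rates.mean() == pytest.approx(fit.rates[0], rel=0.35)
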