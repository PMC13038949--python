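"""Mk1 likelihood, rate fitting, marginal ASR, and stochastic mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecophylo.mk import (Mk1Model, MkModel, fit_mk1, marginal_asr,
                         mk_likelihood, mk_transition_matrix, stochastic_maps)
from ecophylo.simulate import SimConfig, simulate_trait, simulate_tree
from ecophylo.trees import parse_newick

from .conftest import (brute_force_mk_loglik, brute_force_mk_marginal,
                       random_tree, two_taxon_tree)


class TestTransitionMatrix:
    @given(st.integers(2, 5), st.floats(0.01, 5.0), st.floats(0.0, 10.0))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_rows_sum_to_one(self, k, q, t):
        P = mk_transition_matrix(MkModel(k=k, q=q), t)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert (P >= 0).all()

    def test_limits(self):
        m = MkModel(k=3, q=0.7)
        np.testing.assert_allclose(mk_transition_matrix(m, 0.0), np.eye(3),
                                   atol=1e-15)
        np.testing.assert_allclose(mk_transition_matrix(m, 1e6), 1.0 / 3,
                                   atol=1e-12)


class TestLikelihood:
    def test_zero_rate_monomorphic_is_root_prior(self, four_tip_tree):
        ll = mk_likelihood(four_tip_tree, np.zeros(4), MkModel(k=3, q=0.0))
        assert ll == pytest.approx(np.log(1 / 3))

    def test_zero_rate_polymorphic_is_impossible(self, four_tip_tree):
        ll = mk_likelihood(four_tip_tree, np.array([0, 1, 0, 1]),
                           MkModel(k=2, q=0.0))
        assert ll == -np.inf

    def test_unknown_state_names_tip(self, four_tip_tree):
        with pytest.raises(ValueError, match="D"):
            mk_likelihood(four_tip_tree, np.array([0, 1, 0, 5]),
                          MkModel(k=2, q=0.1))

    def test_matches_enumeration_on_four_tips(self, four_tip_tree):
        ll = mk_likelihood(four_tip_tree, np.array([0, 1, 0, 1]),
                           MkModel(k=2, q=0.3))
        bf = brute_force_mk_loglik(four_tip_tree, [0, 1, 0, 1],
                                   MkModel(k=2, q=0.3))
        assert ll == pytest.approx(bf, abs=1e-12)

    @given(st.integers(0, 5_000), st.integers(2, 4), st.floats(0.01, 3.0))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_pruning_equals_enumeration_small_trees(self, seed, k, q):
        rng = np.random.default_rng(seed)
        t = random_tree(rng, int(rng.integers(2, 6)))
        states = rng.integers(0, k, t.n_tips)
        model = MkModel(k=k, q=q)
        assert mk_likelihood(t, states, model) == pytest.approx(
            brute_force_mk_loglik(t, states, model), abs=1e-10)

    def test_invariant_to_child_order(self):
        t1 = parse_newick("((A:1,B:1):0.5,(C:0.7,D:0.7):0.8);")
        t2 = parse_newick("((D:0.7,C:0.7):0.8,(B:1,A:1):0.5);")
        st_map = {"A": 0, "B": 1, "C": 1, "D": 0}
        m = MkModel(k=2, q=0.4)
        ll1 = mk_likelihood(t1, np.array([st_map[x] for x in t1.tip_labels]), m)
        ll2 = mk_likelihood(t2, np.array([st_map[x] for x in t2.tip_labels]), m)
        assert ll1 == pytest.approx(ll2, abs=1e-12)


class TestFit:
    def test_monomorphic_boundary(self, four_tip_tree):
        model, ll, boundary = fit_mk1(four_tip_tree, np.zeros(4), k=2)
        assert model.q == 0.0
        assert boundary

    def test_optimum_beats_grid(self):
        rng = np.random.default_rng(20)
        t = random_tree(rng, 30)
        cfg = SimConfig(seed=1, n_species=30, mk_rate=0.4, mk_states=2)
        states = simulate_trait(t, "discrete", cfg, seed=2)
        if len(set(states)) < 2:
            states[0] = 1 - states[0]
        model, ll, _ = fit_mk1(t, states, k=2)
        grid = np.exp(np.linspace(np.log(1e-6), np.log(50 / t.height), 50))
        for q in grid:
            assert ll >= mk_likelihood(t, states, MkModel(k=2, q=q)) - 1e-8

    def test_rate_recovery(self):
        """Median q-hat within +/-30% of truth at q=0.5 on 200-tip trees."""
        q_true, reps = 0.5, 40
        qs = []
        for s in range(reps):
            cfg = SimConfig(seed=s, n_species=200, mk_rate=q_true, mk_states=2)
            t = simulate_tree(cfg)
            states = simulate_trait(t, "discrete", cfg, seed=40_000 + s)
            if len(set(states)) < 2:
                continue
            model, _, _ = fit_mk1(t, states, k=2)
            qs.append(model.q)
        assert 0.35 <= np.median(qs) <= 0.65


class TestMarginalAsr:
    def test_two_tip_symmetry(self):
        t = two_taxon_tree(2.0)
        res = marginal_asr(t, np.array([0, 1]), MkModel(k=2, q=0.3))
        np.testing.assert_allclose(res.node_probs[t.root], [0.5, 0.5],
                                   atol=1e-12)

    def test_saturation_gives_uniform(self):
        t = parse_newick("((A:10,B:10):10,(C:10,D:10):10);")
        res = marginal_asr(t, np.array([0, 1, 0, 1]), MkModel(k=2, q=5.0))
        for p in res.node_probs.values():
            np.testing.assert_allclose(p, 0.5, atol=1e-3)

    def test_matches_enumeration(self, four_tip_tree):
        states = np.array([0, 1, 1, 0])
        model = MkModel(k=3, q=0.25)
        res = marginal_asr(four_tip_tree, states, model)
        for node, p in res.node_probs.items():
            bf = brute_force_mk_marginal(four_tip_tree, states, model, node)
            np.testing.assert_allclose(p, bf, atol=1e-10)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(21)
        t = random_tree(rng, 15)
        states = rng.integers(0, 3, 15)
        res = marginal_asr(t, states, MkModel(k=3, q=0.5))
        for p in res.node_probs.values():
            assert p.sum() == pytest.approx(1.0, abs=1e-9)


class TestStochasticMaps:
    def test_zero_rate_monomorphic_no_transitions(self, four_tip_tree):
        s = stochastic_maps(four_tip_tree, np.zeros(4, dtype=int),
                            MkModel(k=2, q=0.0), n_maps=20, seed=1)
        assert s.transition_mean.sum() == 0.0
        np.testing.assert_array_equal(s.origin_counts, 0)

    def test_node_frequencies_match_marginal_asr(self, four_tip_tree):
        """Sampled node-state frequencies converge to the marginal
        posterior within Monte Carlo error."""
        states = np.array([0, 1, 0, 1])
        model = MkModel(k=2, q=0.4)
        n_maps = 2000
        s = stochastic_maps(four_tip_tree, states, model, n_maps=n_maps, seed=2)
        asr = marginal_asr(four_tip_tree, states, model)
        for node, p in asr.node_probs.items():
            tol = 3 * np.sqrt(np.maximum(p * (1 - p), 1e-12) / n_maps) + 1e-9
            assert (np.abs(s.node_state_freq[node] - p) <= tol).all()

    def test_two_independent_origins_at_low_rate(self):
        """State 1 at two tips separated by a state-0 backbone: with tiny q
        the modal map has exactly two origins of state 1."""
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        states = np.array([1, 0, 1, 0])  # A and C derived, B and D ancestral
        model = MkModel(k=2, q=0.01)
        s = stochastic_maps(t, states, model, n_maps=500, seed=3, focal_state=1)
        counts = np.bincount(s.origin_counts)
        assert np.argmax(counts) == 2

    def test_reproducible(self, four_tip_tree):
        states = np.array([0, 1, 0, 1])
        model = MkModel(k=2, q=0.4)
        a = stochastic_maps(four_tip_tree, states, model, 50, seed=9)
        b = stochastic_maps(four_tip_tree, states, model, 50, seed=9)
        np.testing.assert_array_equal(a.origin_counts, b.origin_counts)
        np.testing.assert_allclose(a.transition_mean, b.transition_mean)

    def test_mean_transition_count_stable(self):
        """The mean substitution count converges: two long runs agree."""
        t = parse_newick("((A:1,B:1):0.5,(C:0.7,D:0.7):0.8);")
        states = np.array([0, 1, 1, 0])
        model = MkModel(k=2, q=0.6)
        a = stochastic_maps(t, states, model, 3000, seed=10)
        b = stochastic_maps(t, states, model, 3000, seed=11)
        assert a.transition_mean.sum() == pytest.approx(
            b.transition_mean.sum(), rel=0.1)


class TestModelResultsApi:
    def test_fit_and_summary(self):
        rng = np.random.default_rng(22)
        t = random_tree(rng, 20)
        cfg = SimConfig(seed=5, n_species=20, mk_rate=0.3, mk_states=2)
        states = simulate_trait(t, "discrete", cfg, seed=6)
        if len(set(states)) < 2:
            states[0] = 1 - states[0]
        res = Mk1Model(t, states).fit()
        assert res.q > 0
        assert "Mk1" in res.summary()
        asr = res.ancestral_states()
        assert set(asr.node_probs) == set(range(t.n_tips, t.n_nodes))
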