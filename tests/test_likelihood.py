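import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bissekit import (IntegratorConfig, PhyloTree, RateSet, RootMode,
                      bisse_loglik, branch_integrate, node_combine, tip_init)
from bissekit.likelihood import IntegrationError, LikelihoodState
from bissekit.stationary import StationaryUndefinedError, stationary_state0_freq
from conftest import bd_mk_loglik, rk4_branch, rk4_tree_loglik, simulated_tree


class TestTipInit:
    def test_observed_state_certainty(self):
        s0 = tip_init(0)
        assert (s0.E0, s0.E1, s0.D0, s0.D1) == (0.0, 0.0, 1.0, 0.0)
        s1 = tip_init(1)
        assert (s1.D0, s1.D1) == (0.0, 1.0)

    def test_bad_state_rejected(self):
        with pytest.raises(ValueError):
            tip_init(2)


class TestBranchIntegrate:
    def test_pure_extinction_closed_form(self):
        # with lambda0 = q = 0: E0(t) = 1 - exp(-mu0 t)
        rates = RateSet(0.0, 0.1, 0.03, 0.0, 0.0, 0.0)
        out = branch_integrate(tip_init(0), rates, 10.0)
        assert out.E0 == pytest.approx(1.0 - np.exp(-0.3), abs=1e-9)

    def test_pure_birth_decay_closed_form(self):
        # D0(t) = exp(-lambda0 t) when mu = q = 0
        rates = RateSet(0.1, 0.0, 0.0, 0.0, 0.0, 0.0)
        out = branch_integrate(tip_init(0), rates, 1.0)
        assert out.D0 == pytest.approx(np.exp(-0.1), abs=1e-10)

    @pytest.mark.parametrize("t", [1.0, 5.0, 20.0])
    def test_constant_rate_extinction_probability(self, t):
        # state-independent rates: E(t) = mu (e^{rt}-1) / (lam e^{rt} - mu)
        la, mu = 0.1, 0.03
        rates = RateSet(la, la, mu, mu, 0.01, 0.01)
        out = branch_integrate(tip_init(0), rates, t)
        r = la - mu
        expected = mu * (np.exp(r * t) - 1) / (la * np.exp(r * t) - mu)
        assert out.E0 == pytest.approx(expected, abs=1e-6)
        assert out.E1 == pytest.approx(expected, abs=1e-6)

    def test_zero_length_is_identity(self):
        init = LikelihoodState(0.2, 0.3, 0.4, 0.5, -1.0)
        out = branch_integrate(init, RateSet(0.1, 0.2, 0.01, 0.02, 0.03,
                                             0.04), 0.0)
        assert out == init

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.floats(0.005, 0.5), min_size=6, max_size=6),
           st.floats(0.5, 15.0), st.integers(0, 1))
    def test_matches_fine_step_rk4(self, vals, length, state):
        rates = RateSet(*vals)
        out = branch_integrate(tip_init(state), rates, length)
        ref = rk4_branch(tip_init(state).as_array(), rates, length, 20000)
        got = out.as_array() * np.exp(out.log_scale)
        assert np.allclose(got, ref, atol=1e-8)

    def test_clamp_floor_failure_reported(self):
        # rates far too fast for the step window
        rates = RateSet(50.0, 50.0, 10.0, 10.0, 5.0, 5.0)
        cfg = IntegratorConfig(initial_step=2.0)
        with pytest.raises(IntegrationError):
            branch_integrate(tip_init(0), rates, 20.0, cfg)


class TestNodeCombine:
    RATES = RateSet(0.1, 0.2, 0.03, 0.03, 0.01, 0.01)

    def test_speciation_factor(self):
        a = LikelihoodState(0, 0, 1.0, 0.0)
        out = node_combine(a, a, self.RATES)
        assert (out.D0, out.D1) == (pytest.approx(0.1), 0.0)

    def test_absorbing_zero(self):
        a = LikelihoodState(0, 0, 0.0, 0.5)
        b = LikelihoodState(0, 0, 0.7, 0.5)
        assert node_combine(a, b, self.RATES).D0 == 0.0

    def test_commutative(self):
        a = LikelihoodState(0.1, 0.2, 0.3, 0.4, -1.0)
        b = LikelihoodState(0.1, 0.2, 0.5, 0.6, -2.0)
        ab = node_combine(a, b, self.RATES)
        ba = node_combine(b, a, self.RATES)
        assert np.allclose(ab.as_array(), ba.as_array(), rtol=1e-15)
        assert ab.log_scale == ba.log_scale

    def test_e_mismatch_rejected(self):
        a = LikelihoodState(0.1, 0.2, 1.0, 0.0)
        b = LikelihoodState(0.4, 0.2, 1.0, 0.0)
        with pytest.raises(IntegrationError):
            node_combine(a, b, self.RATES)


class TestBisseLoglik:
    def test_cherry_closed_form(self, cherry_tree):
        # two state-0 tips on unit branches, pure birth: the likelihood is
        # lambda0 * exp(-2 lambda0 t)
        rates = RateSet(0.1, 0.0001, 0.0, 0.0, 0.0, 0.0)
        ll = bisse_loglik(cherry_tree, rates, RootMode("given", (1.0, 0.0)))
        assert ll == pytest.approx(np.log(0.1) - 0.2, abs=1e-9)

    def test_label_swap_invariance(self):
        rates = RateSet(0.1, 0.15, 0.03, 0.05, 0.02, 0.01)
        tree = simulated_tree(31, 40, rates)
        ll = bisse_loglik(tree, rates)
        flipped = PhyloTree(
            n_tips=tree.n_tips, children=tree.children.copy(),
            lengths=tree.lengths.copy(), tip_states=1 - tree.tip_states,
            tip_labels=list(tree.tip_labels))
        ll_flip = bisse_loglik(flipped, rates.swapped())
        assert ll_flip == pytest.approx(ll, abs=1e-7)

    @pytest.mark.parametrize("c", [0.5, 2.0])
    def test_time_rate_rescaling(self, c):
        # multiplying rates by c and dividing lengths by c changes ln L by
        # exactly (n - 1) ln c (the n-1 node speciation factors)
        rates = RateSet(0.1, 0.15, 0.03, 0.05, 0.02, 0.01)
        tree = simulated_tree(32, 25, rates)
        scaled_rates = RateSet(*(c * v for v in rates.as_array()))
        scaled_tree = PhyloTree(
            n_tips=tree.n_tips, children=tree.children.copy(),
            lengths=tree.lengths / c, tip_states=tree.tip_states.copy(),
            tip_labels=list(tree.tip_labels))
        base = bisse_loglik(tree, rates)
        scaled = bisse_loglik(scaled_tree, scaled_rates)
        assert scaled - base == pytest.approx((tree.n_tips - 1) * np.log(c),
                                              abs=1e-6)

    def test_four_tip_tree_matches_rk4_oracle(self, four_tip_tree):
        rates = RateSet(0.11, 0.23, 0.05, 0.02, 0.04, 0.013)
        w0 = stationary_state0_freq(rates).x_hat
        ll = bisse_loglik(four_tip_tree, rates)
        ref = rk4_tree_loglik(four_tip_tree, rates, w0, 1 - w0, 4000)
        assert ll == pytest.approx(ref, abs=1e-6)

    def test_random_trees_match_rk4_oracle(self):
        rng = np.random.default_rng(77)
        for i in range(12):
            n = int(rng.integers(4, 17))
            las = np.exp(rng.uniform(np.log(0.05), np.log(0.5), size=2))
            mus = las * rng.uniform(0.0, 0.7, size=2)
            qs = np.exp(rng.uniform(np.log(0.005), np.log(0.1), size=2))
            rates = RateSet(las[0], las[1], mus[0], mus[1], qs[0], qs[1])
            tree = simulated_tree(100 + i, n, rates, "fixed0")
            w0 = stationary_state0_freq(rates).x_hat
            ll = bisse_loglik(tree, rates)
            ref = rk4_tree_loglik(tree, rates, w0, 1 - w0)
            assert ll == pytest.approx(ref, abs=1e-5), f"tree {i}"

    def test_state_independent_matches_bd_mk_factorization(self):
        # independent closed-form oracle: birth-death tree term times a
        # matrix-exponential Mk character term
        rates = RateSet(0.1, 0.1, 0.03, 0.03, 0.01, 0.005)
        tree = simulated_tree(42, 40, rates)
        x = stationary_state0_freq(rates).x_hat
        ref = bd_mk_loglik(tree, 0.1, 0.03, 0.01, 0.005, x, 1 - x)
        assert bisse_loglik(tree, rates) == pytest.approx(ref, abs=1e-6)

    def test_stationary_root_requires_transitions(self, cherry_tree):
        with pytest.raises(StationaryUndefinedError):
            bisse_loglik(cherry_tree, RateSet(0.1, 0.1, 0.0, 0.0, 0.0, 0.0))

    def test_root_mode_weights(self, cherry_tree):
        rates = RateSet(0.1, 0.1, 0.03, 0.03, 0.01, 0.01)
        ll_eq = bisse_loglik(cherry_tree, rates, RootMode("equal"))
        ll_st = bisse_loglik(cherry_tree, rates)
        # symmetric rates: stationary weights are (1/2, 1/2)
        assert ll_eq == pytest.approx(ll_st, abs=1e-12)
        ll0 = bisse_loglik(cherry_tree, rates, RootMode("fixed0"))
        assert ll0 > ll_eq  # both tips are state 0
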