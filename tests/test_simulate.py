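import numpy as np
import pytest
from scipy.stats import kstest

from bissekit import RateSet, Scenario, tip_state_summary
from bissekit.simulate import (ExtinctionRetryError, SimTree, batch_rng,
                               prune_extinct, simulate_batch, simulate_tree)


class TestSimulateTree:
    def test_pure_birth_keeps_everyone(self):
        rng = batch_rng(1, 0)
        sim = simulate_tree(RateSet(0.1, 0, 0, 0, 0, 0), 4, rng, "fixed0")
        assert sim.extant_count == 4
        assert not any(sim.extinct)
        tree = prune_extinct(sim)
        assert tree.n_tips == 4
        assert np.all(tree.tip_states == 0)

    @pytest.mark.parametrize("n_tips", [3, 10, 57])
    def test_stops_exactly_at_target(self, n_tips):
        rates = RateSet(0.1, 0.1, 0.03, 0.03, 0.01, 0.01)
        tree = prune_extinct(simulate_tree(rates, n_tips, batch_rng(2, n_tips)))
        assert tree.n_tips == n_tips
        assert tree.is_ultrametric()

    def test_contemporaneous_tips(self):
        rates = RateSet(0.1, 0.12, 0.05, 0.03, 0.02, 0.01)
        sim = simulate_tree(rates, 30, batch_rng(3, 0))
        ends = [sim.end[i] for i in sim.extant_tips]
        assert np.allclose(ends, sim.stop_time)

    def test_retry_cap_raises(self):
        # extinction far above speciation: the clade dies essentially always
        rates = RateSet(0.01, 0.01, 5.0, 5.0, 0.01, 0.01)
        with pytest.raises(ExtinctionRetryError):
            simulate_tree(rates, 50, batch_rng(4, 0), max_retries=3)

    def test_yule_waiting_times_are_exponential(self):
        # with k lineages the next speciation is Exp(k * lambda); pooled
        # normalized waiting times must be standard exponential
        la = 0.1
        rates = RateSet(la, 0, 0, 0, 0, 0)
        pooled = []
        for rep in range(1000):
            sim = simulate_tree(rates, 6, batch_rng(5, rep), "fixed0")
            events = sorted(set(t for t in sim.end if np.isfinite(t)))
            times = [0.0] + events
            for k, (a, b) in enumerate(zip(times[:-1], times[1:]), start=1):
                pooled.append(k * la * (b - a))
        stat = kstest(pooled, "expon")
        assert stat.pvalue > 0.01

    def test_stationary_root_needs_transitions(self):
        with pytest.raises(Exception):
            simulate_tree(RateSet(0.1, 0.1, 0, 0, 0, 0), 5, batch_rng(6, 0),
                          "stationary")


class TestPruneExtinct:
    def test_hand_built_tree_with_one_extinct_tip(self):
        # root speciates at t=1 into A (survives to t=3) and B; B speciates
        # at t=2 into C (extinct at t=2.5) and D (survives); pruning must
        # remove C, splice B+D, and keep depths intact
        sim = SimTree()
        root = sim.add_node(-1, 0.0, 0)
        a = sim.add_node(root, 1.0, 0)
        b = sim.add_node(root, 1.0, 0)
        sim.end[root] = 1.0
        c = sim.add_node(b, 2.0, 0)
        d = sim.add_node(b, 2.0, 1)
        sim.end[b] = 2.0
        sim.end[c] = 2.5
        sim.extinct[c] = True
        sim.end[a] = 3.0
        sim.end[d] = 3.0
        sim.stop_time = 3.0
        tree = prune_extinct(sim)
        assert tree.n_tips == 2
        assert tree.is_ultrametric()
        # both tips at clock depth 2 below the crown split at t=1
        assert tree.depths()[: 2] == pytest.approx([2.0, 2.0])
        assert sorted(tree.tip_states) == [0, 1]

    def test_no_extinction_keeps_topology_minus_stem(self):
        rates = RateSet(0.1, 0.1, 0, 0, 0.01, 0.01)
        sim = simulate_tree(rates, 20, batch_rng(7, 0), "fixed0")
        tree = prune_extinct(sim)
        assert tree.n_tips == 20
        # every internal speciation event below the crown is retained
        crown_children = 2 * 20 - 2
        assert len(tree.children) == 19

    def test_single_survivor_rejected(self):
        sim = SimTree()
        root = sim.add_node(-1, 0.0, 0)
        sim.end[root] = 1.0
        with pytest.raises(ValueError):
            prune_extinct(sim)


class TestTipStateSummary:
    def test_counts(self, four_tip_tree):
        c0, c1, f0 = tip_state_summary(four_tip_tree)
        assert (c0, c1) == (3, 1)
        assert f0 == pytest.approx(0.75)

    def test_monomorphic(self):
        tree = prune_extinct(simulate_tree(
            RateSet(0.1, 0, 0, 0, 0, 0), 5, batch_rng(8, 0), "fixed0"))
        assert tip_state_summary(tree) == (5, 0, 1.0)


class TestSimulateBatch:
    def test_determinism_and_single_rep_equivalence(self):
        rates = RateSet(0.1, 0.1, 0.03, 0.03, 0.01, 0.01)
        scen = Scenario(rates=rates, n_tips=10, n_reps=1, seed=42)
        trees1, _ = simulate_batch(scen)
        trees2, _ = simulate_batch(scen)
        assert trees1[0].to_newick() == trees2[0].to_newick()
        direct = prune_extinct(simulate_tree(rates, 10, batch_rng(42, 0)))
        assert direct.to_newick() == trees1[0].to_newick()

    def test_symmetric_rates_give_half_state0(self):
        rates = RateSet(0.1, 0.1, 0.03, 0.03, 0.01, 0.01)
        scen = Scenario(rates=rates, n_tips=60, n_reps=150, seed=9)
        _, summary = simulate_batch(scen)
        se = summary["sd_frac_state0"] / np.sqrt(scen.n_reps)
        assert abs(summary["mean_frac_state0"] - 0.5) < 3.5 * se

    def test_label_swap_symmetry(self):
        rates = RateSet(0.1, 0.13, 0.03, 0.05, 0.02, 0.01)
        scen = Scenario(rates=rates, n_tips=50, n_reps=120, seed=10)
        _, fwd = simulate_batch(scen)
        _, rev = simulate_batch(scen.with_(rates=rates.swapped()))
        se = np.hypot(fwd["sd_frac_state0"], rev["sd_frac_state0"]) \
            / np.sqrt(scen.n_reps)
        assert abs(fwd["mean_frac_state0"] - (1 - rev["mean_frac_state0"])) \
            < 4 * se
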