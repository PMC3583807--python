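import json

import numpy as np
import pytest

from bissekit import (BisseModel, ConstraintPattern, OptimizerConfig,
                      RateSet, bisse_loglik, brent_minimize_1d, fit_chain,
                      fit_model)
from bissekit.optimize import OptimizationError
from bissekit.rates import expand_params
from conftest import simulated_tree


class TestBrent1D:
    def test_quadratic(self):
        x, f = brent_minimize_1d(lambda x: (x - 2.0) ** 2, (0.0, 5.0),
                                 tol=1e-10)
        assert x == pytest.approx(2.0, abs=1e-8)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_non_smooth_absolute_value(self):
        x, _ = brent_minimize_1d(lambda x: abs(x - 1.0), (0.0, 3.0),
                                 tol=1e-8)
        assert x == pytest.approx(1.0, abs=1e-6)

    def test_nonfinite_objective_raises(self):
        with pytest.raises(OptimizationError):
            brent_minimize_1d(lambda x: np.nan, (0.0, 1.0))

    def test_profile_slice_matches_grid_scan(self, medium_tree):
        # 1-D profile in lambda0 with the other rates fixed at truth
        base = RateSet(0.1, 0.125, 0.03, 0.03, 0.01, 0.01)

        def nll(la0):
            return -bisse_loglik(medium_tree, base.replace(lambda0=la0))

        grid = np.linspace(0.02, 0.4, 10_000)
        vals = [nll(x) for x in grid]
        x_grid = grid[int(np.argmin(vals))]
        x_opt, _ = brent_minimize_1d(nll, (0.02, 0.4), tol=1e-8)
        assert abs(x_opt - x_grid) <= (grid[1] - grid[0])


class TestFitModel:
    def test_symmetric_recovery_on_medium_trees(self):
        # lambda is the best-identified rate; median relative error over a
        # few replicates should be modest
        truth = RateSet(0.1, 0.1, 0.03, 0.03, 0.01, 0.01)
        pat = ConstraintPattern.reduced_null()
        errs = []
        for k in range(6):
            tree = simulated_tree(300 + k, 150, truth)
            fit = fit_model(tree, pat, cfg=OptimizerConfig(
                n_random_starts=2, seed=k))
            errs.append(abs(fit.rates.lambda0 - 0.1) / 0.1)
        assert np.median(errs) < 0.25

    def test_nesting_inequality(self, medium_tree):
        fits = fit_chain(medium_tree, [
            ConstraintPattern.reduced_null(),
            ConstraintPattern.constrained("speciation"),
            ConstraintPattern.full(),
        ], cfg=OptimizerConfig(n_random_starts=1, seed=0))
        ll3, ll5, ll6 = (f.loglik for f in fits)
        assert ll6 >= ll5 - 1e-9
        assert ll5 >= ll3 - 1e-9

    def test_loglik_consistent_with_reevaluation(self, medium_tree):
        fit = fit_model(medium_tree, ConstraintPattern.reduced_null(),
                        cfg=OptimizerConfig(n_random_starts=1, seed=3))
        assert bisse_loglik(medium_tree, fit.rates) == pytest.approx(
            fit.loglik, abs=1e-6)

    def test_deterministic_given_seed(self, medium_tree):
        cfg = OptimizerConfig(n_random_starts=2, seed=11)
        a = fit_model(medium_tree, ConstraintPattern.reduced_null(), cfg=cfg)
        b = fit_model(medium_tree, ConstraintPattern.reduced_null(), cfg=cfg)
        assert json.dumps(a.to_dict(), sort_keys=True) == \
            json.dumps(b.to_dict(), sort_keys=True)

    def test_monomorphic_tips_flagged_not_fatal(self):
        tree = simulated_tree(55, 12, RateSet(0.1, 0.0, 0.0, 0.0, 0.0, 0.0),
                              "fixed0")
        fit = fit_model(tree, ConstraintPattern.reduced_null(),
                        cfg=OptimizerConfig(n_random_starts=2, seed=1))
        assert fit.monomorphic

    def test_small_tree_matches_grid_search(self):
        # exhaustive 3-D grid over the symmetric model on an 8-tip tree
        truth = RateSet(0.2, 0.2, 0.05, 0.05, 0.03, 0.03)
        tree = simulated_tree(77, 8, truth)
        pat = ConstraintPattern.reduced_null()
        grid = np.logspace(-3, 0.5, 30)
        best = -np.inf
        from bissekit.likelihood import IntegrationError
        for la in grid:
            for mu in grid:
                for q in grid:
                    try:
                        ll = bisse_loglik(tree,
                                          expand_params([la, mu, q], pat))
                    except IntegrationError:
                        continue  # too stiff for the default step window
                    if np.isfinite(ll) and ll > best:
                        best = ll
        fit = fit_model(tree, pat, cfg=OptimizerConfig(n_random_starts=3,
                                                       seed=2))
        assert fit.loglik >= best - 1e-3


class TestModelInterface:
    def test_fit_and_summary(self, medium_tree):
        model = BisseModel(medium_tree,
                           pattern=ConstraintPattern.reduced_null())
        res = model.fit(OptimizerConfig(n_random_starts=1, seed=0))
        assert res.converged
        assert res.df_model == 3
        text = res.summary()
        assert "ln L" in text and "lambda0" in text
        assert res.llf == pytest.approx(model.loglike(res.rates), abs=1e-6)

    def test_lrt_between_nested_results(self, medium_tree):
        full = BisseModel(medium_tree).fit(
            OptimizerConfig(n_random_starts=1, seed=0))
        constrained = BisseModel(
            medium_tree,
            pattern=ConstraintPattern.constrained("speciation")).fit(
            OptimizerConfig(n_random_starts=1, seed=0))
        stat, pval = full.lrt(constrained)
        assert stat >= 0.0
        assert 0.0 <= pval <= 1.0

    def test_results_simulate_roundtrip(self, medium_tree):
        res = BisseModel(medium_tree,
                         pattern=ConstraintPattern.reduced_null()).fit(
            OptimizerConfig(n_random_starts=1, seed=0))
        trees = res.simulate(n_tips=10, n_reps=2, seed=4)
        assert [t.n_tips for t in trees] == [10, 10]
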