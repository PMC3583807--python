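"""Model/Results interface for fitting BiSSE to a tree with tip states.

`BisseModel` binds the data (an ultrametric tree and its binary tip
states) to a constraint pattern and root-prior mode; `fit()` runs the
multi-start coordinate-descent ML search and returns a `BisseResults`
carrying the estimates, diagnostics, a `summary()` table, and simulation
under the fitted rates.

    >>> model = BisseModel.from_files("tree.nwk", "states.tsv")
    >>> res = model.fit()
    >>> print(res.summary())
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .likelihood import IntegratorConfig, RootMode, bisse_loglik
from .optimize import FitResult, OptimizerConfig, fit_chain, fit_model
from .rates import ConstraintPattern, RateSet
from .trees import PhyloTree, tip_state_summary


class BisseModel:
    """State-dependent diversification model bound to one data set.

    Parameters
    ----------
    tree
        Ultrametric extant-only tree with binary tip states.
    pattern
        Equality constraints defining the 3- to 6-parameter model; the
        unconstrained six-parameter model by default.
    root
        Root-prior weighting for the two states (stationary by default).
    integrator
        Adaptive-integrator settings for the likelihood.
    """

    def __init__(
        self,
        tree: PhyloTree,
        pattern: ConstraintPattern | None = None,
        root: RootMode | None = None,
        integrator: IntegratorConfig | None = None,
    ):
        tree.check_ultrametric()
        self.tree = tree
        self.pattern = pattern or ConstraintPattern.full()
        self.root = root or RootMode()
        self.integrator = integrator

    @classmethod
    def from_files(cls, tree_path, states_path, **kwargs) -> "BisseModel":
        from .io import attach_states, read_newick, read_states

        tree = read_newick(tree_path)
        return cls(attach_states(tree, read_states(states_path)), **kwargs)

    # ------------------------------------------------------------------

    def loglike(self, rates: RateSet) -> float:
        """Log-likelihood of the data under explicit rates."""
        return bisse_loglik(self.tree, rates, self.root, self.integrator)

    def fit(
        self,
        config: OptimizerConfig | None = None,
        warm_chain: bool = True,
    ) -> "BisseResults":
        """Maximum-likelihood fit under the model's constraint pattern.

        With ``warm_chain`` (default) the search first fits the fully
        symmetric three-parameter model and feeds its estimates forward as
        a warm start, alongside the random restarts.
        """
        config = config or OptimizerConfig()
        if warm_chain and self.pattern.free_count > 3:
            results = fit_chain(
                self.tree, [ConstraintPattern.reduced_null(), self.pattern],
                self.root, config, self.integrator)
            fit = results[-1]
        else:
            fit = fit_model(self.tree, self.pattern, self.root, config,
                            self.integrator)
        return BisseResults(self, fit)


class BisseResults:
    """Fitted BiSSE model: estimates, diagnostics and derived quantities."""

    def __init__(self, model: BisseModel, fit: FitResult):
        self.model = model
        self.fit = fit

    # statsmodels-flavoured accessors ----------------------------------

    @property
    def rates(self) -> RateSet:
        return self.fit.rates

    @property
    def params(self) -> np.ndarray:
        from .rates import project_params

        return project_params(self.fit.rates, self.fit.pattern)

    @property
    def llf(self) -> float:
        return self.fit.loglik

    @property
    def df_model(self) -> int:
        return self.fit.pattern.free_count

    @property
    def converged(self) -> bool:
        return self.fit.converged

    def lrt(self, constrained: "BisseResults") -> tuple[float, float]:
        """LRT statistic 2*(lnL - lnL_constrained) against a nested fit,
        plus the chi-square(df) p-value for reference (the study's
        preferred cutoff is a simulated critical value)."""
        from scipy.stats import chi2

        if not constrained.fit.pattern.nests_in(self.fit.pattern):
            raise ValueError("patterns are not nested")
        stat = 2.0 * (self.llf - constrained.llf)
        stat = 0.0 if -1e-6 <= stat < 0.0 else stat
        df = self.df_model - constrained.df_model
        return stat, float(chi2.sf(stat, max(df, 1)))

    def simulate(
        self,
        n_tips: int | None = None,
        n_reps: int = 1,
        seed: int = 0,
        root_state_mode: str = "stationary",
    ) -> list[PhyloTree]:
        """Simulate trees under the fitted rates."""
        from .simulate import batch_rng, prune_extinct, simulate_tree

        n = n_tips or self.model.tree.n_tips
        return [
            prune_extinct(simulate_tree(self.rates, n, batch_rng(seed, k),
                                        root_state_mode))
            for k in range(n_reps)
        ]

    def summary(self) -> str:
        c0, c1, f0 = tip_state_summary(self.model.tree)
        lines = [
            "BiSSE maximum-likelihood fit",
            "=" * 46,
            f"tips: {self.model.tree.n_tips}  (state 0: {c0}, state 1: {c1},"
            f" frac0 = {f0:.4f})",
            f"pattern: {self.fit.pattern.to_string()}"
            f"  (free parameters: {self.df_model})",
            f"root prior: {self.model.root.mode}",
            f"ln L = {self.llf:.6f}   converged: {self.fit.converged}"
            f"   cycles: {self.fit.n_cycles_used}",
            "-" * 46,
            f"{'rate':>9} {'estimate':>12}",
        ]
        for name, value in self.rates.as_dict().items():
            flag = ""
            if any(name in cls for cls in [self.fit.pattern.classes[
                    self.fit.pattern.free_names.index(b)]
                    for b in self.fit.boundary_rates]):
                flag = "  (at bound)"
            lines.append(f"{name:>9} {value:>12.6g}{flag}")
        if self.fit.monomorphic:
            lines.append("warning: tips are monomorphic; boundary estimates "
                         "expected")
        lines.append("=" * 46)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return self.fit.to_dict()
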