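"""Likelihood-ratio power analysis with simulated null distributions.

For a process of interest, the test compares a full model against the
nested model in which that process's two rates are forced equal: six vs
five free parameters when the other processes are left free, or four vs
three when they are assumed symmetric. Because the chi-square reference
can be unreliable for these tests, the critical value is the empirical
(1 - alpha) quantile of the LRT statistic over replicates simulated under
symmetric (null) rates; power is the fraction of alternative-scenario
replicates exceeding it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .likelihood import IntegratorConfig, RootMode
from .optimize import FitResult, OptimizerConfig, fit_chain
from .rates import ConstraintPattern
from .scenarios import Scenario
from .simulate import batch_rng, prune_extinct, simulate_tree
from .trees import PhyloTree, tip_state_summary

__all__ = [
    "ModelPair",
    "LRTResult",
    "NullDistribution",
    "PowerEstimate",
    "lrt_statistic",
    "build_null_distribution",
    "estimate_power",
    "run_power_grid",
    "chi2_critical_value",
]


@dataclass(frozen=True)
class ModelPair:
    """A nested (constrained, full) pattern pair testing one process."""

    process: str
    #: "6v5" (other processes free) or "4v3" (other processes symmetric)
    kind: str = "6v5"

    def patterns(self) -> tuple[ConstraintPattern, ConstraintPattern]:
        if self.kind == "6v5":
            return (ConstraintPattern.constrained(self.process),
                    ConstraintPattern.full())
        if self.kind == "4v3":
            return (ConstraintPattern.reduced_null(),
                    ConstraintPattern.reduced_full(self.process))
        raise ValueError(f"unknown model pair kind {self.kind!r}")

    @property
    def df(self) -> int:
        return 1  # each pair differs by one equality constraint


@dataclass
class LRTResult:
    """2 x (ln L_full - ln L_constrained) for one replicate."""

    stat: float
    full_fit: FitResult
    constrained_fit: FitResult
    replicate: int = 0

    @property
    def suspicious(self) -> bool:
        """Negative beyond numerical noise: an optimizer-failure signal."""
        return self.stat < -1e-6


@dataclass
class NullDistribution:
    #: sorted LRT statistics
    stats: np.ndarray
    alpha: float
    critical_value: float
    n_reps: int
    n_tips: int
    pair: ModelPair
    n_redrawn: int = 0
    #: the same statistics in replicate order (for resampling diagnostics)
    stats_raw: np.ndarray = field(default_factory=lambda: np.empty(0))

    @classmethod
    def from_stats(cls, stats, alpha, n_tips, pair, n_redrawn=0):
        raw = np.asarray(stats, dtype=float)
        stats = np.sort(raw)
        # linear (type-7) interpolation of the empirical quantile
        crit = float(np.quantile(stats, 1.0 - alpha, method="linear"))
        return cls(stats=stats, alpha=alpha, critical_value=crit,
                   n_reps=len(stats), n_tips=n_tips, pair=pair,
                   n_redrawn=n_redrawn, stats_raw=raw)


@dataclass
class PowerEstimate:
    label: str
    process: str
    pair_kind: str
    n_tips: int
    n_alt_reps: int
    critical_value: float
    power: float
    mean_frac_state0: float = np.nan
    stats: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def ci_halfwidth(self) -> float:
        p, n = self.power, self.n_alt_reps
        return 1.96 * float(np.sqrt(p * (1.0 - p) / n))


def chi2_critical_value(alpha: float = 0.05, df: int = 1) -> float:
    """The conventional chi-square cutoff (3.841 at alpha=0.05, df=1),
    offered as an alternative to the simulated critical value."""
    return float(chi2.ppf(1.0 - alpha, df))


def lrt_statistic(
    tree: PhyloTree,
    full_pattern: ConstraintPattern,
    constrained_pattern: ConstraintPattern,
    root: RootMode | None = None,
    cfg: OptimizerConfig | None = None,
    integ: IntegratorConfig | None = None,
    replicate: int = 0,
) -> LRTResult:
    """Fit both nested models (constrained first, warm-starting the full
    fit) and return the likelihood-ratio statistic."""
    if not constrained_pattern.nests_in(full_pattern):
        raise ValueError(
            f"{constrained_pattern!r} does not nest in {full_pattern!r}")
    chain_patterns: list[ConstraintPattern] = []
    if constrained_pattern.free_count > 3:
        chain_patterns.append(ConstraintPattern.reduced_null())
    chain_patterns += [constrained_pattern]
    if full_pattern != constrained_pattern:
        chain_patterns.append(full_pattern)
    fits = fit_chain(tree, chain_patterns, root, cfg, integ)
    constrained_fit = fits[-2] if full_pattern != constrained_pattern else fits[-1]
    full_fit = fits[-1]
    stat = 2.0 * (full_fit.loglik - constrained_fit.loglik)
    if -1e-6 <= stat < 0.0:
        stat = 0.0
    return LRTResult(stat=stat, full_fit=full_fit,
                     constrained_fit=constrained_fit, replicate=replicate)


def _replicate_stat(scenario, pair, rep, root_mode, cfg, integ, stream_tag):
    """Simulate one tree and compute its LRT statistic."""
    rng = batch_rng(scenario.seed, rep + stream_tag)
    sim = simulate_tree(scenario.rates, scenario.n_tips, rng, root_mode)
    tree = prune_extinct(sim)
    constrained, full = pair.patterns()
    rep_cfg = cfg or OptimizerConfig()
    rep_cfg = OptimizerConfig(
        n_random_starts=rep_cfg.n_random_starts,
        start_bounds=rep_cfg.start_bounds, max_cycles=rep_cfg.max_cycles,
        convergence_tol=rep_cfg.convergence_tol,
        rate_bounds=rep_cfg.rate_bounds, coord_tol=rep_cfg.coord_tol,
        accelerate=rep_cfg.accelerate, abandon_margin=rep_cfg.abandon_margin,
        warm_start=rep_cfg.warm_start, seed=rep)
    res = lrt_statistic(tree, full, constrained, RootMode(root_mode),
                        rep_cfg, integ, replicate=rep)
    return res, tip_state_summary(tree)[2]


#: default optimizer budget for pipeline replicates: the warm-start chain
#: does the heavy lifting, so fewer random restarts per replicate suffice
PIPELINE_OPTIMIZER = OptimizerConfig(n_random_starts=2)


def build_null_distribution(
    null_scenario: Scenario,
    pair: ModelPair,
    alpha: float = 0.05,
    root_mode: str = "stationary",
    cfg: OptimizerConfig | None = None,
    integ: IntegratorConfig | None = None,
    max_redraws: int = 20,
) -> NullDistribution:
    """Simulate under symmetric rates and collect the LRT statistic's
    empirical distribution; the critical value is its (1 - alpha)
    quantile (linear / type-7 interpolation)."""
    r = null_scenario.rates
    for a, b in ((r.lambda0, r.lambda1), (r.mu0, r.mu1), (r.q01, r.q10)):
        if not np.isclose(a, b):
            raise ValueError("null scenario rates must be symmetric")
    if not (0.0 < alpha <= 0.5):
        raise ValueError("alpha must be in (0, 0.5]")
    cfg = cfg or PIPELINE_OPTIMIZER
    stats = []
    redrawn = 0
    rep = 0
    produced = 0
    while produced < null_scenario.n_reps:
        res, _ = _replicate_stat(null_scenario, pair, rep, root_mode, cfg,
                                 integ, stream_tag=0)
        rep += 1
        if res.suspicious:
            redrawn += 1
            if redrawn > max_redraws:
                raise RuntimeError(
                    "too many optimizer failures while building the null "
                    "distribution")
            continue
        stats.append(res.stat)
        produced += 1
    return NullDistribution.from_stats(stats, alpha, null_scenario.n_tips,
                                       pair, n_redrawn=redrawn)


def estimate_power(
    alt_scenario: Scenario,
    null_dist: NullDistribution,
    pair: ModelPair | None = None,
    root_mode: str = "stationary",
    cfg: OptimizerConfig | None = None,
    integ: IntegratorConfig | None = None,
) -> PowerEstimate:
    """Fraction of alternative-scenario LRT statistics exceeding the null
    distribution's critical value."""
    pair = pair or null_dist.pair
    if alt_scenario.n_tips != null_dist.n_tips:
        raise ValueError(
            f"tree-size mismatch: alternative has {alt_scenario.n_tips} "
            f"tips, null distribution used {null_dist.n_tips}")
    if pair != null_dist.pair:
        raise ValueError("model pair differs from the null distribution's")
    cfg = cfg or PIPELINE_OPTIMIZER
    stats = np.empty(alt_scenario.n_reps)
    fracs = np.empty(alt_scenario.n_reps)
    for rep in range(alt_scenario.n_reps):
        # offset the stream so alternative draws never collide with null's
        res, frac = _replicate_stat(alt_scenario, pair, rep, root_mode, cfg,
                                    integ, stream_tag=500_000)
        stats[rep] = res.stat
        fracs[rep] = frac
    power = float(np.mean(stats > null_dist.critical_value))
    return PowerEstimate(
        label=alt_scenario.label, process=pair.process, pair_kind=pair.kind,
        n_tips=alt_scenario.n_tips, n_alt_reps=alt_scenario.n_reps,
        critical_value=null_dist.critical_value, power=power,
        mean_frac_state0=float(fracs.mean()), stats=stats)


_GRID_COLUMNS = ["label", "process", "n_tips", "pair", "n_reps",
                 "critical_value", "power", "ci_halfwidth",
                 "mean_frac_state0"]


def run_power_grid(
    scenarios: list[Scenario],
    tree_sizes: list[int],
    model_pairs: list[ModelPair],
    alpha: float = 0.05,
    root_mode: str = "stationary",
    cfg: OptimizerConfig | None = None,
    integ: IntegratorConfig | None = None,
    checkpoint: Optional[Path] = None,
    use_chi2_cutoff: bool = False,
) -> pd.DataFrame:
    """One row per (scenario, tree size, model pair).

    With ``checkpoint``, completed rows are written after each estimate and
    reloaded on restart, so long grids are resumable.
    """
    done = pd.DataFrame(columns=_GRID_COLUMNS)
    if checkpoint is not None and Path(checkpoint).exists():
        done = pd.read_csv(checkpoint, comment="#")
        done["label"] = done["label"].fillna("").astype(str)
    rows = [dict(r) for _, r in done.iterrows()]
    for scenario in scenarios:
        for n_tips in tree_sizes:
            for pair in model_pairs:
                key = (scenario.label, n_tips, pair.kind)
                if any((r["label"], r["n_tips"], r["pair"]) == key
                       for r in rows):
                    continue
                alt = scenario.with_(n_tips=n_tips)
                null_scen = scenario.null_counterpart().with_(n_tips=n_tips)
                try:
                    if use_chi2_cutoff:
                        null = NullDistribution(
                            stats=np.empty(0), alpha=alpha,
                            critical_value=chi2_critical_value(alpha, pair.df),
                            n_reps=0, n_tips=n_tips, pair=pair)
                    else:
                        null = build_null_distribution(
                            null_scen, pair, alpha, root_mode, cfg, integ)
                    est = estimate_power(alt, null, pair, root_mode, cfg,
                                         integ)
                    rows.append({
                        "label": est.label, "process": est.process,
                        "n_tips": est.n_tips, "pair": est.pair_kind,
                        "n_reps": est.n_alt_reps,
                        "critical_value": est.critical_value,
                        "power": est.power,
                        "ci_halfwidth": est.ci_halfwidth,
                        "mean_frac_state0": est.mean_frac_state0,
                    })
                except RuntimeError as err:
                    rows.append({
                        "label": scenario.label, "process": pair.process,
                        "n_tips": n_tips, "pair": pair.kind,
                        "n_reps": 0, "critical_value": np.nan,
                        "power": np.nan, "ci_halfwidth": np.nan,
                        "mean_frac_state0": np.nan,
                    })
                if checkpoint is not None:
                    pd.DataFrame(rows, columns=_GRID_COLUMNS).to_csv(
                        checkpoint, index=False)
    return pd.DataFrame(rows, columns=_GRID_COLUMNS)
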