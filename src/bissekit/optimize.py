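"""Maximum-likelihood fitting of BiSSE rates under constraint patterns.

Free parameters (one per equality class of the pattern) are searched in
log10 space with cyclic one-dimensional Brent-style minimization: each
cycle runs one bounded derivative-free line search per free parameter, and
cycles repeat until the per-cycle log-likelihood gain falls below a
threshold. The search is repeated from several random starting points
(log-uniform over a configurable window) plus an optional warm start taken
from a more-constrained model's fit; the best final log-likelihood wins,
with ties broken by the lowest start index so results are deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .likelihood import IntegratorConfig, IntegrationError, RootMode, bisse_loglik
from .rates import ConstraintPattern, RateSet, expand_params, project_params
from .trees import PhyloTree

__all__ = ["OptimizerConfig", "FitResult", "brent_minimize_1d", "fit_model",
           "fit_chain"]

#: objective value standing in for an impossible / failed likelihood
_PENALTY = 1e12


class OptimizationError(RuntimeError):
    pass


@dataclass(frozen=True)
class OptimizerConfig:
    n_random_starts: int = 3
    #: log-uniform sampling window for random starting rates
    start_bounds: tuple[float, float] = (1e-4, 10.0)
    max_cycles: int = 200
    #: minimum ln L improvement per full cycle to keep iterating
    convergence_tol: float = 1e-6
    rate_bounds: tuple[float, float] = (1e-8, 1e2)
    #: line-search tolerance in log10-rate units
    coord_tol: float = 3e-3
    #: after each cycle, run one extra line search along the cycle's net
    #: displacement (Powell-style); greatly reduces ridge crawling
    accelerate: bool = True
    #: abandon a start whose ln L trails the best finished start by this
    #: much after a few cycles (None disables)
    abandon_margin: Optional[float] = 5.0
    warm_start: Optional["FitResult"] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_random_starts < 1:
            raise ValueError("n_random_starts must be >= 1")
        lo, hi = self.rate_bounds
        if not (0 < lo < hi):
            raise ValueError("rate bounds must be positive with lower < upper")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")


@dataclass
class FitResult:
    """Outcome of one constrained ML fit."""

    rates: RateSet
    loglik: float
    pattern: ConstraintPattern
    n_cycles_used: int
    converged: bool
    start_index: int
    all_start_logliks: list[float] = field(default_factory=list)
    #: free-parameter names whose estimate sits at a rate bound
    boundary_rates: list[str] = field(default_factory=list)
    #: tips were monomorphic; boundary estimates are expected
    monomorphic: bool = False

    def to_dict(self) -> dict:
        return {
            "rates": self.rates.as_dict(),
            "loglik": float(self.loglik),
            "pattern": self.pattern.to_string(),
            "n_cycles_used": int(self.n_cycles_used),
            "converged": bool(self.converged),
            "start_index": int(self.start_index),
            "all_start_logliks": [float(v) for v in self.all_start_logliks],
            "boundary_rates": list(self.boundary_rates),
            "monomorphic": bool(self.monomorphic),
        }


def brent_minimize_1d(
    objective: Callable[[float], float],
    bracket: tuple[float, float],
    tol: float = 1e-8,
) -> tuple[float, float]:
    """Bounded derivative-free 1-D minimization (golden section with
    parabolic interpolation). Never evaluates outside the bracket; raises
    if the objective returns a non-finite value."""
    lo, hi = bracket
    if not lo < hi:
        raise ValueError("bracket must satisfy lo < hi")

    def guarded(x: float) -> float:
        v = objective(x)
        if not np.isfinite(v):
            raise OptimizationError(f"objective is non-finite at x={x!r}")
        return v

    res = minimize_scalar(guarded, bounds=(lo, hi), method="bounded",
                          options={"xatol": tol})
    return float(res.x), float(res.fun)


def _line_search(f, x0, f0, lo, hi, tol):
    """Line search around x0: a local window first, widened to the full
    bounds whenever the minimizer lands on the window edge."""
    half = 1.0  # one decade each way
    while True:
        wlo = max(lo, x0 - half)
        whi = min(hi, x0 + half)
        res = minimize_scalar(f, bounds=(wlo, whi), method="bounded",
                              options={"xatol": tol})
        x, v = float(res.x), float(res.fun)
        at_edge = (x - wlo < 4 * tol and wlo > lo) or (whi - x < 4 * tol and whi < hi)
        if not at_edge:
            break
        half *= 4.0
        x0 = x
    if v < f0:
        return x, v
    return x0, f0


def fit_model(
    tree: PhyloTree,
    pattern: ConstraintPattern,
    root: RootMode | None = None,
    cfg: OptimizerConfig | None = None,
    integ: IntegratorConfig | None = None,
) -> FitResult:
    """ML estimate of the rates under the pattern's equality constraints."""
    root = root or RootMode()
    cfg = cfg or OptimizerConfig()
    if integ is None or integ.initial_step is None:
        base = integ or IntegratorConfig()
        integ = IntegratorConfig(
            initial_step=max(tree.height, 1e-12) / 100.0,
            rel_tol=base.rel_tol, abs_tol=base.abs_tol,
            clamp_lo=base.clamp_lo, clamp_hi=base.clamp_hi,
            e_match_tol=base.e_match_tol)

    k = pattern.free_count
    monomorphic = len(set(tree.tip_states.tolist())) < 2
    log_lo, log_hi = np.log10(cfg.rate_bounds[0]), np.log10(cfg.rate_bounds[1])

    # stiffer rate sets may need a smaller starting step (the clamp window
    # scales with it); fall back twice before declaring the point infeasible
    integ_ladder = [integ] + [
        IntegratorConfig(initial_step=integ.initial_step / f,
                         rel_tol=integ.rel_tol, abs_tol=integ.abs_tol,
                         clamp_lo=integ.clamp_lo, clamp_hi=integ.clamp_hi,
                         e_match_tol=integ.e_match_tol)
        for f in (10.0, 100.0)
    ]

    memo: dict[tuple, float] = {}

    def neg_loglik(v: np.ndarray) -> float:
        key = tuple(np.round(v, 7))
        hit = memo.get(key)
        if hit is not None:
            return hit
        val = _neg_loglik_raw(v)
        memo[key] = val
        return val

    def _neg_loglik_raw(v: np.ndarray) -> float:
        try:
            rates = expand_params(10.0 ** v, pattern)
        except ValueError:
            return _PENALTY
        # fast rates need finer steps than the tree-height default; start
        # the ladder where the step can plausibly resolve the dynamics
        stiffness = float(np.max(rates.as_array())) * integ_ladder[0].initial_step
        first = 0 if stiffness <= 1.0 else (1 if stiffness <= 10.0 else 2)
        for ic in integ_ladder[first:]:
            try:
                ll = bisse_loglik(tree, rates, root, ic)
            except IntegrationError as err:
                if err.status == 1:
                    continue  # retry with a smaller starting step
                return _PENALTY
            return -ll if np.isfinite(ll) else _PENALTY
        return _PENALTY

    # assemble starting points: warm start first, then random draws
    starts: list[np.ndarray] = []
    if cfg.warm_start is not None:
        starts.append(np.log10(np.maximum(
            project_params(cfg.warm_start.rates, pattern), cfg.rate_bounds[0])))
    rng = np.random.default_rng([int(cfg.seed), 1791])
    s_lo, s_hi = np.log10(cfg.start_bounds[0]), np.log10(cfg.start_bounds[1])
    for _ in range(cfg.n_random_starts):
        starts.append(rng.uniform(s_lo, s_hi, size=k))

    best: tuple[float, int, np.ndarray, int, bool] | None = None
    all_logliks: list[float] = []
    for si, v0 in enumerate(starts):
        v = np.clip(v0, log_lo, log_hi).astype(float)
        f = neg_loglik(v)
        cycles = 0
        converged = False
        for cycle in range(cfg.max_cycles):
            cycles = cycle + 1
            f_prev = f
            v_prev = v.copy()
            for j in range(k):
                def f1d(x, j=j):
                    w = v.copy()
                    w[j] = x
                    return neg_loglik(w)
                xj, fj = _line_search(f1d, v[j], f, log_lo, log_hi,
                                      cfg.coord_tol)
                v[j] = xj
                f = fj
            if cfg.accelerate:
                d = v - v_prev
                dn = float(np.max(np.abs(d)))
                if dn > 4 * cfg.coord_tol:
                    def fdir(t):
                        return neg_loglik(np.clip(v + t * d, log_lo, log_hi))
                    res = minimize_scalar(
                        fdir, bounds=(-0.5, 4.0), method="bounded",
                        options={"xatol": max(cfg.coord_tol / dn, 2e-2)})
                    if float(res.fun) < f:
                        v = np.clip(v + float(res.x) * d, log_lo, log_hi)
                        f = float(res.fun)
            # stop when the cycle's ln L gain is negligible or the whole
            # cycle moved every coordinate by less than the line-search
            # resolution (further cycles would only chase search noise)
            if (f_prev - f < cfg.convergence_tol
                    or float(np.max(np.abs(v - v_prev))) < 2 * cfg.coord_tol):
                converged = True
                break
            if (cfg.abandon_margin is not None and cycle >= 1
                    and best is not None
                    and f > best[0] + cfg.abandon_margin):
                break
        all_logliks.append(-f)
        if best is None or f < best[0] - 0.0:
            best = (f, si, v.copy(), cycles, converged)

    if best is None or best[0] >= _PENALTY:
        raise OptimizationError("all starting points failed to produce a "
                                "finite likelihood")
    f, si, v, cycles, converged = best
    boundary = [name for name, x in zip(pattern.free_names, v)
                if x - log_lo < 5e-3 or log_hi - x < 5e-3]
    return FitResult(
        rates=expand_params(10.0 ** v, pattern),
        loglik=-f,
        pattern=pattern,
        n_cycles_used=cycles,
        converged=converged,
        start_index=si,
        all_start_logliks=all_logliks,
        boundary_rates=boundary,
        monomorphic=monomorphic,
    )


def fit_chain(
    tree: PhyloTree,
    patterns: Sequence[ConstraintPattern],
    root: RootMode | None = None,
    cfg: OptimizerConfig | None = None,
    integ: IntegratorConfig | None = None,
) -> list[FitResult]:
    """Fit a nested sequence of patterns (most constrained first), warm
    starting each fit from the previous one's estimates."""
    cfg = cfg or OptimizerConfig()
    results: list[FitResult] = []
    warm = cfg.warm_start
    for pat in patterns:
        step_cfg = OptimizerConfig(
            n_random_starts=cfg.n_random_starts,
            start_bounds=cfg.start_bounds,
            max_cycles=cfg.max_cycles,
            convergence_tol=cfg.convergence_tol,
            rate_bounds=cfg.rate_bounds,
            coord_tol=cfg.coord_tol,
            warm_start=warm,
            seed=cfg.seed,
        )
        # the warm start is itself a candidate start and line searches are
        # monotone, so each fit's ln L can only exceed its predecessor's
        res = fit_model(tree, pat, root, step_cfg, integ)
        results.append(res)
        warm = res
    return results
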