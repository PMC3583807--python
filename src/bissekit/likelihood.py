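"""BiSSE log-likelihood of a tree with binary tip states.

The likelihood is computed by the standard pruning recursion: each tip is
initialised with certainty in its observed state (complete sampling), the
per-state extinction probabilities E and partial likelihoods D are
integrated backward in time along every branch (adaptive RKF45; see
``_ode``), daughters are combined at each node with the state-specific
speciation rate factor, and at the root the two partial likelihoods are
combined with a weight vector (stationary frequencies of the rate set by
default). Underflow is prevented by per-node rescaling of (D0, D1), with
the log rescale factors accumulated into the returned log-likelihood.

The likelihood is that of the reconstructed tree itself; it is not
conditioned on survival of the clade.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _ode
from .rates import RateSet
from .stationary import StationaryUndefinedError, stationary_state0_freq
from .trees import PhyloTree

__all__ = [
    "LikelihoodState",
    "IntegratorConfig",
    "RootMode",
    "IntegrationError",
    "tip_init",
    "branch_integrate",
    "node_combine",
    "bisse_loglik",
    "root_weights",
]

_STATUS_MSG = {
    1: "step size hit the clamp floor with local error above tolerance",
    2: "extinction probability left [0, 1]",
    3: "non-finite intermediate value",
    4: "sister-lineage extinction probabilities disagree",
}


class IntegrationError(RuntimeError):
    """The branch integrator could not meet its contract."""

    def __init__(self, status: int, node: int | None = None):
        self.status = status
        self.node = node
        where = f" at node {node}" if node is not None else ""
        super().__init__(f"{_STATUS_MSG.get(status, 'integration failure')}{where}")


@dataclass
class LikelihoodState:
    """Per-state extinction probabilities and partial likelihoods at one
    point on the tree, with an accumulated log rescale factor."""

    E0: float = 0.0
    E1: float = 0.0
    D0: float = 0.0
    D1: float = 0.0
    log_scale: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.E0, self.E1, self.D0, self.D1])


@dataclass(frozen=True)
class IntegratorConfig:
    """Adaptive RKF45 settings.

    ``initial_step`` defaults to (tree height)/100 when integrating a whole
    tree, or (branch length)/100 for a lone branch. The step size is never
    allowed outside ``initial_step x [clamp_lo, clamp_hi]``.
    """

    initial_step: Optional[float] = None
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    clamp_lo: float = 0.1
    clamp_hi: float = 10.0
    #: tolerance for the sister-lineage E consistency check at nodes
    e_match_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be positive")
        if not (0 < self.clamp_lo <= 1.0 <= self.clamp_hi):
            raise ValueError("need 0 < clamp_lo <= 1 <= clamp_hi")
        if self.initial_step is not None and self.initial_step <= 0:
            raise ValueError("initial_step must be positive")

    def step_for(self, scale: float) -> float:
        return self.initial_step if self.initial_step is not None else scale / 100.0


@dataclass(frozen=True)
class RootMode:
    """How the two root partial likelihoods are weighted.

    Modes: ``stationary`` (weights from the rate set's stationary
    character frequency; the default, matching the simulator's root-state
    rule), ``equal`` (1/2, 1/2), ``fixed0``/``fixed1``, or ``given`` with
    explicit ``weights``.
    """

    mode: str = "stationary"
    weights: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.mode not in ("stationary", "equal", "fixed0", "fixed1", "given"):
            raise ValueError(f"unknown root mode {self.mode!r}")
        if self.mode == "given":
            if self.weights is None:
                raise ValueError("mode='given' requires weights")
            w0, w1 = self.weights
            if w0 < 0 or w1 < 0 or abs(w0 + w1 - 1.0) > 1e-9:
                raise ValueError("weights must be non-negative and sum to 1")


def root_weights(root: RootMode, rates: RateSet) -> tuple[float, float]:
    if root.mode == "equal":
        return 0.5, 0.5
    if root.mode == "fixed0":
        return 1.0, 0.0
    if root.mode == "fixed1":
        return 0.0, 1.0
    if root.mode == "given":
        return root.weights  # type: ignore[return-value]
    try:
        x = stationary_state0_freq(rates).x_hat
    except StationaryUndefinedError as err:
        raise StationaryUndefinedError(
            "q01 = q10 = 0: the stationary root prior is undefined; pass an "
            "explicit RootMode ('equal', 'fixed0', 'fixed1' or 'given')"
        ) from err
    return x, 1.0 - x


def tip_init(observed_state: int) -> LikelihoodState:
    """Initial condition at a sampled tip: D = 1 for the observed state,
    0 for the other; extinction probabilities 0 (complete sampling)."""
    if observed_state not in (0, 1):
        raise ValueError(f"tip state must be 0 or 1, got {observed_state!r}")
    return LikelihoodState(D0=1.0 - observed_state, D1=float(observed_state))


def branch_integrate(
    init: LikelihoodState,
    rates: RateSet,
    length: float,
    cfg: IntegratorConfig | None = None,
) -> LikelihoodState:
    """Integrate E and D rootward along one branch of the given length."""
    if length < 0:
        raise ValueError("branch length must be >= 0")
    cfg = cfg or IntegratorConfig()
    if length == 0.0:
        return LikelihoodState(init.E0, init.E1, init.D0, init.D1, init.log_scale)
    h0 = cfg.step_for(length)
    y = init.as_array()
    ls, status, _, _ = _ode.integrate_branch(
        y, rates.as_array(), float(length), h0, cfg.rel_tol, cfg.abs_tol,
        cfg.clamp_lo, cfg.clamp_hi, np.empty((9, 4)))
    if status != 0:
        raise IntegrationError(status)
    return LikelihoodState(y[0], y[1], y[2], y[3], init.log_scale + ls)


def node_combine(
    left: LikelihoodState,
    right: LikelihoodState,
    rates: RateSet,
    e_tol: float = 1e-6,
) -> LikelihoodState:
    """Join two daughter lineages at a speciation node."""
    if max(abs(left.E0 - right.E0), abs(left.E1 - right.E1)) > e_tol:
        raise IntegrationError(4)
    return LikelihoodState(
        E0=0.5 * (left.E0 + right.E0),
        E1=0.5 * (left.E1 + right.E1),
        D0=rates.lambda0 * left.D0 * right.D0,
        D1=rates.lambda1 * left.D1 * right.D1,
        log_scale=left.log_scale + right.log_scale,
    )


def bisse_loglik(
    tree: PhyloTree,
    rates: RateSet,
    root: RootMode | None = None,
    cfg: IntegratorConfig | None = None,
) -> float:
    """Natural-log BiSSE likelihood of the tree and its tip states.

    Returns ``-inf`` when the data have probability zero under the rates
    (e.g. an observed state that can never be reached); raises
    :class:`IntegrationError` when the integrator cannot meet its
    tolerance within the step-size clamp.
    """
    ll, _ = bisse_loglik_with_diagnostics(tree, rates, root, cfg)
    return ll


def bisse_loglik_with_diagnostics(
    tree: PhyloTree,
    rates: RateSet,
    root: RootMode | None = None,
    cfg: IntegratorConfig | None = None,
) -> tuple[float, dict]:
    """As :func:`bisse_loglik`, also returning integrator step counts."""
    root = root or RootMode()
    cfg = cfg or IntegratorConfig()
    w0, w1 = root_weights(root, rates)
    if cfg.initial_step is not None:
        h0 = cfg.initial_step
    else:
        h = tree.height
        h0 = (h if h > 0 else 1.0) / 100.0
    d0, d1, _, _, logsum, status, node, steps, rejects = _ode.tree_loglik(
        tree.children, tree.lengths, tree.tip_states, rates.as_array(),
        h0, cfg.rel_tol, cfg.abs_tol, cfg.clamp_lo, cfg.clamp_hi,
        cfg.e_match_tol)
    diag = {"steps": int(steps), "rejects": int(rejects),
            "initial_step": h0}
    if status != 0:
        raise IntegrationError(status, node)
    lik = w0 * d0 + w1 * d1
    ll = -np.inf if lik <= 0.0 else float(np.log(lik) + logsum)
    return ll, diag
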