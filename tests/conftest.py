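"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the package's adaptive integrator:
a fixed-step classical RK4 integrator with a pure-Python pruning pass, and
a closed-form birth-death x Mk factorization for state-independent
diversification (matrix exponentials for the character, Kendall's
single-descendant probability for the tree).
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.linalg import expm

from bissekit import PhyloTree, RateSet
from bissekit.simulate import batch_rng, prune_extinct, simulate_tree


# ---------------------------------------------------------------- oracles


def bisse_rhs(y, r: RateSet):
    E0, E1, D0, D1 = y
    return np.array([
        r.mu0 - (r.lambda0 + r.mu0 + r.q01) * E0 + r.q01 * E1
        + r.lambda0 * E0 * E0,
        r.mu1 - (r.lambda1 + r.mu1 + r.q10) * E1 + r.q10 * E0
        + r.lambda1 * E1 * E1,
        -(r.lambda0 + r.mu0 + r.q01) * D0 + r.q01 * D1
        + 2.0 * r.lambda0 * E0 * D0,
        -(r.lambda1 + r.mu1 + r.q10) * D1 + r.q10 * D0
        + 2.0 * r.lambda1 * E1 * D1,
    ])


def rk4_branch(y0, rates: RateSet, length: float, n_steps: int):
    """Classical fixed-step RK4 along one branch."""
    y = np.asarray(y0, dtype=float).copy()
    h = length / n_steps
    for _ in range(n_steps):
        k1 = bisse_rhs(y, rates)
        k2 = bisse_rhs(y + 0.5 * h * k1, rates)
        k3 = bisse_rhs(y + 0.5 * h * k2, rates)
        k4 = bisse_rhs(y + h * k3, rates)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return y


def rk4_tree_loglik(tree: PhyloTree, rates: RateSet, w0: float, w1: float,
                    steps_per_branch: int = 400) -> float:
    """Pure-Python pruning pass using the fixed-step RK4 integrator."""
    n = tree.n_tips
    state = np.zeros((tree.n_nodes, 4))
    logs = np.zeros(tree.n_nodes)
    for i in range(n):
        state[i, 2 + tree.tip_states[i]] = 1.0
    for k in range(n - 1):
        node = n + k
        l, r = tree.children[k]
        for c in (l, r):
            if tree.lengths[c] > 0:
                state[c] = rk4_branch(state[c], rates, tree.lengths[c],
                                      steps_per_branch)
        assert abs(state[l, 0] - state[r, 0]) < 1e-5
        E = 0.5 * (state[l, :2] + state[r, :2])
        D0 = rates.lambda0 * state[l, 2] * state[r, 2]
        D1 = rates.lambda1 * state[l, 3] * state[r, 3]
        logs[node] = logs[l] + logs[r]
        s = D0 + D1
        if s > 0:
            logs[node] += np.log(s)
            D0, D1 = D0 / s, D1 / s
        state[node] = [E[0], E[1], D0, D1]
    root = tree.n_nodes - 1
    lik = w0 * state[root, 2] + w1 * state[root, 3]
    return float(np.log(lik) + logs[root])


def kendall_p1(t, la, mu):
    """Probability a lineage leaves exactly one descendant lineage after
    time t under a constant-rate birth-death process."""
    r = la - mu
    ert = np.exp(r * t)
    return r * r * ert / (la * ert - mu) ** 2


def bd_mk_loglik(tree: PhyloTree, la, mu, q01, q10, w0, w1) -> float:
    """Closed-form oracle for state-independent diversification: the
    likelihood factorizes into a birth-death tree term and an Mk character
    term computed with matrix exponentials."""
    d = tree.depths()
    t_from_present = d[: tree.n_tips].max() - d
    n = tree.n_tips
    Q = np.array([[-q01, q01], [q10, -q10]])
    L = np.zeros((tree.n_nodes, 2))
    for i in range(n):
        L[i, tree.tip_states[i]] = 1.0
    ln_tree = 0.0
    ln_scale = 0.0
    for k in range(n - 1):
        node = n + k
        ln_tree += np.log(la)
        prod = np.ones(2)
        for c in tree.children[k]:
            tlo, thi = t_from_present[c], t_from_present[node]
            if thi > tlo:
                ln_tree += np.log(kendall_p1(thi, la, mu))
                ln_tree -= np.log(kendall_p1(tlo, la, mu))
            prod *= expm(Q * (thi - tlo)) @ L[c]
        s = prod.sum()
        ln_scale += np.log(s)
        L[node] = prod / s
    root = tree.n_nodes - 1
    return float(ln_tree + ln_scale + np.log(w0 * L[root, 0] + w1 * L[root, 1]))


def eq1_bisection(rates: RateSet, tol: float = 1e-12) -> float:
    """Independent bisection solver for the stationary-frequency equation."""
    g = rates.lambda0 - rates.mu0 - rates.lambda1 + rates.mu1

    def f(x):
        return g * x * (1 - x) - x * rates.q01 + (1 - x) * rates.q10

    lo, hi = 0.0, 1.0
    assert f(lo) >= 0 >= f(hi)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) >= 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------- fixtures


@pytest.fixture
def cherry_tree() -> PhyloTree:
    return PhyloTree(n_tips=2, children=[[0, 1]], lengths=[1.0, 1.0, 0.0],
                     tip_states=[0, 0])


@pytest.fixture
def four_tip_tree() -> PhyloTree:
    # ((t1:1,t2:1):1,(t3:1.5,t4:1.5):0.5);
    return PhyloTree(
        n_tips=4,
        children=[[0, 1], [2, 3], [4, 5]],
        lengths=[1.0, 1.0, 1.5, 1.5, 1.0, 0.5, 0.0],
        tip_states=[0, 0, 1, 0],
    )


def simulated_tree(seed: int, n_tips: int, rates: RateSet | None = None,
                   root_state_mode: str = "stationary") -> PhyloTree:
    rates = rates or RateSet(0.1, 0.1, 0.03, 0.03, 0.01, 0.01)
    return prune_extinct(
        simulate_tree(rates, n_tips, batch_rng(seed, 0), root_state_mode))


@pytest.fixture(scope="session")
def medium_tree() -> PhyloTree:
    """One 100-tip tree under mildly asymmetric rates, reused read-only."""
    return prune_extinct(simulate_tree(
        RateSet(0.1, 0.125, 0.03, 0.03, 0.01, 0.01), 100, batch_rng(2024, 0)))
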