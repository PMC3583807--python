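"""Numba kernels for the BiSSE pruning likelihood.

Along each branch, integrating from the branch's tipward end toward the
root (time measured into the past), the per-state extinction probabilities
E and partial-likelihood densities D obey

    E0' = mu0 - (lambda0 + mu0 + q01) E0 + q01 E1 + lambda0 E0^2
    D0' = -(lambda0 + mu0 + q01) D0 + q01 D1 + 2 lambda0 E0 D0

and symmetrically with 0 <-> 1. The integrator is a Runge-Kutta-Fehlberg
4(5) embedded pair with adaptive step size; accepted steps satisfy the
mixed absolute/relative local-error tolerance, and the step is never
allowed outside [initial_step * clamp_lo, initial_step * clamp_hi]. The
higher-order (5th) solution is propagated. D values are rescaled mid-branch
when they underflow toward zero, with the log of the factors accumulated.

Status codes: 0 ok; 1 step-size underflow at the clamp floor with the
error still above tolerance; 2 extinction probability left [0, 1];
3 non-finite values; 4 sister-lineage E mismatch at a node.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Fehlberg tableau
_A21 = 1.0 / 4.0
_A31, _A32 = 3.0 / 32.0, 9.0 / 32.0
_A41, _A42, _A43 = 1932.0 / 2197.0, -7200.0 / 2197.0, 7296.0 / 2197.0
_A51, _A52, _A53, _A54 = 439.0 / 216.0, -8.0, 3680.0 / 513.0, -845.0 / 4104.0
_A61, _A62, _A63, _A64, _A65 = (-8.0 / 27.0, 2.0, -3544.0 / 2565.0,
                                1859.0 / 4104.0, -11.0 / 40.0)
_B41, _B43, _B44, _B45 = 25.0 / 216.0, 1408.0 / 2565.0, 2197.0 / 4104.0, -1.0 / 5.0
_B51, _B53, _B54, _B55, _B56 = (16.0 / 135.0, 6656.0 / 12825.0,
                                28561.0 / 56430.0, -9.0 / 50.0, 2.0 / 55.0)

_TINY_D = 1e-140


@njit(cache=True, fastmath=True)
def _rhs(y, p, dy):
    la0, la1, mu0, mu1, q01, q10 = p[0], p[1], p[2], p[3], p[4], p[5]
    E0, E1, D0, D1 = y[0], y[1], y[2], y[3]
    dy[0] = mu0 - (la0 + mu0 + q01) * E0 + q01 * E1 + la0 * E0 * E0
    dy[1] = mu1 - (la1 + mu1 + q10) * E1 + q10 * E0 + la1 * E1 * E1
    dy[2] = -(la0 + mu0 + q01) * D0 + q01 * D1 + 2.0 * la0 * E0 * D0
    dy[3] = -(la1 + mu1 + q10) * D1 + q10 * D0 + 2.0 * la1 * E1 * D1


@njit(cache=True, fastmath=True)
def integrate_branch(y, p, length, h0, rtol, atol, clamp_lo, clamp_hi,
                     work):
    """Advance (E0, E1, D0, D1) rootward along a branch of given length.

    Modifies ``y`` in place; ``work`` is a (9, 4) scratch array shared
    across calls to avoid per-branch allocations. Returns (log_rescale,
    status, n_steps, n_rejects).
    """
    logscale = 0.0
    nsteps = 0
    nrejects = 0
    if length <= 0.0:
        return logscale, 0, nsteps, nrejects
    h_min = h0 * clamp_lo
    h_max = h0 * clamp_hi
    t = 0.0
    h = min(h0, length)

    k1 = work[0]
    k2 = work[1]
    k3 = work[2]
    k4 = work[3]
    k5 = work[4]
    k6 = work[5]
    yt = work[6]
    y4 = work[7]
    y5 = work[8]

    while t < length:
        h_eff = h
        if t + h_eff > length:
            h_eff = length - t  # land exactly on the branch end

        _rhs(y, p, k1)
        for i in range(4):
            yt[i] = y[i] + h_eff * _A21 * k1[i]
        _rhs(yt, p, k2)
        for i in range(4):
            yt[i] = y[i] + h_eff * (_A31 * k1[i] + _A32 * k2[i])
        _rhs(yt, p, k3)
        for i in range(4):
            yt[i] = y[i] + h_eff * (_A41 * k1[i] + _A42 * k2[i] + _A43 * k3[i])
        _rhs(yt, p, k4)
        for i in range(4):
            yt[i] = y[i] + h_eff * (_A51 * k1[i] + _A52 * k2[i]
                                    + _A53 * k3[i] + _A54 * k4[i])
        _rhs(yt, p, k5)
        for i in range(4):
            yt[i] = y[i] + h_eff * (_A61 * k1[i] + _A62 * k2[i] + _A63 * k3[i]
                                    + _A64 * k4[i] + _A65 * k5[i])
        _rhs(yt, p, k6)

        ratio = 0.0
        for i in range(4):
            y4[i] = y[i] + h_eff * (_B41 * k1[i] + _B43 * k3[i]
                                    + _B44 * k4[i] + _B45 * k5[i])
            y5[i] = y[i] + h_eff * (_B51 * k1[i] + _B53 * k3[i] + _B54 * k4[i]
                                    + _B55 * k5[i] + _B56 * k6[i])
            sc = atol + rtol * max(abs(y[i]), abs(y5[i]))
            err = abs(y5[i] - y4[i])
            r = err / sc
            if r > ratio:
                ratio = r

        if not np.isfinite(ratio):
            return logscale, 3, nsteps, nrejects

        if ratio <= 1.0:
            # accept
            t += h_eff
            for i in range(4):
                y[i] = y5[i]
            nsteps += 1
            # extinction probabilities must stay in [0, 1]; overshoot on
            # the order of the local-error tolerance is clipped
            for i in range(2):
                if y[i] < -1e-6 or y[i] > 1.0 + 1e-6:
                    return logscale, 2, nsteps, nrejects
                if y[i] < 0.0:
                    y[i] = 0.0
                elif y[i] > 1.0:
                    y[i] = 1.0
            # mid-branch rescue of underflowing D
            dmax = max(abs(y[2]), abs(y[3]))
            if 0.0 < dmax < _TINY_D:
                y[2] /= dmax
                y[3] /= dmax
                logscale += np.log(dmax)
        else:
            nrejects += 1
            if h_eff <= h_min * (1.0 + 1e-12):
                return logscale, 1, nsteps, nrejects

        # PI-free standard step update, clamped to the configured window
        if ratio > 0.0:
            fac = 0.9 * ratio ** (-0.2)
        else:
            fac = 5.0
        if fac > 5.0:
            fac = 5.0
        elif fac < 0.1:
            fac = 0.1
        h = h_eff * fac
        if h < h_min:
            h = h_min
        elif h > h_max:
            h = h_max
    return logscale, 0, nsteps, nrejects


@njit(cache=True, fastmath=True)
def tree_loglik(children, lengths, tip_states, p, h0, rtol, atol,
                clamp_lo, clamp_hi, e_tol):
    """Post-order pruning pass over the whole tree.

    Returns (root_D0, root_D1, root_E0, root_E1, log_scale_sum, status,
    bad_node, total_steps, total_rejects). Tips are nodes 0..n_tips-1; internal node n_tips + k has
    children ``children[k]`` and every node's subtending branch length is
    ``lengths[node]``.
    """
    n_tips = tip_states.shape[0]
    n_nodes = 2 * n_tips - 1
    E = np.zeros((n_nodes, 2))
    D = np.zeros((n_nodes, 2))
    logs = np.zeros(n_nodes)
    y = np.empty(4)
    work = np.empty((9, 4))
    tot_steps = 0
    tot_rejects = 0

    # integrate every non-root branch from its child's values
    for k in range(n_tips - 1):
        node = n_tips + k
        for j in range(2):
            c = children[k, j]
            if c < n_tips:
                E[c, 0] = 0.0
                E[c, 1] = 0.0
                D[c, tip_states[c]] = 1.0
                D[c, 1 - tip_states[c]] = 0.0
            y[0] = E[c, 0]
            y[1] = E[c, 1]
            y[2] = D[c, 0]
            y[3] = D[c, 1]
            ls, status, nst, nrj = integrate_branch(
                y, p, lengths[c], h0, rtol, atol, clamp_lo, clamp_hi, work)
            tot_steps += nst
            tot_rejects += nrj
            if status != 0:
                return 0.0, 0.0, 0.0, 0.0, 0.0, status, c, tot_steps, tot_rejects
            E[c, 0], E[c, 1], D[c, 0], D[c, 1] = y[0], y[1], y[2], y[3]
            logs[c] += ls
        l = children[k, 0]
        r = children[k, 1]
        de = max(abs(E[l, 0] - E[r, 0]), abs(E[l, 1] - E[r, 1]))
        if de > e_tol:
            return 0.0, 0.0, 0.0, 0.0, 0.0, 4, node, tot_steps, tot_rejects
        E[node, 0] = 0.5 * (E[l, 0] + E[r, 0])
        E[node, 1] = 0.5 * (E[l, 1] + E[r, 1])
        d0 = p[0] * D[l, 0] * D[r, 0]
        d1 = p[1] * D[l, 1] * D[r, 1]
        logs[node] = logs[l] + logs[r]
        s = d0 + d1
        if not np.isfinite(s):
            return 0.0, 0.0, 0.0, 0.0, 0.0, 3, node, tot_steps, tot_rejects
        if s > 0.0:
            d0 /= s
            d1 /= s
            logs[node] += np.log(s)
        D[node, 0] = d0
        D[node, 1] = d1

    root = n_nodes - 1
    return (D[root, 0], D[root, 1], E[root, 0], E[root, 1],
            logs[root], 0, root, tot_steps, tot_rejects)
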