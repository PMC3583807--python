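"""Stationary character-state frequency under BiSSE rates.

Over a long-run BiSSE process, the expected proportion ``x_hat`` of lineages
in state 0 satisfies

    g * x(1 - x) - x * q01 + (1 - x) * q10 = 0,      g = l0 - m0 - l1 + m1,

a quadratic in ``x`` with exactly one root in [0, 1] whenever q01 + q10 > 0.
The expected tip ratio of a simulated clade is (1 - x_hat) : x_hat
(state 1 : state 0).

This module solves that equation in closed form, and inverts it: given a
target stationary frequency, find the rate ratio ``r`` such that placing a
process's two rates geometrically around a base value (base/sqrt(r) and
base*sqrt(r), higher diversification assigned to the favored state) hits
the target.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.optimize import brentq

from .rates import RateSet

__all__ = [
    "StationarySolution",
    "stationary_state0_freq",
    "solve_rate_ratio",
    "StationaryUndefinedError",
    "TargetUnreachableError",
]


class StationaryUndefinedError(ValueError):
    """No character change (q01 = q10 = 0): the stationary frequency of the
    character does not exist."""


class TargetUnreachableError(ValueError):
    """No rate ratio attains the requested stationary frequency."""


@dataclass(frozen=True)
class StationarySolution:
    """Root of the stationary-frequency equation for a rate set."""

    x_hat: float  #: stationary frequency of state 0, in [0, 1]
    g: float      #: lambda0 - mu0 - lambda1 + mu1

    @property
    def tip_ratio(self) -> str:
        """Nearest-integer display ratio 'N1:M0' (state 1 : state 0)."""
        if self.x_hat <= 0.0:
            return "inf:1"
        frac = Fraction((1.0 - self.x_hat) / self.x_hat).limit_denominator(1000)
        return f"{frac.numerator}:{frac.denominator}"


def _residual(x: float, g: float, q01: float, q10: float) -> float:
    return g * x * (1.0 - x) - x * q01 + (1.0 - x) * q10


def stationary_state0_freq(rates: RateSet) -> StationarySolution:
    """Solve the stationary-frequency equation for state 0.

    Closed form: when g = 0 the equation is linear with root
    q10/(q01+q10); otherwise it is the quadratic
    ``-g x^2 + (g - q01 - q10) x + q10 = 0`` and the root in [0, 1] is
    returned (exactly one exists when q01 + q10 > 0). A bisection fallback
    covers any numerically marginal case.
    """
    q01, q10 = rates.q01, rates.q10
    if q01 + q10 <= 0.0:
        raise StationaryUndefinedError(
            "stationary frequency undefined: q01 = q10 = 0")
    g = rates.lambda0 - rates.mu0 - rates.lambda1 + rates.mu1
    if g == 0.0:
        x = q10 / (q01 + q10)
        return StationarySolution(x_hat=x, g=g)
    # -g x^2 + (g - q01 - q10) x + q10 = 0
    a, b, c = -g, g - q01 - q10, q10
    disc = b * b - 4.0 * a * c
    x = np.nan
    if disc >= 0.0:
        sq = np.sqrt(disc)
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            for root in ((-b + sq) / (2.0 * a), (-b - sq) / (2.0 * a)):
                if -1e-12 <= root <= 1.0 + 1e-12:
                    x = min(1.0, max(0.0, root))
                    break
    if not np.isfinite(x) or abs(_residual(x, g, q01, q10)) > 1e-10:
        # bisection fallback; f(0) = q10 >= 0, f(1) = -q01 <= 0
        x = brentq(_residual, 0.0, 1.0, args=(g, q01, q10), xtol=1e-15)
    return StationarySolution(x_hat=float(x), g=float(g))


def solve_rate_ratio(
    process: str,
    base_rates: RateSet,
    target_x_hat: float,
    *,
    ratio_max: float = 1e6,
) -> tuple[float, RateSet]:
    """Find the asymmetry ratio in one process yielding a target frequency.

    The two rates of ``process`` are placed geometrically around their
    (symmetric) base value b as ``b/sqrt(r)`` and ``b*sqrt(r)``, with signs
    arranged so state 1 is favored when ``target_x_hat < 0.5`` (higher
    speciation in state 1, higher extinction in state 0, or more 0->1
    transitions) and state 0 favored when ``target_x_hat > 0.5``. All other
    rates keep their base values.

    Returns ``(ratio, rates_out)`` with ratio >= 1 and
    ``stationary_state0_freq(rates_out).x_hat == target_x_hat`` to 1e-8.
    """
    if not (0.0 < target_x_hat < 1.0):
        raise ValueError(f"target_x_hat must be in (0,1), got {target_x_hat}")
    r0, r1 = base_rates.process_rates(process)
    if not np.isclose(r0, r1):
        raise ValueError(
            f"base rates for {process} must be symmetric, got {r0} != {r1}")
    base = r0
    if base <= 0.0:
        raise ValueError(f"base rate for {process} must be positive")

    favored1 = target_x_hat < 0.5

    def rates_for(ratio: float) -> RateSet:
        lo, hi = base / np.sqrt(ratio), base * np.sqrt(ratio)
        if process == "speciation":
            # higher speciation in the favored state
            l0, l1 = (lo, hi) if favored1 else (hi, lo)
            return base_rates.replace(lambda0=l0, lambda1=l1)
        if process == "extinction":
            # higher extinction in the disfavored state
            m0, m1 = (hi, lo) if favored1 else (lo, hi)
            return base_rates.replace(mu0=m0, mu1=m1)
        # more transitions out of the disfavored state
        qa, qb = (hi, lo) if favored1 else (lo, hi)
        return base_rates.replace(q01=qa, q10=qb)

    def gap(log_ratio: float) -> float:
        return stationary_state0_freq(rates_for(np.exp(log_ratio))).x_hat - target_x_hat

    g0 = gap(0.0)
    if abs(g0) < 1e-14:
        return 1.0, rates_for(1.0)
    # increasing the ratio always pushes x_hat toward the favored state
    hi = np.log(ratio_max)
    ghi = gap(hi)
    if np.sign(g0) == np.sign(ghi):
        raise TargetUnreachableError(
            f"no {process} ratio in [1, {ratio_max:g}] attains "
            f"x_hat = {target_x_hat} (residuals {g0:.3g}, {ghi:.3g})")
    log_r = brentq(gap, 0.0, hi, xtol=1e-13, rtol=8.9e-16)
    ratio = float(np.exp(log_r))
    rates_out = rates_for(ratio)
    assert abs(stationary_state0_freq(rates_out).x_hat - target_x_hat) < 1e-8
    return ratio, rates_out
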