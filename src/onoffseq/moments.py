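"""Closed-form moments of the inter-birth time T.

T is the time between consecutive births.  It always starts in the
on-state and consists of ``G - 1`` on/off loops — G geometric on {1, 2, ...}
with success probability ``p = lambda_1 / (lambda_1 + q_off)`` — followed by
the passage through the L birth phases.  Wald's equation for geometric sums
gives closed forms for its mean and variance:

    E[T]   = sum_i 1/lambda_i + q_off / (q_on * lambda_1)
    Var[T] = sum_i 1/lambda_i^2
             + (2 q_off lambda_1 + q_off^2 + 2 q_on q_off) / (lambda_1^2 q_on^2)

For q_off = 0 (or no switch) T is plain hypoexponential.  These moments are
invariant under permutations of lambda_2..lambda_L — the root cause of the
identifiability problem that order constraints resolve.
"""

from __future__ import annotations

import numpy as np

from .model import InvalidParameterError, Params

__all__ = [
    "loop_success_probability",
    "expected_interbirth",
    "var_interbirth",
    "Ecdf",
    "ecdf",
]


def _switch_rates(params: Params) -> tuple[float, float]:
    q_on = params.q_on if params.has_switch else 0.0
    q_off = params.q_off if params.has_switch else 0.0
    if q_off > 0 and q_on <= 0:
        raise InvalidParameterError(
            "q_off > 0 with q_on = 0: the off-period never ends and T has "
            "infinite mean"
        )
    return q_on, q_off


def loop_success_probability(params: Params) -> float:
    """P(no further off-loop) = lambda_1 / (lambda_1 + q_off)."""
    _, q_off = _switch_rates(params)
    return params.lambdas[0] / (params.lambdas[0] + q_off)


def expected_interbirth(params: Params) -> float:
    """E[T] = sum_i 1/lambda_i + q_off / (q_on * lambda_1)."""
    q_on, q_off = _switch_rates(params)
    base = sum(1.0 / lam for lam in params.lambdas)
    if q_off == 0:
        return base
    return base + q_off / (q_on * params.lambdas[0])


def var_interbirth(params: Params) -> float:
    """Var[T] via Wald's equation for the geometric sum of loops."""
    q_on, q_off = _switch_rates(params)
    base = sum(1.0 / lam**2 for lam in params.lambdas)
    if q_off == 0:
        return base
    lam1 = params.lambdas[0]
    return base + (2 * q_off * lam1 + q_off**2 + 2 * q_on * q_off) / (lam1**2 * q_on**2)


class Ecdf:
    """Right-continuous empirical distribution function of sampled times."""

    def __init__(self, samples) -> None:
        samples = np.asarray(samples, dtype=float)
        if samples.size == 0:
            raise ValueError("ecdf needs at least one sample")
        self.x = np.sort(samples)
        self.n = samples.size

    def __call__(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        vals = np.searchsorted(self.x, t, side="right") / self.n
        return vals if vals.ndim else float(vals)

    def as_pairs(self) -> np.ndarray:
        """Sorted (t, F(t)) step points, one row per sample."""
        return np.column_stack([self.x, np.arange(1, self.n + 1) / self.n])


def ecdf(samples) -> Ecdf:
    """Empirical distribution function as an evaluable step function."""
    return Ecdf(samples)
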