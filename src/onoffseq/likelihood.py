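"""Likelihood of discretely observed counts via the hidden-phase forward
recursion.

The log-likelihood of N independent series is the sum of per-series terms;
each series term sums, over all hidden phase paths, the product of lag-Delta
transition probabilities.  That sum is computed by a scaled forward
recursion over the phase marginal (the phase set has at most L+1 elements),
with the Erlangization kernel supplying the transition probabilities.

The first factor of the per-series likelihood is treated by *conditioning*
on the observed initial count: only the initial phase gets a law, the
stationary distribution of the phase chain.  (With mu = 0 the count process
is a pure birth process and has no stationary law, so an unconditional
model for M_0 would be undefined exactly in the pure-birth designs.)
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .kernel import DEFAULT_ELL, TransitionKernel, erlang_kernel
from .model import InvalidParameterError, ModelSpec, Params, build_generator, stationary_phase_distribution
from .simulate import ObservationSet, TimeSeries

__all__ = [
    "LOGZERO",
    "TruncationError",
    "LogLikelihood",
    "initial_phase_weights",
    "series_loglik",
    "brute_force_loglik",
    "total_loglik",
]

#: Signed log-zero sentinel returned for series of probability zero; large
#: and finite so an optimizer can keep searching instead of crashing.
LOGZERO = -1e15


class TruncationError(RuntimeError):
    """An observed count exceeds the kernel's truncation level C."""


@dataclass(frozen=True)
class LogLikelihood:
    """Total log-likelihood with its per-series decomposition."""

    value: float
    per_series: np.ndarray
    params: Params
    C: int
    ell: int
    delta: float


def initial_phase_weights(params: Params, spec: ModelSpec, m0: int = 0) -> np.ndarray:
    """Law of the initial phase X_0 (the level m0 is conditioned on).

    Returns the stationary phase distribution regardless of m0; the count
    m0 only determines at which level the mass is placed.
    """
    if m0 < 0:
        raise InvalidParameterError(f"m0 must be >= 0, got {m0}")
    return stationary_phase_distribution(params, spec)


def _forward_equal_length(
    P4: np.ndarray, pi: np.ndarray, counts: np.ndarray
) -> np.ndarray:
    """Scaled forward recursion for a batch of equal-length series.

    ``counts`` is (N, n+1); returns the (N,) vector of log-likelihoods.
    ``P4`` is the kernel reshaped to (C+1, nE, C+1, nE).
    """
    N, n_obs = counts.shape
    loglik = np.zeros(N)
    if n_obs == 1:
        return loglik
    alive = np.ones(N, dtype=bool)
    alpha = np.broadcast_to(pi, (N, pi.size)).copy()
    # one gather of all per-step phase blocks: (N, n, nE, nE)
    all_blocks = P4[counts[:, :-1], :, counts[:, 1:], :]
    for i in range(1, n_obs):
        blocks = all_blocks[:, i - 1]
        alpha = np.einsum("ne,nef->nf", alpha, blocks)
        scale = alpha.sum(axis=1)
        dead = alive & (scale <= 0.0)
        if dead.any():
            loglik[dead] = LOGZERO
            alive &= ~dead
        loglik[alive] += np.log(scale[alive])
        # dead series keep a harmless uniform forward vector
        scale[~alive] = 1.0
        alpha /= scale[:, None]
        alpha[~alive] = 1.0 / alpha.shape[1]
    return loglik


def series_loglik(
    kernel: TransitionKernel, params: Params, spec: ModelSpec, series: TimeSeries
) -> float:
    """Log-probability of one series given the observed initial count.

    Computes ``log sum_{x_0..x_n} pi(x_0) prod_i p_{x_{i-1} x_i}(m_{i-1},
    m_i; Delta)`` by the forward recursion, rescaling the forward vector to
    sum one at each step.  Returns the LOGZERO sentinel for a series of
    probability zero.
    """
    if series.delta != kernel.delta:
        raise InvalidParameterError(
            f"series delta {series.delta} differs from kernel delta {kernel.delta}"
        )
    C = kernel.statespace.C
    if series.counts.max() > C:
        raise TruncationError(
            f"series contains count {int(series.counts.max())} > truncation "
            f"level C={C}; enlarge C"
        )
    pi = initial_phase_weights(params, spec, int(series.counts[0]))
    out = _forward_equal_length(kernel.blocks(), pi, series.counts[None, :])
    return float(out[0])


def brute_force_loglik(
    kernel: TransitionKernel, params: Params, spec: ModelSpec, series: TimeSeries
) -> float:
    """Literal sum over all hidden phase paths (test oracle, tiny n only)."""
    nE = spec.n_phases
    n = series.n
    if nE ** (n + 1) > 1_000_000:
        raise ValueError(f"{nE ** (n + 1)} phase paths is too many to enumerate")
    if series.counts.max() > kernel.statespace.C:
        raise TruncationError("count exceeds truncation level C")
    pi = initial_phase_weights(params, spec, int(series.counts[0]))
    P4 = kernel.blocks()
    m = series.counts
    total = 0.0
    for path in itertools.product(range(nE), repeat=n + 1):
        prob = pi[path[0]]
        for i in range(1, n + 1):
            prob *= P4[m[i - 1], path[i - 1], m[i], path[i]]
        total += prob
    return float(np.log(total)) if total > 0 else LOGZERO


def total_loglik(
    params: Params,
    spec: ModelSpec,
    data: ObservationSet,
    C: int,
    ell: int = DEFAULT_ELL,
    kernel: TransitionKernel | None = None,
) -> LogLikelihood:
    """Log-likelihood of N independent series (variable lengths allowed).

    Builds the generator and Erlangization kernel once for this parameter
    vector, then runs the forward recursion batched over series of equal
    length.
    """
    if data.max_count > C:
        raise TruncationError(
            f"data contains count {data.max_count} > truncation level C={C}"
        )
    if kernel is None:
        kernel = erlang_kernel(build_generator(params, spec, C), data.delta, ell)
    P4 = kernel.blocks()
    pi = stationary_phase_distribution(params, spec)
    per_series = np.empty(data.N)
    by_length: dict[int, list[int]] = {}
    for idx, s in enumerate(data.series):
        by_length.setdefault(s.n, []).append(idx)
    for n, idxs in by_length.items():
        counts = np.stack([data.series[i].counts for i in idxs])
        per_series[idxs] = _forward_equal_length(P4, pi, counts)
    return LogLikelihood(
        value=float(per_series.sum()),
        per_series=per_series,
        params=params,
        C=C,
        ell=kernel.ell,
        delta=data.delta,
    )
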