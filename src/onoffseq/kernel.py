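"""Erlangization approximation of the lag-Delta transition kernel.

The transition probabilities ``p_{xx'}(m, m'; Delta)`` of the truncated QBD
are hard to compute at a deterministic lag, but easy at an exponential one:
the state distribution at an Exp(eta) time is the resolvent kernel
``Pi_eta = eta (eta I - Q)^{-1}``, obtained from one linear solve.  An
Erlang(ell, ell/Delta) time concentrates on Delta as ell grows, so
``(Pi_{ell/Delta})^ell`` converges to the lag-Delta kernel; with ell a power
of two the power is computed by exact repeated squaring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .model import (
    Generator,
    InvalidParameterError,
    ModelSpec,
    Params,
    StateSpace,
    build_generator,
)

__all__ = [
    "TransitionKernel",
    "resolvent_kernel",
    "erlang_kernel",
    "matrix_exponential_oracle",
    "choose_truncation",
]

#: Entries more negative than this in a resolvent solve indicate a broken
#: system rather than benign roundoff, and raise instead of being clipped.
NEG_TOL = 1e-12

DEFAULT_ELL = 2048
DEFAULT_EPSILON = 1e-8


@dataclass(frozen=True)
class TransitionKernel:
    """Row-stochastic D x D approximation of the lag-Delta probabilities."""

    P: np.ndarray
    delta: float
    ell: int
    statespace: StateSpace

    def blocks(self) -> np.ndarray:
        """View P as a (C+1, nE, C+1, nE) array indexed (m, x, m', x')."""
        nE, Cp1 = self.statespace.n_phases, self.statespace.C + 1
        return self.P.reshape(Cp1, nE, Cp1, nE)


def _clip_and_renormalize(P: np.ndarray) -> np.ndarray:
    low = P.min()
    if low < -NEG_TOL:
        raise FloatingPointError(
            f"resolvent solve produced entry {low:.3e} < -{NEG_TOL:.0e}; "
            "the linear system is numerically broken"
        )
    if low < 0.0:
        np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


def resolvent_kernel(gen: Generator, eta: float) -> np.ndarray:
    """State distribution at an Exp(eta) time: ``eta (eta I - Q)^{-1}``.

    One LU factorization of ``(eta I - Q)`` serves all D right-hand sides.
    Tiny negative entries from roundoff are clipped and each row
    renormalized; entries below ``-1e-12`` raise.
    """
    if eta <= 0:
        raise InvalidParameterError(f"eta must be > 0, got {eta}")
    Q = gen.Q
    D = Q.shape[0]
    A = eta * np.eye(D) - Q
    # the level-major QBD generator is banded with bandwidth n_phases;
    # exploit that when it holds, fall back to dense LU otherwise
    band = min(gen.statespace.n_phases, D - 1)
    banded = (
        D > 1
        and np.abs(np.triu(A, band + 1)).max() == 0.0
        and np.abs(np.tril(A, -band - 1)).max() == 0.0
    )
    if banded:
        ab = np.zeros((2 * band + 1, D))
        for offset in range(-band, band + 1):
            diag = np.diagonal(A, offset)
            if offset >= 0:
                ab[band - offset, offset:] = diag
            else:
                ab[band - offset, : D + offset] = diag
        P = eta * sla.solve_banded((band, band), ab, np.eye(D))
    else:
        lu, piv = sla.lu_factor(A)
        P = eta * sla.lu_solve((lu, piv), np.eye(D))
    return _clip_and_renormalize(P)


def erlang_kernel(gen: Generator, delta: float, ell: int = DEFAULT_ELL) -> TransitionKernel:
    """Lag-Delta kernel as the ell-fold power of the resolvent.

    ``ell`` must be a power of two so the power is log2(ell) exact repeated
    squarings; every intermediate power is renormalized to stay
    row-stochastic to machine precision.
    """
    if delta <= 0:
        raise InvalidParameterError(f"delta must be > 0, got {delta}")
    if ell < 1 or (ell & (ell - 1)) != 0:
        raise InvalidParameterError(f"ell must be a power of two >= 1, got {ell}")
    P = resolvent_kernel(gen, ell / delta)
    for _ in range(ell.bit_length() - 1):
        P = P @ P
        P /= P.sum(axis=1, keepdims=True)
    return TransitionKernel(P=P, delta=delta, ell=ell, statespace=gen.statespace)


def matrix_exponential_oracle(gen: Generator, delta: float) -> np.ndarray:
    """``e^{Q Delta}`` by uniformization (test oracle for small D).

    With ``lam_bar = max_i |Q_ii|`` and ``P_bar = I + Q / lam_bar``, the
    matrix exponential is the Poisson(lam_bar * Delta)-weighted sum of
    powers of ``P_bar``; terms are added until the remaining Poisson tail
    mass drops below 1e-12.
    """
    if delta < 0:
        raise InvalidParameterError(f"delta must be >= 0, got {delta}")
    Q = gen.Q
    D = Q.shape[0]
    lam_bar = float(np.max(np.abs(np.diag(Q))))
    if delta == 0.0 or lam_bar == 0.0:
        return np.eye(D)
    Pbar = np.eye(D) + Q / lam_bar
    rate = lam_bar * delta
    weight = np.exp(-rate)
    term = np.eye(D)
    out = weight * term
    accumulated = weight
    j = 0
    while accumulated < 1.0 - 1e-12:
        j += 1
        weight *= rate / j
        term = term @ Pbar
        out += weight * term
        accumulated += weight
    return out


def choose_truncation(
    params: Params,
    spec: ModelSpec,
    data_max: int,
    delta: float,
    epsilon: float = DEFAULT_EPSILON,
    ell: int = DEFAULT_ELL,
    hard_cap: int = 100_000,
) -> int:
    """Smallest truncation level C on a doubling schedule with negligible
    one-lag mass near the boundary.

    Starting from ``max(2 * data_max, 20)`` and doubling, C is accepted once
    the kernel built at C puts total probability less than ``epsilon`` on
    the top 10% of levels within one lag from any state at a level at most
    ``data_max``.  Always returns at least ``data_max + 1``.
    """
    if not (0.0 < epsilon < 1.0):
        raise InvalidParameterError(f"epsilon must be in (0,1), got {epsilon}")
    if data_max < 0:
        raise InvalidParameterError(f"data_max must be >= 0, got {data_max}")
    C = max(2 * data_max, 20)
    while C <= hard_cap:
        kern = erlang_kernel(build_generator(params, spec, C), delta, ell)
        nE = kern.statespace.n_phases
        top_start = int(np.floor(0.9 * C)) + 1
        P = kern.P
        rows = P[: (data_max + 1) * nE, top_start * nE :]
        if rows.sum(axis=1).max() < epsilon:
            return max(C, data_max + 1)
        C *= 2
    raise RuntimeError(
        f"no adequate truncation level found below {hard_cap}; check that the "
        "birth rates and lag are sensible"
    )
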