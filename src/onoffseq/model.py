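"""Model family, parameters, and the quasi birth-death generator.

The on/off-seq-L process is a bivariate continuous-time Markov chain
``(X_t, M_t)``: ``M_t`` is the molecule count (the *level*) and ``X_t`` is a
hidden *phase* chain on ``E = {0, 1, ..., L}`` tracking the promoter switch
(0 = off, 1 = on) and the progress of the sequential birth phases
(``2..L``).  Births require completing L exponential phases and can only be
initiated while the switch is on; each molecule dies independently at rate
``mu``.  Truncating the level at ``C`` makes the joint chain a finite quasi
birth-death process with a block-tridiagonal generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg as sla

__all__ = [
    "InvalidParameterError",
    "SingularityError",
    "ModelSpec",
    "Params",
    "StateSpace",
    "QBDBlocks",
    "Generator",
    "build_blocks",
    "assemble_generator",
    "build_generator",
    "marginal_phase_generator",
    "stationary_phase_distribution",
]


class InvalidParameterError(ValueError):
    """A rate is negative, missing, or inconsistent with the model spec."""


class SingularityError(RuntimeError):
    """The marginal phase chain has no unique stationary distribution."""


@dataclass(frozen=True)
class ModelSpec:
    """Which on/off-seq-L variant is being considered.

    Parameters
    ----------
    L
        Number of sequential exponential birth phases (>= 1).
    has_switch
        Whether the on/off promoter switch is part of the model.  Without it
        the phase chain lives on ``{1, ..., L}`` and ``q_on``/``q_off`` are
        absent (the "seq-L" variants).
    tied_lambdas
        If True all phase rates share a single value ``lambda``.
    fixed
        Mapping of parameter names held at known values and therefore not
        counted as free (e.g. ``{"mu": 0.0}`` for a pure-birth fit).
    """

    L: int
    has_switch: bool = True
    tied_lambdas: bool = False
    fixed: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.L < 1:
            raise InvalidParameterError(f"L must be >= 1, got {self.L}")
        object.__setattr__(self, "fixed", dict(self.fixed))
        for name in self.fixed:
            if name not in self.param_names:
                raise InvalidParameterError(
                    f"fixed parameter {name!r} is not a parameter of this model"
                )

    @property
    def param_names(self) -> tuple[str, ...]:
        names: list[str] = []
        if self.has_switch:
            names += ["q_on", "q_off"]
        if self.tied_lambdas:
            names.append("lam")
        else:
            names += [f"lam_{i}" for i in range(1, self.L + 1)]
        names.append("mu")
        return tuple(names)

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.param_names if n not in self.fixed)

    @property
    def k(self) -> int:
        """Number of free parameters (the AIC dimension)."""
        return len(self.free_names)

    @property
    def phases(self) -> tuple[int, ...]:
        """Phase labels in rank order (0 = off, only with the switch)."""
        first = 0 if self.has_switch else 1
        return tuple(range(first, self.L + 1))

    @property
    def n_phases(self) -> int:
        return self.L + 1 if self.has_switch else self.L


@dataclass(frozen=True)
class Params:
    """Rate vector theta of an on/off-seq-L process.

    ``lambdas`` has length L; ``q_on``/``q_off`` must be present iff the
    model has the switch.  All rates are per unit time.
    """

    lambdas: tuple[float, ...]
    mu: float = 0.0
    q_on: float | None = None
    q_off: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "lambdas", tuple(float(v) for v in self.lambdas))
        if any(lam <= 0 for lam in self.lambdas):
            raise InvalidParameterError(f"all phase rates must be > 0, got {self.lambdas}")
        if self.mu < 0:
            raise InvalidParameterError(f"mu must be >= 0, got {self.mu}")
        for name in ("q_on", "q_off"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise InvalidParameterError(f"{name} must be >= 0, got {v}")

    @property
    def L(self) -> int:
        return len(self.lambdas)

    @property
    def has_switch(self) -> bool:
        return self.q_on is not None

    def check_spec(self, spec: ModelSpec) -> None:
        if spec.L != self.L:
            raise InvalidParameterError(f"spec has L={spec.L} but params have L={self.L}")
        if spec.has_switch != (self.q_on is not None and self.q_off is not None):
            raise InvalidParameterError("switch rates must be present iff the model has a switch")
        if spec.tied_lambdas and len(set(self.lambdas)) > 1:
            raise InvalidParameterError("tied_lambdas spec requires equal phase rates")

    def theta(self) -> np.ndarray:
        """Full rate vector (q_on, q_off, lambda_1..lambda_L, mu) as printed."""
        head = [self.q_on, self.q_off] if self.has_switch else []
        return np.array(head + list(self.lambdas) + [self.mu], dtype=float)

    @classmethod
    def from_dict(cls, spec: ModelSpec, values: Mapping[str, float]) -> "Params":
        """Build Params from a name -> value mapping matching ``spec``."""
        if spec.tied_lambdas:
            lambdas = (values["lam"],) * spec.L
        else:
            lambdas = tuple(values[f"lam_{i}"] for i in range(1, spec.L + 1))
        kw = {}
        if spec.has_switch:
            kw = {"q_on": values["q_on"], "q_off": values["q_off"]}
        return cls(lambdas=lambdas, mu=values.get("mu", 0.0), **kw)

    def to_dict(self, spec: ModelSpec) -> dict[str, float]:
        out: dict[str, float] = {}
        if spec.has_switch:
            out["q_on"] = float(self.q_on)
            out["q_off"] = float(self.q_off)
        if spec.tied_lambdas:
            out["lam"] = float(self.lambdas[0])
        else:
            for i, lam in enumerate(self.lambdas, start=1):
                out[f"lam_{i}"] = float(lam)
        out["mu"] = float(self.mu)
        return out


@dataclass(frozen=True)
class StateSpace:
    """Level-major flat indexing of the truncated joint chain.

    State ``(x, m)`` with phase ``x`` of rank ``r`` and level ``m`` in
    ``0..C`` sits at flat position ``m * n_phases + r``, so the generator is
    block tridiagonal with bandwidth ``n_phases``.
    """

    L: int
    C: int
    has_switch: bool = True

    @property
    def phases(self) -> tuple[int, ...]:
        first = 0 if self.has_switch else 1
        return tuple(range(first, self.L + 1))

    @property
    def n_phases(self) -> int:
        return self.L + 1 if self.has_switch else self.L

    @property
    def D(self) -> int:
        return self.n_phases * (self.C + 1)

    def rank(self, phase: int) -> int:
        return phase if self.has_switch else phase - 1

    def flat(self, phase: int, m: int) -> int:
        if not (0 <= m <= self.C):
            raise IndexError(f"level {m} outside 0..{self.C}")
        return m * self.n_phases + self.rank(phase)

    def unflat(self, idx: int) -> tuple[int, int]:
        m, r = divmod(idx, self.n_phases)
        phase = r if self.has_switch else r + 1
        return phase, m


@dataclass(frozen=True)
class QBDBlocks:
    """Level blocks of the truncated QBD generator.

    ``within_level[m]`` holds the phase jumps at fixed level m (row sums
    zero in isolation), ``births[m]`` the level m -> m+1 jumps (the single
    entry ``lambda_L`` at phase L -> phase 1), and ``deaths[m]`` the
    m -> m-1 jumps (``m * mu`` times the identity).
    """

    within_level: tuple[np.ndarray, ...]
    births: tuple[np.ndarray, ...]
    deaths: tuple[np.ndarray, ...]
    statespace: StateSpace


@dataclass(frozen=True)
class Generator:
    """Assembled D x D rate matrix of the truncated joint chain."""

    Q: np.ndarray
    statespace: StateSpace


def build_blocks(params: Params, spec: ModelSpec, C: int) -> QBDBlocks:
    """Build the level blocks of the on/off-seq-L generator truncated at C.

    Within a level: ``q_on`` (0 -> 1), ``q_off`` (1 -> 0) and ``lambda_i``
    (i -> i+1 for i < L).  The completion of the last phase, ``lambda_L`` at
    (L -> 1), increases the level by one and therefore lives in the birth
    block; deaths occur at rate ``m * mu`` without moving the phase.
    """
    params.check_spec(spec)
    if C < 1:
        raise InvalidParameterError(f"truncation level C must be >= 1, got {C}")
    ss = StateSpace(L=spec.L, C=C, has_switch=spec.has_switch)
    nE = ss.n_phases
    lam = params.lambdas
    L = spec.L

    W = np.zeros((nE, nE))
    if spec.has_switch:
        W[ss.rank(0), ss.rank(1)] = params.q_on
        W[ss.rank(1), ss.rank(0)] = params.q_off
    for i in range(1, L):
        W[ss.rank(i), ss.rank(i + 1)] = lam[i - 1]
    np.fill_diagonal(W, 0.0)
    np.fill_diagonal(W, -W.sum(axis=1))

    B = np.zeros((nE, nE))
    B[ss.rank(L), ss.rank(1)] = lam[L - 1]

    within = tuple(W.copy() for _ in range(C + 1))
    births = tuple(B.copy() for _ in range(C))
    deaths = tuple(m * params.mu * np.eye(nE) for m in range(1, C + 1))
    return QBDBlocks(within_level=within, births=births, deaths=deaths, statespace=ss)


def assemble_generator(blocks: QBDBlocks) -> Generator:
    """Assemble the block-tridiagonal generator with zero row sums.

    The diagonal blocks are the within-level blocks with their diagonals
    re-adjusted so that each *full* row of Q sums to zero (they therefore
    depend on the level, unlike the raw within-level blocks).  At level C
    the birth block is absent: the process waits there for a death.
    """
    ss = blocks.statespace
    nE, C, D = ss.n_phases, ss.C, ss.D
    for name, blist, count in (
        ("within_level", blocks.within_level, C + 1),
        ("births", blocks.births, C),
        ("deaths", blocks.deaths, C),
    ):
        if len(blist) != count or any(b.shape != (nE, nE) for b in blist):
            raise ValueError(f"{name} blocks inconsistent with state space")

    Q = np.zeros((D, D))
    for m in range(C + 1):
        sl = slice(m * nE, (m + 1) * nE)
        Q[sl, sl] = blocks.within_level[m]
        if m < C:
            Q[sl, slice((m + 1) * nE, (m + 2) * nE)] = blocks.births[m]
        if m > 0:
            Q[sl, slice((m - 1) * nE, m * nE)] = blocks.deaths[m - 1]
    d = np.arange(D)
    Q[d, d] = 0.0
    Q[d, d] = -Q.sum(axis=1)
    return Generator(Q=Q, statespace=ss)


def build_generator(params: Params, spec: ModelSpec, C: int) -> Generator:
    """Convenience: ``assemble_generator(build_blocks(...))``."""
    return assemble_generator(build_blocks(params, spec, C))


def marginal_phase_generator(params: Params, spec: ModelSpec) -> np.ndarray:
    """Generator of the phase chain X alone, on the phase set.

    Includes the wrap-around ``lambda_L`` (L -> 1) transition since it moves
    X; for L = 1 that transition is a self-loop of X and is omitted (it does
    not move the phase, only the level).
    """
    params.check_spec(spec)
    nE = spec.n_phases
    rank = (lambda p: p) if spec.has_switch else (lambda p: p - 1)
    QX = np.zeros((nE, nE))
    if spec.has_switch:
        QX[rank(0), rank(1)] = params.q_on
        QX[rank(1), rank(0)] = params.q_off
    for i in range(1, spec.L):
        QX[rank(i), rank(i + 1)] = params.lambdas[i - 1]
    if spec.L > 1:
        QX[rank(spec.L), rank(1)] = params.lambdas[-1]
    np.fill_diagonal(QX, 0.0)
    np.fill_diagonal(QX, -QX.sum(axis=1))
    return QX


def stationary_phase_distribution(params: Params, spec: ModelSpec) -> np.ndarray:
    """Stationary distribution pi of the marginal phase chain.

    Solves ``pi Q_X = 0`` with the normalization ``sum(pi) = 1`` by replacing
    one balance equation with the normalization row.  This is the law of the
    initial phase ``X_0``.
    """
    params.check_spec(spec)
    if spec.has_switch:
        if params.q_on <= 0 and params.q_off > 0:
            raise SingularityError(
                "q_on = 0 with q_off > 0: the off-state is absorbing and the "
                "phase chain has no meaningful stationary law"
            )
    nE = spec.n_phases
    if nE == 1:
        return np.ones(1)
    QX = marginal_phase_generator(params, spec)
    A = QX.T.copy()
    A[-1, :] = 1.0
    b = np.zeros(nE)
    b[-1] = 1.0
    try:
        pi = sla.solve(A, b)
    except sla.LinAlgError as exc:  # pragma: no cover - defensive
        raise SingularityError("phase chain stationary solve is singular") from exc
    if not np.all(np.isfinite(pi)) or np.any(pi < -1e-10):
        raise SingularityError(
            f"phase chain is degenerate for these rates (pi = {pi})"
        )
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()
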