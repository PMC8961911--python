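"""Exact stochastic simulation of the on/off-seq-L process.

Event-driven (Gillespie) simulation of the joint chain ``(X_t, M_t)`` with
no level truncation, gridded observation at a fixed lag, and direct
sampling of inter-birth times from their geometric-sum representation:
an inter-birth time is ``G - 1`` on/off loops (G geometric with success
probability ``lambda_1 / (lambda_1 + q_off)``) followed by the passage
through the L birth phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import InvalidParameterError, ModelSpec, Params, stationary_phase_distribution

__all__ = [
    "TimeSeries",
    "ObservationSet",
    "simulate_path",
    "sample_series",
    "sample_dataset",
    "sample_interbirth_times",
]


@dataclass(frozen=True)
class TimeSeries:
    """Molecule counts of one cell observed at a fixed lag.

    ``counts[i]`` is the count at time ``i * delta``; consecutive counts may
    differ by more than one since many events can occur within one lag.
    """

    counts: np.ndarray
    delta: float
    series_id: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise InvalidParameterError("counts must be integers")
        counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise InvalidParameterError("counts must be non-negative")
        if self.delta <= 0:
            raise InvalidParameterError(f"delta must be > 0, got {self.delta}")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        """Number of lags (observations minus one)."""
        return len(self.counts) - 1


@dataclass(frozen=True)
class ObservationSet:
    """N independent count series sharing one observation lag."""

    series: tuple[TimeSeries, ...]
    delta: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "series", tuple(self.series))
        if not self.series:
            raise InvalidParameterError("an ObservationSet needs at least one series")
        if any(s.delta != self.delta for s in self.series):
            raise InvalidParameterError("all series must share the common delta")

    @property
    def N(self) -> int:
        return len(self.series)

    @property
    def max_count(self) -> int:
        return int(max(s.counts.max() for s in self.series))


@dataclass
class Path:
    """Right-continuous piecewise-constant trajectory (jump representation)."""

    times: np.ndarray      # jump epochs, starting at 0.0
    phases: np.ndarray     # phase after each epoch
    counts: np.ndarray     # level after each epoch

    def state_at(self, t: float) -> tuple[int, int]:
        i = int(np.searchsorted(self.times, t, side="right")) - 1
        return int(self.phases[i]), int(self.counts[i])


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _draw_initial_phase(params: Params, spec: ModelSpec, rng: np.random.Generator) -> int:
    pi = stationary_phase_distribution(params, spec)
    return int(spec.phases[rng.choice(len(pi), p=pi)])


def _step(params: Params, spec: ModelSpec, x: int, m: int, rng: np.random.Generator):
    """One Gillespie step from state (x, m); returns (dt, x', m')."""
    lam = params.lambdas
    L = spec.L
    rates: list[float] = []
    targets: list[tuple[int, int]] = []
    if spec.has_switch and x == 0:
        rates.append(params.q_on)
        targets.append((1, m))
    else:
        if spec.has_switch and x == 1:
            rates.append(params.q_off)
            targets.append((0, m))
        if x < L:
            rates.append(lam[x - 1])
            targets.append((x + 1, m))
        else:  # completion of the last phase: a birth
            rates.append(lam[L - 1])
            targets.append((1, m + 1))
    if m > 0 and params.mu > 0:
        rates.append(m * params.mu)
        targets.append((x, m - 1))
    total = sum(rates)
    if total <= 0:
        return np.inf, x, m
    dt = rng.exponential(1.0 / total)
    u = rng.random() * total
    acc = 0.0
    for r, (xn, mn) in zip(rates, targets):
        acc += r
        if u <= acc:
            return dt, xn, mn
    return dt, *targets[-1]  # pragma: no cover - roundoff guard


def simulate_path(
    params: Params,
    spec: ModelSpec,
    t_max: float,
    m0: int = 0,
    rng=None,
    x0: int | None = None,
) -> Path:
    """Exact event path of ``(X_t, M_t)`` on [0, t_max], unbounded level.

    ``X_0`` is drawn from the stationary phase distribution unless ``x0`` is
    given.  The returned path records the state after every jump.
    """
    if t_max <= 0:
        raise InvalidParameterError(f"t_max must be > 0, got {t_max}")
    if m0 < 0:
        raise InvalidParameterError(f"m0 must be >= 0, got {m0}")
    params.check_spec(spec)
    rng = _as_rng(rng)
    x = _draw_initial_phase(params, spec, rng) if x0 is None else x0
    m = m0
    t = 0.0
    times, phases, counts = [0.0], [x], [m]
    while True:
        dt, xn, mn = _step(params, spec, x, m, rng)
        t += dt
        if t > t_max:
            break
        x, m = xn, mn
        times.append(t)
        phases.append(x)
        counts.append(m)
    return Path(np.asarray(times), np.asarray(phases), np.asarray(counts))


def _sample_grid(
    params: Params,
    spec: ModelSpec,
    n: int,
    delta: float,
    m0: int,
    rng: np.random.Generator,
    x0: int | None = None,
) -> np.ndarray:
    """Counts at the grid times 0, delta, ..., n*delta (path discarded)."""
    x = _draw_initial_phase(params, spec, rng) if x0 is None else x0
    m = m0
    t = 0.0
    counts = np.empty(n + 1, dtype=np.int64)
    counts[0] = m0
    next_idx = 1
    while next_idx <= n:
        dt, xn, mn = _step(params, spec, x, m, rng)
        t_new = t + dt
        while next_idx <= n and next_idx * delta < t_new:
            counts[next_idx] = m
            next_idx += 1
        x, m, t = xn, mn, t_new
    return counts


def sample_series(
    params: Params,
    spec: ModelSpec,
    n: int,
    delta: float,
    m0: int = 0,
    rng=None,
    series_id: str = "",
    x0: int | None = None,
) -> TimeSeries:
    """One simulated count series with n+1 observations at lag delta."""
    if n < 0:
        raise InvalidParameterError(f"n must be >= 0, got {n}")
    if delta <= 0:
        raise InvalidParameterError(f"delta must be > 0, got {delta}")
    params.check_spec(spec)
    rng = _as_rng(rng)
    counts = _sample_grid(params, spec, n, delta, m0, rng, x0=x0)
    return TimeSeries(counts=counts, delta=delta, series_id=series_id)


def sample_dataset(
    params: Params,
    spec: ModelSpec,
    N: int,
    lengths,
    delta: float = 1.0,
    m0: int = 0,
    rng=None,
    x0: int | None = None,
) -> ObservationSet:
    """N independent series on independent RNG substreams.

    ``lengths`` is one n broadcast to all series or a per-series sequence
    (series k then has ``lengths[k] + 1`` observations).  Substreams are
    spawned per series index from the root seed, so increasing N leaves the
    earlier series unchanged.  ``x0`` fixes the initial phase of every cell
    (default: a fresh stationary draw per cell).
    """
    if N < 1:
        raise InvalidParameterError(f"N must be >= 1, got {N}")
    ns = np.broadcast_to(np.asarray(lengths, dtype=int), (N,))
    if isinstance(rng, np.random.Generator):
        children = rng.spawn(N)
    else:
        children = [np.random.default_rng(s) for s in np.random.SeedSequence(rng).spawn(N)]
    series = tuple(
        sample_series(params, spec, int(ns[k]), delta, m0=m0, rng=children[k],
                      series_id=f"cell_{k:04d}", x0=x0)
        for k in range(N)
    )
    return ObservationSet(series=series, delta=delta)


def sample_interbirth_times(params: Params, B: int, rng=None) -> np.ndarray:
    """B draws of the inter-birth time T from its geometric-sum form.

    T is a geometric number ``G - 1`` of on/off loops, each the sum of an
    Exp(lambda_1 + q_off) and an Exp(q_on) duration, plus the final passage
    Exp(lambda_1 + q_off) + Exp(lambda_2) + ... + Exp(lambda_L).
    """
    if B < 1:
        raise InvalidParameterError(f"B must be >= 1, got {B}")
    q_off = params.q_off if params.has_switch else 0.0
    q_on = params.q_on if params.has_switch else 0.0
    lam = params.lambdas
    if q_off > 0 and q_on <= 0:
        raise InvalidParameterError(
            "q_off > 0 with q_on = 0 gives an infinite off-period"
        )
    rng = _as_rng(rng)
    rate1 = lam[0] + q_off
    p = lam[0] / rate1
    if q_off == 0:
        loops = np.zeros(B)
    else:
        G = rng.geometric(p, size=B)  # support {1, 2, ...}
        # sum of (G-1) loop durations; Exp-sum with integer count via Gamma
        loops = rng.gamma(np.maximum(G - 1, 0), 1.0 / rate1) + rng.gamma(
            np.maximum(G - 1, 0), 1.0 / q_on
        )
    final = rng.exponential(1.0 / rate1, size=B)
    for rate in lam[1:]:
        final = final + rng.exponential(1.0 / rate, size=B)
    return loops + final
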