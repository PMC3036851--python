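"""Simulated-annealing marker orderer minimising SARF.

The orderer treats the marker permutation as the state of a Metropolis
sampler whose energy is the SARF objective.  At control parameter (the
"temperature") ``c`` a candidate order drawn uniformly from the neighborhood
of the current order is always accepted when it does not worsen SARF, and
accepted with probability ``exp(-(f(y) - f(x)) / c)`` otherwise.  The control
parameter starts at a constant ``A`` chosen large enough that essentially all
initial moves are accepted and decays towards zero over ``m`` cooling steps
of ``L`` inner moves each, so the chain degenerates into strict descent as it
cools.  The default A = 2 is calibrated to the recombination-fraction scale
of the SARF objective proper (adjacent r's sum to a few units at most, so
early worsening moves of typical size are accepted freely); matrices built by
two-point estimation therefore carry ``units="r"``.

Candidate moves are O(1): the SARF change of a position swap or a segment
reversal only involves the edges at the boundary of the move, so a run costs
O(m * L) regardless of how the objective scales with k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import (
    ConfigurationError,
    DataError,
    DistanceMatrix,
    DomainError,
    MarkerOrder,
    canonicalize,
    sarf,
)

__all__ = [
    "SAConfig",
    "AnnealResult",
    "neighbor",
    "accept_probability",
    "cooling",
    "anneal",
    "anneal_best_of",
]

_SCHEDULES = ("linear", "geometric", "logarithmic")
_NEIGHBORHOODS = ("swap", "reverse")


@dataclass(frozen=True)
class SAConfig:
    """Annealing controls.

    A
        Initial control parameter c_0 (temperature), on the scale of the
        objective.  Default 2: large enough on the recombination-fraction
        SARF scale that early worsening moves are freely accepted.
    m
        Number of cooling steps.  Default 8000, which with the default chain
        length gives about 4e5 objective evaluations for a 51-marker group —
        denser groups automatically get a larger total budget, matching the
        observation that saturated groups need many more iterations.
    L
        Chain length per cooling step (moves attempted at each temperature);
        ``None`` means the number of markers k.
    schedule
        ``linear`` (default): c_n = A * (1 - n / (m + 1)); ``geometric``:
        c_n = A * alpha^n; ``logarithmic``: c_n = A / ln(n + e).  All stay
        strictly positive and non-increasing.
    neighborhood
        ``reverse`` (default): reverse a uniformly chosen contiguous block of
        length >= 2 (the classic 2-opt move, which matches the path structure
        of the objective); ``swap``: exchange the markers at two distinct
        uniformly chosen positions.
    patience
        Stop after this many consecutive cooling steps without improving the
        best SARF; ``None`` disables early stopping (run all m steps).
    """

    A: float = 2.0
    m: int = 8000
    L: int | None = None
    schedule: str = "linear"
    alpha: float = 0.95
    neighborhood: str = "reverse"
    seed: int | None = None
    patience: int | None = None
    record_trajectory: bool = True

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ConfigurationError("A must be positive")
        if self.m < 1:
            raise ConfigurationError("m must be >= 1")
        if self.L is not None and self.L < 1:
            raise ConfigurationError("L must be >= 1")
        if self.schedule not in _SCHEDULES:
            raise ConfigurationError(f"unknown schedule {self.schedule!r}")
        if self.neighborhood not in _NEIGHBORHOODS:
            raise ConfigurationError(f"unknown neighborhood {self.neighborhood!r}")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")


@dataclass
class AnnealResult:
    """Output of one annealing run.

    ``trajectory`` (when recorded) has one row per inner iteration with
    columns iteration, temperature, current_sarf, best_sarf; the best-so-far
    column is non-increasing and ends at ``sarf``.
    """

    order: MarkerOrder
    sarf: float
    accepted: int
    evaluations: int
    config: SAConfig
    trajectory: pd.DataFrame | None = None

    def write_trajectory(self, path) -> None:
        if self.trajectory is None:
            raise ConfigurationError("trajectory was not recorded")
        self.trajectory.to_csv(path, sep="\t", index=False)


def accept_probability(f_x: float, f_y: float, c: float) -> float:
    """Metropolis acceptance probability for moving from cost f_x to f_y at c."""
    if c <= 0:
        raise DomainError("control parameter c must be positive")
    if f_y <= f_x:
        return 1.0
    return math.exp(-(f_y - f_x) / c)


def cooling(n: int, config: SAConfig) -> float:
    """Control parameter c_n at cooling step ``n`` (c_0 = A; strictly positive)."""
    if not 0 <= n <= config.m:
        raise DomainError(f"cooling step {n} outside [0, {config.m}]")
    if config.schedule == "linear":
        return config.A * (1.0 - n / (config.m + 1.0))
    if config.schedule == "geometric":
        return config.A * config.alpha**n
    return config.A / math.log(n + math.e)


def neighbor(
    order: MarkerOrder, rng: np.random.Generator, kind: str = "swap"
) -> MarkerOrder:
    """Draw a uniform candidate order from the neighborhood of ``order``.

    ``swap`` exchanges two distinct uniformly chosen positions; ``reverse``
    reverses a uniformly chosen contiguous block of length >= 2.  The result
    always differs from the input.
    """
    k = len(order)
    if k < 2:
        raise DomainError("need at least 2 markers")
    if kind not in _NEIGHBORHOODS:
        raise ConfigurationError(f"unknown neighborhood {kind!r}")
    a = int(rng.integers(0, k))
    b = int((a + 1 + rng.integers(0, k - 1)) % k)
    if a > b:
        a, b = b, a
    p = list(order.perm)
    if kind == "swap":
        p[a], p[b] = p[b], p[a]
    else:
        p[a : b + 1] = reversed(p[a : b + 1])
    return MarkerOrder(tuple(p))


def _swap_delta(p: list[int], v: list[list[float]], a: int, b: int, k: int) -> float:
    # SARF change of swapping positions a < b; only boundary edges move.
    pa, pb = p[a], p[b]
    old = new = 0.0
    if a > 0:
        old += v[p[a - 1]][pa]
        new += v[p[a - 1]][pb]
    if b == a + 1:
        if b < k - 1:
            old += v[pb][p[b + 1]]
            new += v[pa][p[b + 1]]
        return new - old
    old += v[pa][p[a + 1]]
    new += v[pb][p[a + 1]]
    old += v[p[b - 1]][pb]
    new += v[p[b - 1]][pa]
    if b < k - 1:
        old += v[pb][p[b + 1]]
        new += v[pa][p[b + 1]]
    return new - old


def _reversal_delta(p: list[int], v: list[list[float]], a: int, b: int, k: int) -> float:
    # SARF change of reversing the block p[a..b]; interior edges are unchanged.
    delta = 0.0
    if a > 0:
        delta += v[p[a - 1]][p[b]] - v[p[a - 1]][p[a]]
    if b < k - 1:
        delta += v[p[a]][p[b + 1]] - v[p[b]][p[b + 1]]
    return delta


def anneal(D: DistanceMatrix, config: SAConfig | None = None) -> AnnealResult:
    """Run simulated annealing on a distance matrix; fully seed-reproducible.

    Starts from a uniform random order, performs ``L`` candidate moves at each
    of the ``m`` cooling steps with Metropolis acceptance (a candidate that
    does not worsen SARF is always taken), tracks the best order ever visited,
    and returns it in canonical form with its SARF recomputed from scratch.
    """
    if config is None:
        config = SAConfig()
    k = D.k
    if k < 2:
        raise DomainError("need at least 2 markers")
    values = D.values
    if not np.all(np.isfinite(values)):
        raise DataError("distance matrix contains non-finite entries")
    v = values.tolist()  # nested lists: faster scalar indexing in the hot loop

    rng = np.random.default_rng(config.seed)
    L = config.L if config.L is not None else k
    m = config.m
    total = m * L
    swap_moves = config.neighborhood == "swap"

    p = [int(i) for i in rng.permutation(k)]
    f = sum(v[p[i]][p[i + 1]] for i in range(k - 1))
    best_f = f
    best_p = list(p)
    accepted = 0

    record = config.record_trajectory
    if record:
        traj_c = np.empty(total)
        traj_cur = np.empty(total)
        traj_best = np.empty(total)

    it = 0
    evals = 0
    stale = 0
    exp = math.exp
    for n in range(m):
        c = cooling(n, config)
        # pre-draw the whole chain for this temperature
        aa = rng.integers(0, k, size=L)
        off = rng.integers(1, k, size=L)
        uu = rng.random(L)
        improved = False
        for t in range(L):
            a = int(aa[t])
            b = int((a + off[t]) % k)
            if a > b:
                a, b = b, a
            if swap_moves:
                delta = _swap_delta(p, v, a, b, k)
            else:
                delta = _reversal_delta(p, v, a, b, k)
            if delta <= 0.0 or uu[t] < exp(-delta / c):
                if swap_moves:
                    p[a], p[b] = p[b], p[a]
                else:
                    p[a : b + 1] = reversed(p[a : b + 1])
                f += delta
                accepted += 1
                if f < best_f - 1e-12:
                    best_f = f
                    best_p = list(p)
                    improved = True
            evals += 1
            if record:
                traj_c[it] = c
                traj_cur[it] = f
                traj_best[it] = best_f
                it += 1
        stale = 0 if improved else stale + 1
        if config.patience is not None and stale >= config.patience:
            break

    best_order = canonicalize(best_p)
    best_sarf = sarf(best_order, D)  # recompute: no accumulated float drift
    trajectory = None
    if record:
        trajectory = pd.DataFrame(
            {
                "iteration": np.arange(1, it + 1),
                "temperature": traj_c[:it],
                "current_sarf": traj_cur[:it],
                "best_sarf": traj_best[:it],
            }
        )
    return AnnealResult(
        order=best_order,
        sarf=best_sarf,
        accepted=accepted,
        evaluations=evals,
        config=config,
        trajectory=trajectory,
    )


def anneal_best_of(
    D: DistanceMatrix, reps: int, config: SAConfig | None = None, seed: int | None = None
) -> tuple[AnnealResult, list[AnnealResult]]:
    """Run ``reps`` independently seeded annealing runs; return (best, all).

    Per-repetition seeds are spawned from ``seed`` (or from ``config.seed``),
    so the whole ensemble is reproducible from one integer.
    """
    if reps < 1:
        raise DomainError("reps must be >= 1")
    if config is None:
        config = SAConfig()
    base = seed if seed is not None else config.seed
    child_seeds = np.random.SeedSequence(base).generate_state(reps) % (2**31 - 1)
    results = [
        anneal(D, replace(config, seed=int(s))) for s in child_seeds
    ]
    best = min(results, key=lambda r: r.sarf)
    return best, results
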