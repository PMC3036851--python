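"""Rapid chain delineation: greedy chain growth polished by window inversions.

The chain is seeded with the globally closest marker pair (smallest estimated
recombination fraction); the unmapped marker with the smallest r to either
chain terminal is then repeatedly attached at that terminal until every
marker is placed.  A "ripple" pass then scans the order left to right and
reverses any window of 2 or 3 markers that strictly lowers SARF, repeating
until a full pass makes no change.  A length-2 reversal is an adjacent
transposition, so the double- and triple-window passes together undo the
local misorderings the greedy phase tends to leave.

The whole procedure is deterministic: ties in the greedy phase are broken by
lowest marker index, then by the left terminal.
"""

from __future__ import annotations

import numpy as np

from .core import (
    ConfigurationError,
    DistanceMatrix,
    DomainError,
    MarkerOrder,
    canonicalize,
    sarf,
)

__all__ = ["build_chain", "ripple", "rcd"]

_MAX_RIPPLE_PASSES = 50


def build_chain(D: DistanceMatrix) -> MarkerOrder:
    """Greedy chain growth on the recombination-fraction matrix.

    Seeds with the pair of smallest r (ties: lexicographically smallest index
    pair) and repeatedly attaches the unmapped marker closest to a terminal
    (ties: lowest marker index, then the left terminal).
    """
    if D.r is None:
        raise ConfigurationError("build_chain requires the r matrix")
    k = D.k
    if k < 2:
        raise DomainError("need at least 2 markers")
    r = np.asarray(D.r, dtype=float)

    # seed pair: smallest off-diagonal r, lexicographic tie-break
    iu, ju = np.triu_indices(k, 1)
    vals = r[iu, ju]
    best = np.flatnonzero(vals == vals.min())[0]  # triu order is lexicographic
    chain = [int(iu[best]), int(ju[best])]
    unmapped = [i for i in range(k) if i not in chain]

    while unmapped:
        best_key = None
        best_marker = -1
        best_side = 0
        for mk in unmapped:  # ascending index: first strict win fixes ties
            for side, terminal in ((0, chain[0]), (1, chain[-1])):
                key = (r[mk, terminal], mk, side)
                if best_key is None or key < best_key:
                    best_key = key
                    best_marker = mk
                    best_side = side
        unmapped.remove(best_marker)
        if best_side == 0:
            chain.insert(0, best_marker)
        else:
            chain.append(best_marker)
    return MarkerOrder(tuple(chain))


def _reversal_delta(p: list[int], v, a: int, b: int, k: int) -> float:
    delta = 0.0
    if a > 0:
        delta += v[p[a - 1]][p[b]] - v[p[a - 1]][p[a]]
    if b < k - 1:
        delta += v[p[a]][p[b + 1]] - v[p[b]][p[b + 1]]
    return delta


def ripple(
    order: MarkerOrder, D: DistanceMatrix, window: int, max_passes: int = _MAX_RIPPLE_PASSES
) -> MarkerOrder:
    """Left-to-right window-reversal polish; never increases SARF.

    At each position the ``window`` markers are reversed in place when that
    strictly lowers SARF; full passes repeat until one makes no change (or the
    pass cap is hit).  Strict improvement prevents cycling.
    """
    if window not in (2, 3):
        raise DomainError("window must be 2 or 3")
    k = D.k
    if len(order) != k:
        raise DomainError("order and matrix sizes differ")
    if k < window:
        return order
    v = D.values.tolist()
    p = list(order.perm)
    for _ in range(max_passes):
        changed = False
        for a in range(k - window + 1):
            b = a + window - 1
            if _reversal_delta(p, v, a, b, k) < -1e-12:
                p[a : b + 1] = reversed(p[a : b + 1])
                changed = True
        if not changed:
            break
    return MarkerOrder(tuple(p))


def rcd(D: DistanceMatrix) -> tuple[MarkerOrder, float]:
    """Full rapid-chain-delineation ordering: greedy chain, then ripple(2), ripple(3).

    Double- and triple-window passes alternate until neither changes the
    order.  Deterministic; returns the canonical order and its SARF.
    """
    order = build_chain(D)
    for _ in range(_MAX_RIPPLE_PASSES):
        improved = ripple(order, D, 2)
        improved = ripple(improved, D, 3)
        if improved.perm == order.perm:
            break
        order = improved
    order = canonicalize(order)
    return order, sarf(order, D)
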