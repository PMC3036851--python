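"""Exhaustive brute-force ordering for small marker sets.

Enumerates every canonical order (first index < last, which halves the k!
search space since SARF is reversal-invariant) and returns the global SARF
minimum.  Serves as the ground truth that both heuristic orderers are tested
against; guarded to small k because the search is factorial.
"""

from __future__ import annotations

import itertools

import numpy as np

from .core import DistanceMatrix, DomainError, MarkerOrder

__all__ = ["exhaustive_best_order"]

_CHUNK = 40320  # evaluate permutations in batches of up to 8! rows


def exhaustive_best_order(
    D: DistanceMatrix, max_k: int = 9
) -> tuple[MarkerOrder, float]:
    """Global SARF minimiser over all k!/2 canonical orders (k <= max_k).

    Ties are broken lexicographically (the enumeration is in lexicographic
    order and only a strictly better SARF replaces the incumbent).
    """
    k = D.k
    if k < 2:
        raise DomainError("need at least 2 markers")
    if k > max_k:
        raise DomainError(f"k={k} exceeds max_k={max_k}; exhaustive search refused")
    v = D.values
    best_val = np.inf
    best_perm: tuple[int, ...] | None = None

    def flush(batch: list[tuple[int, ...]]) -> None:
        nonlocal best_val, best_perm
        arr = np.array(batch, dtype=np.intp)
        sums = v[arr[:, :-1], arr[:, 1:]].sum(axis=1)
        i = int(np.argmin(sums))  # first minimum: lexicographically smallest
        if sums[i] < best_val:
            best_val = float(sums[i])
            best_perm = batch[i]

    batch: list[tuple[int, ...]] = []
    for perm in itertools.permutations(range(k)):
        if perm[0] > perm[-1]:
            continue  # skip non-canonical duplicates (reversals)
        batch.append(perm)
        if len(batch) == _CHUNK:
            flush(batch)
            batch = []
    if batch:
        flush(batch)
    assert best_perm is not None
    return MarkerOrder(best_perm), best_val
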