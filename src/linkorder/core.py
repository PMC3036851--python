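"""Domain types and ordering objectives for linkage-map construction.

Ordering the markers of a linkage group is a path variant of the travelling
salesman problem: given a symmetric matrix ``D`` of pairwise distances between
``k`` markers, find the permutation that minimises the summed distance along
adjacent pairs.  That sum is the SARF criterion (Sum of Adjacent Recombination
Fractions) when evaluated on recombination fractions, or the total map length
in centimorgans when evaluated on cM distances; any cellwise monotone map
function induces the same optimal ordering.  Two alternatives are provided:
PARF (product of adjacent recombination fractions, minimised) and SALOD (sum
of adjacent LOD scores, maximised).

An order and its reversal describe the same linkage map, so orders are
canonicalised to have their first marker index smaller than their last.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DEFAULT_CAP_CM",
    "LinkageGroup",
    "GenomeSpec",
    "MarkerOrder",
    "DistanceMatrix",
    "ObjectiveKind",
    "sarf",
    "path_length_cm",
    "objective",
    "map_function",
    "canonicalize",
    "LinkorderError",
    "SizeMismatchError",
    "DomainError",
    "ConfigurationError",
    "EstimationError",
    "ParseError",
    "DataError",
]

#: Ceiling distance (cM) assigned to unlinked pairs (r >= 0.5) so that the
#: ordering objective stays finite.  Applied as ``min(map(r), cap)``, which is
#: monotone in r and leaves every distance below the cap untouched.
DEFAULT_CAP_CM = 100.0


class LinkorderError(Exception):
    """Base class for all package-specific errors."""


class SizeMismatchError(LinkorderError, ValueError):
    """Shapes or lengths of two inputs do not agree."""


class DomainError(LinkorderError, ValueError):
    """An argument is outside its mathematical domain."""


class ConfigurationError(LinkorderError, ValueError):
    """A configuration value or requested mode is not recognised or available."""


class EstimationError(LinkorderError, RuntimeError):
    """An estimate cannot be formed from the data provided."""


class ParseError(LinkorderError, ValueError):
    """A file could not be parsed; the message names the offending location."""


class DataError(LinkorderError, ValueError):
    """Numeric input data violate a structural requirement."""


# ---------------------------------------------------------------------------
# Genome description


@dataclass(frozen=True)
class LinkageGroup:
    """One linkage group of the true map: ordered markers with cM positions.

    Positions are non-negative and strictly increasing; the group length is the
    distance between the first and last marker.
    """

    names: tuple[str, ...]
    positions: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.positions):
            raise SizeMismatchError(
                f"{len(self.names)} names but {len(self.positions)} positions"
            )
        if len(self.names) == 0:
            raise DomainError("a linkage group needs at least one marker")
        pos = np.asarray(self.positions, dtype=float)
        if np.any(pos < 0):
            raise DomainError("marker positions must be non-negative")
        if len(pos) > 1 and not np.all(np.diff(pos) > 0):
            raise DomainError("marker positions must be strictly increasing")

    @classmethod
    def equally_spaced(
        cls, prefix: str, n_markers: int, spacing_cm: float, start_number: int = 1
    ) -> "LinkageGroup":
        """Build a group of ``n_markers`` markers ``{prefix}{i}`` spaced evenly."""
        if n_markers < 1:
            raise DomainError("n_markers must be >= 1")
        if spacing_cm <= 0:
            raise DomainError("spacing_cm must be positive")
        names = tuple(f"{prefix}{start_number + i}" for i in range(n_markers))
        positions = tuple(float(i) * spacing_cm for i in range(n_markers))
        return cls(names, positions)

    @property
    def k(self) -> int:
        return len(self.names)

    @property
    def length(self) -> float:
        """Group length in cM (last minus first position)."""
        return float(self.positions[-1] - self.positions[0])

    @property
    def spacings(self) -> tuple[float, ...]:
        """Adjacent inter-marker distances in cM."""
        return tuple(float(b - a) for a, b in zip(self.positions, self.positions[1:]))


@dataclass(frozen=True)
class GenomeSpec:
    """The true map used as simulation ground truth: a set of linkage groups.

    Marker names must be unique genome-wide.
    """

    groups: tuple[LinkageGroup, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.groups:
            for name in g.names:
                if name in seen:
                    raise DomainError(f"duplicate marker name {name!r}")
                seen.add(name)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_markers(self) -> int:
        return sum(g.k for g in self.groups)

    @property
    def marker_names(self) -> tuple[str, ...]:
        return tuple(n for g in self.groups for n in g.names)

    @property
    def group_assignment(self) -> tuple[int, ...]:
        """Group index of each marker, in genome-wide column order."""
        return tuple(i for i, g in enumerate(self.groups) for _ in g.names)


# ---------------------------------------------------------------------------
# Orders


@dataclass(frozen=True)
class MarkerOrder:
    """A permutation of marker indices 0..k-1 (an order to walk the markers).

    The canonical representative of the pair {order, reversed order} is the one
    whose first element is smaller than its last; both describe the same map.
    """

    perm: tuple[int, ...]

    def __post_init__(self) -> None:
        k = len(self.perm)
        if k == 0:
            raise DomainError("empty order")
        if sorted(self.perm) != list(range(k)):
            raise DomainError(f"perm is not a permutation of 0..{k - 1}")

    def __len__(self) -> int:
        return len(self.perm)

    def __iter__(self):
        return iter(self.perm)

    def reverse(self) -> "MarkerOrder":
        return MarkerOrder(tuple(reversed(self.perm)))

    @property
    def is_canonical(self) -> bool:
        return len(self.perm) == 1 or self.perm[0] < self.perm[-1]

    def canonical(self) -> "MarkerOrder":
        return self if self.is_canonical else self.reverse()

    def names(self, marker_names: Sequence[str]) -> tuple[str, ...]:
        """Marker names along this order."""
        return tuple(marker_names[i] for i in self.perm)


def canonicalize(order: "MarkerOrder | Sequence[int]") -> MarkerOrder:
    """Return the canonical representative of an order (first index < last)."""
    if not isinstance(order, MarkerOrder):
        order = MarkerOrder(tuple(int(i) for i in order))
    return order.canonical()


# ---------------------------------------------------------------------------
# Map functions


def _haldane_cm_to_r(d):
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


def _haldane_r_to_cm(r):
    return -50.0 * np.log(1.0 - 2.0 * r)


def _kosambi_cm_to_r(d):
    return 0.5 * np.tanh(2.0 * d / 100.0)


def _kosambi_r_to_cm(r):
    return 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


_MAP_FUNCS = {
    ("cm_to_r", "haldane"): _haldane_cm_to_r,
    ("r_to_cm", "haldane"): _haldane_r_to_cm,
    ("cm_to_r", "kosambi"): _kosambi_cm_to_r,
    ("r_to_cm", "kosambi"): _kosambi_r_to_cm,
}


def map_function(
    x,
    direction: str,
    kind: str = "haldane",
    cap: float = DEFAULT_CAP_CM,
):
    """Convert between map distance (cM) and recombination fraction r.

    Haldane's function assumes no crossover interference
    (``r = (1 - e^(-2d/100)) / 2``); Kosambi's allows partial interference
    (``r = tanh(2d/100) / 2``).  Both are involutive pairs: the round trip
    ``r_to_cm(cm_to_r(d))`` is the identity for ``d < cap``.

    ``r_to_cm`` returns ``min(formula, cap)`` and maps r >= 0.5 (unlinked) to
    ``cap`` rather than infinity, so downstream ordering objectives stay
    finite.

    Accepts scalars or arrays; returns a float for scalar input.
    """
    if direction not in ("cm_to_r", "r_to_cm"):
        raise ConfigurationError(f"unknown direction {direction!r}")
    if kind not in ("haldane", "kosambi"):
        raise ConfigurationError(f"unknown map function {kind!r}")
    arr = np.asarray(x, dtype=float)
    scalar = arr.ndim == 0
    func = _MAP_FUNCS[(direction, kind)]
    if direction == "cm_to_r":
        if np.any(arr < 0):
            raise DomainError("map distance must be non-negative")
        out = func(arr)
    else:
        if np.any(arr < 0):
            raise DomainError("recombination fraction must be non-negative")
        out = np.where(arr >= 0.5, cap, np.minimum(func(np.minimum(arr, 0.4999999999)), cap))
    return float(out) if scalar else out


# ---------------------------------------------------------------------------
# Distance matrices


@dataclass
class DistanceMatrix:
    """Pairwise marker distances plus companion r and LOD matrices.

    ``d`` holds map distances in cM (unlinked pairs capped, see
    :data:`DEFAULT_CAP_CM`); ``r`` holds recombination-fraction estimates in
    [0, 0.5]; ``lod`` the two-point LOD scores.  All are symmetric with zero
    diagonal.  ``units`` selects which matrix the SARF objective sums:
    ``"cM"`` (default, comparable to reported map lengths) or ``"r"``.
    """

    d: np.ndarray
    r: np.ndarray | None = None
    lod: np.ndarray | None = None
    names: tuple[str, ...] | None = None
    units: str = "cM"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.ndim != 2 or self.d.shape[0] != self.d.shape[1]:
            raise SizeMismatchError(f"d must be square, got shape {self.d.shape}")
        if self.units not in ("cM", "r"):
            raise ConfigurationError(f"unknown units {self.units!r}")
        if not np.all(np.isfinite(self.d)):
            raise DataError("d contains non-finite entries")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise DataError("d is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise DataError("d has a non-zero diagonal")
        for attr in ("r", "lod"):
            m = getattr(self, attr)
            if m is None:
                continue
            m = np.asarray(m, dtype=float)
            if m.shape != self.d.shape:
                raise SizeMismatchError(f"{attr} shape {m.shape} != d shape {self.d.shape}")
            if not np.allclose(m, m.T, atol=1e-9):
                raise DataError(f"{attr} is not symmetric")
            setattr(self, attr, m)
        if self.names is not None:
            self.names = tuple(self.names)
            if len(self.names) != self.d.shape[0]:
                raise SizeMismatchError("names length does not match matrix size")

    @property
    def k(self) -> int:
        return self.d.shape[0]

    @property
    def values(self) -> np.ndarray:
        """The matrix the SARF objective runs on, per ``units``."""
        if self.units == "cM":
            return self.d
        if self.r is None:
            raise ConfigurationError("units='r' but no r matrix present")
        return self.r

    @classmethod
    def from_positions(
        cls,
        positions: Sequence[float],
        names: Sequence[str] | None = None,
        map_kind: str = "haldane",
        cap: float = DEFAULT_CAP_CM,
    ) -> "DistanceMatrix":
        """True-map distance matrix from collinear cM positions.

        Distances are ``min(|p_i - p_j|, cap)``; r follows from the map
        function.  Used for ground-truth matrices in simulation studies.
        """
        pos = np.asarray(positions, dtype=float)
        d_true = np.abs(pos[:, None] - pos[None, :])
        r = map_function(d_true, "cm_to_r", map_kind)
        d = np.minimum(d_true, cap)
        return cls(d=d, r=r, names=tuple(names) if names is not None else None)

    def subset(self, idx: Sequence[int]) -> "DistanceMatrix":
        idx = np.asarray(idx, dtype=int)
        return DistanceMatrix(
            d=self.d[np.ix_(idx, idx)],
            r=None if self.r is None else self.r[np.ix_(idx, idx)],
            lod=None if self.lod is None else self.lod[np.ix_(idx, idx)],
            names=None if self.names is None else tuple(self.names[i] for i in idx),
            units=self.units,
        )


# ---------------------------------------------------------------------------
# Objectives


class ObjectiveKind(str, Enum):
    """Ordering criteria: SARF and PARF are minimised, SALOD is maximised."""

    SARF = "sarf"
    PARF = "parf"
    SALOD = "salod"


def _as_perm_array(order: "MarkerOrder | Sequence[int]", k: int) -> np.ndarray:
    if not isinstance(order, MarkerOrder):
        order = MarkerOrder(tuple(int(i) for i in order))
    if len(order) != k:
        raise SizeMismatchError(f"order has {len(order)} markers, matrix has {k}")
    return np.asarray(order.perm, dtype=int)


def sarf(order: "MarkerOrder | Sequence[int]", D: DistanceMatrix) -> float:
    """Total distance along an order: sum of adjacent pairwise distances.

    Evaluated on ``D.values`` (cM by default), so with default units the result
    is the order's map length in cM.  Invariant under order reversal.
    """
    if D.k < 2:
        raise DomainError("need at least 2 markers")
    p = _as_perm_array(order, D.k)
    v = D.values
    return float(v[p[:-1], p[1:]].sum())


def path_length_cm(order: "MarkerOrder | Sequence[int]", D: DistanceMatrix) -> float:
    """Map length in cM of an order: sum of adjacent entries of ``D.d``.

    Unlike :func:`sarf` this always reads the cM matrix, so it reports a
    comparable map length even when the ordering criterion runs on r.
    """
    if D.k < 2:
        raise DomainError("need at least 2 markers")
    p = _as_perm_array(order, D.k)
    return float(D.d[p[:-1], p[1:]].sum())


def objective(
    order: "MarkerOrder | Sequence[int]",
    D: DistanceMatrix,
    kind: "ObjectiveKind | str" = ObjectiveKind.SARF,
) -> float:
    """Evaluate an ordering criterion (SARF, PARF or SALOD) for an order."""
    kind = ObjectiveKind(kind)
    if kind is ObjectiveKind.SARF:
        return sarf(order, D)
    if D.k < 2:
        raise DomainError("need at least 2 markers")
    p = _as_perm_array(order, D.k)
    if kind is ObjectiveKind.PARF:
        if D.r is None:
            raise ConfigurationError("PARF requires the r matrix")
        return float(np.prod(D.r[p[:-1], p[1:]]))
    if D.lod is None:
        raise ConfigurationError("SALOD requires the LOD matrix")
    return float(D.lod[p[:-1], p[1:]].sum())
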