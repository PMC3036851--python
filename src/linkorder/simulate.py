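"""Simulation of F2 co-dominant mapping populations.

An F2 intercross starts from two fully inbred parents; every F1 gamete is a
mosaic of the two parental haplotypes.  Gametes are simulated as a Markov
chain along each linkage group: the allele at the first marker is Bernoulli
(1/2) and the allele switches across each adjacent interval of length ``d``
cM with probability equal to Haldane's recombination fraction
``r = (1 - e^(-2d/100)) / 2``.  Intervals recombine independently (no
crossover interference), which is exactly the assumption under which
Haldane's map function is the correct cM-to-r transform.  An F2 individual is
the sum of two independent gametes, giving co-dominant genotype codes
0 (aa), 1 (Aa) and 2 (AA) that segregate 1:2:1 marker-wise.

Linkage groups are unlinked and simulated from independent random streams
spawned from one master seed, so any group or replicate can be reproduced in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .core import (
    DomainError,
    GenomeSpec,
    LinkageGroup,
    SizeMismatchError,
    map_function,
)

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "benchmark_genome",
    "simulate_gametes",
    "simulate_gamete",
    "simulate_f2",
    "inject_missing",
]

#: Genotype code for a missing observation.
MISSING = -9


@dataclass(frozen=True)
class GenotypeMatrix:
    """n individuals x k markers of F2 co-dominant genotype codes.

    Codes: 0 = homozygote for parent-1 allele (aa), 1 = heterozygote (Aa),
    2 = homozygote for parent-2 allele (AA), -9 = missing.  ``groups`` gives
    the linkage-group index of each marker column (all zeros when unknown).
    """

    codes: np.ndarray
    names: tuple[str, ...]
    groups: tuple[int, ...]

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int8)
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "groups", tuple(int(g) for g in self.groups))
        if codes.ndim != 2:
            raise DomainError(f"codes must be 2-D, got {codes.ndim}-D")
        if len(self.names) != codes.shape[1]:
            raise SizeMismatchError(
                f"{len(self.names)} names for {codes.shape[1]} columns"
            )
        if len(self.groups) != codes.shape[1]:
            raise SizeMismatchError(
                f"{len(self.groups)} group labels for {codes.shape[1]} columns"
            )
        valid = np.isin(codes, (0, 1, 2, MISSING))
        if not valid.all():
            bad = codes[~valid].ravel()[0]
            raise DomainError(f"invalid genotype code {int(bad)}")

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def k(self) -> int:
        return self.codes.shape[1]

    @property
    def group_ids(self) -> tuple[int, ...]:
        """Distinct group indices in column order of first appearance."""
        seen: list[int] = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    def group_columns(self, group: int) -> np.ndarray:
        """Column indices of the markers in one linkage group."""
        cols = np.flatnonzero(np.asarray(self.groups) == group)
        if cols.size == 0:
            raise DomainError(f"no markers in group {group}")
        return cols

    def subset(self, cols: Sequence[int]) -> "GenotypeMatrix":
        cols = np.asarray(cols, dtype=int)
        return GenotypeMatrix(
            codes=self.codes[:, cols],
            names=tuple(self.names[c] for c in cols),
            groups=tuple(self.groups[c] for c in cols),
        )


def benchmark_genome() -> GenomeSpec:
    """Four-group benchmark genome spanning 100 cM per group.

    Groups of 51, 21, 11 and 6 markers at 2, 5, 10 and 20 cM adjacent spacing
    (markers m1..m89) — four saturation levels of the same map length, the
    standard design for stress-testing marker-ordering algorithms.
    """
    sizes = ((51, 2.0), (21, 5.0), (11, 10.0), (6, 20.0))
    groups = []
    start = 1
    for n_markers, spacing in sizes:
        groups.append(LinkageGroup.equally_spaced("m", n_markers, spacing, start))
        start += n_markers
    return GenomeSpec(tuple(groups))


def simulate_gametes(
    positions: Sequence[float], n: int, rng: np.random.Generator
) -> np.ndarray:
    """Simulate ``n`` gametes over one linkage group; returns an (n, k) 0/1 array.

    First allele Bernoulli(1/2); each adjacent interval switches the allele
    independently with Haldane probability for its cM length.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 1 or pos.size == 0:
        raise DomainError("positions must be a non-empty 1-D sequence")
    if pos.size > 1 and not np.all(np.diff(pos) > 0):
        raise DomainError("positions must be strictly increasing")
    k = pos.size
    first = rng.integers(0, 2, size=(n, 1), dtype=np.int8)
    if k == 1:
        return first
    r = map_function(np.diff(pos), "cm_to_r", "haldane")
    switches = (rng.random((n, k - 1)) < r).astype(np.int8)
    # allele_j = first XOR (parity of switches up to j)
    parity = np.cumsum(switches, axis=1, dtype=np.int32) % 2
    out = np.empty((n, k), dtype=np.int8)
    out[:, 0] = first[:, 0]
    out[:, 1:] = (first ^ parity).astype(np.int8)
    return out


def simulate_gamete(positions: Sequence[float], rng: np.random.Generator) -> np.ndarray:
    """One gamete haplotype (0/1 per marker) over a linkage group."""
    return simulate_gametes(positions, 1, rng)[0]


def simulate_f2(
    genome: GenomeSpec, n: int, seed: int | None = None
) -> GenotypeMatrix:
    """Simulate an F2 co-dominant population of ``n`` individuals.

    Each individual is the sum of two independent gametes per group; groups
    are unlinked and use independent streams spawned from ``seed``, so output
    is deterministic for a fixed seed.
    """
    if n < 0:
        raise DomainError("population size must be non-negative")
    streams = np.random.SeedSequence(seed).spawn(genome.n_groups)
    blocks = []
    for group, ss in zip(genome.groups, streams):
        rng = np.random.default_rng(ss)
        g1 = simulate_gametes(group.positions, n, rng)
        g2 = simulate_gametes(group.positions, n, rng)
        blocks.append((g1 + g2).astype(np.int8))
    codes = (
        np.hstack(blocks) if blocks else np.empty((n, 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        codes=codes,
        names=genome.marker_names,
        groups=genome.group_assignment,
    )


def inject_missing(
    gm: GenotypeMatrix, rate: float, seed: int | None = None
) -> GenotypeMatrix:
    """Set each genotype entry to missing independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise DomainError("missing rate must be in [0, 1)")
    if rate == 0.0:
        return gm
    rng = np.random.default_rng(seed)
    mask = rng.random(gm.codes.shape) < rate
    codes = gm.codes.copy()
    codes[mask] = MISSING
    return replace(gm, codes=codes)
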