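"""Head-to-head comparison protocol: simulate, estimate, order by both methods.

For one simulated population, each linkage group is reduced to its two-point
distance matrix, ordered once by the deterministic rapid-chain-delineation
method, and ordered ``reps`` times by independently seeded simulated
annealing.  The headline summary per group is the percentage of annealing
repetitions whose SARF is less than or equal to the RCD SARF (ties count as
wins: on sparse groups both methods typically land on the identical order),
plus the best-of-repetitions annealing SARF.  Both orderers see the same
simulated data — the repetitions vary only the annealer's seed.

Wall-clock times are recorded for context but are hardware-dependent and
never part of any contract.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import DomainError, GenomeSpec, MarkerOrder, path_length_cm
from .order_rcd import rcd
from .order_sa import SAConfig, anneal
from .simulate import simulate_f2
from .twopoint import recomb_matrix

__all__ = [
    "GroupComparison",
    "ComparisonResult",
    "run_comparison",
    "summary_table",
    "format_summary",
    "write_summary",
    "read_summary",
]

#: SARF equality tolerance when scoring a win/tie (floating-point slack only).
_WIN_TOL = 1e-9


@dataclass
class GroupComparison:
    """Per-group outcome of the RCD vs annealing comparison.

    SARF values are on the optimisation scale (summed adjacent r-hat for
    matrices built by two-point estimation); ``*_length_cm`` give the same
    orders' map lengths in centimorgans for comparison with reported maps.
    """

    group: int
    k: int
    marker_names: tuple[str, ...]
    rcd_order: MarkerOrder
    rcd_sarf: float
    rcd_length_cm: float
    sa_sarfs: np.ndarray
    sa_best_order: MarkerOrder
    sa_best_sarf: float
    sa_best_length_cm: float
    pct_win: float
    rcd_time_s: float
    sa_time_s: float
    best_trajectory: pd.DataFrame | None = None


@dataclass
class ComparisonResult:
    """Comparison outcomes for every linkage group of one simulated population."""

    population_size: int
    reps: int
    seed: int | None
    groups: list[GroupComparison] = field(default_factory=list)

    def group(self, index: int) -> GroupComparison:
        for g in self.groups:
            if g.group == index:
                return g
        raise KeyError(f"no comparison for group {index}")


def run_comparison(
    genome: GenomeSpec,
    n_individuals: int,
    reps: int = 100,
    sa_config: SAConfig | None = None,
    seed: int | None = None,
    groups: Sequence[int] | None = None,
    keep_trajectories: bool = False,
) -> ComparisonResult:
    """Simulate one population and compare the two orderers on every group.

    One F2 population of ``n_individuals`` is simulated from ``seed``; per
    linkage group the pairwise distance matrix is estimated, RCD runs once,
    and ``reps`` annealing runs use independent child seeds.  A repetition
    counts as a win when its SARF <= RCD's SARF (ties included).
    """
    if reps < 1:
        raise DomainError("reps must be >= 1")
    if sa_config is None:
        sa_config = SAConfig()
    root = np.random.SeedSequence(seed)
    sim_seed, sa_root = (int(s) for s in root.generate_state(2) % (2**31 - 1))
    gm = simulate_f2(genome, n_individuals, seed=sim_seed)

    group_ids = list(groups) if groups is not None else list(range(genome.n_groups))
    result = ComparisonResult(
        population_size=n_individuals, reps=reps, seed=seed
    )
    for gi in group_ids:
        D = recomb_matrix(gm, group=gi)
        t0 = time.perf_counter()
        rcd_order, rcd_sarf = rcd(D)
        rcd_time = time.perf_counter() - t0

        rep_seeds = np.random.SeedSequence(sa_root + gi).generate_state(reps) % (
            2**31 - 1
        )
        sarfs = np.empty(reps)
        best_result = None
        t0 = time.perf_counter()
        for j, s in enumerate(rep_seeds):
            cfg = replace(
                sa_config, seed=int(s), record_trajectory=keep_trajectories
            )
            res = anneal(D, cfg)
            sarfs[j] = res.sarf
            if best_result is None or res.sarf < best_result.sarf:
                best_result = res
        sa_time = time.perf_counter() - t0

        pct = 100.0 * float(np.mean(sarfs <= rcd_sarf + _WIN_TOL))
        result.groups.append(
            GroupComparison(
                group=gi,
                k=D.k,
                marker_names=D.names,
                rcd_order=rcd_order,
                rcd_sarf=rcd_sarf,
                rcd_length_cm=path_length_cm(rcd_order, D),
                sa_sarfs=sarfs,
                sa_best_order=best_result.order,
                sa_best_sarf=best_result.sarf,
                sa_best_length_cm=path_length_cm(best_result.order, D),
                pct_win=pct,
                rcd_time_s=rcd_time,
                sa_time_s=sa_time,
                best_trajectory=best_result.trajectory,
            )
        )
    return result


def summary_table(result: ComparisonResult) -> pd.DataFrame:
    """Long-form summary: one row per group with win percentage, SARFs and times."""
    rows = [
        {
            "population_size": result.population_size,
            "group": g.group + 1,
            "n_markers": g.k,
            "pct_sa_wins": g.pct_win,
            "rcd_sarf": g.rcd_sarf,
            "sa_best_sarf": g.sa_best_sarf,
            "sa_mean_sarf": float(np.mean(g.sa_sarfs)),
            "rcd_length_cm": g.rcd_length_cm,
            "sa_best_length_cm": g.sa_best_length_cm,
            "reps": result.reps,
            "rcd_time_s": g.rcd_time_s,
            "sa_time_s": g.sa_time_s,
        }
        for g in result.groups
    ]
    columns = [
        "population_size",
        "group",
        "n_markers",
        "pct_sa_wins",
        "rcd_sarf",
        "sa_best_sarf",
        "sa_mean_sarf",
        "rcd_length_cm",
        "sa_best_length_cm",
        "reps",
        "rcd_time_s",
        "sa_time_s",
    ]
    return pd.DataFrame(rows, columns=columns)


def format_summary(table: pd.DataFrame) -> str:
    """Human-readable rendering of a summary table."""
    if table.empty:
        return "\t".join(table.columns)
    return table.to_string(index=False, float_format=lambda x: f"{x:.2f}")


def write_summary(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_summary(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
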