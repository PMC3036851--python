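import itertools

import numpy as np
import pytest

from linkorder import DistanceMatrix, benchmark_genome
from linkorder.core import map_function


@pytest.fixture(scope="session")
def genome():
    return benchmark_genome()


@pytest.fixture(scope="session")
def group4_true_matrix(genome):
    """True-distance matrix of the sparsest group: 6 markers at 20 cM."""
    g = genome.groups[3]
    return DistanceMatrix.from_positions(g.positions, names=g.names)


def random_r_matrix(rng: np.random.Generator, k: int) -> DistanceMatrix:
    """Random symmetric recombination-fraction matrix with Haldane distances."""
    r = rng.uniform(0.01, 0.49, size=(k, k))
    r = (r + r.T) / 2
    np.fill_diagonal(r, 0.0)
    d = map_function(r, "r_to_cm", "haldane")
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d=d, r=r, units="r")


def brute_force_best(values: np.ndarray):
    """Independent exhaustive SARF minimiser (plain loop over all k! orders)."""
    k = values.shape[0]
    best_perm, best_val = None, np.inf
    for perm in itertools.permutations(range(k)):
        total = sum(values[perm[i], perm[i + 1]] for i in range(k - 1))
        if total < best_val - 1e-12:
            best_val = total
            best_perm = perm
    return best_perm, best_val
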