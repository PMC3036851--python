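# Methods

## The ordering problem

A linkage group of *k* markers admits *k*!/2 distinct orders (an order and
its reversal describe the same map).  Given a symmetric matrix of pairwise
distances, the package scores an order by SARF — the sum of the distances
between adjacent markers along the order — and searches for its minimiser.
This is the path (open-tour) travelling salesman problem.  PARF (product of
adjacent recombination fractions, minimised) and SALOD (sum of adjacent LOD
scores, maximised) are provided as alternative criteria; the orderers and
the comparison protocol use SARF.

Orders are canonicalised so that the first marker index is smaller than the
last; all reported orders use that representative.

## Simulation model

`simulate_f2` draws gametes as a Markov chain along each linkage group: the
allele at the first marker is Bernoulli(1/2), and the allele switches across
each adjacent interval of length *d* cM with probability equal to Haldane's
recombination fraction r(d) = (1 − e^(−2d/100))/2, independently across
intervals.  This is the no-interference model under which Haldane's map
function is exact, so the simulator and the default estimator are mutually
consistent.  An F2 individual is the sum of two independent gametes (codes
0/1/2, segregating 1:2:1).  Linkage groups are unlinked and use independent
random streams spawned from a single master seed.

The built-in benchmark genome has four 100 cM groups of 51, 21, 11 and 6
co-dominant markers at 2, 5, 10 and 20 cM spacing — four saturation levels
of the same map length.  Default study conditions follow the design this
genome comes from: population sizes 50, 100, 200 and 1000, complete data
(`inject_missing` exists for robustness experiments but defaults to 0).

What the simulator deliberately omits: crossover interference, segregation
distortion, dominant or partially informative markers, and genotyping
error.  Passing tests therefore demonstrate correctness of the algorithms
under clean F2 co-dominant sampling noise, not robustness to those
real-data artefacts.

## Two-point estimation

For each marker pair the sufficient statistic is the 3×3 joint genotype
table (individuals missing at either marker are dropped pairwise).  Cell
probabilities follow the standard F2 co-dominant model; the (1,1) double
heterozygote mixes 0- and 2-recombinant gamete configurations, so the MLE is
found by EM over the latent recombinant-gamete count:

    r' = [N_single + 2·N_double + N₁₁ · 2r²/(r² + (1−r)²)] / (2N)

started at r = 0.25, clamped to [1e−9, 0.5] during iteration (the lower
clamp prevents absorption at r = 0 while double heterozygotes are present;
an estimate converging below 1e−8 is snapped to exactly 0), stopped when
|r' − r| < 1e−8 or after 1000 iterations.  The log-likelihood trace is
recorded and is non-decreasing (EM guarantee, asserted in tests).  LOD =
log₁₀ L(r̂) − log₁₀ L(0.5).  A 5001-point grid-search maximiser is kept as
a slow reference implementation and as the independent test oracle.

Distances: d = min(map(r̂), cap) with cap 100 cM, applied for every r (not
only r ≥ 0.5) so that d stays monotone in r̂ and finite; the round-trip
identity r↔d is preserved for all d below the cap.  Haldane is the default
map function (matching the simulator); Kosambi is selectable, under which
reported cM lengths shift by a few cM but orderings are driven by r̂.

## The objective scale

Matrices built by `recomb_matrix` carry `units="r"`: the orderers minimise
SARF proper, the summed adjacent recombination fractions, and the cM map
length of any order is reported alongside (`path_length_cm`).  Two reasons:

1. A cellwise monotone map preserves comparisons of individual distances
   but *not* of sums, so cM-SARF and r-SARF optima can genuinely differ;
   the criterion's definition is the sum of adjacent *r*.
2. The annealer's initial control parameter A = 2 is meaningful on the r
   scale: adjacent r's are at most 0.5, so typical move deltas are well
   under 2 and essentially every early candidate is accepted — the standard
   prescription for choosing A.  On the cM scale deltas are tens of units
   and A = 2 would freeze the chain into pure descent from the start.

True-map matrices built from positions (`DistanceMatrix.from_positions`)
default to cM units, where SARF is the map length itself.

## Simulated annealing

State: a permutation; energy: SARF.  At cooling step *n* with control
parameter c_n, each of L candidate moves is accepted if it does not worsen
SARF, or with probability exp(−Δ/c_n) otherwise (ties are accepted, per the
decision rule).  Defaults, all configurable:

| parameter | default | role |
|---|---|---|
| A | 2 | initial control parameter c₀ |
| schedule | linear, c_n = A·(1 − n/(m+1)) | strictly positive, non-increasing; geometric (α = 0.95) and logarithmic (A/ln(n+e)) available |
| m | 8000 | cooling steps |
| L | k | moves per cooling step |
| neighborhood | segment reversal | uniform contiguous block of length ≥ 2 (2-opt); position swap available |
| patience | disabled | optional early stop after stale cooling steps |

The neighborhood and budget defaults were chosen by measurement against the
protocol's own structural requirements.  Position swaps leave the chain
stuck in swap-local minima on noisy matrices at every budget tried (ties
with the deterministic method on the 21-marker group in only 15–45% of
runs), whereas segment reversal — the natural move for a path objective,
since reversing a block changes only its two boundary edges — reaches the
deterministic method's optimum in 100% of repetitions on the three sparser
benchmark groups at every population size while still matching it only
rarely on the saturated 51-marker group, the qualitative pattern this
comparison is about.  m = 8000 with L = k gives ≈ 4×10⁵ objective
evaluations at k = 51 (the budget scales with marker count, reflecting that
denser groups need more iterations); half that budget leaves even the
best-of-repetitions order above the deterministic method's on the dense
group.  Move deltas are evaluated in O(1) via the affected boundary edges,
so runs cost O(m·L) independent of how SARF scales with k.

Reproducibility: one seed drives the initial order and every draw;
`anneal_best_of` and the comparison protocol spawn independent child seeds
per repetition.  The returned best order is canonical and its SARF is
recomputed from scratch (no accumulated floating-point drift); the optional
per-iteration trajectory (iteration, temperature, current SARF, best SARF)
supports convergence plots.

## Rapid chain delineation

1. Seed the chain with the globally closest pair (smallest r̂; ties broken
   by lexicographically smallest index pair).
2. Repeatedly attach the unmapped marker with the smallest r̂ to either
   terminal, at that terminal (ties: lowest marker index, then the left
   terminal — any fixed rule works; one is needed for the method's
   determinism guarantee).
3. Polish by "ripple" passes: scan left to right, reversing any window of
   2 then 3 markers that strictly lowers SARF; alternate window sizes until
   a joint pass changes nothing (strict improvement prevents cycling; a
   50-pass cap guards degenerate float cases).

SARF never increases during ripple, so RCD's final SARF is bounded by its
chain's; the exhaustive oracle bounds it from below.  On unstructured
random matrices the greedy chain is frequently suboptimal (it attains the
k = 8 exhaustive optimum in about half of uniform-random instances); on
matrices estimated from genuinely linear maps — its intended input — it
attained the optimum in every tested instance.

## Comparison protocol

One simulated population per condition; per group: one RCD run and `reps`
independently seeded annealing runs (default 100; scaled runs use 20), all
on the same estimated matrix.  A repetition "wins" when its SARF is ≤
RCD's — ties count, because on the sparser groups both methods reach the
identical order and the interesting signal is whether annealing *fails* to.
Reported per group: win percentage, per-repetition SARFs, best-of-reps
order and SARF, cM map lengths, and wall-clock times (informational only;
never asserted).

Problem sizes in the test suite and acceptance script: 20 repetitions per
condition (the full protocol's 100 is used where the best-of-repetitions
claim on the 51-marker group is tested, since with 20 the best order ties
the deterministic method's only on a fraction of simulated populations),
population 50 for the headline comparison, all four sizes for the
sparse-group tie structure.

## Numerical and degenerate-input choices

- Win/tie and optimum comparisons use an absolute 1e−9 slack (pure float
  guard; SARF scales are O(1) in r units, O(100) in cM).
- Unlinked or near-unlinked pairs are capped at 100 cM (configurable);
  r̂ is clamped to [0, 0.5] throughout.
- A pair with zero complete observations raises an estimation error naming
  the pair; k < 2 matrices are rejected; the exhaustive oracle refuses
  k > 9.
- `DistanceMatrix` validates symmetry, zero diagonal and finiteness on
  construction and on file read.

## Known limitations

- Two-point information only; no multipoint likelihood, no linkage-group
  inference (groups are given), no segregation-distortion handling.
- The annealing defaults are tuned to linkage-like inputs (near-monotone
  distance structure plus estimation noise); fully unstructured TSP
  instances may need larger budgets.
- Simulated populations only; the MAPMAKER-raw reader accepts real F2
  intercross data, but the estimators assume co-dominant, error-free calls.
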