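# Methods

## Overview

`oceandecay` analyses how the composition of planktonic communities diverges
with surface-ocean transit time. Its pipeline has four layers: a Lagrangian
connectivity model producing station-pair transit times; β-diversity and
environmental distance matrices; permutation statistics and time-decay
models on those matrices; and cross-group regressions of the derived
dispersal statistics against body size and abundance. A synthetic-community
generator with known decay behaviour ties the layers together into testable
end-to-end claims.

## Surrogate flow and transit times

Real surface connectivity estimates come from global circulation models;
here an analytic stand-in supplies the same structural ingredients —
divergence-free flow, closed boundaries, mixing barriers, and asymmetric
transport — at desk scale. The flow is the classic periodically perturbed
double gyre, stream function `psi = A sin(pi f(xi, t)) sin(pi eta)` with
`f(xi, t) = e xi² + (1 − 2e) xi`, `e = eps sin(2 pi t / period)`, on
normalized coordinates `xi ∈ [0, 2]`, `eta ∈ [0, 1]`. Normal velocity
vanishes identically on all four walls; `eps = 0` gives a steady field with
stagnation points at the gyre centers; `eps > 0` makes the central barrier
oscillate so fluid is exchanged between the gyres through lobe dynamics.

Particles are advected with fixed-step 4th-order Runge–Kutta (default step
0.25 d) using horizontal velocities only and no added diffusivity; positions
are recorded every 3 days. Trajectories are aggregated onto a rectangular
patch grid: the *direct* transit time i→j is the minimum over all particles
and visit pairs of (time observed in j − an earlier time observed in i).
Because a finite simulation realizes only part of the connectivity, the
directed matrix is completed with Dijkstra's algorithm over the graph of
direct times (scipy `csgraph`); completion can only shorten entries,
preserves unreachability, is idempotent, and restores the triangle
inequality. Station-pair matrices take the patch-level entry of the patches
containing the stations, reduced to symmetric form by the elementwise
**minimum** of the two directions by default ("minimum connection time"
semantics; elementwise mean is available). Remaining unreachable pairs
propagate as missing values and are dropped from pair-level fits.

### Packaged test bed

`testbed.default_test_bed` fixes one configuration used throughout the
simulation studies: amplitude 0.1 degree/day, perturbation 0.02, period
20 d, 400 grid-seeded particles advected 1000 d, 20 × 10 patches on the
2° × 1° basin, minimum-direction symmetrization, and a `time_scale` of 25.
The time scale is an exact dynamical rescaling — slowing the gyre by a
factor s multiplies every transit time by s when the perturbation period is
scaled alike — chosen so station-pair times span roughly 25–600 days with
~15–20% of pairs inside the 100-day initial-similarity window. That range
exercises both sides of the S0 reference time while keeping runs at a few
seconds. What the test bed does *not* emulate: basin-scale asymmetries
of real oceans (times here span ~1.5 orders of magnitude, real surface
oceans ~4), seasonal variability, and any vertical structure.

## Similarity, environment, BIOENV

Community similarity is the Jaccard index on presence–absence data.
Dissimilarity for BIOENV, clustering, and Mantel tests is `1 − J`. Pairs
with an empty union (a + b + c = 0) are undefined and excluded rather than
imputed. Environmental distance is Euclidean over z-scored variables
(sample standard deviation, ddof = 1); zero-variance variables are rejected
by name. BIOENV enumerates every variable subset up to a size cap, scores
each by the Spearman rank correlation (average ranks on ties) between its
distances and the community dissimilarities, and breaks score ties toward
smaller, then lexicographically earlier, subsets.

## Permutation statistics

All matrix tests vectorize the upper triangle and permute rows and columns
of one matrix simultaneously (ANOSIM permutes labels). Conventions, recorded
in the result objects: one-tailed (greater) tests; `p = (1 + hits) /
(1 + n_perm)` so p can never be zero; default 9999 permutations; seeded
generators make runs bit-reproducible. The partial Mantel statistic is the
first-order partial correlation computed from the three pairwise Pearson
correlations, with the Y-permutation null holding r_xz fixed; it is
cross-checked in the tests against a residual-regression formulation. MRM
fits OLS on the vectorized triangles and permutes the response; the R²
p-value is one-tailed, coefficient p-values two-sided on |coefficient|.
Measured type-I error at nominal 0.05 over 200 independent-noise
simulations: Mantel ≈ 0.03–0.05, ANOSIM ≈ 0.05–0.06.

## Time-decay models and the halving-time

Two regressions describe the decline of similarity S with transit time t
(days, natural logarithms throughout):

* power law: `ln S = a + b ln t` — zero-similarity pairs are excluded (log
  undefined) and counted; b is the species spatial-turnover rate;
* logarithmic decay: `S = c ln t + int` — fitted on the raw similarity
  scale with zero-similarity pairs retained.

The initial similarity S0 is the *empirical mean* similarity over pairs with
t ≤ 100 days — deliberately not the fitted value of the decay line at
100 d, so S0 describes the data near the origin even when the global fit
under- or over-shoots there. When no pair is that close, the 10 smallest-t
pairs are averaged instead and the result is flagged.

The halving-time solves the fitted logarithmic model at `S = S0/2`:

    t_H = exp((S0/2 − int) / c),  c < 0,

reported in days and years (365.25 d/yr). This inversion is the only form
dimensionally consistent with the fitted model, and it exactly round-trips
published (c, S0, halving-time) triplets for all nine main biological
groups (max relative error < 1e-12 in the consistency check). Two
monotonicity facts worth stating precisely: t_H decreases as the decay
steepens (|c| larger, int and S0 fixed); and t_H increases with S0 *when
the fitted line is anchored through (100 d, S0)* so the intercept co-varies
— holding the intercept fixed instead, a larger S0 halves earlier, since
the halving threshold S0/2 then sits higher on the same curve.

## Synthetic communities

The generator produces presence–absence matrices whose expected Jaccard
similarity declines approximately linearly in ln(transit time) at a
prescribed slope c\* and initial similarity S0\*. Each taxon chooses a focal
station and a transit-time radius R, occupying every station within R of
the focal. Radii follow a Lomax (shifted-Pareto) law,
`P(R > r) = (1 + r/tau)^(−alpha)`: the heavy tail is what makes the decay
of expected similarity logarithmic rather than exponential. For a station
pair (i, j) the large-pool expectation is available in closed form,

    E[J(i,j)] ≈ Σ_f S_R(max(T_fi, T_fj)) / Σ_f S_R(min(T_fi, T_fj)),

so (alpha, tau) are calibrated by least squares in log-parameter space,
matching *exactly the estimators used downstream* (log-decay slope and
S0 of the expected curve) to (c\*, S0\*). Calibration fails loudly when the
targets are infeasible on the given transit matrix (implied similarity ≤ 0
at the maximum transit time) or unreachable by the Lomax family.

Sampling uses stratified radius quantiles and focal stations cycling
through the station list: marginal distributions are exact while
between-seed variance from the heavy tail roughly halves. Empty stations
(rare) receive one private taxon each, so no station row is all-zero.
Validation on the packaged test bed: the realized expectation matches the
calibration curve to within ±0.6% in slope across the target range
(c\* from −0.0116 to −0.0562), and 20-seed recovery at 25 stations ×
500 taxa returns mean c within a few percent and S0 within ±0.01.

Abundance is attached as group metadata only — all analyses are
presence–absence, so generation never consumes it. The default 9-group
ensemble assigns decay slopes by `c = −0.042 − 0.004 ln(size mm)` and
abundances by `ln A = 5.002 − 2.820 ln(size mm)`, with a common
S0\* = 0.45 (mid-range of the packaged group summaries, which span
0.12–0.55).

## Cross-group scaling regressions

The packaged, checksum-guarded TSV transcribes published per-group
summaries: 17 groups spanning body sizes from 0.0005 mm (prokaryotes) to
35 mm (myctophid fishes), with decay slope, S0, halving-time, size
statistics, habitat, and abundances for the nine main groups. Six
regressions relate ln(halving-time) and the raw decay slope c to ln(size)
and ln(abundance) over the 9-group and 16-group sets. Conventions that
matter and are verified numerically in the tests: halving-times are
converted to **days** before the log transform (year units shift only the
intercept); c is regressed **untransformed** on ln size (its logarithm is
undefined — c < 0); adjusted r² uses the (n − 2) correction; RMSE is the
regression standard error `sqrt(SSR/(n − 2))`.

Bootstrap CIs use case resampling with B = 10,000 by default. Three
interval flavors are implemented; the default is the studentized
bootstrap-t because measured coverage of 95% intervals at n = 9 in this
design is ~0.89 for plain percentile, ~0.90 for BCa, and ~0.95 for
bootstrap-t under well-behaved errors. On the heteroskedastic errors of the
end-to-end ensemble experiment the realized coverage of all flavors is
~0.90 — a known small-sample limitation of case-resampling intervals that
readers should keep in mind when interpreting the 95% label at n = 9.
Degenerate resamples (all x identical, or zero within-resample slope
standard error) are redrawn; an exactly collinear input yields the
degenerate interval at the point estimate.

## Clustering and networks

Stations are clustered by UPGMA (average linkage) on Jaccard distances;
scipy's deterministic merge order breaks ties. Selecting a *significant*
number of clusters requires care: testing cluster labels with
label-permutation ANOSIM on the same matrix that produced them is circular
and wildly anticonservative (measured null selection rate ~80% at
alpha = 0.05). `select_cluster_count` therefore scores each candidate k
against a matrix-shuffle null — surrogate matrices with the condensed
dissimilarities randomly permuted are re-clustered and re-scored — which is
exact under an exchangeable-noise null (measured null selection ≈ the
nominal level) and approximate for strongly metric data (shuffled
surrogates are not metric). The descriptive label-permutation ANOSIM R and
p are still attached to the chosen clustering. Similarity networks keep
edges at or above the largest threshold leaving every node with at least
`min_degree` neighbours (equivalently, the minimum over nodes of each
node's min_degree-th largest similarity); lowering `min_degree` can only
raise the threshold.

## Problem sizes and determinism

The simulation studies run at: 25 stations, 500 taxa, 20 seeds for
(c\*, S0\*) recovery; 50 replicate 9-group ensembles with B = 1000 CIs for
scaling-law coverage; 200 simulations with 199 permutations for type-I
error; 200 simulations with B = 500 for bootstrap coverage. These sizes
keep each study in the seconds-to-a-minute range while leaving Monte-Carlo
noise well below the effect sizes being checked. Every stochastic component
takes an explicit seed, and derived seeds come from numpy `SeedSequence`
paths, so all results are bit-reproducible for a given master seed.

## Known limitations

- The double-gyre surrogate compresses the dynamic range of real
  ocean transit times and has no land masses, so absolute halving-times
  from the test bed are not comparable to observational values — only the
  internal consistency and ordering of groups is meaningful.
- The occupancy-ball generator reproduces the first moment of the
  similarity–time relation, not the taxon-richness spectrum, occupancy
  distributions, or abundance structure of real communities; passing
  recovery tests demonstrate estimator correctness, not ecological realism.
- Presence–absence Jaccard is insensitive to dominance shifts;
  abundance-weighted indices are out of scope by design.
- BIOENV enumerates subsets exhaustively and is exponential in the number
  of candidate variables; it is intended for the handful of variables
  typical of shipboard sensor suites.
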