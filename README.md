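# oceandecay

**Planktonic β-diversity along surface-ocean transit times: time-decay
models, halving-time dispersal scales, and body-size scaling.**

Over long timescales every part of the surface ocean is connected by
currents, but the *time* it takes water to travel between two sites varies
by orders of magnitude. For passively dispersed plankton this transit time —
not raw geographic distance — is the natural axis along which communities
diverge. `oceandecay` implements the full analysis chain linking community
composition to ocean connectivity:

- **Surrogate connectivity** (`flow`, `transit`, `testbed`): an analytic,
  periodically perturbed double-gyre flow on a closed basin stands in for a
  global circulation model. Virtual particles are advected with fixed-step
  RK4 (horizontal velocities only, no added diffusivity), trajectories are
  aggregated to a patch grid as *direct* minimum connection times, and the
  directed patch-to-patch matrix is completed with Dijkstra's shortest-path
  algorithm — pairs never realized directly can still be connected through
  intermediate patches.
- **Community metrics** (`metrics`): presence–absence Jaccard similarity
  `J = a / (a + b + c)` (a = shared taxa, b and c = taxa private to each
  site); Euclidean environmental distance over z-scored variables; BIOENV
  exhaustive subset selection maximizing the Spearman rank correlation with
  community dissimilarity.
- **Matrix permutation statistics** (`matrixstats`): Mantel, partial Mantel,
  multiple regression on distance matrices (MRM), and ANOSIM, all one-tailed
  with `p = (1 + hits) / (1 + n_perm)` and seeded, bit-reproducible
  permutations (default 9999).
- **Time-decay models** (`decay`): the power-law fit `ln S = a + b ln t` and
  the logarithmic decay `S = c ln t + int`; the initial similarity `S0`
  (mean J over station pairs within 100 days transit time); and the
  halving-time

  ```
  t_H = exp((S0/2 − int) / c),    c < 0,
  ```

  the transit time at which fitted similarity falls to half its initial
  value — a proxy for the community's dispersal scale.
- **Cross-group scaling** (`scaling`): packaged per-group summaries (decay
  slope, S0, halving-time, body size, abundance) for 17 pelagic groups from
  prokaryotes to lanternfishes, and the six log–log regressions of
  halving-time and decay slope against body size and local abundance, with
  parametric fits plus case-resampling bootstrap CIs (studentized by
  default).
- **Synthetic communities** (`synth`, `experiments`): a generator with
  *known* decay behaviour — taxa occupy "balls" in transit-time space with
  heavy-tailed (Lomax) radii calibrated so the downstream estimators recover
  prescribed (c\*, S0\*) — used for end-to-end validation of every stage.
- **Biogeography** (`clusternet`): UPGMA clustering of Jaccard distances,
  cluster-count selection against a matrix-shuffle null, and similarity
  networks thresholded to a minimum node degree (GraphML / edge-list
  export).

## Worked example

```python
import numpy as np
from oceandecay import (
    default_test_bed, generate_env_fields, generate_group_community,
    GroupDispersalParams, jaccard_matrix, env_distance_matrix,
    mantel, partial_mantel, group_decay_analysis,
)
from oceandecay.pairwise import PairwiseMatrix

# 25 stations in the double-gyre basin + completed transit-time matrix (days)
stations, transit = default_test_bed(n_stations=25, seed=42)

# a macrozooplankton-like community: steep decay, high initial similarity
params = GroupDispersalParams(
    name="macrozooplankton", size_mean_mm=5.4, abundance_per_m3=0.179,
    c_target=-0.055, s0_target=0.5, n_taxa=500, seed=7,
)
community = generate_group_community(stations, transit, params)
similarity = jaccard_matrix(community)

# weakly transit-coupled environment, as in the open ocean
stations_env = generate_env_fields(stations, transit, coupling=0.3, seed=1)
env_dist = env_distance_matrix(
    stations_env, ["temperature", "salinity", "oxygen", "fluorescence", "turbidity"]
)

dissim = PairwiseMatrix(1 - similarity.values, similarity.labels, kind="distance")
m1 = mantel(dissim, transit, n_perm=9999, seed=0)
m2 = partial_mantel(dissim, transit, env_dist, n_perm=9999, seed=0)
print(f"Mantel r (dissimilarity vs transit time): {m1.r:.2f} (p = {m1.p:.4f})")
print(f"  partialling out environment:            {m2.r:.2f} (p = {m2.p:.4f})")

logdecay, loglog = group_decay_analysis(similarity, transit)
print(f"time-decay slope c = {logdecay.slope:.4f} per ln day, "
      f"intercept = {logdecay.intercept:.3f}")
print(f"S0 (mean similarity at <= 100 d) = {logdecay.s0:.3f}")
print(f"halving-time = {logdecay.halving_days:.0f} days "
      f"({logdecay.halving_years:.1f} years)")
```

Output:

```
Mantel r (dissimilarity vs transit time): 0.68 (p = 0.0001)
  partialling out environment:            0.68 (p = 0.0001)
time-decay slope c = -0.0598 per ln day, intercept = 0.776
S0 (mean similarity at <= 100 d) = 0.506
halving-time = 6313 days (17.3 years)
```

Community dissimilarity rises strongly with transit time (Mantel r = 0.68)
and the correlation is untouched by controlling for the environment — the
signature of dispersal-limited community assembly. The fitted decay slope is
close to the generator's target (−0.055), and the halving-time of ~17 years
places this synthetic group in the range typical of large-bodied
zooplankton, orders of magnitude shorter than the millennia-scale
halving-times of highly abundant microbes.

A thin CLI covers the file-based workflows:

```sh
oceandecay transit simulate --config flow.yaml --out transit.csv
oceandecay metrics bioenv --community comm.tsv --stations stations.csv
oceandecay stats mantel --x jaccard_dist.csv --y transit.csv --nperm 9999 --seed 1
oceandecay scaling cross-group --out report.tsv
```

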