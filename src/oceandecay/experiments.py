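"""Simulation studies: parameter recovery, law coverage, test calibration.

These experiments exercise the full pipeline on the packaged double-gyre
test bed and quantify how well it behaves: whether communities generated
with known decay targets are recovered by the fits, whether the cross-group
scaling laws survive the end-to-end analysis, and whether the permutation
tests and bootstrap intervals hold their nominal levels. They back both the
test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .decay import build_pairs, fit_logdecay, initial_similarity
from .matrixstats import anosim, mantel
from .metrics import jaccard_matrix
from .pairwise import PairwiseMatrix
from .scaling import bootstrap_slope_ci
from .synth import (
    DEFAULT_ABUNDANCE_SIZE_LAW,
    DEFAULT_DECAY_SIZE_LAW,
    DEFAULT_ENSEMBLE_S0,
    DEFAULT_SIZE_SPECTRUM_MM,
    GroupDispersalParams,
    calibrate_radius_distribution,
    generate_group_community,
)
from .testbed import default_test_bed

__all__ = [
    "recovery_experiment",
    "ensemble_law_coverage",
    "mantel_type_i_error",
    "anosim_type_i_error",
    "bootstrap_coverage",
]


def _subseed(seed: int, *path: int) -> int:
    """Stable derived seed below 2**31."""
    return int(np.random.default_rng([seed, *path]).integers(2**31 - 1))


def recovery_experiment(
    c_target: float = -0.03,
    s0_target: float = 0.4,
    n_seeds: int = 20,
    n_stations: int = 25,
    n_taxa: int = 500,
    seed: int = 0,
) -> dict:
    """Generate-and-refit: do the decay estimators recover (c*, S0*)?"""
    stations, transit = default_test_bed(n_stations=n_stations, seed=seed)
    radius_params = calibrate_radius_distribution(transit, c_target, s0_target)
    cs, s0s = [], []
    for k in range(n_seeds):
        params = GroupDispersalParams(
            "recovery", 1.0, 1.0, c_target, s0_target,
            n_taxa=n_taxa, seed=_subseed(seed, 1, k),
        )
        comm = generate_group_community(stations, transit, params, radius_params)
        pairs = build_pairs(jaccard_matrix(comm), transit)
        cs.append(fit_logdecay(pairs).slope)
        s0s.append(initial_similarity(pairs)[0])
    mean_c = float(np.mean(cs))
    mean_s0 = float(np.mean(s0s))
    return {
        "c_target": c_target,
        "s0_target": s0_target,
        "mean_c": mean_c,
        "c_rel_err": (mean_c - c_target) / abs(c_target),
        "mean_s0": mean_s0,
        "s0_abs_err": mean_s0 - s0_target,
        "n_seeds": n_seeds,
    }


def ensemble_law_coverage(
    n_replicates: int = 50,
    n_stations: int = 25,
    n_taxa: int = 500,
    B: int = 1000,
    seed: int = 0,
    s0_target: float = DEFAULT_ENSEMBLE_S0,
) -> dict:
    """Do bootstrap CIs of the cross-group slopes cover the generating laws?

    For each replicate, a 9-group ensemble is generated under the default
    decay-size and abundance-size laws, the per-group decay slope is
    re-estimated end to end, and both cross-group regressions are
    re-fitted with case-resampling bootstrap CIs. Coverage counts
    replicates whose CIs contain the generating slopes.
    """
    stations, transit = default_test_bed(n_stations=n_stations, seed=seed)
    sizes = np.asarray(DEFAULT_SIZE_SPECTRUM_MM)
    a_int, a_slope = DEFAULT_ABUNDANCE_SIZE_LAW
    c_int, c_slope = DEFAULT_DECAY_SIZE_LAW
    targets = c_int + c_slope * np.log(sizes)
    abundances = np.exp(a_int + a_slope * np.log(sizes))
    calibs = [
        calibrate_radius_distribution(transit, float(ct), s0_target)
        for ct in targets
    ]
    cover_c = cover_a = cover_both = 0
    c_law_slopes = []
    tol = 1e-9
    for rep in range(n_replicates):
        fitted_c = []
        for g, size in enumerate(sizes):
            params = GroupDispersalParams(
                f"group{g:02d}", float(size), float(abundances[g]),
                float(targets[g]), s0_target, n_taxa=n_taxa,
                seed=_subseed(seed, 2, rep, g),
            )
            comm = generate_group_community(stations, transit, params, calibs[g])
            pairs = build_pairs(jaccard_matrix(comm), transit)
            fitted_c.append(fit_logdecay(pairs).slope)
        lo_c, hi_c = bootstrap_slope_ci(
            sizes, np.asarray(fitted_c), transform="logx", B=B,
            seed=_subseed(seed, 3, rep),
        )
        lo_a, hi_a = bootstrap_slope_ci(
            sizes, abundances, transform="loglog", B=B,
            seed=_subseed(seed, 4, rep),
        )
        ok_c = lo_c - tol <= c_slope <= hi_c + tol
        ok_a = lo_a - tol <= a_slope <= hi_a + tol
        cover_c += ok_c
        cover_a += ok_a
        cover_both += ok_c and ok_a
        xc = np.log(sizes) - np.log(sizes).mean()
        yc = np.asarray(fitted_c) - np.mean(fitted_c)
        c_law_slopes.append(float(xc @ yc / (xc @ xc)))
    return {
        "coverage_decay_law": cover_c / n_replicates,
        "coverage_abundance_law": cover_a / n_replicates,
        "coverage_both": cover_both / n_replicates,
        "mean_fitted_decay_law_slope": float(np.mean(c_law_slopes)),
        "decay_law_slope_target": c_slope,
        "n_replicates": n_replicates,
    }


def _random_distance(n: int, rng: np.random.Generator) -> PairwiseMatrix:
    vals = rng.random(n * (n - 1) // 2)
    return PairwiseMatrix.from_condensed(vals, [f"s{i}" for i in range(n)])


def mantel_type_i_error(
    n_sims: int = 200,
    n_stations: int = 15,
    n_perm: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Rejection rate of the Mantel test on independent matrices."""
    rng = np.random.default_rng([seed, 10])
    rejections = 0
    for k in range(n_sims):
        X = _random_distance(n_stations, rng)
        Y = _random_distance(n_stations, rng)
        res = mantel(X, Y, n_perm=n_perm, seed=_subseed(seed, 11, k))
        rejections += res.p <= alpha
    return {"rate": rejections / n_sims, "n_sims": n_sims, "alpha": alpha}


def anosim_type_i_error(
    n_sims: int = 200,
    n_stations: int = 16,
    n_perm: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Rejection rate of ANOSIM with random balanced group labels."""
    rng = np.random.default_rng([seed, 20])
    half = n_stations // 2
    rejections = 0
    for k in range(n_sims):
        D = _random_distance(n_stations, rng)
        labels = rng.permutation(["a"] * half + ["b"] * (n_stations - half))
        res = anosim(D, labels, n_perm=n_perm, seed=_subseed(seed, 21, k))
        rejections += res.p <= alpha
    return {"rate": rejections / n_sims, "n_sims": n_sims, "alpha": alpha}


def bootstrap_coverage(
    n_sims: int = 200,
    n_points: int = 15,
    B: int = 500,
    seed: int = 0,
) -> dict:
    """Coverage of the 95% bootstrap slope CI when the true slope is 0."""
    rng = np.random.default_rng([seed, 30])
    covered = 0
    for k in range(n_sims):
        x = np.exp(rng.normal(size=n_points))
        y = rng.normal(size=n_points)
        lo, hi = bootstrap_slope_ci(
            x, y, transform="logx", B=B, seed=_subseed(seed, 31, k)
        )
        covered += lo <= 0.0 <= hi
    return {"coverage": covered / n_sims, "n_sims": n_sims}
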