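"""Synthetic stations, environments, and communities with known time-decay.

Ground truth for every downstream stage: station sets scattered in the flow
domain, environmental fields whose correlation with transit time is dialed
by a single coupling knob, and presence-absence communities engineered so
that the expected pairwise Jaccard similarity declines approximately
linearly with ln(transit time) at a prescribed slope c* and initial
similarity S0*.

The community construction is an occupancy-ball model: each taxon picks a
focal station and a transit-time radius drawn from a heavy-tailed Lomax
distribution, and occupies every station within that radius of the focal.
Heavy tails make the expected similarity a slowly (≈ logarithmically)
decaying function of transit time; the two Lomax parameters (tail index
alpha, scale tau) are calibrated numerically against (c*, S0*) by matching
the exact expected-similarity curve — computable in closed form given the
transit matrix — through the same estimators used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .decay import (
    S0_FALLBACK_PAIRS,
    S0_REFERENCE_DAYS,
)
from .pairwise import PairwiseMatrix

__all__ = [
    "GroupDispersalParams",
    "generate_stations",
    "generate_env_fields",
    "generate_group_community",
    "generate_group_ensemble",
    "community_from_balls",
    "calibrate_radius_distribution",
    "DEFAULT_SIZE_SPECTRUM_MM",
    "DEFAULT_ABUNDANCE_SIZE_LAW",
    "DEFAULT_DECAY_SIZE_LAW",
]

Bounds = tuple[float, float, float, float]

# nine main-group body-size means (mm), prokaryotes to myctophids
DEFAULT_SIZE_SPECTRUM_MM = (0.0005, 0.002, 0.014, 0.033, 0.043, 2.65, 5.0, 5.4, 35.0)
# ln(abundance per m^3) = 5.002 - 2.820 ln(size mm)
DEFAULT_ABUNDANCE_SIZE_LAW = (5.002, -2.820)
# decay slope c = -0.042 - 0.004 ln(size mm)
DEFAULT_DECAY_SIZE_LAW = (-0.042, -0.004)
DEFAULT_ENSEMBLE_S0 = 0.45


@dataclass
class GroupDispersalParams:
    """Generator targets for one biological group."""

    name: str
    size_mean_mm: float
    abundance_per_m3: float
    c_target: float          # similarity per ln day, negative
    s0_target: float         # dimensionless in (0, 1]
    n_taxa: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.c_target < 0:
            raise ValueError("target decay slope c* must be negative")
        if not 0 < self.s0_target <= 1:
            raise ValueError("target S0* must lie in (0, 1]")
        if self.size_mean_mm <= 0 or self.abundance_per_m3 <= 0:
            raise ValueError("size and abundance must be positive")


def generate_stations(
    n: int,
    domain: Bounds = (0.0, 2.0, 0.0, 1.0),
    seed: int | None = None,
) -> pd.DataFrame:
    """Uniform random sampling stations inside the flow domain."""
    if n < 3:
        raise ValueError("need at least 3 stations for matrix statistics")
    x0, x1, y0, y1 = domain
    rng = np.random.default_rng(seed)
    width = max(3, len(str(n)))
    return pd.DataFrame(
        {
            "station": [f"st{i:0{width}d}" for i in range(n)],
            "x": rng.uniform(x0, x1, size=n),
            "y": rng.uniform(y0, y1, size=n),
        }
    )


# smooth basis fields: deterministic functions of position (normalized to
# the station bounding box), one per standard variable name
def _smooth_basis(xn: np.ndarray, yn: np.ndarray) -> dict[str, np.ndarray]:
    return {
        "temperature": -yn + 0.2 * np.sin(np.pi * xn),
        "salinity": np.sin(np.pi * xn) * np.cos(0.5 * np.pi * yn),
        "oxygen": ((xn - 0.5) ** 2 + (yn - 0.5) ** 2),
        "fluorescence": np.cos(2 * np.pi * xn) + 0.5 * yn,
        "turbidity": xn * yn,
    }


def generate_env_fields(
    stations: pd.DataFrame,
    transit: PairwiseMatrix | None = None,
    coupling: float = 0.0,
    seed: int | None = None,
    noise: float = 1.0,
) -> pd.DataFrame:
    """Attach environmental variables with controllable spatial structure.

    Each variable is ``coupling * smooth(x, y) + (1 - coupling) * noise``,
    with the smooth part a fixed function of position standardized across
    stations. At ``coupling = 0`` the variables are pure noise, so the
    expected Mantel correlation between environmental distance and any
    spatially structured matrix (e.g. transit time) is ~0; the correlation
    grows monotonically with ``coupling``. At ``coupling = 1`` and
    ``noise = 0`` the fields are deterministic functions of position.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = stations.copy()
    x = out["x"].to_numpy(dtype=float)
    y = out["y"].to_numpy(dtype=float)
    xn = (x - x.min()) / max(np.ptp(x), 1e-12)
    yn = (y - y.min()) / max(np.ptp(y), 1e-12)
    for name, f in _smooth_basis(xn, yn).items():
        sd = f.std()
        smooth = (f - f.mean()) / (sd if sd > 0 else 1.0)
        eps = rng.standard_normal(len(out)) * noise
        out[name] = coupling * smooth + (1.0 - coupling) * eps
    return out


# --------------------------------------------------------------------------
# occupancy-ball community construction
# --------------------------------------------------------------------------


def _lomax_survival(r: np.ndarray, alpha: float, tau: float) -> np.ndarray:
    return (1.0 + r / tau) ** (-alpha)


def _expected_jaccard_curve(
    tmin: np.ndarray, tmax: np.ndarray, alpha: float, tau: float
) -> np.ndarray:
    """Expected Jaccard per pair from the ball model, in closed form.

    For a taxon with focal f and radius R, the pair (i, j) shares it iff
    R >= max(T[f,i], T[f,j]) and at least one of them holds it iff
    R >= min(...). With many taxa, J(i,j) -> sum_f S(max) / sum_f S(min)
    where S is the radius survival function. ``tmin``/``tmax`` have shape
    (n_focals, n_pairs).
    """
    num = _lomax_survival(tmax, alpha, tau).sum(axis=0)
    den = _lomax_survival(tmin, alpha, tau).sum(axis=0)
    return num / den


def _fit_c_s0(jexp: np.ndarray, t: np.ndarray) -> tuple[float, float]:
    """Apply the downstream estimators (log-decay slope, S0) to a curve."""
    res = stats.linregress(np.log(t), jexp)
    near = t <= S0_REFERENCE_DAYS
    if near.any():
        s0 = float(jexp[near].mean())
    else:
        idx = np.argsort(t)[: min(S0_FALLBACK_PAIRS, t.size)]
        s0 = float(jexp[idx].mean())
    return float(res.slope), s0


def calibrate_radius_distribution(
    transit: PairwiseMatrix,
    c_target: float,
    s0_target: float,
) -> tuple[float, float]:
    """Solve for Lomax (alpha, tau) matching the (c*, S0*) targets.

    Matches the slope and S0 that the downstream estimators would report on
    the exact expected-similarity curve. Raises if the target combination is
    infeasible (implied similarity below 0 at the maximum transit time) or
    if no radius distribution reproduces it on this transit matrix.
    """
    T = np.where(np.isfinite(transit.values), transit.values, np.nan)
    n = T.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    t_pair = T[iu, ju]
    valid = np.isfinite(t_pair) & (t_pair > 0)
    if valid.sum() < 3:
        raise ValueError("transit matrix has fewer than 3 usable pairs")
    t_pair = t_pair[valid]
    # feasibility: the target line must stay positive over the observed range
    t_max = t_pair.max()
    implied_end = s0_target + c_target * (np.log(t_max) - np.log(S0_REFERENCE_DAYS))
    if implied_end <= 0:
        raise ValueError(
            f"infeasible targets: implied similarity {implied_end:.3f} <= 0 "
            f"at max transit time {t_max:.0f} d"
        )
    # (n_focals, n_pairs) max/min of focal-to-endpoint times, fixed once
    Ti = T[:, iu[valid]]
    Tj = T[:, ju[valid]]
    tmax = np.fmax(Ti, Tj)
    tmin = np.fmin(Ti, Tj)
    # focals with missing times to an endpoint contribute nothing for it
    bad = ~np.isfinite(tmax) | ~np.isfinite(tmin)
    tmax = np.where(bad, np.inf, tmax)
    tmin = np.where(bad, np.inf, tmin)

    def residuals(logp: np.ndarray) -> np.ndarray:
        alpha, tau = np.exp(logp)
        c_fit, s0_fit = _fit_c_s0(
            _expected_jaccard_curve(tmin, tmax, alpha, tau), t_pair
        )
        return np.array(
            [(c_fit - c_target) / abs(c_target), (s0_fit - s0_target) / 0.05]
        )

    t_med = float(np.median(t_pair))
    best = None
    for alpha0, tau0 in [(1.0, t_med), (0.5, t_med / 4), (2.0, 4 * t_med),
                         (0.3, t_med), (1.0, t_med / 20)]:
        sol = optimize.least_squares(
            residuals, np.log([alpha0, tau0]), method="lm", xtol=1e-12
        )
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-6:
            break
    resid = residuals(best.x)
    if abs(resid[0]) > 0.05 or abs(resid[1]) > 0.5:  # 5% on c, 0.025 on S0
        raise ValueError(
            "no radius distribution reproduces the (c*, S0*) targets on this "
            f"transit matrix (residuals {resid})"
        )
    alpha, tau = np.exp(best.x)
    return float(alpha), float(tau)


def community_from_balls(
    transit: PairwiseMatrix,
    focal_idx: np.ndarray,
    radii: np.ndarray,
    taxon_prefix: str = "taxon",
) -> pd.DataFrame:
    """Binary community table from explicit focal stations and radii.

    Station s holds taxon k iff the (symmetric) transit time from the
    taxon's focal station is within its radius; unreachable pairs are never
    within any finite radius. Taxa that occupy no station are dropped.
    """
    T = np.where(np.isfinite(transit.values), transit.values, np.inf)
    occupancy = T[np.asarray(focal_idx, dtype=int), :] <= np.asarray(radii)[:, None]
    X = occupancy.T.astype(np.int8)  # stations x taxa
    keep = X.sum(axis=0) > 0
    X = X[:, keep]
    cols = [f"{taxon_prefix}_{k:05d}" for k in range(X.shape[1])]
    return pd.DataFrame(X, index=transit.labels, columns=cols)


def generate_group_community(
    stations: pd.DataFrame,
    transit: PairwiseMatrix,
    params: GroupDispersalParams,
    radius_params: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Generate one group's presence-absence matrix with target decay.

    Calibrates the radius distribution against (c*, S0*) on the supplied
    transit matrix, then samples ``params.n_taxa`` taxa (uniform focal
    station, Lomax radius). Stations left empty by sampling noise receive an
    extra private taxon each, so no station row is all-zero. Pass
    ``radius_params = (alpha, tau)`` to reuse a previous calibration.
    """
    if list(stations["station"].astype(str)) != transit.labels:
        raise ValueError("station table and transit matrix disagree on stations")
    alpha, tau = radius_params or calibrate_radius_distribution(
        transit, params.c_target, params.s0_target
    )
    rng = np.random.default_rng(params.seed)
    n = transit.n
    N = params.n_taxa
    # stratified draws: focals cycle through stations, radius quantiles are
    # stratified across taxa (exact marginals, far less between-seed noise
    # from the heavy tail)
    focal = rng.permutation(np.resize(np.arange(n), N))
    u = rng.permutation((np.arange(N) + rng.random(N)) / N)
    radii = tau * ((1.0 - u) ** (-1.0 / alpha) - 1.0)
    comm = community_from_balls(transit, focal, radii, taxon_prefix=params.name)
    empty = np.flatnonzero(comm.to_numpy().sum(axis=1) == 0)
    if empty.size:
        extra = community_from_balls(
            transit, empty, np.zeros(empty.size), taxon_prefix=f"{params.name}_fill"
        )
        comm = pd.concat([comm, extra], axis=1)
    return comm


def generate_group_ensemble(
    size_spectrum_mm=DEFAULT_SIZE_SPECTRUM_MM,
    abundance_law: tuple[float, float] = DEFAULT_ABUNDANCE_SIZE_LAW,
    decay_law: tuple[float, float] = DEFAULT_DECAY_SIZE_LAW,
    seed: int = 0,
    stations: pd.DataFrame | None = None,
    transit: PairwiseMatrix | None = None,
    s0_target: float = DEFAULT_ENSEMBLE_S0,
    n_taxa: int = 500,
) -> list[tuple[GroupDispersalParams, pd.DataFrame]]:
    """One community per body-size class under the default scaling laws.

    The decay slope and abundance of each size class follow the configured
    (intercept, slope) laws in ln(size mm); abundance is carried as group
    metadata only (all analyses are presence-absence). Stations and transit
    default to the packaged double-gyre test bed.
    """
    sizes = np.asarray(size_spectrum_mm, dtype=float)
    if sizes.size == 0:
        raise ValueError("size spectrum must be non-empty")
    if stations is None or transit is None:
        from .testbed import default_test_bed

        stations, transit = default_test_bed(seed=seed)
    a_int, a_slope = abundance_law
    c_int, c_slope = decay_law
    out = []
    for g, size in enumerate(sizes):
        params = GroupDispersalParams(
            name=f"group{g:02d}",
            size_mean_mm=float(size),
            abundance_per_m3=float(np.exp(a_int + a_slope * np.log(size))),
            c_target=float(c_int + c_slope * np.log(size)),
            s0_target=s0_target,
            n_taxa=n_taxa,
            seed=int(np.random.default_rng([seed, g]).integers(2**31 - 1)),
        )
        out.append((params, generate_group_community(stations, transit, params)))
    return out
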