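"""Permutation statistics on distance/similarity matrices.

Mantel, partial Mantel, multiple regression on distance matrices (MRM) and
ANOSIM, all with the same permutation machinery: rows and columns of one
matrix (or the group labels, for ANOSIM) are permuted simultaneously,
statistics are recomputed on vectorized upper triangles, and the p-value
includes the observed statistic in the reference set,
p = (1 + #{permuted >= observed}) / (1 + n_perm), so it can never be 0.
Tests are one-tailed (greater) unless noted — the ecological convention for
positive matrix association. Default n_perm = 9999.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .pairwise import PairwiseMatrix

__all__ = [
    "MantelResult",
    "MRMResult",
    "AnosimResult",
    "mantel",
    "partial_mantel",
    "mrm",
    "anosim",
]

DEFAULT_PERMUTATIONS = 9999


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    n_stations: int
    partialled: str | None = None
    tail: str = "greater"
    seed: int | None = None


@dataclass
class MRMResult:
    coefficients: dict[str, float]
    intercept: float
    r_squared: float
    coef_p: dict[str, float]
    r_squared_p: float
    n_perm: int
    seed: int | None = None
    # conventions recorded so output is self-describing
    meta: dict = field(
        default_factory=lambda: {
            "r_squared_tail": "greater",
            "coef_tail": "two-sided on |coef|",
            "p_correction": "+1/+1",
        }
    )


@dataclass
class AnosimResult:
    R: float
    p: float
    n_perm: int
    groups: dict[str, int]
    seed: int | None = None


def _condensed(m: PairwiseMatrix) -> np.ndarray:
    v = m.condensed()
    if not np.all(np.isfinite(v)):
        raise ValueError("matrix has missing pairs; drop or complete them first")
    return v


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("constant matrix: Mantel correlation undefined")
    return float((xc @ yc) / denom)


def _triu_of_permuted(values: np.ndarray, perm: np.ndarray, iu) -> np.ndarray:
    p = values[np.ix_(perm, perm)]
    return p[iu]


def mantel(
    X: PairwiseMatrix,
    Y: PairwiseMatrix,
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
) -> MantelResult:
    """Mantel test: Pearson correlation of two distance matrices.

    The permutation null simultaneously permutes rows and columns of Y;
    one-tailed (greater).
    """
    X.align_with(Y)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = X.n
    iu = np.triu_indices(n, k=1)
    x = _condensed(X)
    y = _condensed(Y)
    r_obs = _pearson(x, y)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = _pearson(x, _triu_of_permuted(Y.values, perm, iu))
        if r_p >= r_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, n_stations=n, seed=seed)


def _partial_r(rxy: float, rxz: float, ryz: float) -> float:
    denom = (1 - rxz**2) * (1 - ryz**2)
    if denom <= 0:
        raise ValueError("degenerate partial correlation: a control correlation is +/-1")
    return (rxy - rxz * ryz) / np.sqrt(denom)


def partial_mantel(
    X: PairwiseMatrix,
    Y: PairwiseMatrix,
    Z: PairwiseMatrix,
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
) -> MantelResult:
    """Partial Mantel: correlation of X and Y controlling for Z.

    Uses the first-order partial-correlation formula on vectorized upper
    triangles; the null permutes Y (rows and columns jointly) and recomputes
    the partial statistic with r_xz held fixed.
    """
    X.align_with(Y)
    X.align_with(Z)
    n = X.n
    iu = np.triu_indices(n, k=1)
    x, y, z = _condensed(X), _condensed(Y), _condensed(Z)
    rxz = _pearson(x, z)
    r_obs = _partial_r(_pearson(x, y), rxz, _pearson(y, z))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = _triu_of_permuted(Y.values, perm, iu)
        r_p = _partial_r(_pearson(x, yp), rxz, _pearson(yp, z))
        if r_p >= r_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return MantelResult(
        r=float(r_obs), p=p, n_perm=n_perm, n_stations=n, partialled="Z", seed=seed
    )


def mrm(
    response: PairwiseMatrix,
    predictors: dict[str, PairwiseMatrix],
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
) -> MRMResult:
    """Multiple regression on distance matrices.

    OLS of the response upper triangle on the predictor upper triangles;
    significance by jointly permuting rows/columns of the response matrix.
    R² p-value is one-tailed (greater); coefficient p-values are two-sided
    on the absolute coefficient.
    """
    if len(predictors) < 1:
        raise ValueError("need at least one predictor matrix")
    names = list(predictors)
    for m in predictors.values():
        response.align_with(m)
    n = response.n
    iu = np.triu_indices(n, k=1)
    y = _condensed(response)
    Xmat = np.column_stack(
        [np.ones_like(y)] + [_condensed(predictors[k]) for k in names]
    )
    if np.linalg.matrix_rank(Xmat) < Xmat.shape[1]:
        raise ValueError("rank-deficient design: collinear predictor matrices")
    pinv = np.linalg.pinv(Xmat)
    hat = Xmat @ pinv

    def fit(yv):
        beta = pinv @ yv
        resid = yv - hat @ yv
        ss_tot = np.sum((yv - yv.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else np.nan
        return beta, r2

    beta_obs, r2_obs = fit(y)
    rng = np.random.default_rng(seed)
    r2_hits = 0
    coef_hits = np.zeros(len(names))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = _triu_of_permuted(response.values, perm, iu)
        beta_p, r2_p = fit(yp)
        if r2_p >= r2_obs:
            r2_hits += 1
        coef_hits += np.abs(beta_p[1:]) >= np.abs(beta_obs[1:])
    denom = 1 + n_perm
    return MRMResult(
        coefficients={k: float(b) for k, b in zip(names, beta_obs[1:])},
        intercept=float(beta_obs[0]),
        r_squared=float(r2_obs),
        coef_p={k: float((1 + h) / denom) for k, h in zip(names, coef_hits)},
        r_squared_p=(1 + r2_hits) / denom,
        n_perm=n_perm,
        seed=seed,
    )


def _anosim_R(ranks: np.ndarray, within: np.ndarray, n: int) -> float:
    rb = ranks[~within].mean()
    rw = ranks[within].mean()
    return float((rb - rw) / (n * (n - 1) / 4.0))


def anosim(
    dissim: PairwiseMatrix,
    grouping,
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
) -> AnosimResult:
    """Analysis of similarities: between- vs within-group dissimilarity ranks.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4),
    ranks (average ties) over the condensed dissimilarities; p by permuting
    group labels, one-tailed (greater).
    """
    labels = np.asarray([str(g) for g in grouping])
    if len(labels) != dissim.n:
        raise ValueError("grouping length does not match matrix size")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if np.any(counts < 2):
        small = uniq[counts < 2].tolist()
        raise ValueError(f"singleton group(s) not allowed: {small}")
    n = dissim.n
    iu, ju = np.triu_indices(n, k=1)
    d = _condensed(dissim)
    ranks = rankdata(d)
    within_obs = labels[iu] == labels[ju]
    R_obs = _anosim_R(ranks, within_obs, n)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        lp = labels[rng.permutation(n)]
        if _anosim_R(ranks, lp[iu] == lp[ju], n) >= R_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return AnosimResult(
        R=R_obs,
        p=p,
        n_perm=n_perm,
        groups={str(u): int(c) for u, c in zip(uniq, counts)},
        seed=seed,
    )
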