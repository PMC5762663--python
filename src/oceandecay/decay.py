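"""Time-decay models of community similarity and the halving-time statistic.

Two regressions relate pairwise community similarity S to surface-ocean
transit time t (days):

* power-law (log-log) decay:   ln S = a + b ln t   — b is the spatial
  species-turnover rate per unit ln-time;
* logarithmic decay:           S = c ln t + int    — c is the time-decay
  slope on the raw similarity scale.

The dispersal-scale proxy is the halving-time t_H, the transit time at which
the fitted similarity falls to half the initial similarity S0. S0 is the
empirical mean similarity over station pairs with transit time at or below
100 days (a fallback to the 10 closest pairs is applied, and flagged, when
no pair is that close). Inverting the logarithmic model at S = S0/2 gives

    t_H = exp((S0/2 - int) / c),   c < 0,

reported in days and years (365.25 d/yr).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pairwise import PairwiseMatrix

__all__ = [
    "DAYS_PER_YEAR",
    "PairSamples",
    "LogLogFit",
    "LogDecayFit",
    "build_pairs",
    "fit_loglog",
    "fit_logdecay",
    "initial_similarity",
    "halving_time",
    "group_decay_analysis",
]

DAYS_PER_YEAR = 365.25
S0_REFERENCE_DAYS = 100.0
S0_FALLBACK_PAIRS = 10


@dataclass
class PairSamples:
    """Station-pair samples: similarity S in [0,1] vs transit time t > 0 days."""

    similarity: np.ndarray
    transit_days: np.ndarray
    pair_labels: list[tuple[str, str]]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.similarity = np.asarray(self.similarity, dtype=float)
        self.transit_days = np.asarray(self.transit_days, dtype=float)
        if self.similarity.shape != self.transit_days.shape:
            raise ValueError("similarity and transit vectors differ in length")

    @property
    def n_pairs(self) -> int:
        return self.similarity.size


@dataclass
class LogLogFit:
    intercept: float     # a in ln S = a + b ln t
    slope: float         # b, per unit ln-time
    r_squared: float
    p_value: float
    n_pairs: int
    n_zero_excluded: int = 0


@dataclass
class LogDecayFit:
    slope: float         # c, similarity per ln-day
    intercept: float     # int
    r_squared: float
    p_value: float
    n_pairs: int
    s0: float | None = None
    s0_fallback: bool = False
    halving_days: float | None = None
    halving_years: float | None = None


def build_pairs(similarity: PairwiseMatrix, transit: PairwiseMatrix) -> PairSamples:
    """Vectorize two matrices into matched station-pair samples.

    Pairs with an unreachable transit time or undefined similarity (NaN) and
    pairs at zero transit time (same patch; ln t undefined) are dropped and
    counted.
    """
    similarity.align_with(transit)
    s = similarity.condensed()
    t = transit.condensed()
    labels = similarity.pair_labels()
    keep = np.isfinite(s) & np.isfinite(t) & (t > 0)
    if not keep.any():
        raise ValueError("no valid station pairs after dropping missing entries")
    return PairSamples(
        similarity=s[keep],
        transit_days=t[keep],
        pair_labels=[lab for lab, k in zip(labels, keep) if k],
        n_dropped=int((~keep).sum()),
    )


def fit_loglog(pairs: PairSamples, zero_handling: str = "exclude") -> LogLogFit:
    """OLS of ln S on ln t (power-law time decay).

    ``zero_handling``: "exclude" drops S = 0 pairs (ln undefined) and
    reports the count; "error" raises on any zero.
    """
    s, t = pairs.similarity, pairs.transit_days
    zero = s <= 0
    if zero_handling == "error" and zero.any():
        raise ValueError(f"{int(zero.sum())} zero-similarity pairs")
    if zero_handling not in ("exclude", "error"):
        raise ValueError(f"unknown zero_handling policy {zero_handling!r}")
    s, t = s[~zero], t[~zero]
    if s.size < 3:
        raise ValueError("need at least 3 pairs with positive similarity")
    res = stats.linregress(np.log(t), np.log(s))
    return LogLogFit(
        intercept=float(res.intercept),
        slope=float(res.slope),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n_pairs=int(s.size),
        n_zero_excluded=int(zero.sum()),
    )


def fit_logdecay(pairs: PairSamples) -> LogDecayFit:
    """OLS of raw similarity S on ln t (logarithmic time decay).

    Zero-similarity pairs are retained: S is not transformed.
    """
    if pairs.n_pairs < 3:
        raise ValueError("need at least 3 pairs")
    res = stats.linregress(np.log(pairs.transit_days), pairs.similarity)
    return LogDecayFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n_pairs=pairs.n_pairs,
    )


def initial_similarity(
    pairs: PairSamples, t0: float = S0_REFERENCE_DAYS
) -> tuple[float, bool]:
    """Mean similarity over pairs with transit time <= t0 days (S0).

    Returns ``(s0, fallback)``; when no pair is within t0, falls back to the
    mean of the ``S0_FALLBACK_PAIRS`` smallest-transit pairs and flags it.
    """
    if pairs.n_pairs == 0:
        raise ValueError("empty pair set")
    near = pairs.transit_days <= t0
    if near.any():
        return float(pairs.similarity[near].mean()), False
    k = min(S0_FALLBACK_PAIRS, pairs.n_pairs)
    idx = np.argsort(pairs.transit_days)[:k]
    return float(pairs.similarity[idx].mean()), True


def halving_time(fit: LogDecayFit, s0: float) -> tuple[float, float]:
    """Halving-time (days, years) from a logarithmic-decay fit and S0.

    Solves S0/2 = c ln(t_H) + int for t_H. Requires a genuinely decaying
    fit (c < 0).
    """
    if not fit.slope < 0:
        raise ValueError("no decay: logarithmic slope c must be negative")
    days = float(np.exp((s0 / 2.0 - fit.intercept) / fit.slope))
    return days, days / DAYS_PER_YEAR


def group_decay_analysis(
    similarity: PairwiseMatrix,
    transit: PairwiseMatrix,
    t0: float = S0_REFERENCE_DAYS,
) -> tuple[LogDecayFit, LogLogFit]:
    """Full per-group decay analysis: both fits, S0, and the halving-time."""
    pairs = build_pairs(similarity, transit)
    logdecay = fit_logdecay(pairs)
    loglog = fit_loglog(pairs)
    s0, fb = initial_similarity(pairs, t0=t0)
    logdecay.s0 = s0
    logdecay.s0_fallback = fb
    if logdecay.slope < 0:
        logdecay.halving_days, logdecay.halving_years = halving_time(logdecay, s0)
    return logdecay, loglog
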