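"""Patch-to-patch surface transit times from particle trajectories.

Trajectories are aggregated onto a rectangular patch grid: the direct transit
time i -> j is the minimum, over all particles and all visit pairs, of the
time a particle is first seen in patch j minus an earlier time it was seen in
patch i. Because a finite simulation realizes only some connections directly,
the matrix is completed with Dijkstra's all-pairs shortest-path algorithm on
the directed graph of direct times, and pairs that remain unreachable are
carried as missing. Station-level symmetric matrices are extracted by mapping
stations to patches and reducing the directed pair (i->j, j->i).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .flow import TrajectorySet
from .pairwise import PairwiseMatrix

__all__ = [
    "PatchGrid",
    "TransitTimeMatrix",
    "aggregate_to_patches",
    "shortest_path_times",
    "station_transit_matrix",
]

Bounds = tuple[float, float, float, float]


@dataclass(frozen=True)
class PatchGrid:
    """Rectangular tiling of a domain into nx * ny patches."""

    bounds: Bounds
    nx: int
    ny: int

    @property
    def n_patches(self) -> int:
        return self.nx * self.ny

    def patch_index(self, x, y) -> np.ndarray:
        """Map positions to flat patch indices (row-major over (col, row))."""
        x0, x1, y0, y1 = self.bounds
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.any((x < x0) | (x > x1) | (y < y0) | (y > y1)):
            raise ValueError("position outside patch-grid domain")
        ix = np.minimum((self.nx * (x - x0) / (x1 - x0)).astype(int), self.nx - 1)
        iy = np.minimum((self.ny * (y - y0) / (y1 - y0)).astype(int), self.ny - 1)
        return iy * self.nx + ix

    def patch_rowcol(self, index: int) -> tuple[int, int]:
        return divmod(int(index), self.nx)


@dataclass
class TransitTimeMatrix:
    """Directed P x P minimum connection times in days; inf = unreachable."""

    times: np.ndarray
    grid: PatchGrid | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        n = self.times.shape[0]
        if self.times.shape != (n, n):
            raise ValueError("transit matrix must be square")
        if np.any(self.times[np.isfinite(self.times)] < 0):
            raise ValueError("transit times must be non-negative")
        np.fill_diagonal(self.times, 0.0)

    @property
    def n_patches(self) -> int:
        return self.times.shape[0]

    def to_csv(self, path) -> None:
        out = pd.DataFrame(self.times).replace(np.inf, np.nan)
        out.index = out.columns = [f"p{i}" for i in range(self.n_patches)]
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "TransitTimeMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float, na_value=np.inf))


def aggregate_to_patches(traj: TrajectorySet, grid: PatchGrid) -> TransitTimeMatrix:
    """Reduce trajectories to direct patch-to-patch minimum transit times.

    For every particle, every recorded position is assigned to a patch; the
    direct time i -> j is the minimum over all (earlier in i, later in j)
    visit pairs. The result is independent of particle ordering.
    """
    if traj.n_particles == 0:
        raise ValueError("empty trajectory set")
    P = grid.n_patches
    direct = np.full((P, P), np.inf)
    times = traj.times
    for p in range(traj.n_particles):
        patches = grid.patch_index(traj.x[p], traj.y[p])
        # last_seen[q] = latest time this particle was observed in patch q
        last_seen = np.full(P, -np.inf)
        last_seen[patches[0]] = times[0]
        for k in range(1, len(times)):
            q = patches[k]
            seen = last_seen > -np.inf
            cand = times[k] - last_seen[seen]
            direct[seen, q] = np.minimum(direct[seen, q], cand)
            last_seen[q] = times[k]
    np.fill_diagonal(direct, 0.0)
    return TransitTimeMatrix(direct, grid)


def shortest_path_times(direct: TransitTimeMatrix) -> TransitTimeMatrix:
    """Complete a direct transit matrix with all-pairs shortest paths.

    Runs Dijkstra's algorithm from every patch over the directed graph whose
    edge weights are the direct times. Completed entries never exceed the
    direct entries; unreachable pairs stay unreachable. Idempotent.
    """
    t = direct.times
    if np.any(t[np.isfinite(t)] < 0):
        raise ValueError("negative transit time in direct matrix")
    finite = np.isfinite(t) & ~np.eye(t.shape[0], dtype=bool)
    rows, cols = np.nonzero(finite)
    graph = csr_matrix((t[rows, cols], (rows, cols)), shape=t.shape)
    completed = dijkstra(graph, directed=True)
    np.fill_diagonal(completed, 0.0)
    return TransitTimeMatrix(completed, direct.grid)


def station_transit_matrix(
    transit: TransitTimeMatrix,
    stations: pd.DataFrame,
    symmetrize: str = "min",
) -> PairwiseMatrix:
    """Extract a symmetric station-pair transit matrix.

    ``stations`` must carry ``station``, ``x``, ``y`` columns; each station
    maps to the patch containing it. Because the patch matrix is directed
    while matrix statistics need symmetry, the directed pair (i->j, j->i) is
    reduced elementwise with ``symmetrize`` in {"min", "mean"} (default
    "min", the minimum-connection-time reading). Pairs unreachable in both
    directions ("min") or either direction ("mean") come out NaN.
    """
    if symmetrize not in ("min", "mean"):
        raise ValueError(f"symmetrize must be 'min' or 'mean', got {symmetrize!r}")
    if transit.grid is None:
        raise ValueError("transit matrix has no patch grid attached")
    idx = transit.grid.patch_index(
        stations["x"].to_numpy(), stations["y"].to_numpy()
    )
    sub = transit.times[np.ix_(idx, idx)]
    if symmetrize == "min":
        sym = np.minimum(sub, sub.T)
    else:
        sym = 0.5 * (sub + sub.T)
    sym = np.where(np.isfinite(sym), sym, np.nan)
    np.fill_diagonal(sym, 0.0)
    return PairwiseMatrix(
        sym, list(stations["station"].astype(str)), kind="distance", units="days"
    )
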