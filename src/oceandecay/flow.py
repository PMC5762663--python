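"""Analytic surface-flow surrogate and Lagrangian particle advection.

The connectivity analysis needs a divergence-free velocity field with mixing
barriers and asymmetric transport. A periodically perturbed double gyre on a
closed rectangular basin provides exactly that structure: two counter-rotating
cells separated by a time-oscillating transport barrier, with stagnation
points at the gyre centers. Virtual particles are advected with fixed-step
RK4 using horizontal velocities only and no added diffusivity; positions are
recorded on a coarse output interval (default every 3 days).

Units: positions in abstract degrees, velocities in degrees/day, time in days.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "FlowField",
    "TrajectorySet",
    "build_double_gyre_field",
    "build_uniform_field",
    "advect_particles",
]

Bounds = tuple[float, float, float, float]  # (x0, x1, y0, y1)


@dataclass
class FlowField:
    """A 2-D velocity field on a rectangular domain.

    ``velocity(x, y, t)`` accepts arrays and returns ``(u, v)`` in
    degrees/day. ``boundary`` is ``"closed"`` (zero normal flow at the walls)
    or ``"periodic"``.
    """

    bounds: Bounds
    velocity: Callable[[np.ndarray, np.ndarray, float], tuple[np.ndarray, np.ndarray]]
    boundary: str = "closed"
    meta: dict = field(default_factory=dict)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x0, x1, y0, y1 = self.bounds
        return (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)


@dataclass
class TrajectorySet:
    """Recorded particle trajectories: shared time grid, per-particle paths."""

    times: np.ndarray          # (n_times,) days, strictly increasing
    x: np.ndarray              # (n_particles, n_times)
    y: np.ndarray              # (n_particles, n_times)
    step: float                # integration step (days)

    @property
    def n_particles(self) -> int:
        return self.x.shape[0]


def build_double_gyre_field(
    amplitude: float = 0.1,
    domain: Bounds = (0.0, 2.0, 0.0, 1.0),
    perturbation: float = 0.1,
    period: float = 20.0,
) -> FlowField:
    """Construct the periodically perturbed double-gyre field.

    Stream function psi = A sin(pi f(xi, t)) sin(pi eta) on normalized
    coordinates xi in [0, 2], eta in [0, 1], with
    f(xi, t) = eps sin(2 pi t / period) xi^2 + (1 - 2 eps sin(2 pi t / period)) xi.
    ``perturbation = 0`` gives the steady field; normal velocity vanishes on
    all four walls, so the basin is closed.

    Parameters
    ----------
    amplitude : float
        Velocity scale A in degrees/day (peak speed ~ pi*A). Must be > 0.
    domain : (x0, x1, y0, y1)
        Basin bounds in degrees.
    perturbation : float
        Dimensionless gyre-boundary oscillation amplitude eps (0 = steady).
    period : float
        Oscillation period in days.
    """
    if amplitude <= 0:
        raise ValueError(f"amplitude must be positive, got {amplitude}")
    x0, x1, y0, y1 = domain
    if not (x1 > x0 and y1 > y0):
        raise ValueError(f"degenerate domain bounds {domain}")
    sx = (x1 - x0) / 2.0  # xi = (x - x0)/sx in [0, 2]
    sy = (y1 - y0) / 1.0
    A, eps, omega = float(amplitude), float(perturbation), 2.0 * np.pi / period

    def velocity(x, y, t):
        xi = (np.asarray(x, dtype=float) - x0) / sx
        eta = (np.asarray(y, dtype=float) - y0) / sy
        e = eps * np.sin(omega * t)
        f = e * xi**2 + (1.0 - 2.0 * e) * xi
        dfdxi = 2.0 * e * xi + (1.0 - 2.0 * e)
        u = -np.pi * A * np.sin(np.pi * f) * np.cos(np.pi * eta)
        v = np.pi * A * np.cos(np.pi * f) * np.sin(np.pi * eta) * dfdxi
        return u, v

    meta = {
        "kind": "double_gyre",
        "amplitude": A,
        "perturbation": eps,
        "period": period,
        # steady-state gyre centers (stagnation points)
        "gyre_centers": [
            (x0 + 0.5 * sx, y0 + 0.5 * sy),
            (x0 + 1.5 * sx, y0 + 0.5 * sy),
        ],
    }
    return FlowField(domain, velocity, boundary="closed", meta=meta)


def build_uniform_field(
    u: float, v: float, domain: Bounds = (0.0, 2.0, 0.0, 1.0)
) -> FlowField:
    """Constant velocity field, mainly useful for integrator checks."""

    def velocity(x, y, t):
        x = np.asarray(x, dtype=float)
        return np.full_like(x, u), np.full_like(x, v)

    return FlowField(domain, velocity, boundary="closed", meta={"kind": "uniform"})


def advect_particles(
    field: FlowField,
    seeds: Sequence[tuple[float, float]] | np.ndarray,
    step: float = 0.25,
    duration: float = 100.0,
    output_interval: float = 3.0,
    start_time: float = 0.0,
) -> TrajectorySet:
    """Advect particles through ``field`` with fixed-step RK4.

    Positions are recorded at t = start_time and every ``output_interval``
    days thereafter (the final time is always recorded). Particles that
    would leave a closed domain are clipped to the walls; with an exactly
    closed field this only corrects floating-point drift.

    Raises
    ------
    ValueError
        If ``step`` or ``duration`` is invalid or a seed lies outside the
        domain.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    if duration < step:
        raise ValueError(f"duration ({duration}) must be at least one step ({step})")
    seeds = np.asarray(seeds, dtype=float)
    if seeds.ndim != 2 or seeds.shape[1] != 2:
        raise ValueError("seeds must be an (n, 2) array of positions")
    x = seeds[:, 0].copy()
    y = seeds[:, 1].copy()
    if not np.all(field.contains(x, y)):
        bad = np.flatnonzero(~field.contains(x, y))
        raise ValueError(f"seed positions outside domain at indices {bad.tolist()}")

    n_steps = int(round(duration / step))
    record_every = max(1, int(round(output_interval / step)))
    rec_t = [start_time]
    rec_x = [x.copy()]
    rec_y = [y.copy()]

    x0, x1, y0, y1 = field.bounds
    span_x, span_y = x1 - x0, y1 - y0
    t = start_time
    for k in range(1, n_steps + 1):
        u1, v1 = field.velocity(x, y, t)
        u2, v2 = field.velocity(x + 0.5 * step * u1, y + 0.5 * step * v1, t + 0.5 * step)
        u3, v3 = field.velocity(x + 0.5 * step * u2, y + 0.5 * step * v2, t + 0.5 * step)
        u4, v4 = field.velocity(x + step * u3, y + step * v3, t + step)
        x = x + (step / 6.0) * (u1 + 2 * u2 + 2 * u3 + u4)
        y = y + (step / 6.0) * (v1 + 2 * v2 + 2 * v3 + v4)
        t = start_time + k * step
        if field.boundary == "closed":
            np.clip(x, x0, x1, out=x)
            np.clip(y, y0, y1, out=y)
        else:  # periodic wrap
            x = x0 + np.mod(x - x0, span_x)
            y = y0 + np.mod(y - y0, span_y)
        if k % record_every == 0 or k == n_steps:
            rec_t.append(t)
            rec_x.append(x.copy())
            rec_y.append(y.copy())

    return TrajectorySet(
        times=np.asarray(rec_t),
        x=np.stack(rec_x, axis=1),
        y=np.stack(rec_y, axis=1),
        step=step,
    )
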