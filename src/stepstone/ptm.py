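"""Lagrangian random-walk particle transport over a gridded flow field.

Particles stand in for passive, neutrally buoyant larvae.  Each time step
every particle is advected by the bilinearly interpolated velocity and
displaced by an isotropic random walk::

    dx = u dt + sqrt(2 D dt) z1,   dy = v dt + sqrt(2 D dt) z2

with independent standard normal draws and horizontal dispersion
coefficient ``D`` (m^2/s).  There is no mortality: the particle count is
conserved for the whole tracking window.  Transport is two-dimensional
(depth-averaged).

Arrivals: a particle is counted at a destination at its first entry into
that site's capture radius, at most once per destination, and keeps
moving afterwards.  Counts over all origins form the asymmetric
source x destination arrival matrix; its diagonal is local retention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
import xarray as xr

from .sites import KM_PER_DEGREE, SiteTable


@dataclass
class PTMConfig:
    """Release schedule and transport parameters.

    Defaults follow a spring spawning pulse: releases start on day-of-year
    59 (1 March), with 1,489 particles every 30 minutes for 14 days
    (672 release events per origin), tracked for 70 days at 30-minute
    steps.
    """

    release_start_day: int = 59
    particles_per_release: int = 1489
    release_interval_min: float = 30.0
    release_duration_days: float = 14.0
    tracking_duration_days: float = 70.0
    time_step_min: float = 30.0
    dispersion_m2_s: float = 10.0
    capture_radius_km: float = 2.0
    boundary: Literal["reflect", "absorb"] = "reflect"

    def __post_init__(self) -> None:
        for name in (
            "release_interval_min",
            "release_duration_days",
            "tracking_duration_days",
            "time_step_min",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.capture_radius_km <= 0:
            raise ValueError("capture_radius_km must be positive")
        if self.dispersion_m2_s < 0:
            raise ValueError("dispersion_m2_s must be non-negative")
        if self.particles_per_release < 1:
            raise ValueError("particles_per_release must be >= 1")
        ratio = self.release_interval_min / self.time_step_min
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("time_step must divide release_interval")
        if self.boundary not in ("reflect", "absorb"):
            raise ValueError(f"unknown boundary policy {self.boundary!r}")

    @property
    def n_release_events(self) -> int:
        """Release events per origin (schedule arithmetic)."""
        return int(round(self.release_duration_days * 24 * 60 / self.release_interval_min))

    @property
    def particles_per_origin(self) -> int:
        return self.n_release_events * self.particles_per_release


class FlowInterpolator:
    """Bilinear-in-space, linear-in-time velocity lookup on an x/y/t grid."""

    def __init__(self, flow: xr.Dataset):
        self.x = np.asarray(flow["x"].values, dtype=float)
        self.y = np.asarray(flow["y"].values, dtype=float)
        self.t = np.asarray(flow["t"].values, dtype=float)
        for name, arr in (("x", self.x), ("y", self.y), ("t", self.t)):
            if len(arr) < 2 or np.any(np.diff(arr) <= 0):
                raise ValueError(f"flow grid axis {name!r} must be strictly increasing")
        self.u = np.asarray(flow["u"].transpose("t", "y", "x").values, dtype=float)
        self.v = np.asarray(flow["v"].transpose("t", "y", "x").values, dtype=float)
        if not (np.isfinite(self.u).all() and np.isfinite(self.v).all()):
            raise ValueError("flow field contains non-finite velocities")

    @property
    def domain(self) -> tuple[float, float, float, float]:
        return self.x[0], self.x[-1], self.y[0], self.y[-1]

    def _axis_weights(self, grid: np.ndarray, q: np.ndarray):
        q = np.clip(q, grid[0], grid[-1])
        hi = np.clip(np.searchsorted(grid, q, side="right"), 1, len(grid) - 1)
        lo = hi - 1
        w = (q - grid[lo]) / (grid[hi] - grid[lo])
        return lo, hi, w

    def velocity(self, x: np.ndarray, y: np.ndarray, t: float) -> tuple[np.ndarray, np.ndarray]:
        """(u, v) in m/s at positions (km) and time (hours)."""
        if not (self.t[0] - 1e-9 <= t <= self.t[-1] + 1e-9):
            raise ValueError(
                f"time {t} h outside flow snapshot range [{self.t[0]}, {self.t[-1]}]"
            )
        xlo, xhi, wx = self._axis_weights(self.x, np.asarray(x, float))
        ylo, yhi, wy = self._axis_weights(self.y, np.asarray(y, float))
        tlo, thi, wt = self._axis_weights(self.t, np.asarray([t], float))
        tlo, thi, wt = int(tlo[0]), int(thi[0]), float(wt[0])
        out = []
        for f in (self.u, self.v):
            ft = (1 - wt) * f[tlo] + wt * f[thi]  # (ny, nx)
            f00 = ft[ylo, xlo]
            f01 = ft[ylo, xhi]
            f10 = ft[yhi, xlo]
            f11 = ft[yhi, xhi]
            out.append(
                (1 - wy) * ((1 - wx) * f00 + wx * f01) + wy * ((1 - wx) * f10 + wx * f11)
            )
        return out[0], out[1]


def interpolate_velocity(
    flow: xr.Dataset, position: tuple[float, float], time_h: float
) -> tuple[float, float]:
    """Velocity (m/s) at a single (x, y) km position and time in hours."""
    interp = FlowInterpolator(flow)
    u, v = interp.velocity(np.array([position[0]]), np.array([position[1]]), time_h)
    return float(u[0]), float(v[0])


def _reflect(pos: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold positions back into [lo, hi] (billiard reflection)."""
    span = hi - lo
    q = np.mod(pos - lo, 2 * span)
    q = np.where(q > span, 2 * span - q, q)
    return q + lo


def advance_particles(
    positions: np.ndarray,
    interp: FlowInterpolator,
    time_h: float,
    dt_s: float,
    dispersion_m2_s: float,
    rng: np.random.Generator,
    boundary: str = "reflect",
    alive: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One transport step; returns (new positions, alive mask).

    Positions are in km.  With the ``absorb`` policy, particles leaving
    the domain are frozen and flagged dead; ``reflect`` keeps them inside.
    """
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    if alive is None:
        alive = np.ones(len(positions), dtype=bool)
    new = positions.copy()
    if not alive.any():
        return new, alive
    x, y = positions[alive, 0], positions[alive, 1]
    u, v = interp.velocity(x, y, time_h)
    if not (np.isfinite(u).all() and np.isfinite(v).all()):
        bad = int(np.flatnonzero(~(np.isfinite(u) & np.isfinite(v)))[0])
        raise ValueError(f"NaN velocity for particle {bad} at t={time_h} h")
    sigma_km = np.sqrt(2.0 * dispersion_m2_s * dt_s) / 1000.0
    z = rng.standard_normal((int(alive.sum()), 2))
    nx = x + (u * dt_s) / 1000.0 + sigma_km * z[:, 0]
    ny = y + (v * dt_s) / 1000.0 + sigma_km * z[:, 1]
    x0, x1, y0, y1 = interp.domain
    if boundary == "reflect":
        nx = _reflect(nx, x0, x1)
        ny = _reflect(ny, y0, y1)
        new[alive, 0], new[alive, 1] = nx, ny
    elif boundary == "absorb":
        out = (nx < x0) | (nx > x1) | (ny < y0) | (ny > y1)
        new[alive, 0], new[alive, 1] = nx, ny
        idx = np.flatnonzero(alive)
        alive = alive.copy()
        alive[idx[out]] = False
    else:
        raise ValueError(f"unknown boundary policy {boundary!r}")
    return new, alive


@dataclass
class ArrivalMatrix:
    """Asymmetric source x destination particle-arrival counts."""

    counts: pd.DataFrame  # rows = origin site, columns = destination site
    released: pd.Series  # particles released per origin
    config: PTMConfig = field(default_factory=PTMConfig)

    def __post_init__(self) -> None:
        c = self.counts.to_numpy()
        if (c < 0).any():
            raise ValueError("arrival counts must be non-negative")
        if (c > self.released.to_numpy()[:, None]).any():
            raise ValueError("arrival counts cannot exceed particles released")

    @property
    def local_retention(self) -> pd.Series:
        return pd.Series(np.diag(self.counts.to_numpy()), index=self.counts.index)


def site_positions_km(sites: SiteTable, flow: xr.Dataset) -> pd.DataFrame:
    """Project site lat/lon onto the flow field's km plane.

    Uses the flow's ``origin_lat``/``origin_lon`` anchor when present,
    otherwise the site cloud's south-west corner.
    """
    origin = None
    if "origin_lat" in flow.attrs and "origin_lon" in flow.attrs:
        origin = (float(flow.attrs["origin_lat"]), float(flow.attrs["origin_lon"]))
    return sites.positions_km(origin=origin)


def run_ptm(
    flow: xr.Dataset,
    sites: SiteTable,
    config: PTMConfig | None = None,
    seed: int | None = None,
    positions_km: pd.DataFrame | None = None,
) -> ArrivalMatrix:
    """Release particles on the configured schedule from every site and
    accumulate first-entry arrival counts per destination.

    ``positions_km`` overrides the geographic projection (useful for
    purely synthetic domains); it must be indexed by site_id with columns
    x_km, y_km.
    """
    config = config or PTMConfig()
    if positions_km is None:
        positions_km = site_positions_km(sites, flow)
    pos_sites = positions_km.loc[sites.site_ids]
    interp = FlowInterpolator(flow)
    x0, x1, y0, y1 = interp.domain
    sx = pos_sites["x_km"].to_numpy(float)
    sy = pos_sites["y_km"].to_numpy(float)
    outside = (sx < x0) | (sx > x1) | (sy < y0) | (sy > y1)
    if outside.any():
        bad = [sites.site_ids[i] for i in np.flatnonzero(outside)]
        raise ValueError(f"site(s) outside flow domain: {bad}")

    S = len(sx)
    rng = np.random.default_rng(seed)
    dt_s = config.time_step_min * 60.0
    dt_h = config.time_step_min / 60.0
    n_steps = int(round(config.tracking_duration_days * 24 * 60 / config.time_step_min))
    steps_per_release = int(round(config.release_interval_min / config.time_step_min))
    n_events = config.n_release_events
    t_grid_start = float(interp.t[0])

    origin_of = np.empty(0, dtype=np.int64)
    pos = np.empty((0, 2), dtype=float)
    alive = np.empty(0, dtype=bool)
    arrived = np.empty((0, S), dtype=bool)
    counts = np.zeros((S, S), dtype=np.int64)
    released = np.zeros(S, dtype=np.int64)

    site_xy = np.stack([sx, sy], axis=1)
    r2 = config.capture_radius_km**2

    def record_arrivals():
        nonlocal arrived
        if len(pos) == 0:
            return
        d2 = ((pos[:, None, :] - site_xy[None, :, :]) ** 2).sum(axis=2)
        inside = (d2 <= r2) & alive[:, None] & ~arrived
        if inside.any():
            p_idx, s_idx = np.nonzero(inside)
            np.add.at(counts, (origin_of[p_idx], s_idx), 1)
            arrived[p_idx, s_idx] = True

    for step in range(n_steps + 1):
        if step % steps_per_release == 0 and step // steps_per_release < n_events:
            new_origin = np.repeat(np.arange(S), config.particles_per_release)
            new_pos = site_xy[new_origin].astype(float)
            origin_of = np.concatenate([origin_of, new_origin])
            pos = np.concatenate([pos, new_pos])
            alive = np.concatenate([alive, np.ones(len(new_origin), bool)])
            arrived = np.concatenate([arrived, np.zeros((len(new_origin), S), bool)])
            released += config.particles_per_release
            record_arrivals()  # release point may already lie inside a radius
        if step == n_steps:
            break
        t_h = t_grid_start + step * dt_h
        pos, alive = advance_particles(
            pos, interp, t_h, dt_s, config.dispersion_m2_s, rng, config.boundary, alive
        )
        record_arrivals()

    ids = sites.site_ids
    return ArrivalMatrix(
        pd.DataFrame(counts, index=ids, columns=ids),
        pd.Series(released, index=ids),
        config,
    )


def arrivals_to_proportions(
    matrix: ArrivalMatrix, include_retention: bool = True
) -> pd.DataFrame:
    """Row-stochastic arrival proportions: counts[s, d] / released[s].

    Zero rows (origins with no arrivals anywhere) stay zero and are
    flagged in ``result.attrs['zero_rows']``.  With
    ``include_retention=False`` the diagonal is zeroed before scaling.
    """
    counts = matrix.counts.to_numpy(float).copy()
    if not include_retention:
        np.fill_diagonal(counts, 0.0)
    released = matrix.released.to_numpy(float)
    if (released <= 0).any():
        bad = list(matrix.released.index[released <= 0])
        raise ValueError(f"released totals must be positive, offending rows: {bad}")
    props = counts / released[:, None]
    out = pd.DataFrame(props, index=matrix.counts.index, columns=matrix.counts.columns)
    out.attrs["zero_rows"] = list(out.index[(counts.sum(axis=1) == 0)])
    return out
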