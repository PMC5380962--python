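"""Lagrangian particle advection through gridded velocity fields.

Particles are integrated in longitude/latitude with a fixed-step
fourth-order Runge-Kutta scheme (default step 6 h), sampling the velocity
field with bilinear interpolation in space and linear interpolation in
time.  The zonal/meridional metric conversion uses a spherical Earth of
radius 6,371 km.  The ensemble size never changes: particles that leave the
velocity grid are frozen in place and flagged, not dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import R_EARTH_M, SECONDS_PER_DAY
from .grid import GridField, bilinear_sample

log = logging.getLogger(__name__)

DEG = 180.0 / np.pi


@dataclass
class ParticleEnsemble:
    """Positions of a fixed set of particles at stored times.

    ``lon``/``lat`` have shape ``(n_times, n_particles)``; ``frozen`` marks
    particles that left the grid during advection.
    """

    times: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    frozen: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.times = np.atleast_1d(np.asarray(self.times, float))
        self.lon = np.atleast_2d(np.asarray(self.lon, float))
        self.lat = np.atleast_2d(np.asarray(self.lat, float))
        if self.lon.shape != self.lat.shape or self.lon.shape[0] != self.times.size:
            raise ValueError("inconsistent ensemble shapes")
        if np.any(np.abs(self.lat) >= 90):
            raise ValueError("latitudes must lie strictly inside (-90, 90)")
        if self.frozen is None:
            self.frozen = np.zeros(self.lon.shape[1], dtype=bool)

    @property
    def n_particles(self) -> int:
        return self.lon.shape[1]

    def at_time(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > 1e-6:
            raise ValueError(f"time {t} not stored")
        return self.lon[i], self.lat[i]

    def to_frame(self) -> pd.DataFrame:
        nt, npart = self.lon.shape
        return pd.DataFrame(
            {
                "time_day": np.repeat(self.times, npart),
                "particle_id": np.tile(np.arange(npart), nt),
                "lon": self.lon.ravel(),
                "lat": self.lat.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ParticleEnsemble":
        df = pd.read_csv(path)
        times = np.sort(df["time_day"].unique())
        npart = df["particle_id"].nunique()
        piv_lon = df.pivot(index="time_day", columns="particle_id", values="lon")
        piv_lat = df.pivot(index="time_day", columns="particle_id", values="lat")
        return cls(times=times, lon=piv_lon.to_numpy(), lat=piv_lat.to_numpy())


def seed_particles_from_mask(
    tracer: GridField,
    level: float,
    t0: float,
    density: int = 10,
    rng_seed: int = 0,
) -> ParticleEnsemble:
    """Seed ``density`` particles (uniform jitter) in every cell >= level.

    Cloud-masked cells are excluded.  Raises if no cell exceeds the level.
    """
    ti = tracer.time_index(t0)
    var = next(k for k in tracer.data if k not in ("u", "v"))
    conc = tracer.data[var][ti]
    cloud = tracer.mask[ti] if tracer.mask is not None else np.zeros_like(conc, bool)
    cells = (conc >= level) & ~cloud
    if not cells.any():
        raise ValueError(f"empty patch: no cell reaches level {level}")
    rng = np.random.default_rng(rng_seed)
    ii, jj = np.nonzero(cells)
    dlon, dlat = tracer.dlon, tracer.dlat
    lon0 = tracer.lon[jj].repeat(density) - dlon / 2
    lat0 = tracer.lat[ii].repeat(density) - dlat / 2
    n = lon0.size
    lons = lon0 + rng.random(n) * dlon
    lats = lat0 + rng.random(n) * dlat
    return ParticleEnsemble(times=[t0], lon=lons[None, :], lat=lats[None, :])


class _VelocitySampler:
    """Bilinear-in-space, linear-in-time sampler; masked cells act as zero."""

    def __init__(self, velocity: GridField):
        self.lon = velocity.lon
        self.lat = velocity.lat
        self.times = velocity.time
        u = velocity.data["u"].copy()
        v = velocity.data["v"].copy()
        if velocity.mask is not None and velocity.mask.any():
            log.warning("masked velocity cells treated as zero velocity")
            u[velocity.mask] = 0.0
            v[velocity.mask] = 0.0
        self.u, self.v = u, v
        self.global_lon = (self.lon[-1] - self.lon[0]) >= 360.0 - 1.5 * np.mean(
            np.diff(self.lon)
        )

    def __call__(self, t, lons, lats):
        lons = np.where(lons >= 360.0, lons - 360.0, np.where(lons < 0, lons + 360.0, lons))
        i = int(np.clip(np.searchsorted(self.times, t) - 1, 0, max(self.times.size - 2, 0)))
        if self.times.size == 1:
            u2d, v2d = self.u[0], self.v[0]
        else:
            f = (t - self.times[i]) / (self.times[i + 1] - self.times[i])
            f = float(np.clip(f, 0.0, 1.0))
            u2d = (1 - f) * self.u[i] + f * self.u[i + 1]
            v2d = (1 - f) * self.v[i] + f * self.v[i + 1]
        us = bilinear_sample(self.lon, self.lat, u2d, lons, lats)
        vs = bilinear_sample(self.lon, self.lat, v2d, lons, lats)
        return us, vs


def advect(
    particles: ParticleEnsemble,
    velocity: GridField,
    t0: float,
    t1: float,
    dt_hours: float = 6.0,
    output_stride_days: float = 1.0,
) -> ParticleEnsemble:
    """RK4 advection of the ensemble from t0 to t1.

    Positions evolve as dlon/dt = u / (R cos(lat)), dlat/dt = v / R
    (converted to degrees per day).  Particles whose RK4 stages sample
    outside the grid are frozen at their last position and flagged.
    Trajectories are stored every ``output_stride_days`` plus the endpoint.
    """
    if dt_hours <= 0:
        raise ValueError("dt must be positive")
    if not velocity.covers_time(t0, t1):
        raise ValueError("velocity field does not cover the advection window")
    sampler = _VelocitySampler(velocity)
    dt = dt_hours / 24.0
    n_steps = max(int(round((t1 - t0) / dt)), 1)
    dt = (t1 - t0) / n_steps  # adjust to land exactly on t1

    lon, lat = particles.at_time(t0)
    lon = lon.copy()
    lat = lat.copy()
    frozen = particles.frozen.copy()

    def rhs(t, lo, la):
        us, vs = sampler(t, lo, la)
        conv = SECONDS_PER_DAY / R_EARTH_M * DEG  # m/s -> deg/day (meridional)
        dlon = us * conv / np.cos(np.deg2rad(la))
        dlat = vs * conv
        return dlon, dlat

    out_times = [t0]
    out_lon = [lon.copy()]
    out_lat = [lat.copy()]
    store_every = max(int(round(output_stride_days / dt)), 1)

    t = t0
    for step in range(1, n_steps + 1):
        k1x, k1y = rhs(t, lon, lat)
        k2x, k2y = rhs(t + dt / 2, lon + dt / 2 * k1x, lat + dt / 2 * k1y)
        k3x, k3y = rhs(t + dt / 2, lon + dt / 2 * k2x, lat + dt / 2 * k2y)
        k4x, k4y = rhs(t + dt, lon + dt * k3x, lat + dt * k3y)
        dlon = dt / 6 * (k1x + 2 * k2x + 2 * k3x + k4x)
        dlat = dt / 6 * (k1y + 2 * k2y + 2 * k3y + k4y)
        bad = ~np.isfinite(dlon) | ~np.isfinite(dlat)
        newly = bad & ~frozen
        if newly.any():
            log.warning("%d particle(s) left the grid and were frozen", newly.sum())
            frozen |= newly
        ok = ~frozen
        lon[ok] += dlon[ok]
        lat[ok] += dlat[ok]
        if sampler.global_lon:
            lon = np.mod(lon, 360.0)
        t = t0 + step * dt
        if step % store_every == 0 or step == n_steps:
            out_times.append(t)
            out_lon.append(lon.copy())
            out_lat.append(lat.copy())

    return ParticleEnsemble(
        times=np.array(out_times),
        lon=np.array(out_lon),
        lat=np.array(out_lat),
        frozen=frozen,
    )


def particle_density(particles: ParticleEnsemble, grid, t: float) -> GridField:
    """Per-cell particle counts normalized by spherical cell area (km^-2).

    ``grid`` may be a GridField or a FieldSpec-like object with ``axes()``.
    """
    if hasattr(grid, "lon_edges"):
        lon_e, lat_e = grid.lon_edges, grid.lat_edges
        lon_ax, lat_ax = grid.lon, grid.lat
    else:
        lon_ax, lat_ax, _ = grid.axes()
        dlo = lon_ax[1] - lon_ax[0]
        dla = lat_ax[1] - lat_ax[0]
        lon_e = np.concatenate([lon_ax - dlo / 2, [lon_ax[-1] + dlo / 2]])
        lat_e = np.concatenate([lat_ax - dla / 2, [lat_ax[-1] + dla / 2]])
    lons, lats = particles.at_time(t)
    counts, _, _ = np.histogram2d(lats, lons, bins=[lat_e, lon_e])
    out = GridField(lon=lon_ax, lat=lat_ax, time=np.array([t]), data={})
    density = counts / out.cell_areas_km2()
    out.data["density"] = density[None, :, :]
    return out
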