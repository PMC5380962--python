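"""Synthetic ocean fields with known ground truth.

Every input the analysis pipeline consumes — eddying surface currents,
chlorophyll-like tracer fields with a bloom and cloud gaps, temperature
profiles with a known mixed layer, and diffusing patch-area series — can be
generated here with controlled parameters, so each downstream stage is
testable against the generator's truth.

Velocity fields are built from a random-phase streamfunction, which makes
them divergence-free by construction: the u and v components are obtained by
finite-differencing the streamfunction with the same centred stencils a
diagnostic would use, so the discrete divergence vanishes to round-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import R_EARTH_M, SECONDS_PER_DAY, m2s_to_km2d
from .dispersion import AREA_GROWTH_PER_DIFFUSIVITY
from .grid import GridField, bilinear_sample
from .mld import TemperatureProfile
from .patch_tracking import PatchSeries


# ---------------------------------------------------------------------------
# specs


@dataclass
class FieldSpec:
    """Grid geometry and time axis for a generated field."""

    lon_range: tuple[float, float] = (195.0, 205.0)
    lat_range: tuple[float, float] = (28.0, 36.0)
    grid_step: float = 0.25  # degrees
    time_span: float = 60.0  # days
    time_step: float = 1.0  # days
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_step <= 0 or self.time_step <= 0:
            raise ValueError("grid_step and time_step must be positive")
        if self.lon_range[1] <= self.lon_range[0] or self.lat_range[1] <= self.lat_range[0]:
            raise ValueError("degenerate lon/lat range")
        if self.time_span <= 0:
            raise ValueError("time_span must be positive")

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        lon = np.arange(self.lon_range[0], self.lon_range[1] + 1e-9, self.grid_step)
        lat = np.arange(self.lat_range[0], self.lat_range[1] + 1e-9, self.grid_step)
        time = np.arange(0.0, self.time_span + 1e-9, self.time_step)
        if lon.size < 2 or lat.size < 2:
            raise ValueError("degenerate grid: fewer than 2 points per axis")
        return lon, lat, time

    def meters_axes(self) -> tuple[np.ndarray, np.ndarray, float]:
        """Local tangent-plane x/y coordinates (m) and the reference latitude."""
        lon, lat, _ = self.axes()
        lat_c = float(lat.mean())
        x = np.deg2rad(lon - lon[0]) * R_EARTH_M * np.cos(np.deg2rad(lat_c))
        y = np.deg2rad(lat - lat[0]) * R_EARTH_M
        return x, y, lat_c


@dataclass
class EddyFieldSpec:
    """Parameters of the random-phase eddy streamfunction."""

    eddy_length_scale_km: float = 150.0
    rms_speed: float = 0.15  # m s^-1
    n_modes: int = 24
    evolution_timescale_days: float = 20.0

    def __post_init__(self) -> None:
        if min(
            self.eddy_length_scale_km,
            self.rms_speed,
            self.n_modes,
            self.evolution_timescale_days,
        ) <= 0:
            raise ValueError("all eddy-field parameters must be positive")


@dataclass
class ProfileSpec:
    """Two-layer temperature profile: mixed layer over a linear thermocline."""

    mld_true: float = 40.0  # m
    surface_temp: float = 24.0  # degC
    thermocline_gradient: float = -0.1  # degC per m, must be negative
    noise_sd: float = 0.02  # degC
    depth_step: float = 5.0  # m
    max_depth: float = 200.0  # m

    def __post_init__(self) -> None:
        if self.mld_true <= 0:
            raise ValueError("mld_true must be positive")
        if self.thermocline_gradient >= 0:
            raise ValueError("thermocline_gradient must be negative")
        if self.depth_step >= self.mld_true:
            raise ValueError("depth_step must resolve the mixed layer")


# ---------------------------------------------------------------------------
# velocity fields


def make_velocity_field(spec: FieldSpec, eddies: EddyFieldSpec) -> GridField:
    """Divergence-free eddying velocity field from a random streamfunction.

    The streamfunction is a sum of ``n_modes`` Fourier modes with random
    directions and phases, wavelengths within +-30% of the eddy length
    scale, and phases drifting on the evolution timescale.  u = -dpsi/dy,
    v = +dpsi/dx via centred finite differences; the field is rescaled so
    its overall RMS speed equals ``rms_speed`` exactly.
    """
    lon, lat, time = spec.axes()
    x, y, _ = spec.meters_axes()
    rng = np.random.default_rng(spec.rng_seed)
    L = eddies.eddy_length_scale_km * 1000.0
    wavelengths = L * rng.uniform(0.7, 1.3, eddies.n_modes)
    theta = rng.uniform(0, 2 * np.pi, eddies.n_modes)
    phase = rng.uniform(0, 2 * np.pi, eddies.n_modes)
    omega = (2 * np.pi / eddies.evolution_timescale_days) * rng.uniform(
        0.5, 1.5, eddies.n_modes
    ) * rng.choice([-1.0, 1.0], eddies.n_modes)
    amp = rng.uniform(0.5, 1.0, eddies.n_modes)

    X, Y = np.meshgrid(x, y)
    psi = np.zeros((time.size, y.size, x.size))
    for j in range(eddies.n_modes):
        k = 2 * np.pi / wavelengths[j]
        kx, ky = k * np.cos(theta[j]), k * np.sin(theta[j])
        sp = kx * X + ky * Y + phase[j]
        for it, t in enumerate(time):
            psi[it] += amp[j] * np.sin(sp + omega[j] * t)

    dx = float(x[1] - x[0])
    dy = float(y[1] - y[0])
    u = -np.gradient(psi, dy, axis=1)
    v = np.gradient(psi, dx, axis=2)
    rms = np.sqrt(np.mean(u**2 + v**2))
    scale = eddies.rms_speed / rms
    return GridField(lon=lon, lat=lat, time=time, data={"u": u * scale, "v": v * scale})


def make_uniform_flow(spec: FieldSpec, u: float, v: float = 0.0) -> GridField:
    """Spatially uniform, steady flow (m s^-1)."""
    lon, lat, time = spec.axes()
    shape = (time.size, lat.size, lon.size)
    return GridField(
        lon=lon,
        lat=lat,
        time=time,
        data={"u": np.full(shape, float(u)), "v": np.full(shape, float(v))},
    )


def make_solid_body_rotation(spec: FieldSpec, omega_per_day: float) -> GridField:
    """Solid-body rotation about the domain centre.

    ``omega_per_day`` is the angular rate in radians per day; speed at
    distance r from the centre is omega*r.  Velocities are in m s^-1 on the
    local tangent plane.
    """
    lon, lat, time = spec.axes()
    x, y, _ = spec.meters_axes()
    X, Y = np.meshgrid(x - x.mean(), y - y.mean())
    w = omega_per_day / SECONDS_PER_DAY  # rad s^-1
    u2d, v2d = -w * Y, w * X
    u = np.broadcast_to(u2d, (time.size,) + u2d.shape).copy()
    v = np.broadcast_to(v2d, (time.size,) + v2d.shape).copy()
    return GridField(lon=lon, lat=lat, time=time, data={"u": u, "v": v})


# ---------------------------------------------------------------------------
# tracer bloom


def _laplacian_neumann(c: np.ndarray, dx: float, dy: float) -> np.ndarray:
    p = np.pad(c, 1, mode="edge")  # no-flux boundaries: conserves mass
    return (p[1:-1, 2:] - 2 * c + p[1:-1, :-2]) / dx**2 + (
        p[2:, 1:-1] - 2 * c + p[:-2, 1:-1]
    ) / dy**2


def make_tracer_bloom(
    velocity: GridField,
    center: tuple[float, float],
    sigma_km: float,
    peak: float,
    k_small: float = 0.0,
    background: float = 0.1,
    cloud_fraction: float = 0.0,
    rng_seed: int = 0,
    n_substeps: int = 1,
) -> GridField:
    """Advect-diffuse a Gaussian bloom through the velocity field.

    The initial tracer is ``background + peak * exp(-r^2 / (2 sigma^2))``
    centred at ``center`` (lon, lat).  Each interval between stored times is
    integrated in ``n_substeps`` steps of semi-Lagrangian advection
    (unconditionally stable) followed by explicit diffusion with diffusivity
    ``k_small`` (m^2 s^-1); the diffusion step must satisfy its CFL limit or
    a ValueError naming the maximum stable step is raised.  A seeded i.i.d.
    cloud mask hides ``cloud_fraction`` of the cells in every time slice.
    """
    if not 0.0 <= cloud_fraction < 1.0:
        raise ValueError("cloud_fraction must be in [0, 1)")
    lon, lat, time = velocity.lon, velocity.lat, velocity.time
    lat_c = float(lat.mean())
    x = np.deg2rad(lon - lon[0]) * R_EARTH_M * np.cos(np.deg2rad(lat_c))
    y = np.deg2rad(lat - lat[0]) * R_EARTH_M
    dx, dy = float(x[1] - x[0]), float(y[1] - y[0])

    if time.size > 1:
        dt_days = float(np.diff(time).mean()) / n_substeps
        dt_sec = dt_days * SECONDS_PER_DAY
        if k_small > 0:
            stable = 0.25 * min(dx, dy) ** 2 / k_small
            if dt_sec > stable:
                raise ValueError(
                    f"diffusion step {dt_sec:.3g} s violates the CFL limit; "
                    f"maximum stable step is {stable:.3g} s "
                    f"({stable / SECONDS_PER_DAY:.3g} days)"
                )

    X, Y = np.meshgrid(x, y)
    cx = np.interp(center[0], lon, x)
    cy = np.interp(center[1], lat, y)
    r2 = (X - cx) ** 2 + (Y - cy) ** 2
    c = background + peak * np.exp(-r2 / (2 * (sigma_km * 1000.0) ** 2))

    conc = np.empty((time.size, lat.size, lon.size))
    conc[0] = c
    for it in range(1, time.size):
        t_prev = time[it - 1]
        for s in range(n_substeps):
            ts = t_prev + s * dt_days
            # velocity at the substep midpoint, linear in time
            um, vm = _velocity_at(velocity, ts + 0.5 * dt_days)
            # semi-Lagrangian: backtrack departure points (midpoint rule)
            dts = dt_days * SECONDS_PER_DAY
            xd = X - um * dts
            yd = Y - vm * dts
            cn = bilinear_sample(x, y, c, xd, yd)
            cn = np.where(np.isnan(cn), background, cn)
            if k_small > 0:
                cn = cn + k_small * dts * _laplacian_neumann(cn, dx, dy)
            c = np.maximum(cn, 0.0)
        conc[it] = c

    mask = None
    if cloud_fraction > 0:
        rng = np.random.default_rng(rng_seed)
        mask = rng.random(conc.shape) < cloud_fraction
    return GridField(lon=lon, lat=lat, time=time, data={"conc": conc}, mask=mask)


def _velocity_at(velocity: GridField, t: float) -> tuple[np.ndarray, np.ndarray]:
    """u, v slices linearly interpolated in time (clamped to the ends)."""
    times = velocity.time
    t = float(np.clip(t, times[0], times[-1]))
    i = int(np.clip(np.searchsorted(times, t) - 1, 0, times.size - 2))
    f = (t - times[i]) / (times[i + 1] - times[i]) if times.size > 1 else 0.0
    u = (1 - f) * velocity.data["u"][i] + f * velocity.data["u"][i + 1]
    v = (1 - f) * velocity.data["v"][i] + f * velocity.data["v"][i + 1]
    return u, v


def make_expanding_patch_tracer(
    spec: FieldSpec,
    center: tuple[float, float],
    A0_km2: float,
    k_e_m2_s: float,
    peak: float = 0.16,
    background: float = 0.1,
    edge_width_cells: float = 1.0,
    drift: tuple[np.ndarray, np.ndarray] | None = None,
    cloud_fraction: float = 0.0,
    rng_seed: int = 0,
) -> GridField:
    """Tracer patch whose area grows at exactly the dispersion-theory rate.

    The patch is a disk of prescribed area A(t) = A0 + 8*pi*k_e*t with
    uniform interior concentration ``peak`` over ``background`` and a smooth
    edge about one grid cell wide; the contour at the half-way concentration
    (background + peak)/2 sits exactly on the prescribed radius.  This is
    the controlled stand-in for a bloom dispersed in the large-time eddy
    regime: mean concentration stays constant while area (hence
    mixed-layer-integrated biomass) grows linearly, and the generator's
    ``k_e`` is the ground truth for recovery tests.

    ``drift`` optionally gives per-time-step centre coordinates
    ``(lons, lats)`` (e.g. a trajectory from the advection module); default
    is a stationary centre.
    """
    if A0_km2 <= 0 or k_e_m2_s < 0:
        raise ValueError("A0 must be positive and k_e non-negative")
    lon, lat, time = spec.axes()
    x, y, _ = spec.meters_axes()
    X, Y = np.meshgrid(x, y)
    if drift is None:
        clons = np.full(time.size, center[0])
        clats = np.full(time.size, center[1])
    else:
        clons, clats = (np.asarray(d, float) for d in drift)
        if clons.size != time.size:
            raise ValueError("drift trajectory length must match the time axis")
    slope_km2_d = m2s_to_km2d(AREA_GROWTH_PER_DIFFUSIVITY * k_e_m2_s)
    w = edge_width_cells * min(x[1] - x[0], y[1] - y[0])
    conc = np.empty((time.size, lat.size, lon.size))
    for it, t in enumerate(time):
        r_edge = np.sqrt((A0_km2 + slope_km2_d * t) * 1e6 / np.pi)  # m
        cx = np.interp(clons[it], lon, x)
        cy = np.interp(clats[it], lat, y)
        r = np.hypot(X - cx, Y - cy)
        s = np.clip((r_edge - r) / w + 0.5, 0.0, 1.0)
        conc[it] = background + (peak - background) * s
    mask = None
    if cloud_fraction > 0:
        if not cloud_fraction < 1:
            raise ValueError("cloud_fraction must be in [0, 1)")
        rng = np.random.default_rng(rng_seed)
        mask = rng.random(conc.shape) < cloud_fraction
    return GridField(lon=lon, lat=lat, time=time, data={"conc": conc}, mask=mask)


# ---------------------------------------------------------------------------
# patch-area series and profiles


def make_diffusing_patch_series(
    A0_km2: float,
    k_e_m2_s: float,
    duration_days: float,
    noise_sd_km2: float = 0.0,
    rng_seed: int = 0,
    dt_days: float = 1.0,
) -> PatchSeries:
    """Patch-area series growing linearly at the dispersion-theory rate.

    A(t) = A0 + 8*pi*k_e*t (+ Gaussian noise), the linear growth expected
    when a patch is dispersed by eddies smaller than itself.  Noise draws
    that would make an area non-positive are resampled (up to 100 times).
    """
    if A0_km2 <= 0:
        raise ValueError("A0 must be positive")
    if k_e_m2_s < 0:
        raise ValueError("k_e must be non-negative")
    times = np.arange(0.0, duration_days + 1e-9, dt_days)
    slope_km2_d = m2s_to_km2d(AREA_GROWTH_PER_DIFFUSIVITY * k_e_m2_s)
    area = A0_km2 + slope_km2_d * times
    if noise_sd_km2 > 0:
        rng = np.random.default_rng(rng_seed)
        noisy = area + rng.normal(0, noise_sd_km2, times.size)
        for _ in range(100):
            bad = noisy <= 0
            if not bad.any():
                break
            noisy[bad] = area[bad] + rng.normal(0, noise_sd_km2, int(bad.sum()))
        else:
            raise ValueError("noise too large: areas non-positive after 100 resamples")
        area = noisy
    nan = np.full(times.size, np.nan)
    return PatchSeries(
        times=times,
        area_km2=area,
        mean_conc=nan.copy(),
        total_biomass_mg=nan.copy(),
        coverage_fraction=nan.copy(),
        contour_level=np.nan,
        mld_m=np.nan,
    )


def make_profiles(
    spec: ProfileSpec, n_profiles: int = 1, rng_seed: int = 0
) -> list[TemperatureProfile]:
    """Two-layer temperature profiles with optional measurement noise."""
    rng = np.random.default_rng(rng_seed)
    depths = np.arange(spec.depth_step, spec.max_depth + 1e-9, spec.depth_step)
    base = np.where(
        depths <= spec.mld_true,
        spec.surface_temp,
        spec.surface_temp + spec.thermocline_gradient * (depths - spec.mld_true),
    )
    out = []
    for pid in range(n_profiles):
        noise = rng.normal(0, spec.noise_sd, depths.size) if spec.noise_sd > 0 else 0.0
        out.append(TemperatureProfile(depth=depths.copy(), temperature=base + noise, profile_id=pid))
    return out
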