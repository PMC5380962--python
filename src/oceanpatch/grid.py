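"""Gridded lon/lat/time fields.

A :class:`GridField` holds one or more scalar variables (e.g. a tracer in
mg m^-3, or the ``u``/``v`` components of a surface current in m s^-1) on a
regular longitude/latitude grid with a time axis in days since scenario
start.  An optional boolean mask marks missing (e.g. cloud-covered) cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import R_EARTH_KM


def _require_monotonic(name: str, axis: np.ndarray) -> None:
    if axis.ndim != 1 or axis.size < 2:
        raise ValueError(f"{name} axis must be 1-D with at least 2 points")
    if not np.all(np.diff(axis) > 0):
        raise ValueError(f"{name} axis must be strictly increasing")


@dataclass
class GridField:
    """A set of gridded variables on a shared lon/lat/time grid.

    Parameters
    ----------
    lon, lat : 1-D arrays, degrees east / north, strictly increasing.
    time : 1-D array, days since scenario start, strictly increasing.
    data : mapping of variable name to ``(time, lat, lon)`` array.
    mask : optional boolean ``(time, lat, lon)`` array, True where missing.
    """

    lon: np.ndarray
    lat: np.ndarray
    time: np.ndarray
    data: dict[str, np.ndarray] = field(default_factory=dict)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        _require_monotonic("lon", self.lon)
        _require_monotonic("lat", self.lat)
        if self.time.ndim != 1 or self.time.size < 1:
            raise ValueError("time axis must be 1-D and non-empty")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time axis must be strictly increasing")
        shape = (self.time.size, self.lat.size, self.lon.size)
        for name, arr in self.data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != shape:
                raise ValueError(
                    f"variable {name!r} has shape {arr.shape}, expected {shape}"
                )
            self.data[name] = arr
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != shape:
                raise ValueError(f"mask has shape {self.mask.shape}, expected {shape}")

    # -- geometry -----------------------------------------------------------

    @property
    def is_vector(self) -> bool:
        return {"u", "v"} <= set(self.data)

    @property
    def dlon(self) -> float:
        return float(np.mean(np.diff(self.lon)))

    @property
    def dlat(self) -> float:
        return float(np.mean(np.diff(self.lat)))

    @property
    def lon_edges(self) -> np.ndarray:
        d = self.dlon
        return np.concatenate([self.lon - d / 2, [self.lon[-1] + d / 2]])

    @property
    def lat_edges(self) -> np.ndarray:
        d = self.dlat
        return np.concatenate([self.lat - d / 2, [self.lat[-1] + d / 2]])

    def cell_areas_km2(self) -> np.ndarray:
        """Spherical cell areas, km^2, shape ``(nlat, nlon)``.

        Cell area = R^2 * dlambda * (sin(phi_top) - sin(phi_bottom)).
        """
        lam = np.deg2rad(self.lon_edges)
        phi = np.deg2rad(self.lat_edges)
        band = R_EARTH_KM**2 * (np.sin(phi[1:]) - np.sin(phi[:-1]))  # per lat row
        return np.outer(band, np.diff(lam))

    # -- lookup -------------------------------------------------------------

    def time_index(self, t: float, atol: float = 1e-6) -> int:
        i = int(np.argmin(np.abs(self.time - t)))
        if abs(self.time[i] - t) > atol:
            raise ValueError(f"time {t} not on the stored time axis")
        return i

    def covers_time(self, t0: float, t1: float) -> bool:
        return self.time[0] <= t0 + 1e-9 and t1 <= self.time[-1] + 1e-9


def bilinear_sample(
    xaxis: np.ndarray,
    yaxis: np.ndarray,
    field2d: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
) -> np.ndarray:
    """Bilinear interpolation of ``field2d`` (shape ``(ny, nx)``) at points.

    Points outside the axis ranges return NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = np.full(np.broadcast(x, y).shape, np.nan)
    inside = (
        (x >= xaxis[0]) & (x <= xaxis[-1]) & (y >= yaxis[0]) & (y <= yaxis[-1])
    )
    if not np.any(inside):
        return out
    xi = np.clip(np.searchsorted(xaxis, x[inside]) - 1, 0, xaxis.size - 2)
    yi = np.clip(np.searchsorted(yaxis, y[inside]) - 1, 0, yaxis.size - 2)
    fx = (x[inside] - xaxis[xi]) / (xaxis[xi + 1] - xaxis[xi])
    fy = (y[inside] - yaxis[yi]) / (yaxis[yi + 1] - yaxis[yi])
    f00 = field2d[yi, xi]
    f01 = field2d[yi, xi + 1]
    f10 = field2d[yi + 1, xi]
    f11 = field2d[yi + 1, xi + 1]
    out[inside] = (
        f00 * (1 - fx) * (1 - fy)
        + f01 * fx * (1 - fy)
        + f10 * (1 - fx) * fy
        + f11 * fx * fy
    )
    return out
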