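"""Bloom-patch delineation and Lagrangian time series.

A bloom patch is the connected set of grid cells whose tracer concentration
exceeds a chosen contour level.  Tracking the patch through time yields a
Lagrangian series of its surface area A_p, its area-weighted mean
concentration, and the mixed-layer-integrated total biomass
(mean concentration x area x MLD, assuming the mixed layer is homogeneous
in the tracer).

Cloud-masked cells enclosed by the patch count toward its area but are
excluded from the concentration mean: a cloud gap is unobserved water, not
zero concentration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .constants import M2_PER_KM2
from .grid import GridField

log = logging.getLogger(__name__)

_EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass
class PatchMask:
    """Cells belonging to one delineated patch at one time."""

    cells: np.ndarray  # bool (nlat, nlon), includes flagged cloud cells
    flagged_cloud: np.ndarray  # bool, interior cloud cells included in area
    level: float
    t: float


@dataclass
class PatchSeries:
    """Lagrangian series of patch properties at one contour level."""

    times: np.ndarray
    area_km2: np.ndarray
    mean_conc: np.ndarray  # mg m^-3
    total_biomass_mg: np.ndarray
    coverage_fraction: np.ndarray
    contour_level: float
    mld_m: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_day": self.times,
                "area_km2": self.area_km2,
                "mean_conc_mg_m3": self.mean_conc,
                "total_biomass_mg": self.total_biomass_mg,
                "coverage_fraction": self.coverage_fraction,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, contour_level=np.nan, mld_m=np.nan) -> "PatchSeries":
        df = pd.read_csv(path)
        return cls(
            times=df["time_day"].to_numpy(float),
            area_km2=df["area_km2"].to_numpy(float),
            mean_conc=df.get("mean_conc_mg_m3", pd.Series(np.nan, index=df.index)).to_numpy(float),
            total_biomass_mg=df.get("total_biomass_mg", pd.Series(np.nan, index=df.index)).to_numpy(float),
            coverage_fraction=df.get("coverage_fraction", pd.Series(np.nan, index=df.index)).to_numpy(float),
            contour_level=contour_level,
            mld_m=mld_m,
        )


@dataclass
class ContourSensitivity:
    """Per-level Lagrangian series plus across-level mean and spread."""

    levels: list[float]
    series: dict[float, PatchSeries]
    summary: pd.DataFrame = field(default=None)


def _scalar_var(tracer: GridField) -> str:
    names = [k for k in tracer.data if k not in ("u", "v")]
    if not names:
        raise ValueError("tracer field has no scalar variable")
    return names[0]


def delineate_patch(
    tracer: GridField,
    level: float,
    t: float,
    seed_point="largest",
) -> PatchMask:
    """Connected component (8-connectivity) of cells >= level at time t.

    ``seed_point`` is either the string ``"largest"`` (most cells; ties
    broken by the component first encountered in row-major order) or a
    ``(lon, lat)`` pair that must fall inside a component.  Cloud-masked
    cells enclosed by the component are added to the mask and flagged.
    """
    ti = tracer.time_index(t)
    conc = tracer.data[_scalar_var(tracer)][ti]
    cloud = tracer.mask[ti] if tracer.mask is not None else np.zeros_like(conc, bool)
    above = (conc >= level) & ~cloud
    if not above.any():
        raise ValueError(f"no patch at level {level} at t={t}")
    labels, n = ndimage.label(above, structure=_EIGHT_CONN)
    if isinstance(seed_point, str) and seed_point == "largest":
        counts = np.bincount(labels.ravel())[1:]
        chosen = int(np.argmax(counts)) + 1  # first max = lowest row-major origin
    else:
        lon0, lat0 = seed_point
        j = int(np.argmin(np.abs(tracer.lon - lon0)))
        i = int(np.argmin(np.abs(tracer.lat - lat0)))
        chosen = int(labels[i, j])
        if chosen == 0:
            raise ValueError(f"seed point {seed_point} is not inside any patch")
    comp = labels == chosen
    filled = ndimage.binary_fill_holes(comp)
    flagged = filled & cloud & ~comp
    return PatchMask(cells=comp | flagged, flagged_cloud=flagged, level=level, t=t)


def patch_area(mask, grid: GridField) -> float:
    """Patch surface area in km^2 as the sum of spherical cell areas."""
    cells = mask.cells if isinstance(mask, PatchMask) else np.asarray(mask, bool)
    if not cells.any():
        raise ValueError("empty patch mask")
    return float(grid.cell_areas_km2()[cells].sum())


def _centroid(cells: np.ndarray, grid: GridField) -> tuple[float, float]:
    areas = grid.cell_areas_km2()
    w = np.where(cells, areas, 0.0)
    tot = w.sum()
    lon = float((w.sum(axis=0) * grid.lon).sum() / tot)
    lat = float((w.sum(axis=1) * grid.lat).sum() / tot)
    return lon, lat


def _component_near(
    tracer: GridField, level: float, ti: int, centroid: tuple[float, float], r_eq_km: float
) -> np.ndarray | None:
    """Component containing (or nearest within r_eq_km of) the centroid."""
    conc = tracer.data[_scalar_var(tracer)][ti]
    cloud = tracer.mask[ti] if tracer.mask is not None else np.zeros_like(conc, bool)
    above = (conc >= level) & ~cloud
    if not above.any():
        return None
    labels, _ = ndimage.label(above, structure=_EIGHT_CONN)
    lon0, lat0 = centroid
    j = int(np.argmin(np.abs(tracer.lon - lon0)))
    i = int(np.argmin(np.abs(tracer.lat - lat0)))
    if labels[i, j] > 0:
        return labels == labels[i, j]
    # nearest above-level cell, distance in km on a local tangent plane
    ii, jj = np.nonzero(above)
    kmx = 111.195 * np.cos(np.deg2rad(lat0))
    d = np.hypot((tracer.lon[jj] - lon0) * kmx, (tracer.lat[ii] - lat0) * 111.195)
    k = int(np.argmin(d))
    if d[k] > r_eq_km:
        return None
    return labels == labels[ii[k], jj[k]]


def lagrangian_series(
    tracer: GridField,
    level: float,
    mld_m: float,
    variable: str | None = None,
) -> PatchSeries:
    """Track the patch through time and build its Lagrangian series.

    The patch is delineated as the largest component at the first time step
    and re-identified at later steps by the component containing (or closest
    to, within one equivalent radius) the previous patch centroid.  If the
    patch is lost the series is truncated with a logged reason.
    """
    var = variable or _scalar_var(tracer)
    areas_grid = tracer.cell_areas_km2()
    times, rows = [], []
    prev_centroid = None
    prev_area = None
    for ti, t in enumerate(tracer.time):
        if prev_centroid is None:
            try:
                pm = delineate_patch(tracer, level, t, "largest")
            except ValueError as exc:
                if ti == 0:
                    raise
                log.warning("patch lost at t=%s: %s; series truncated", t, exc)
                break
            cells = pm.cells
        else:
            r_eq = np.sqrt(prev_area / np.pi)
            comp = _component_near(tracer, level, ti, prev_centroid, r_eq)
            if comp is None:
                log.warning(
                    "patch lost at t=%s: no component near previous centroid; "
                    "series truncated",
                    t,
                )
                break
            filled = ndimage.binary_fill_holes(comp)
            cloud = (
                tracer.mask[ti]
                if tracer.mask is not None
                else np.zeros_like(comp, bool)
            )
            cells = comp | (filled & cloud)
        cloud = tracer.mask[ti] if tracer.mask is not None else np.zeros_like(cells, bool)
        observed = cells & ~cloud
        area = float(areas_grid[cells].sum())
        area_obs = float(areas_grid[observed].sum())
        conc = tracer.data[var][ti]
        mean = float((conc[observed] * areas_grid[observed]).sum() / area_obs)
        total = mean * area * M2_PER_KM2 * mld_m  # mg
        times.append(float(t))
        rows.append((area, mean, total, area_obs / area))
        prev_centroid = _centroid(cells, tracer)
        prev_area = area
    arr = np.array(rows)
    return PatchSeries(
        times=np.array(times),
        area_km2=arr[:, 0],
        mean_conc=arr[:, 1],
        total_biomass_mg=arr[:, 2],
        coverage_fraction=arr[:, 3],
        contour_level=level,
        mld_m=mld_m,
    )


def contour_sensitivity(
    tracer: GridField,
    levels,
    mld_m: float,
    variable: str | None = None,
) -> ContourSensitivity:
    """Lagrangian series for a range of contour levels, with spread.

    Levels at which no patch exists at the first time step are skipped with
    a warning.  The summary holds the across-level mean and s.d. of area,
    mean concentration, and total biomass at each time (ignoring levels
    whose series ended early).
    """
    levels = [float(x) for x in levels]
    if len(levels) < 2:
        raise ValueError("need at least 2 contour levels")
    series: dict[float, PatchSeries] = {}
    for lv in levels:
        try:
            series[lv] = lagrangian_series(tracer, lv, mld_m, variable)
        except ValueError as exc:
            log.warning("level %s skipped: %s", lv, exc)
    if not series:
        raise ValueError("no contour level yields a patch")
    all_times = np.unique(np.concatenate([s.times for s in series.values()]))

    def stack(attr):
        out = np.full((len(series), all_times.size), np.nan)
        for k, s in enumerate(series.values()):
            idx = np.searchsorted(all_times, s.times)
            out[k, idx] = getattr(s, attr)
        return out

    area = stack("area_km2")
    conc = stack("mean_conc")
    biom = stack("total_biomass_mg")
    with np.errstate(invalid="ignore"):
        summary = pd.DataFrame(
            {
                "time_day": all_times,
                "area_mean_km2": np.nanmean(area, axis=0),
                "area_sd_km2": np.nanstd(area, axis=0),
                "conc_mean_mg_m3": np.nanmean(conc, axis=0),
                "conc_sd_mg_m3": np.nanstd(conc, axis=0),
                "biomass_mean_mg": np.nanmean(biom, axis=0),
                "biomass_sd_mg": np.nanstd(biom, axis=0),
            }
        )
    return ContourSensitivity(levels=sorted(series), series=series, summary=summary)
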