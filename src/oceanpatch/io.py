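"""NetCDF round-trip for gridded fields (CF-style lon/lat/time coordinates).

Files are written as NetCDF3 classic through xarray's scipy backend, which
keeps the on-disk format readable by any NetCDF tool without extra
dependencies.  The missing-data mask is stored explicitly as an int8
variable so round-trips preserve it exactly.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from .grid import GridField

_COORD_ATTRS = {
    "lon": {"standard_name": "longitude", "units": "degrees_east"},
    "lat": {"standard_name": "latitude", "units": "degrees_north"},
    "time": {"long_name": "time since scenario start", "units": "days"},
}


def write_gridfield(field: GridField, path, units: dict[str, str] | None = None) -> None:
    """Write a GridField to NetCDF; variable units may be supplied."""
    data_vars = {
        name: (("time", "lat", "lon"), arr) for name, arr in field.data.items()
    }
    if field.mask is not None:
        data_vars["mask"] = (
            ("time", "lat", "lon"),
            field.mask.astype(np.int8),
            {"long_name": "missing-data flag", "flag_values": "0: valid, 1: missing"},
        )
    ds = xr.Dataset(
        data_vars,
        coords={"lon": field.lon, "lat": field.lat, "time": field.time},
    )
    for c, attrs in _COORD_ATTRS.items():
        ds[c].attrs.update(attrs)
    for name, u in (units or {}).items():
        if name in ds:
            ds[name].attrs["units"] = u
    ds.to_netcdf(path, engine="scipy")


def read_gridfield(path) -> GridField:
    """Read a GridField written by :func:`write_gridfield`.

    Raises a ValueError naming the expected coordinate variables if any of
    lon/lat/time is missing, and propagates grid-validation errors (e.g.
    non-monotonic latitude).
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        missing = [c for c in ("lon", "lat", "time") if c not in ds.coords and c not in ds]
        if missing:
            raise ValueError(
                f"file lacks coordinate variable(s) {missing}; expected CF-style "
                "'lon', 'lat' and 'time'"
            )
        mask = None
        data = {}
        for name, var in ds.data_vars.items():
            if name == "mask":
                mask = var.values.astype(bool)
            else:
                data[name] = var.values.astype(float)
        return GridField(
            lon=ds["lon"].values,
            lat=ds["lat"].values,
            time=ds["time"].values,
            data=data,
            mask=mask,
        )
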