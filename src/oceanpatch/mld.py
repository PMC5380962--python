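"""Mixed-layer depth from temperature profiles.

The mixed layer is diagnosed with a temperature-threshold criterion: the MLD
is the depth at which temperature first departs from its surface value by
``delta_t`` (default 0.2 degC), with linear interpolation between the two
bracketing measurement levels.  The absolute difference |T(z) - T(surface)|
is used, so both warming and cooling departures count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_DELTA_T = 0.2  # degC


@dataclass
class TemperatureProfile:
    """A single temperature-depth profile, depths positive down."""

    depth: np.ndarray  # m, strictly increasing
    temperature: np.ndarray  # degC
    profile_id: int = 0

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        if self.depth.size < 3:
            raise ValueError("profile needs at least 3 levels")
        if self.depth.shape != self.temperature.shape:
            raise ValueError("depth and temperature lengths differ")
        if not np.all(np.diff(self.depth) > 0):
            raise ValueError("depths must be strictly increasing")
        if self.depth[0] > 10.0:
            raise ValueError("shallowest level must be at or above 10 m")


def compute_mld(profile: TemperatureProfile, delta_t: float = DEFAULT_DELTA_T) -> float:
    """Mixed-layer depth (m) by the temperature-threshold criterion.

    The surface value is the shallowest measurement.  Returns the depth of
    the first crossing of ``|T(z) - T(surface)| = delta_t``, linearly
    interpolated between the bracketing levels; if the crossing falls
    exactly on a sampled level that level's depth is returned.

    Raises
    ------
    ValueError
        If the threshold is never reached within the profile.
    """
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    dev = np.abs(profile.temperature - profile.temperature[0])
    # a level within float round-off of the threshold counts as a crossing
    reached = (dev >= delta_t) | np.isclose(dev, delta_t, rtol=1e-12, atol=1e-12)
    above = np.nonzero(reached)[0]
    if above.size == 0:
        raise ValueError("MLD deeper than profile: threshold never reached")
    i = int(above[0])
    if i == 0 or np.isclose(dev[i], delta_t, rtol=1e-12, atol=1e-12):
        return float(profile.depth[i])
    # linear interpolation of |dT| between levels i-1 and i
    frac = (delta_t - dev[i - 1]) / (dev[i] - dev[i - 1])
    return float(profile.depth[i - 1] + frac * (profile.depth[i] - profile.depth[i - 1]))


def compute_mld_batch(
    profiles: list[TemperatureProfile], delta_t: float = DEFAULT_DELTA_T
) -> pd.DataFrame:
    """MLD per profile; profiles without a crossing get NaN."""
    rows = []
    for p in profiles:
        try:
            depth = compute_mld(p, delta_t)
        except ValueError:
            depth = np.nan
        rows.append({"profile_id": p.profile_id, "mld_m": depth})
    return pd.DataFrame(rows)


def read_profiles_csv(path) -> list[TemperatureProfile]:
    """Read profiles from CSV with columns profile_id, depth_m, temp_c."""
    df = pd.read_csv(path)
    out = []
    for pid, sub in df.groupby("profile_id", sort=True):
        sub = sub.sort_values("depth_m")
        out.append(
            TemperatureProfile(
                depth=sub["depth_m"].to_numpy(),
                temperature=sub["temp_c"].to_numpy(),
                profile_id=int(pid),
            )
        )
    return out


def write_profiles_csv(profiles: list[TemperatureProfile], path) -> None:
    frames = [
        pd.DataFrame(
            {"profile_id": p.profile_id, "depth_m": p.depth, "temp_c": p.temperature}
        )
        for p in profiles
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
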