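"""Dispersion diagnostics of a tracked patch.

When a tracer patch is dispersed by eddies larger than the patch itself, its
area grows linearly in time and the growth rate is proportional to the
effective eddy diffusivity k_e:

    dA/dt = 8 * pi * k_e

The same linear growth, divided by the instantaneous area, defines the
horizontal dilution rate beta(t) = (dA/dt) / A(t).  With A(t) = A0 + (dA/dt) t
this gives beta(t) = beta0 / (1 + beta0 * t), beta0 = (dA/dt) / A0.  Because
the patch occupies a mixed layer of constant depth, relative volume change
and relative area change coincide, so beta is also (1/V) dV/dt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .constants import km2d_to_m2s, m2s_to_km2d

#: Ratio of patch-area growth rate to effective eddy diffusivity in the
#: large-time (eddy sizes smaller than patch) dispersion regime.  Kept as a
#: single named definition so the closure assumption can be changed in one
#: place.
AREA_GROWTH_PER_DIFFUSIVITY = 8.0 * math.pi


@dataclass
class DispersionEstimate:
    """Fitted dispersion quantities with standard errors."""

    area_rate_km2_d: float
    area_rate_se_km2_d: float
    area_rate_m2_s: float
    k_e_m2_s: float
    k_e_se_m2_s: float
    intercept_km2: float
    beta0_per_d: float | None = None
    beta0_se_per_d: float | None = None
    gamma: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def _extract_time_area(series) -> tuple[np.ndarray, np.ndarray]:
    """Accept a PatchSeries, DataFrame, or (times, areas) pair."""
    if hasattr(series, "times") and hasattr(series, "area_km2"):
        return np.asarray(series.times, float), np.asarray(series.area_km2, float)
    if isinstance(series, pd.DataFrame):
        return series["time_day"].to_numpy(float), series["area_km2"].to_numpy(float)
    t, a = series
    return np.asarray(t, float), np.asarray(a, float)


def fit_area_growth(series) -> tuple[float, float]:
    """OLS slope of patch area vs time.

    Returns ``(slope, stderr)`` in km^2 d^-1.  Needs at least 3 points.
    """
    t, a = _extract_time_area(series)
    ok = np.isfinite(t) & np.isfinite(a)
    if ok.sum() < 3:
        raise ValueError("need at least 3 finite time points for a slope fit")
    res = stats.linregress(t[ok], a[ok])
    stderr = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    return float(res.slope), stderr


def eddy_diffusivity(area_rate_m2_s: float) -> float:
    """Effective eddy diffusivity k_e = (dA/dt) / (8*pi), both in m^2 s^-1.

    A negative growth rate (shrinking patch) is passed through with a
    negative result rather than raised, since the relation itself is linear.
    """
    if not np.isfinite(area_rate_m2_s):
        raise ValueError("area growth rate must be finite")
    if area_rate_m2_s < 0:
        import warnings

        warnings.warn("negative area growth rate: patch is shrinking", stacklevel=2)
    return area_rate_m2_s / AREA_GROWTH_PER_DIFFUSIVITY


def dilution_rate(
    A0_km2: float, area_rate_km2_d: float
) -> tuple[float, "callable"]:
    """Initial horizontal dilution rate beta0 and the decay curve beta(t).

    beta0 = (dA/dt)/A0 in d^-1; beta(t) = beta0/(1 + beta0 t) follows from
    linear area growth at constant mixed-layer depth.
    """
    if A0_km2 <= 0:
        raise ValueError("initial area must be positive")
    beta0 = area_rate_km2_d / A0_km2

    def beta(t):
        return beta0 / (1.0 + beta0 * np.asarray(t, dtype=float))

    return float(beta0), beta


def gamma(beta0_per_d: float, mu_per_d: float) -> float:
    """Non-dimensional ratio of dilution to phytoplankton growth, beta0/mu."""
    if mu_per_d <= 0:
        raise ValueError("growth rate mu must be positive")
    return beta0_per_d / mu_per_d


def estimate_dispersion(series, mu: float | None = None) -> DispersionEstimate:
    """Full dispersion report from a patch-area time series.

    Fits dA/dt by OLS, converts to k_e, and (using the fitted intercept as
    A0) derives beta0.  Standard errors propagate linearly through the
    constant factors.
    """
    t, a = _extract_time_area(series)
    slope, se = fit_area_growth((t, a))
    res = stats.linregress(t[np.isfinite(a)], a[np.isfinite(a)])
    intercept = float(res.intercept)
    rate_m2s = km2d_to_m2s(slope)
    k_e = eddy_diffusivity(rate_m2s)
    k_e_se = km2d_to_m2s(se) / AREA_GROWTH_PER_DIFFUSIVITY
    est = DispersionEstimate(
        area_rate_km2_d=slope,
        area_rate_se_km2_d=se,
        area_rate_m2_s=rate_m2s,
        k_e_m2_s=k_e,
        k_e_se_m2_s=k_e_se,
        intercept_km2=intercept,
    )
    if intercept > 0:
        beta0, _ = dilution_rate(intercept, slope)
        est.beta0_per_d = beta0
        est.beta0_se_per_d = se / intercept
        if mu is not None:
            est.gamma = gamma(beta0, mu)
    return est


__all__ = [
    "AREA_GROWTH_PER_DIFFUSIVITY",
    "DispersionEstimate",
    "fit_area_growth",
    "eddy_diffusivity",
    "dilution_rate",
    "gamma",
    "estimate_dispersion",
    "m2s_to_km2d",
    "km2d_to_m2s",
]
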