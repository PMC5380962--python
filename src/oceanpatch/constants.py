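"""Physical constants and unit conversions used throughout the package."""

R_EARTH_M = 6_371_000.0  # mean Earth radius, m
R_EARTH_KM = R_EARTH_M / 1000.0
SECONDS_PER_DAY = 86_400.0
M2_PER_KM2 = 1.0e6


def m2s_to_km2d(rate_m2_s: float) -> float:
    """Convert an areal rate from m^2 s^-1 to km^2 d^-1."""
    return rate_m2_s * SECONDS_PER_DAY / M2_PER_KM2


def km2d_to_m2s(rate_km2_d: float) -> float:
    """Convert an areal rate from km^2 d^-1 to m^2 s^-1."""
    return rate_km2_d * M2_PER_KM2 / SECONDS_PER_DAY
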