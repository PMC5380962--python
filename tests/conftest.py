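import numpy as np
import pytest

from oceanpatch import synthetic_fields as sf


@pytest.fixture(scope="session")
def small_spec():
    """A compact grid for fast field generation."""
    return sf.FieldSpec(
        lon_range=(195.0, 205.0),
        lat_range=(27.0, 37.0),
        grid_step=0.25,
        time_span=20.0,
        time_step=2.0,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def eddy_velocity(small_spec):
    return sf.make_velocity_field(small_spec, sf.EddyFieldSpec())


@pytest.fixture(scope="session")
def expanding_tracer():
    """Expanding-patch tracer with known k_e (ground truth 1,100 m^2/s)."""
    spec = sf.FieldSpec(
        lon_range=(192.0, 216.0),
        lat_range=(25.0, 39.0),
        grid_step=0.125,
        time_span=60.0,
        time_step=1.0,
        rng_seed=5,
    )
    tracer = sf.make_expanding_patch_tracer(
        spec, center=(203.0, 32.0), A0_km2=1.0e4, k_e_m2_s=1100.0
    )
    return spec, tracer, 1100.0
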