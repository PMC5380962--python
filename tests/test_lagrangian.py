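"""Particle advection: closed-form orbits, convergence order, conservation."""

import numpy as np
import pytest

from oceanpatch import lagrangian as lg
from oceanpatch import synthetic_fields as sf
from oceanpatch.constants import R_EARTH_M, SECONDS_PER_DAY


@pytest.fixture(scope="module")
def rotation_field():
    spec = sf.FieldSpec(
        lon_range=(195, 205), lat_range=(27, 37), grid_step=0.2,
        time_span=40, time_step=5,
    )
    period = 20.0  # days
    return sf.make_solid_body_rotation(spec, 2 * np.pi / period), period


def _one_particle(lon, lat):
    return lg.ParticleEnsemble(times=[0.0], lon=[[lon]], lat=[[lat]])


class TestAdvect:
    def test_zero_velocity_leaves_positions_unchanged(self, small_spec):
        vel = sf.make_uniform_flow(small_spec, 0.0, 0.0)
        ens = _one_particle(200.0, 32.0)
        out = lg.advect(ens, vel, 0.0, 10.0)
        assert out.lon[-1, 0] == 200.0
        assert out.lat[-1, 0] == 32.0

    def test_uniform_zonal_flow_at_equator_matches_analytic_displacement(self):
        spec = sf.FieldSpec(lon_range=(0, 20), lat_range=(-5, 5), grid_step=0.5,
                            time_span=20, time_step=5)
        u = 0.2
        vel = sf.make_uniform_flow(spec, u, 0.0)
        out = lg.advect(_one_particle(5.0, 0.0), vel, 0.0, 10.0)
        expected_deg = np.rad2deg(u * 10 * SECONDS_PER_DAY / R_EARTH_M)
        assert out.lon[-1, 0] - 5.0 == pytest.approx(expected_deg, rel=1e-6)
        assert out.lat[-1, 0] == pytest.approx(0.0, abs=1e-12)

    def test_solid_body_orbit_returns_to_start(self, rotation_field):
        vel, period = rotation_field
        lon0, lat0 = 200.5, 32.0
        out = lg.advect(_one_particle(lon0, lat0), vel, 0.0, period, dt_hours=6)
        # error relative to the orbit radius, measured on the tangent plane
        r = np.hypot((lon0 - 200.0) * np.cos(np.deg2rad(32.0)), lat0 - 32.0)
        err = np.hypot(
            (out.lon[-1, 0] - lon0) * np.cos(np.deg2rad(32.0)), out.lat[-1, 0] - lat0
        )
        assert err <= 1e-3 * r

    def test_rk4_convergence_on_dt_halving(self, rotation_field):
        vel, period = rotation_field

        def final(dt_h):
            out = lg.advect(_one_particle(200.8, 32.3), vel, 0.0, period / 2, dt_hours=dt_h)
            return np.array([out.lon[-1, 0], out.lat[-1, 0]])

        d1 = np.linalg.norm(final(24) - final(12))
        d2 = np.linalg.norm(final(12) - final(6))
        d3 = np.linalg.norm(final(6) - final(3))
        # 4th order: each halving should shrink the change ~16x; demand >=10x
        assert d2 <= d1 / 10
        assert d3 <= d2 / 10

    def test_particle_count_invariant_and_out_of_grid_frozen(self, small_spec):
        vel = sf.make_uniform_flow(small_spec, 0.5, 0.0)  # pushes east
        lons = np.array([204.9, 198.0])
        lats = np.array([32.0, 32.0])
        ens = lg.ParticleEnsemble(times=[0.0], lon=lons[None], lat=lats[None])
        out = lg.advect(ens, vel, 0.0, 5.0)
        assert out.n_particles == 2
        assert out.frozen[0] and not out.frozen[1]
        # frozen particle keeps its last in-grid position, inside the domain
        assert out.lon[-1, 0] <= small_spec.lon_range[1] + 0.5

    @staticmethod
    def _shoelace(lon, lat, lat_ref):
        x = lon * np.cos(np.deg2rad(lat_ref))
        y = lat
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

    def test_quad_area_exactly_conserved_under_solid_body_rotation(self, rotation_field):
        # affine divergence-free flow: material area is conserved and the
        # 4-point shoelace represents it exactly
        vel, period = rotation_field
        h = 0.05
        lons = 201.0 + np.array([0, h, h, 0])
        lats = 32.5 + np.array([0, 0, h, h])
        ens = lg.ParticleEnsemble(times=[0.0], lon=lons[None], lat=lats[None])
        out = lg.advect(ens, vel, 0.0, period, dt_hours=6)
        a0 = self._shoelace(out.lon[0], out.lat[0], 32.5)
        a1 = self._shoelace(out.lon[-1], out.lat[-1], 32.5)
        assert a1 == pytest.approx(a0, rel=1e-4)

    def test_material_contour_area_conserved_in_steady_eddy_field(self):
        # one eddy turnover of a densely sampled material loop; beyond that
        # the loop winds and a sampled polygon stops resolving its area
        spec = sf.FieldSpec(lon_range=(196, 208), lat_range=(26, 38),
                            grid_step=0.05, time_span=120, time_step=60,
                            rng_seed=2)
        eddies = sf.EddyFieldSpec(
            eddy_length_scale_km=150.0, rms_speed=0.15, n_modes=2,
            evolution_timescale_days=1.0e6,
        )
        vel = sf.make_velocity_field(spec, eddies)
        turnover = 150.0e3 / 0.15 / SECONDS_PER_DAY  # ~11.6 days
        th = np.linspace(0, 2 * np.pi, 1024, endpoint=False)
        lons = 202.0 + 0.1 * np.cos(th)
        lats = 32.0 + 0.1 * np.sin(th)
        ens = lg.ParticleEnsemble(times=[0.0], lon=lons[None], lat=lats[None])
        out = lg.advect(ens, vel, 0.0, turnover, dt_hours=3,
                        output_stride_days=turnover)
        a0 = self._shoelace(out.lon[0], out.lat[0], 32.0)
        a1 = self._shoelace(out.lon[-1], out.lat[-1], 32.0)
        assert a1 == pytest.approx(a0, rel=0.01)


class TestSeeding:
    def _single_cell_tracer(self, small_spec):
        lon, lat, time = small_spec.axes()
        conc = np.zeros((time.size, lat.size, lon.size))
        conc[:, 10, 12] = 1.0
        from oceanpatch.grid import GridField

        return GridField(lon=lon, lat=lat, time=time, data={"conc": conc})

    def test_single_cell_gets_exactly_density_particles(self, small_spec):
        tracer = self._single_cell_tracer(small_spec)
        ens = lg.seed_particles_from_mask(tracer, 0.5, 0.0, density=10, rng_seed=1)
        assert ens.n_particles == 10
        # all inside that cell's bounds
        clon, clat = tracer.lon[12], tracer.lat[10]
        assert np.all(np.abs(ens.lon[0] - clon) <= small_spec.grid_step / 2)
        assert np.all(np.abs(ens.lat[0] - clat) <= small_spec.grid_step / 2)

    def test_uniform_field_seeds_every_cell(self, small_spec):
        lon, lat, time = small_spec.axes()
        from oceanpatch.grid import GridField

        tracer = GridField(
            lon=lon, lat=lat, time=time,
            data={"conc": np.ones((time.size, lat.size, lon.size))},
        )
        ens = lg.seed_particles_from_mask(tracer, 0.5, 0.0, density=3, rng_seed=1)
        assert ens.n_particles == 3 * lat.size * lon.size

    def test_empty_patch_raises(self, small_spec):
        tracer = self._single_cell_tracer(small_spec)
        with pytest.raises(ValueError, match="empty patch"):
            lg.seed_particles_from_mask(tracer, 2.0, 0.0)

    def test_gaussian_blob_seeded_area_matches_half_maximum_ellipse(self):
        spec = sf.FieldSpec(lon_range=(195, 205), lat_range=(27, 37),
                            grid_step=0.05, time_span=2, time_step=1)
        vel = sf.make_uniform_flow(spec, 0.0, 0.0)
        sigma = 80.0  # km
        tracer = sf.make_tracer_bloom(vel, (200, 32), sigma, 1.0, background=0.0)
        ens = lg.seed_particles_from_mask(tracer, 0.5, 0.0, density=1, rng_seed=0)
        # half-maximum level-set of a Gaussian: A = 2*pi*sigma^2*ln(2)
        cell_km2 = (0.05 * 111.195) * (0.05 * 111.195 * np.cos(np.deg2rad(32)))
        analytic = 2 * np.pi * sigma**2 * np.log(2)
        assert ens.n_particles * cell_km2 == pytest.approx(analytic, rel=0.05)


class TestDensity:
    def test_all_particles_in_one_cell(self, small_spec):
        ens = lg.ParticleEnsemble(
            times=[0.0], lon=[[200.01] * 7], lat=[[32.01] * 7]
        )
        field = lg.particle_density(ens, small_spec, 0.0)
        counts = field.data["density"][0] * field.cell_areas_km2()
        assert counts.max() == pytest.approx(7)
        assert counts.sum() == pytest.approx(7)

    def test_total_count_conserved(self, small_spec, eddy_velocity):
        rng = np.random.default_rng(2)
        n = 500
        ens = lg.ParticleEnsemble(
            times=[0.0],
            lon=rng.uniform(198, 202, n)[None],
            lat=rng.uniform(30, 34, n)[None],
        )
        out = lg.advect(ens, eddy_velocity, 0.0, 10.0)
        field = lg.particle_density(out, small_spec, 10.0)
        counts = field.data["density"][0] * field.cell_areas_km2()
        assert counts.sum() == pytest.approx(n)

    def test_random_walk_second_moment_grows_as_4kt(self, small_spec):
        # Brownian ensemble with known diffusivity, stepped in the test
        rng = np.random.default_rng(7)
        k_km2_d = 200.0  # ~2314 m^2/s
        n, days = 4000, 10
        kmx = 111.195 * np.cos(np.deg2rad(32.0))
        lon = np.full(n, 200.0)
        lat = np.full(n, 32.0)
        for _ in range(days):
            lon = lon + rng.normal(0, np.sqrt(2 * k_km2_d), n) / kmx
            lat = lat + rng.normal(0, np.sqrt(2 * k_km2_d), n) / 111.195
        ens = lg.ParticleEnsemble(times=[float(days)], lon=lon[None], lat=lat[None])
        field = lg.particle_density(ens, small_spec, float(days))
        counts = field.data["density"][0] * field.cell_areas_km2()
        X = field.lon[None, :] * kmx
        Y = field.lat[:, None] * 111.195
        m = counts.sum()
        mx = (counts * X).sum() / m
        my = (counts * Y).sum() / m
        second = ((counts * ((X - mx) ** 2 + (Y - my) ** 2)).sum() / m)
        assert second == pytest.approx(4 * k_km2_d * days, rel=0.1)
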