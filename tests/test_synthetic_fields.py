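"""Generators: known-truth checks against closed forms and counting."""

import numpy as np
import pytest

from oceanpatch import dispersion as dp
from oceanpatch import synthetic_fields as sf
from oceanpatch.constants import SECONDS_PER_DAY


class TestVelocityFields:
    def test_uniform_flow_is_constant(self, small_spec):
        vel = sf.make_uniform_flow(small_spec, 0.1, 0.0)
        assert np.all(vel.data["u"] == 0.1)
        assert np.all(vel.data["v"] == 0.0)

    def test_solid_body_speed_grows_linearly_with_radius(self, small_spec):
        omega = 2 * np.pi / 20.0  # rad per day
        vel = sf.make_solid_body_rotation(small_spec, omega)
        x, y, _ = small_spec.meters_axes()
        X, Y = np.meshgrid(x - x.mean(), y - y.mean())
        r = np.hypot(X, Y)
        speed = np.hypot(vel.data["u"][0], vel.data["v"][0])
        expected = omega / SECONDS_PER_DAY * r
        assert np.allclose(speed, expected, rtol=1e-12)

    def test_eddy_field_is_divergence_free(self, small_spec, eddy_velocity):
        x, y, _ = small_spec.meters_axes()
        dx, dy = x[1] - x[0], y[1] - y[0]
        u, v = eddy_velocity.data["u"], eddy_velocity.data["v"]
        div = np.gradient(u, dx, axis=2) + np.gradient(v, dy, axis=1)
        tol = 1e-6 * sf.EddyFieldSpec().rms_speed / min(dx, dy)
        assert np.abs(div).max() <= tol

    def test_eddy_field_rms_speed_matches_request(self, eddy_velocity):
        u, v = eddy_velocity.data["u"], eddy_velocity.data["v"]
        rms = np.sqrt(np.mean(u**2 + v**2))
        assert rms == pytest.approx(sf.EddyFieldSpec().rms_speed, rel=0.1)

    def test_seeded_generation_is_bit_reproducible(self, small_spec):
        a = sf.make_velocity_field(small_spec, sf.EddyFieldSpec())
        b = sf.make_velocity_field(small_spec, sf.EddyFieldSpec())
        assert np.array_equal(a.data["u"], b.data["u"])
        assert np.array_equal(a.data["v"], b.data["v"])

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            sf.FieldSpec(lon_range=(200.0, 200.0))
        with pytest.raises(ValueError):
            sf.FieldSpec(grid_step=-1.0)


class TestTracerBloom:
    def test_no_velocity_no_diffusion_is_identity(self, small_spec):
        vel = sf.make_uniform_flow(small_spec, 0.0, 0.0)
        tr = sf.make_tracer_bloom(vel, (200.0, 32.0), 50.0, 0.5, k_small=0.0)
        assert np.allclose(tr.data["conc"][-1], tr.data["conc"][0], atol=1e-12)

    def test_diffusion_grows_blob_variance_at_2kt_per_axis(self):
        spec = sf.FieldSpec(
            lon_range=(195, 205), lat_range=(27, 37), grid_step=0.1,
            time_span=20, time_step=1,
        )
        vel = sf.make_uniform_flow(spec, 0.0, 0.0)
        k = 300.0
        tr = sf.make_tracer_bloom(
            vel, (200, 32), sigma_km=40, peak=1.0, k_small=k,
            background=0.0, n_substeps=4,
        )
        x, y, _ = spec.meters_axes()
        X, Y = np.meshgrid(x, y)

        def axis_var(c):
            m = c.sum()
            cx, cy = (c * X).sum() / m, (c * Y).sum() / m
            return (c * (X - cx) ** 2).sum() / m, (c * (Y - cy) ** 2).sum() / m

        v0 = axis_var(tr.data["conc"][0])
        vt = axis_var(tr.data["conc"][-1])
        growth = 2 * k * 20 * SECONDS_PER_DAY
        assert vt[0] - v0[0] == pytest.approx(growth, rel=0.05)
        assert vt[1] - v0[1] == pytest.approx(growth, rel=0.05)

    def test_diffusion_only_conserves_mass(self, small_spec):
        vel = sf.make_uniform_flow(small_spec, 0.0, 0.0)
        tr = sf.make_tracer_bloom(
            vel, (200.0, 32.0), 60.0, 0.5, k_small=100.0, background=0.0,
            n_substeps=2,
        )
        m0 = tr.data["conc"][0].sum()
        mT = tr.data["conc"][-1].sum()
        assert mT == pytest.approx(m0, rel=1e-3)

    def test_cloud_mask_covers_requested_fraction(self):
        # enough cells per slice that the binomial fraction is tight
        spec = sf.FieldSpec(lon_range=(195, 205), lat_range=(27, 37),
                            grid_step=0.05, time_span=4, time_step=1)
        vel = sf.make_uniform_flow(spec, 0.0, 0.0)
        tr = sf.make_tracer_bloom(
            vel, (200.0, 32.0), 50.0, 0.5, cloud_fraction=0.3, rng_seed=4
        )
        frac = tr.mask.mean(axis=(1, 2))
        assert np.all(np.abs(frac - 0.3) < 0.02)

    def test_cfl_violation_names_max_stable_step(self, small_spec):
        vel = sf.make_uniform_flow(small_spec, 0.0, 0.0)
        with pytest.raises(ValueError, match="maximum stable step"):
            sf.make_tracer_bloom(vel, (200.0, 32.0), 50.0, 0.5, k_small=1.0e6)


class TestPatchSeries:
    def test_zero_diffusivity_zero_noise_is_constant(self):
        s = sf.make_diffusing_patch_series(1.0e4, 0.0, 30.0)
        assert np.allclose(s.area_km2, 1.0e4)

    def test_slope_is_8pi_ke_in_km2_per_day(self):
        s = sf.make_diffusing_patch_series(1.0e4, 1100.0, 60.0)
        slope = np.polyfit(s.times, s.area_km2, 1)[0]
        expected = 8 * np.pi * 1100.0 * SECONDS_PER_DAY / 1.0e6  # ~2.39e3
        assert slope == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(2.39e3, rel=0.005)

    def test_seeded_noise_is_reproducible(self):
        a = sf.make_diffusing_patch_series(1e4, 1100.0, 30, noise_sd_km2=500, rng_seed=9)
        b = sf.make_diffusing_patch_series(1e4, 1100.0, 30, noise_sd_km2=500, rng_seed=9)
        assert np.array_equal(a.area_km2, b.area_km2)

    def test_areas_stay_positive_under_large_noise(self):
        s = sf.make_diffusing_patch_series(2e3, 0.0, 60, noise_sd_km2=1.5e3, rng_seed=3)
        assert np.all(s.area_km2 > 0)


class TestExpandingPatchTracer:
    def test_contour_area_follows_prescription(self, expanding_tracer):
        from oceanpatch import patch_tracking as pt

        spec, tracer, k_true = expanding_tracer
        series = pt.lagrangian_series(tracer, 0.13, 40.0)
        slope = np.polyfit(series.times, series.area_km2, 1)[0]
        expected = dp.m2s_to_km2d(8 * np.pi * k_true)
        assert slope == pytest.approx(expected, rel=0.02)

    def test_mean_concentration_stays_nearly_constant(self, expanding_tracer):
        from oceanpatch import patch_tracking as pt

        spec, tracer, _ = expanding_tracer
        series = pt.lagrangian_series(tracer, 0.13, 40.0)
        rel_change = np.abs(series.mean_conc - series.mean_conc[0]) / series.mean_conc[0]
        assert rel_change.max() < 0.15


class TestProfiles:
    def test_noiseless_mixed_layer_is_isothermal(self):
        spec = sf.ProfileSpec(noise_sd=0.0)
        (p,) = sf.make_profiles(spec, 1)
        inside = p.depth < spec.mld_true
        assert np.all(p.temperature[inside] == spec.surface_temp)

    def test_threshold_crossing_sits_two_metres_below_mld(self):
        from oceanpatch.mld import compute_mld

        spec = sf.ProfileSpec(noise_sd=0.0, thermocline_gradient=-0.1, depth_step=1.0)
        (p,) = sf.make_profiles(spec, 1)
        assert compute_mld(p, 0.2) == pytest.approx(42.0, abs=1e-9)

    def test_noisy_ensemble_mld_mean_matches_closed_form(self):
        from oceanpatch.mld import compute_mld

        spec = sf.ProfileSpec(noise_sd=0.05)
        profiles = sf.make_profiles(spec, 50, rng_seed=21)
        ests = [compute_mld(p) for p in profiles]
        assert np.mean(ests) == pytest.approx(42.0, abs=1.0)

    def test_unresolved_mixed_layer_rejected(self):
        with pytest.raises(ValueError):
            sf.ProfileSpec(depth_step=50.0, mld_true=40.0)
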