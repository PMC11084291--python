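"""Haemodynamic field metrics against closed-form fixtures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import graftflow as gf
from graftflow.constants import PhysicalConstants
from graftflow.field_metrics import VectorFieldSeries
from graftflow.synthetic_fields import (
    make_oscillating_wss,
    make_poiseuille,
    make_solid_rotation,
    make_uniform_flow,
)

CONSTANTS = PhysicalConstants()


def _wss_series(times, vectors, n_points=4):
    points = np.zeros((n_points, 3))
    vecs = np.broadcast_to(vectors[:, None, :], (times.size, n_points, 3)).copy()
    return VectorFieldSeries(
        times=times, points=points, vectors=vecs,
        measure=np.ones(n_points), kind="wall_shear",
    )


class TestTAWSS:
    def test_steady_field(self):
        times = np.linspace(0, 1, 11)
        vecs = np.tile([0.0, 3.0, 0.0], (11, 1))
        assert gf.tawss(_wss_series(times, vecs)).values[0] == pytest.approx(3.0)

    @pytest.mark.parametrize("n_t", [501, 1001])
    def test_rectified_sine_mean(self, n_t):
        """|A sin wt| averages to 2A/pi over a full cycle."""
        amp = 3.0
        times = np.linspace(0, 1, n_t)
        vecs = np.zeros((n_t, 3))
        vecs[:, 0] = amp * np.sin(2 * np.pi * times)
        val = gf.tawss(_wss_series(times, vecs)).values[0]
        assert val == pytest.approx(2 * amp / np.pi, rel=1e-4)

    def test_quadrature_converges_with_dt(self):
        vals = []
        for n_t in (251, 501):
            times = np.linspace(0, 1, n_t)
            vecs = np.zeros((n_t, 3))
            vecs[:, 1] = 2.0 + np.cos(2 * np.pi * times)
            vals.append(gf.tawss(_wss_series(times, vecs)).values[0])
        assert vals[1] == pytest.approx(vals[0], rel=1e-3)

    def test_wrong_kind_errors(self):
        field, _ = make_uniform_flow()
        with pytest.raises(ValueError, match="wall_shear"):
            gf.tawss(field)


class TestOSI:
    def test_unidirectional_is_zero(self):
        times = np.linspace(0, 1, 65)
        vecs = np.zeros((65, 3))
        vecs[:, 0] = 1.0 + 0.5 * np.sin(2 * np.pi * times)  # varying magnitude
        assert gf.osi(_wss_series(times, vecs)).values[0] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_reversal_is_half(self):
        field, analytic = make_oscillating_wss(reversal_fraction=0.5)
        np.testing.assert_allclose(gf.osi(field).values, 0.5, atol=1e-12)
        assert analytic["osi"] == 0.5

    def test_uniform_rotation_is_half(self):
        """A WSS vector sweeping a full turn at constant magnitude."""
        times = np.linspace(0, 1, 257)
        vecs = np.column_stack(
            [np.cos(2 * np.pi * times), np.sin(2 * np.pi * times), np.zeros(257)]
        )
        assert gf.osi(_wss_series(times, vecs)).values[0] == pytest.approx(0.5, abs=1e-3)

    def test_partial_reversal_closed_form(self):
        field, analytic = make_oscillating_wss(reversal_fraction=0.25, n_times=128)
        assert gf.osi(field).values[0] == pytest.approx(analytic["osi"], abs=5e-3)

    def test_degenerate_points_reported_zero(self):
        times = np.linspace(0, 1, 9)
        vecs = np.zeros((9, 3))
        np.testing.assert_array_equal(gf.osi(_wss_series(times, vecs)).values, 0.0)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_bounds_for_arbitrary_fields(self, seed):
        r = np.random.default_rng(seed)
        times = np.linspace(0, 1, 33)
        vecs = r.normal(size=(33, 5, 3))
        field = VectorFieldSeries(
            times=times, points=np.zeros((5, 3)), vectors=vecs,
            measure=np.ones(5), kind="wall_shear",
        )
        vals = gf.osi(field).values
        assert np.all(vals >= 0.0) and np.all(vals <= 0.5)

    def test_tawss_bounds_mean_vector(self, rng):
        """TAWSS >= |time-mean WSS vector| with equality iff fixed direction."""
        times = np.linspace(0, 1, 65)
        vecs = rng.normal(size=(65, 3, 3))
        field = VectorFieldSeries(
            times=times, points=np.zeros((3, 3)), vectors=vecs,
            measure=np.ones(3), kind="wall_shear",
        )
        ta = gf.tawss(field).values
        mean_vec = np.linalg.norm(
            np.trapezoid(field.vectors, times, axis=0), axis=1
        )
        assert np.all(ta >= mean_vec - 1e-12)


class TestVorticity:
    def test_uniform_flow_is_irrotational(self):
        field, _ = make_uniform_flow(velocity=(1.0, -0.5, 2.0))
        np.testing.assert_allclose(gf.vorticity(field).values, 0.0, atol=1e-10)

    def test_solid_rotation_curl(self):
        field, analytic = make_solid_rotation(omega=(0.0, 0.0, 5.0))
        vals = gf.vorticity(field).values
        assert np.all(np.abs(vals - analytic["curl_magnitude"]) <= 0.01 * 10.0)

    def test_rotation_about_tilted_axis(self):
        field, analytic = make_solid_rotation(omega=(3.0, -4.0, 12.0))
        np.testing.assert_allclose(
            gf.vorticity(field).values, analytic["curl_magnitude"], rtol=1e-6
        )

    def test_superposed_uniform_flow_leaves_curl(self):
        base, analytic = make_solid_rotation(omega=(0.0, 0.0, 5.0))
        shifted, _ = make_solid_rotation(omega=(0.0, 0.0, 5.0),
                                         uniform_velocity=(2.0, 1.0, -3.0))
        np.testing.assert_allclose(
            gf.vorticity(shifted).values, gf.vorticity(base).values, atol=1e-10
        )

    def test_poiseuille_shear_vorticity(self):
        """|curl u| = |du/dr| for the parabolic profile, interior points."""
        field, analytic = make_poiseuille(n=48)
        vals = gf.vorticity(field).values.reshape(field.grid_shape)
        r = np.linalg.norm(field.points[:, :2], axis=1).reshape(field.grid_shape)
        dp, mu, L, R = analytic["dp"], analytic["mu"], analytic["length"], analytic["radius"]
        expected = dp * r / (2 * mu * L)  # |du/dr|
        interior = r < 0.8 * R
        np.testing.assert_allclose(vals[interior], expected[interior], rtol=1e-9)

    def test_unstructured_input_errors(self):
        field, _ = make_oscillating_wss()
        field.kind = "velocity"
        with pytest.raises(ValueError, match="structured grid"):
            gf.vorticity(field)


class TestTKE:
    def test_identical_realizations_are_laminar(self):
        mean, _ = make_uniform_flow()
        vals = gf.tke(mean, [mean, mean]).values
        np.testing.assert_allclose(vals, 0.0, atol=1e-15)

    def test_isotropic_fluctuation_level(self, rng):
        """k -> (3/2) sigma^2 for iid per-component fluctuations."""
        mean, _ = make_uniform_flow(n=8, n_times=4)
        sigma = 0.3
        reals = []
        for _ in range(400):
            pert = VectorFieldSeries(
                times=mean.times, points=mean.points,
                vectors=mean.vectors + rng.normal(0, sigma, mean.vectors.shape),
                measure=mean.measure, kind="velocity",
                grid_shape=mean.grid_shape, spacing=mean.spacing,
            )
            reals.append(pert)
        k = gf.tke(mean, reals).values.mean()
        assert k == pytest.approx(1.5 * sigma**2, rel=0.05)

    def test_quadratic_scaling(self, rng):
        mean, _ = make_uniform_flow(n=8, n_times=2)
        fluct = rng.normal(size=mean.vectors.shape)

        def real(scale):
            return VectorFieldSeries(
                times=mean.times, points=mean.points,
                vectors=mean.vectors + scale * fluct,
                measure=mean.measure, kind="velocity",
                grid_shape=mean.grid_shape, spacing=mean.spacing,
            )

        k1 = gf.tke(mean, [real(1.0)]).values
        k2 = gf.tke(mean, [real(2.0)]).values
        np.testing.assert_allclose(k2, 4.0 * k1, rtol=1e-12)

    def test_mismatched_grid_errors(self):
        mean, _ = make_uniform_flow(n=8)
        other, _ = make_uniform_flow(n=16)
        with pytest.raises(ValueError, match="grid"):
            gf.tke(mean, [other])


class TestEnergyLoss:
    def test_rigid_rotation_dissipates_nothing(self):
        field, _ = make_solid_rotation(omega=(0.0, 0.0, 5.0))
        assert gf.viscous_energy_loss(field, CONSTANTS, 0.0, 1.0) == pytest.approx(
            0.0, abs=1e-20
        )

    def test_zero_velocity(self):
        field, _ = make_uniform_flow(velocity=(0.0, 0.0, 0.0))
        assert gf.viscous_energy_loss(field, CONSTANTS, 0.0, 1.0) == 0.0

    def test_poiseuille_dissipation_rate(self):
        """Volume-integrated dissipation equals dP*Q within 2% at 64^3."""
        field, analytic = make_poiseuille(n=64, nz=8)
        loss = gf.viscous_energy_loss(field, CONSTANTS, 0.0, 1.0)
        assert loss == pytest.approx(analytic["dissipation_rate"] * 1.0, rel=0.02)

    def test_window_errors(self):
        field, _ = make_uniform_flow()
        with pytest.raises(ValueError, match="window"):
            gf.viscous_energy_loss(field, CONSTANTS, 0.0, 2.0)

    def test_nonnegative_for_random_smooth_fields(self, rng):
        field, _ = make_uniform_flow(n=12)
        field.vectors = field.vectors + rng.normal(size=field.vectors.shape)
        assert gf.viscous_energy_loss(field, CONSTANTS, 0.0, 1.0) >= 0.0


class TestSectionFlow:
    def test_poiseuille_hagen_flow_rate(self):
        field, analytic = make_poiseuille(n=64, nz=8)
        q = gf.section_flow_rate(field, (0.0, 0.0, 0.05), (0.0, 0.0, 1.0))
        np.testing.assert_allclose(q, analytic["flow_rate"], rtol=0.01)

    def test_uniform_axial_flow(self):
        field, analytic = make_poiseuille(n=48)
        u = 1.3
        field.vectors[..., 2] = u
        q = gf.section_flow_rate(field, (0.0, 0.0, 0.05), (0.0, 0.0, 1.0))
        expected = np.pi * analytic["radius"] ** 2 * u
        np.testing.assert_allclose(q, expected, rtol=0.005)

    def test_parallel_sections_conserve_flow(self):
        field, _ = make_poiseuille(n=48)
        q1 = gf.section_flow_rate(field, (0.0, 0.0, 0.02), (0.0, 0.0, 1.0))
        q2 = gf.section_flow_rate(field, (0.0, 0.0, 0.08), (0.0, 0.0, 1.0))
        np.testing.assert_allclose(q1, q2, rtol=1e-9)

    def test_plane_outside_domain_errors(self):
        field, _ = make_poiseuille(n=16, nz=4)
        with pytest.raises(ValueError, match="intersect"):
            gf.section_flow_rate(field, (0.0, 0.0, 5.0), (0.0, 0.0, 1.0))


class TestReverseFlow:
    def test_all_forward(self):
        field, analytic = make_poiseuille(n=32, nz=4)
        rec = gf.reverse_flow(field, (0.0, 0.0, 0.05), (0.0, 0.0, 1.0))
        # residual reversal comes only from partially-covered wall cells
        assert rec["cycle_mean_fraction"] < 0.02
        assert rec["cycle_mean_reverse_velocity"] < 0.05 * analytic["max_velocity"]

    def test_uniform_reversal(self):
        field, _ = make_poiseuille(n=32, nz=4)
        u = 0.8
        field.vectors[...] = 0.0
        field.vectors[..., 2] = -u
        rec = gf.reverse_flow(field, (0.0, 0.0, 0.05), (0.0, 0.0, 1.0))
        assert rec["cycle_mean_fraction"] == pytest.approx(1.0)
        assert rec["cycle_mean_reverse_velocity"] == pytest.approx(u)
        assert rec["cycle_peak_reverse_velocity"] == pytest.approx(u)

    def test_half_and_half_section(self):
        field, _ = make_poiseuille(n=64, nz=4)
        x = field.points[:, 0].reshape(field.grid_shape)
        field.vectors[...] = 0.0
        field.vectors[..., 2] = np.where(x > 0, 1.0, -1.0).reshape(1, -1)
        rec = gf.reverse_flow(field, (0.0, 0.0, 0.05), (0.0, 0.0, 1.0))
        assert rec["cycle_mean_fraction"] == pytest.approx(0.5, abs=0.02)


class TestReynolds:
    def test_peak_systolic_magnitude(self):
        """rho U D / mu with U=1.35 m/s, D=14 mm exceeds 5000."""
        re = gf.reynolds_number(CONSTANTS, 1.35, 0.014)
        assert re == pytest.approx(5009, abs=1)
        assert re > 5000

    def test_zero_speed(self):
        assert gf.reynolds_number(CONSTANTS, 0.0, 0.014) == 0.0

    def test_linear_in_diameter(self):
        re1 = gf.reynolds_number(CONSTANTS, 1.0, 0.01)
        re2 = gf.reynolds_number(CONSTANTS, 1.0, 0.02)
        assert re2 == pytest.approx(2 * re1)


class TestRigidFrameInvariance:
    def test_metrics_under_corotation(self, rng):
        """Rotating points and vectors together leaves scalar metrics."""
        times = np.linspace(0, 1, 33)
        vecs = rng.normal(size=(33, 6, 3))
        field = VectorFieldSeries(
            times=times, points=rng.normal(size=(6, 3)), vectors=vecs,
            measure=np.ones(6), kind="wall_shear",
        )
        theta = 1.1
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ])
        rotated = VectorFieldSeries(
            times=times, points=field.points @ rot.T, vectors=vecs @ rot.T,
            measure=field.measure, kind="wall_shear",
        )
        np.testing.assert_allclose(
            gf.tawss(rotated).values, gf.tawss(field).values, rtol=1e-12
        )
        np.testing.assert_allclose(
            gf.osi(rotated).values, gf.osi(field).values, rtol=1e-12
        )
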