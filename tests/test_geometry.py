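"""Helix fitting, apertures, tilt, grip extent and layer lines."""

import numpy as np
import pytest

from ringmotor import (
    aperture,
    fit_helix,
    gen_pore_loop_helix,
    grip_extent,
    layer_line,
    measure_layer_line,
    pore_tilt,
)


def _rigid_transform(points, seed=0):
    rng = np.random.default_rng(seed)
    # random rotation via QR of a Gaussian matrix
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    shift = rng.normal(scale=50.0, size=3)
    return points @ q.T + shift


class TestFitHelix:
    def test_exact_round_trip_recovers_rise_twist_and_seam(self):
        loops = gen_pore_loop_helix(rise=13.0, twist=60.0, jitter_sd=0.0)
        h = fit_helix(loops)
        assert h.rise == pytest.approx(13.0, abs=1e-9)
        assert h.twist == pytest.approx(60.0, abs=1e-9)
        assert h.seam_index == 5
        assert h.rms_residual < 1e-9
        assert h.pitch == pytest.approx(13.0 * 360.0 / 60.0, abs=1e-6)

    def test_frame_invariance_of_rise_twist_pitch(self):
        loops = gen_pore_loop_helix(rise=10.0, twist=55.0, jitter_sd=0.0)
        pts = loops.coords("NBD1-PL1")
        h0 = fit_helix(pts)
        h1 = fit_helix(_rigid_transform(pts, seed=3))
        assert h1.rise == pytest.approx(h0.rise, abs=1e-9)
        assert h1.twist == pytest.approx(h0.twist, abs=1e-9)
        assert h1.pitch == pytest.approx(h0.pitch, abs=1e-6)

    def test_jittered_recovery_within_five_percent(self):
        rises, twists, seams = [], [], []
        for s in range(100):
            loops = gen_pore_loop_helix(rise=13.0, twist=60.0, jitter_sd=0.5,
                                        seed=s)
            h = fit_helix(loops)
            rises.append(h.rise)
            twists.append(h.twist)
            seams.append(h.seam_index)
        assert abs(np.mean(rises) - 13.0) < 0.05 * 13.0
        assert abs(np.mean(twists) - 60.0) < 0.05 * 60.0
        assert np.mean(np.array(seams) == 5) > 0.9

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.zeros(6), np.zeros(6), np.arange(6.0)])
        with pytest.raises(ValueError, match="collinear"):
            fit_helix(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_helix(np.zeros((3, 3)))


class TestAperture:
    def test_regular_hexagon_diameter(self):
        ang = np.deg2rad(np.arange(6) * 60.0)
        pts = np.column_stack([14 * np.cos(ang), 14 * np.sin(ang), np.zeros(6)])
        assert aperture(pts, [0, 0, 0], [0, 0, 1]) == pytest.approx(28.0)

    def test_minimum_rule_with_one_tighter_loop(self):
        ang = np.deg2rad(np.arange(6) * 60.0)
        radii = np.array([14.0, 14, 14, 14, 14, 9])
        pts = np.column_stack(
            [radii * np.cos(ang), radii * np.sin(ang), np.zeros(6)]
        )
        assert aperture(pts, [0, 0, 0], [0, 0, 1]) == pytest.approx(18.0)

    def test_agrees_with_inscribed_circle_grid_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            radii = rng.uniform(8.0, 20.0, size=6)
            ang = np.sort(rng.uniform(0, 2 * np.pi, size=6))
            pts = np.column_stack(
                [radii * np.cos(ang), radii * np.sin(ang),
                 rng.normal(size=6)]
            )
            measured = aperture(pts, [0, 0, 0], [0, 0, 1])
            # brute force: largest axis-centered circle not containing a point
            grid = np.linspace(0, 25.0, 2501)
            dists = np.linalg.norm(pts[:, :2], axis=1)
            ok = grid[grid <= dists.min()]
            assert measured == pytest.approx(2 * ok.max(), abs=2 * 0.01)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            aperture(np.zeros((2, 3)), [0, 0, 0], [0, 0, 1])


class TestPoreTilt:
    def _hexagon(self, radius=14.0, z=0.0):
        ang = np.deg2rad(np.arange(6) * 60.0)
        return np.column_stack(
            [radius * np.cos(ang), radius * np.sin(ang), np.full(6, z)]
        )

    def test_coaxial_rings_have_zero_tilt(self):
        assert pore_tilt(self._hexagon(z=0), self._hexagon(z=20)) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_lateral_displacement_gives_arctangent(self):
        ring2 = self._hexagon(z=20.0) + np.array([20.0, 0.0, 0.0])
        assert pore_tilt(self._hexagon(), ring2) == pytest.approx(45.0, abs=1e-9)
        ring3 = self._hexagon(z=30.0) + np.array([10.0, 0.0, 0.0])
        expected = np.degrees(np.arctan(10.0 / 30.0))
        assert pore_tilt(self._hexagon(), ring3) == pytest.approx(expected,
                                                                 abs=1e-9)

    def test_programmed_fifteen_degree_offset_recovered_under_jitter(self):
        rng = np.random.default_rng(23)
        h = 25.0
        d = h * np.tan(np.deg2rad(15.0))
        tilts = []
        for _ in range(50):
            r1 = self._hexagon() + rng.normal(0, 0.3, size=(6, 3))
            r2 = (self._hexagon(z=h) + np.array([d, 0, 0])
                  + rng.normal(0, 0.3, size=(6, 3)))
            tilts.append(pore_tilt(r1, r2))
        assert abs(np.mean(tilts) - 15.0) < 0.5

    def test_coincident_centroids_rejected(self):
        with pytest.raises(ValueError):
            pore_tilt(self._hexagon(), self._hexagon())


class TestGripExtent:
    def test_two_axial_points(self):
        pts = np.array([[0.0, 0, 0], [0, 0, 80.0]])
        assert grip_extent(pts) == pytest.approx(80.0)

    def test_staircase_projection_matches_axial_span(self):
        # 5+5 staircase points with 13 A rise and an inter-ring gap
        ang = np.deg2rad(np.arange(5) * 60.0)
        ring1_z = np.arange(5) * 13.0
        ring2_z = ring1_z + 5 * 13.0 + 7.0
        pts = np.vstack(
            [
                np.column_stack([14 * np.cos(ang), 14 * np.sin(ang), ring1_z]),
                np.column_stack([14 * np.cos(ang), 14 * np.sin(ang), ring2_z]),
            ]
        )
        span = grip_extent(pts, axis_direction=[0, 0, 1])
        assert span == pytest.approx(ring2_z.max() - ring1_z.min(), abs=1e-9)

    def test_rigid_rotation_invariance(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(scale=20.0, size=(10, 3))
        a = grip_extent(pts)
        b = grip_extent(_rigid_transform(pts, seed=6))
        assert a == pytest.approx(b, abs=1e-9)


class TestLayerLine:
    def test_predicted_frequency_is_reciprocal_pitch(self):
        assert layer_line(55.0) == pytest.approx(1 / 55.0)
        assert layer_line(110.0) == pytest.approx(layer_line(55.0) / 2)

    def test_measured_peak_matches_programmed_period(self):
        spacing, period, n = 1.0, 55.0, 1024
        z = np.arange(n) * spacing
        profile = 1.0 + 0.5 * np.cos(2 * np.pi * z / period)
        measured = measure_layer_line(profile, spacing)
        bin_width = 1.0 / (n * spacing)
        assert abs(measured - 1 / period) <= bin_width

    def test_noisy_profile_still_resolves_peak(self):
        rng = np.random.default_rng(31)
        spacing, period, n = 1.0, 40.0, 2048
        z = np.arange(n) * spacing
        profile = np.cos(2 * np.pi * z / period) + rng.normal(0, 0.2, n)
        measured = measure_layer_line(profile, spacing)
        assert abs(measured - 1 / period) <= 1.0 / (n * spacing)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            layer_line(0.0)
        with pytest.raises(ValueError):
            measure_layer_line(np.ones(100), 1.0)
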