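import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from dibkit import droplet_geometry as dg, synthetic_data as sd
from dibkit.errors import DetectionError, GeometryError


def slice_volume_oracle(R, rc):
    """Independent oracle: integrate circular slices π(R²-z²) from -R up to
    the bilayer plane at z = sqrt(R²-rc²)."""
    x = np.sqrt(R * R - rc * rc)
    val, _ = integrate.quad(lambda z: np.pi * (R * R - z * z), -R, x)
    return val


class TestTruncatedSphereVolume:
    def test_full_sphere(self):
        assert dg.truncated_sphere_volume(50, 0) == pytest.approx(523598.78, abs=0.01)

    def test_hemisphere(self):
        assert dg.truncated_sphere_volume(50, 50) == pytest.approx(261799.39, abs=0.01)

    def test_cap_cut(self):
        # closed form minus cap pi*h^2*(3R-h)/3 with h=10
        expected = 4 / 3 * np.pi * 50**3 - np.pi * 100 * 140 / 3
        assert expected == pytest.approx(508938.01, abs=0.01)
        assert dg.truncated_sphere_volume(50, 30) == pytest.approx(expected, rel=1e-12)
        assert dg.truncated_sphere_volume(50, 30) == pytest.approx(
            slice_volume_oracle(50, 30), rel=1e-9
        )

    def test_rc_above_R_rejected(self):
        with pytest.raises(GeometryError):
            dg.truncated_sphere_volume(50, 51)

    def test_slice_oracle_100_random_pairs(self, rng):
        for _ in range(100):
            R = rng.uniform(1.0, 200.0)
            rc = rng.uniform(0.0, 0.999) * R
            assert dg.truncated_sphere_volume(R, rc) == pytest.approx(
                slice_volume_oracle(R, rc), rel=1e-6
            )

    @given(
        R=st.floats(1.0, 500.0),
        rc_frac=st.floats(0.0, 0.99),
        dR=st.floats(0.01, 10.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_R(self, R, rc_frac, dR):
        rc = rc_frac * R
        assert dg.truncated_sphere_volume(R + dR, rc) > dg.truncated_sphere_volume(
            R, rc
        )

    @given(R=st.floats(1.0, 500.0), f1=st.floats(0.0, 0.99), f2=st.floats(0.0, 0.99))
    @settings(max_examples=100, deadline=None)
    def test_monotone_decreasing_in_rc(self, R, f1, f2):
        lo, hi = sorted((f1 * R, f2 * R))
        assert dg.truncated_sphere_volume(R, hi) <= dg.truncated_sphere_volume(R, lo)

    def test_continuity_at_rc_zero(self):
        full = 4 / 3 * np.pi * 37.0**3
        assert dg.truncated_sphere_volume(37.0, 1e-7) == pytest.approx(
            full, rel=1e-9
        )


class TestContactArea:
    def test_zero(self):
        assert dg.contact_area(0) == 0

    def test_circle(self):
        assert dg.contact_area(30) == pytest.approx(2827.433, abs=1e-3)

    def test_scaling(self):
        assert dg.contact_area(60) == pytest.approx(4 * dg.contact_area(30), rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(GeometryError):
            dg.contact_area(-1)


class TestContactRadiusFromCenters:
    def test_pythagorean_triple(self):
        # 30-40-50 triangle: equal spheres R=50 at d=80 meet at rc=30
        assert dg.contact_radius_from_centers(50, 50, 80) == pytest.approx(30.0)

    def test_tangent(self):
        assert dg.contact_radius_from_centers(50, 30, 80) == 0.0

    def test_disjoint_rejected(self):
        with pytest.raises(GeometryError):
            dg.contact_radius_from_centers(50, 30, 81.0)

    def test_contained_rejected(self):
        with pytest.raises(GeometryError):
            dg.contact_radius_from_centers(50, 10, 20)

    def test_roundtrip_with_center_distance(self, rng):
        for _ in range(50):
            R1 = rng.uniform(20, 80)
            R2 = rng.uniform(20, 80)
            rc = rng.uniform(0.05, 0.95) * min(R1, R2)
            d = dg.center_distance_from_contact(R1, R2, rc)
            assert dg.contact_radius_from_centers(R1, R2, d) == pytest.approx(
                rc, rel=1e-9
            )


class TestRadiusFromVolume:
    def test_inverts_forward(self, rng):
        for _ in range(100):
            R = rng.uniform(1, 150)
            rc = rng.uniform(0, 0.99) * R
            V = dg.truncated_sphere_volume(R, rc)
            assert dg.radius_from_volume(V, rc) == pytest.approx(R, rel=1e-10)

    def test_below_hemisphere_limit_rejected(self):
        with pytest.raises(GeometryError):
            dg.radius_from_volume(1.0, 30.0)


class TestDropletPairState:
    def test_invariants(self):
        with pytest.raises(GeometryError):
            dg.DropletPairState(0.0, 50, 10)
        with pytest.raises(GeometryError):
            dg.DropletPairState(50, 50, 50)  # rc must be < min radius
        with pytest.raises(GeometryError):
            dg.DropletPairState(50, 50, 30, d=120)  # inconsistent distance

    def test_volumes(self):
        v1, v2 = dg.DropletPairState(50, 40, 20).volumes()
        assert v1 == pytest.approx(dg.truncated_sphere_volume(50, 20))
        assert v2 == pytest.approx(dg.truncated_sphere_volume(40, 20))


class TestFitDropletPair:
    def test_roundtrip_equal_pair(self):
        state = dg.DropletPairState(50, 50, 30)
        frame = sd.render_droplet_image(state, 1.0, (256, 256))
        fit = dg.fit_droplet_pair(frame)
        assert fit.R1 == pytest.approx(50, abs=0.5)
        assert fit.R2 == pytest.approx(50, abs=0.5)
        assert fit.rc == pytest.approx(30, abs=1.0)

    def test_roundtrip_asymmetric_pair(self):
        state = dg.DropletPairState(52, 44, 28)
        fit = dg.fit_droplet_pair(sd.render_droplet_image(state, 1.0, (256, 256)))
        radii = sorted([fit.R1, fit.R2])
        assert radii[1] == pytest.approx(52, abs=0.5)
        assert radii[0] == pytest.approx(44, abs=0.5)
        assert fit.rc == pytest.approx(28, abs=1.0)

    def test_rotation_invariance(self):
        frame = sd.render_droplet_image(dg.DropletPairState(50, 50, 30), 1.0, (256, 256))
        fit = dg.fit_droplet_pair(frame)
        rot = dg.ImageFrame(np.rot90(frame.intensity).copy(), 1.0)
        fit_rot = dg.fit_droplet_pair(rot)
        assert fit_rot.R1 == pytest.approx(fit.R1, abs=0.05)
        assert fit_rot.R2 == pytest.approx(fit.R2, abs=0.05)
        assert fit_rot.rc == pytest.approx(fit.rc, abs=0.05)

    def test_translation_equivariance_and_intensity_scaling(self):
        state = dg.DropletPairState(40, 40, 22)
        frame = sd.render_droplet_image(state, 1.0, (256, 256))
        fit = dg.fit_droplet_pair(frame)
        shifted = np.roll(frame.intensity, (7, -11), axis=(0, 1))
        fit_shift = dg.fit_droplet_pair(dg.ImageFrame(shifted, 1.0))
        assert fit_shift.R1 == pytest.approx(fit.R1, abs=0.05)
        assert fit_shift.rc == pytest.approx(fit.rc, abs=0.05)
        scaled = dg.ImageFrame(frame.intensity * 37.5, 1.0)
        fit_scaled = dg.fit_droplet_pair(scaled)
        assert fit_scaled.R1 == pytest.approx(fit.R1, abs=1e-9)
        assert fit_scaled.rc == pytest.approx(fit.rc, abs=1e-9)

    def test_pixel_size_scale_invariance_in_um(self):
        state = dg.DropletPairState(50, 50, 30)
        fit_1 = dg.fit_droplet_pair(sd.render_droplet_image(state, 1.0, (256, 256)))
        fit_h = dg.fit_droplet_pair(sd.render_droplet_image(state, 0.5, (512, 512)))
        # fitted radii in px double, in μm unchanged
        assert fit_h.R1 / 0.5 == pytest.approx(2 * fit_1.R1 / 1.0, rel=0.01)
        assert fit_h.R1 == pytest.approx(fit_1.R1, abs=0.5)

    def test_blank_frame_rejected(self):
        with pytest.raises(DetectionError):
            dg.fit_droplet_pair(dg.ImageFrame(np.zeros((64, 64)), 1.0))

    def test_single_disk_rejected(self):
        yy, xx = np.mgrid[0:128, 0:128].astype(float)
        img = np.clip(30.5 - np.hypot(xx - 64, yy - 64), 0, 1)
        with pytest.raises(DetectionError) as exc:
            dg.fit_droplet_pair(dg.ImageFrame(img, 1.0))
        assert exc.value.n_found == 1


class TestTrackTrajectory:
    def test_roundtrip_from_simulation(self):
        cfg = sd.DIBSimConfig(true_Pf=74.0, duration=30.0, sample_interval=10.0)
        traj = sd.simulate_dib_trajectory(cfg)
        frames = sd.render_trajectory_frames(traj, 1.0, (256, 256))
        rec = dg.track_trajectory(frames)
        np.testing.assert_allclose(rec.time_s, traj.time_s)
        np.testing.assert_allclose(rec.R1_um, traj.R1_um, atol=0.5)
        np.testing.assert_allclose(rec.R2_um, traj.R2_um, atol=0.5)

    def test_repeated_frame_constant(self):
        frame = sd.render_droplet_image(dg.DropletPairState(50, 50, 30), 1.0, (256, 256))
        frames = [
            dg.ImageFrame(frame.intensity, 1.0, timestamp=t) for t in (0.0, 1.0, 2.0)
        ]
        rec = dg.track_trajectory(frames)
        assert len(rec) == 3
        assert np.ptp(rec.R1_um) == 0
        assert np.ptp(rec.rc_um) == 0

    def test_out_of_order_timestamps_rejected(self):
        frame = sd.render_droplet_image(dg.DropletPairState(50, 50, 30), 1.0, (256, 256))
        frames = [
            dg.ImageFrame(frame.intensity, 1.0, timestamp=t) for t in (0.0, 2.0, 1.0)
        ]
        with pytest.raises(ValueError):
            dg.track_trajectory(frames)

    def test_too_few_frames_rejected(self):
        frame = sd.render_droplet_image(dg.DropletPairState(50, 50, 30), 1.0, (256, 256))
        with pytest.raises(ValueError):
            dg.track_trajectory([frame])
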