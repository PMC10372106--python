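import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lvpet import phantom as ph
from lvpet.imaging import VoxelGrid3D
from lvpet.valve import (
    DegenerateMaskError,
    IndentationCandidate,
    LongAxis,
    Plane3D,
    adjust_plane,
    estimate_long_axis,
    find_indentations,
    select_and_fit_plane,
)


def ellipsoid_grid(semiaxes, rotation=None, shape=(60, 60, 60), spacing=2.0):
    sp = (spacing,) * 3
    origin = tuple(-(n - 1) / 2.0 * spacing for n in shape)
    grid = VoxelGrid3D(np.zeros(shape), sp, origin)
    idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
    world = grid.index_to_world(idx.reshape(-1, 3))
    if rotation is not None:
        world = world @ rotation  # rotate sampling frame = rotate ellipsoid
    q = world / np.asarray(semiaxes)
    inside = (q**2).sum(axis=1) <= 1.0
    return grid.with_values(inside.reshape(shape).astype(float))


class TestLongAxis:
    def test_prolate_ellipsoid_axis_recovered_within_3_degrees(self):
        img = ellipsoid_grid((40.0, 20.0, 20.0))
        axis = estimate_long_axis(img.values > 0.5, img)
        assert abs(axis.direction @ np.array([1.0, 0, 0])) >= np.cos(np.deg2rad(3))

    def test_rotated_ellipsoid_axis_co_rotates(self):
        rot = Rotation.from_euler("z", 35, degrees=True).as_matrix()
        img = ellipsoid_grid((40.0, 20.0, 20.0), rotation=rot)
        axis = estimate_long_axis(img.values > 0.5, img)
        expected = rot @ np.array([1.0, 0, 0])
        assert abs(axis.direction @ expected) >= np.cos(np.deg2rad(3))

    def test_sphere_is_degenerate(self):
        img = ellipsoid_grid((25.0, 25.0, 25.0))
        with pytest.raises(DegenerateMaskError, match="isotropic"):
            estimate_long_axis(img.values > 0.5, img)

    def test_tiny_mask_is_degenerate(self):
        img = ellipsoid_grid((40.0, 20.0, 20.0))
        mask = np.zeros(img.shape, bool)
        mask[30, 30, 30] = True
        with pytest.raises(DegenerateMaskError, match="voxels"):
            estimate_long_axis(mask, img)


class TestIndentations:
    def test_neck_phantom_candidates_cluster_at_the_waist(self, neck_phantom):
        gated, truth = neck_phantom
        avg = gated.time_average()
        left = avg.values >= 0.25 * avg.values.max()
        axis = estimate_long_axis(left, avg)
        candidates = find_indentations(avg, axis, left_mask=left)
        assert len(candidates) >= 10
        # distance of each candidate from the true valve plane
        pts = np.array([c.point for c in candidates])
        dist = np.abs(truth.plane.signed_distance(pts))
        assert np.median(dist) <= 2.0

    def test_single_convex_ellipsoid_has_no_waist(self):
        img = ellipsoid_grid((55.0, 27.0, 27.0), shape=(72, 72, 72))
        axis = estimate_long_axis(img.values > 0.5, img)
        candidates = find_indentations(img, axis, left_mask=img.values > 0.5)
        assert candidates == []

    def test_candidate_invariants(self):
        with pytest.raises(ValueError, match="prominence"):
            IndentationCandidate(0.0, np.zeros(3), width_mm=5.0, prominence_mm=0.0)
        with pytest.raises(ValueError, match="width"):
            IndentationCandidate(0.0, np.zeros(3), width_mm=-1.0, prominence_mm=1.0)


def ring_candidates(z0, radius=15.0, n=24, noise=None, rng=None):
    out = []
    for i, ang in enumerate(np.linspace(0, 180, n, endpoint=False)):
        theta = np.deg2rad(ang)
        p = np.array([radius * np.cos(theta), radius * np.sin(theta), z0])
        if noise is not None:
            p = p + noise[i]
        out.append(IndentationCandidate(float(ang), p, width_mm=10.0, prominence_mm=5.0))
    return out


class TestPlaneFit:
    AXIS = LongAxis(direction=np.array([0.0, 0.0, -1.0]), centroid=np.zeros(3))  # apex at -z

    def test_exact_planar_candidates_recovered_exactly(self):
        plane = select_and_fit_plane(ring_candidates(z0=30.0), self.AXIS)
        assert abs(plane.signed_distance(np.array([[5.0, -3.0, 30.0]]))[0]) < 1e-9
        assert abs(plane.normal @ np.array([0, 0, 1.0])) == pytest.approx(1.0, abs=1e-12)
        assert plane.normal[2] < 0  # oriented toward the apex
        assert not plane.low_confidence

    def test_outliers_rejected_within_tolerance(self):
        rng = np.random.default_rng(3)
        noise = rng.normal(0, 0.3, (24, 3))
        outliers = rng.choice(24, size=5, replace=False)
        noise[outliers, 2] += 15.0  # displace 20% of candidates off the plane
        plane = select_and_fit_plane(ring_candidates(30.0, noise=noise, rng=rng), self.AXIS)
        assert abs(plane.point[2] - 30.0) <= 2.0
        angle = np.degrees(np.arccos(abs(plane.normal @ np.array([0, 0, 1.0]))))
        assert angle <= 5.0

    def test_too_few_candidates_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            select_and_fit_plane(ring_candidates(10.0, n=24)[:2], self.AXIS)

    def test_narrow_angle_span_rejected(self):
        cands = [c for c in ring_candidates(10.0, n=24) if c.angle_deg < 60]
        with pytest.raises(ValueError, match="90 degrees"):
            select_and_fit_plane(cands, self.AXIS)


class TestAdjustPlane:
    PLANE = Plane3D(point=np.array([1.0, 2.0, 3.0]), normal=np.array([0.0, 0.0, -1.0]))

    def test_identity(self):
        out = adjust_plane(self.PLANE, 0.0, 0.0, 0.0)
        np.testing.assert_array_equal(out.point, self.PLANE.point)
        np.testing.assert_array_equal(out.normal, self.PLANE.normal)

    def test_offset_shifts_signed_distances(self):
        out = adjust_plane(self.PLANE, offset_mm=5.0)
        pts = np.array([[0.0, 0.0, 0.0], [4.0, -2.0, 7.0]])
        np.testing.assert_allclose(
            self.PLANE.signed_distance(pts) - out.signed_distance(pts), 5.0
        )

    def test_tilt_then_untilt_restores_normal(self):
        tilted = adjust_plane(self.PLANE, tilt_deg=10.0, tilt_azimuth_deg=30.0)
        assert not np.allclose(tilted.normal, self.PLANE.normal)
        back = adjust_plane(tilted, tilt_deg=-10.0, tilt_azimuth_deg=30.0)
        np.testing.assert_allclose(back.normal, self.PLANE.normal, atol=1e-6)

    def test_implausible_tilt_rejected(self):
        with pytest.raises(ValueError, match="45"):
            adjust_plane(self.PLANE, tilt_deg=50.0)
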