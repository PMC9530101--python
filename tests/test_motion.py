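"""Segment readout: field cropping, PCA axes, arch partition, projections."""

import numpy as np
import pytest

from meniscusmotion.errors import (
    DegeneracyError,
    DegenerateInputError,
    TopologyError,
)
from meniscusmotion.grids import LabelMask
from meniscusmotion.motion import (
    SEGMENT_CODES,
    MeniscusAxes,
    anatomical_axes,
    crop_field,
    partition_arch,
    segment_motion,
)
from meniscusmotion.registration import DeformationField

from conftest import crescent_mask, identity_grid


def ellipsoid(grid, center, semi):
    X = grid.world_grid()
    return sum(((X[i] - center[i]) / semi[i]) ** 2 for i in range(3)) <= 1.0


@pytest.fixture(scope="module")
def axes_setup():
    grid = identity_grid((48, 48, 24))
    mm = LabelMask(ellipsoid(grid, (-10, 0, 0), (6, 9, 2.5)), grid, "meniscus_medial")
    lm = LabelMask(ellipsoid(grid, (10, 0, 0), (5, 8, 2.5)), grid, "meniscus_lateral")
    return grid, mm, lm


class TestCropField:
    def test_returns_one_pair_per_voxel(self):
        grid = identity_grid((10, 10, 6))
        m = np.zeros((10, 10, 6), bool)
        m.ravel()[np.random.default_rng(0).choice(m.size, 10, replace=False)] = True
        mask = LabelMask(m, grid)
        vox, disp = crop_field(DeformationField.zero(grid), mask)
        assert len(vox) == len(disp) == 10

    def test_restriction_of_constant_field(self):
        grid = identity_grid((10, 10, 6))
        m = np.zeros((10, 10, 6), bool)
        m[2:5, 3:6, 2:4] = True
        u = np.zeros((3, 10, 10, 6))
        u[0], u[1], u[2] = 1.0, 2.0, 3.0
        _, disp = crop_field(DeformationField(u, grid), LabelMask(m, grid))
        np.testing.assert_allclose(disp, np.tile([1.0, 2.0, 3.0], (m.sum(), 1)))

    def test_mask_outside_support_yields_zero(self):
        grid = identity_grid((10, 10, 6))
        u = np.zeros((3, 10, 10, 6))
        u[:, 7:, 7:, :] = 4.0
        m = np.zeros((10, 10, 6), bool)
        m[0:3, 0:3, 0:3] = True
        _, disp = crop_field(DeformationField(u, grid), LabelMask(m, grid))
        assert np.all(disp == 0.0)

    def test_empty_mask_rejected(self):
        grid = identity_grid((6, 6, 6))
        with pytest.raises(DegenerateInputError):
            crop_field(DeformationField.zero(grid), LabelMask(np.zeros((6, 6, 6), bool), grid))


class TestAnatomicalAxes:
    def test_ml_axis_follows_centroid_separation(self, axes_setup):
        _, mm, lm = axes_setup
        axes = anatomical_axes(mm, lm, "right")
        d = lm.foreground_world().mean(0) - mm.foreground_world().mean(0)
        d /= np.linalg.norm(d)
        angle = np.degrees(np.arccos(np.clip(abs(axes.ml_axis @ d), -1, 1)))
        assert angle < 2.0
        assert axes.ml_axis @ d > 0  # oriented medial -> lateral

    def test_ap_axis_points_posterior(self, axes_setup):
        _, mm, lm = axes_setup
        axes = anatomical_axes(mm, lm, "right")
        assert axes.ap_axis @ np.array([0.0, -1.0, 0.0]) > 0

    def test_mirrored_configuration_flips_ml_keeps_ap(self, axes_setup):
        grid, mm, lm = axes_setup
        # mirror about x = 0: the lateral meniscus of a left knee sits at -x
        mm2 = LabelMask(ellipsoid(grid, (10, 0, 0), (6, 9, 2.5)), grid, "meniscus_medial")
        lm2 = LabelMask(ellipsoid(grid, (-10, 0, 0), (5, 8, 2.5)), grid, "meniscus_lateral")
        right = anatomical_axes(mm, lm, "right")
        left = anatomical_axes(mm2, lm2, "left")
        np.testing.assert_allclose(left.ap_axis, right.ap_axis, atol=1e-8)
        np.testing.assert_allclose(left.ml_axis, -right.ml_axis, atol=1e-8)

    def test_isotropic_cloud_rejected(self):
        grid = identity_grid((24, 24, 24))
        ball = LabelMask(ellipsoid(grid, (0, 0, 0), (5, 5, 5)), grid)
        with pytest.raises(DegeneracyError):
            anatomical_axes(ball, ball, "right")

    def test_orthonormality(self, axes_setup):
        _, mm, lm = axes_setup
        axes = anatomical_axes(mm, lm, "right")
        assert abs(axes.ml_axis @ axes.ap_axis) < 1e-8
        assert np.linalg.norm(axes.ml_axis) == pytest.approx(1.0, abs=1e-10)
        assert np.linalg.norm(axes.plane_normal) == pytest.approx(1.0, abs=1e-10)


def _plain_axes():
    return MeniscusAxes(
        ml_axis=[1.0, 0.0, 0.0], ap_axis=[0.0, -1.0, 0.0], plane_normal=[0.0, 0.0, 1.0]
    )


def segment_angles(labels, mask, grid):
    """Angular extent of each segment code about the crescent center (oracle)."""
    vox = mask.foreground_indices()
    pts = grid.index_to_world(vox)
    theta = np.degrees(np.arctan2(pts[:, 1], pts[:, 0]))
    codes = labels.data[tuple(vox.T)]
    return {c: (theta[codes == c].min(), theta[codes == c].max()) for c in (1, 2, 3)}


class TestPartitionArch:
    def test_symmetric_half_annulus_thirds(self):
        # constant radius -> arc length proportional to angle, so the cuts
        # of a 180-degree crescent must fall at 60 and 120 degrees (+-6)
        grid = identity_grid((64, 64, 12))
        a = crescent_mask(grid, inner=8.0, outer=12.0, span_deg=180.0,
                          opening_deg=-90.0, z_lo=-1.5, z_hi=1.5)
        mask = LabelMask(a, grid, "meniscus_medial")
        labels = partition_arch(mask, _plain_axes())
        vox = mask.foreground_indices()
        pts = grid.index_to_world(vox)
        theta = np.degrees(np.arctan2(pts[:, 1], pts[:, 0]))  # crescent spans 0..180
        codes = labels.data[tuple(vox.T)]
        # oracle: equal arc length over a circular annulus = equal angle;
        # the ends are AP-symmetric here so either end may be labeled AH —
        # compare the three angular bands irrespective of code order
        bands = sorted((theta[codes == c].min(), theta[codes == c].max()) for c in (1, 2, 3))
        expected = [(0.0, 60.0), (60.0, 120.0), (120.0, 180.0)]
        for (lo, hi), (elo, ehi) in zip(bands, expected):
            assert abs(lo - elo) <= 6.0 and abs(hi - ehi) <= 6.0
        assert codes[np.argmin(theta)] != codes[np.argmax(theta)]  # IH is central

    def test_wide_crescent_equal_angular_thirds(self):
        grid = identity_grid((72, 72, 12))
        a = crescent_mask(grid, inner=9.0, outer=13.0, span_deg=300.0,
                          opening_deg=90.0, z_lo=-1.5, z_hi=1.5)
        mask = LabelMask(a, grid, "meniscus_medial")
        labels = partition_arch(mask, _plain_axes())
        vox = mask.foreground_indices()
        codes = labels.data[tuple(vox.T)]
        pts = grid.index_to_world(vox)
        theta = np.degrees(np.arctan2(pts[:, 1], pts[:, 0]))
        for code in (1, 2, 3):
            t = np.mod(theta[codes == code] - 105.0, 360.0)  # arch starts ~105 deg
            width = t.max() - t.min()
            assert width == pytest.approx(100.0, abs=6.0)

    def test_partition_is_exhaustive_and_disjoint(self):
        grid = identity_grid((48, 48, 12))
        a = crescent_mask(grid, inner=6.0, outer=10.0, span_deg=200.0, z_lo=-1.5, z_hi=1.5)
        mask = LabelMask(a, grid, "meniscus_medial")
        labels = partition_arch(mask, _plain_axes())
        assert (labels.data > 0).sum() == mask.n_foreground
        assert np.all((labels.data > 0) == mask.data)

    def test_anterior_end_is_anterior_horn(self):
        grid = identity_grid((48, 48, 12))
        a = crescent_mask(grid, inner=6.0, outer=10.0, span_deg=200.0,
                          opening_deg=0.0, z_lo=-1.5, z_hi=1.5)
        mask = LabelMask(a, grid, "meniscus_medial")
        labels = partition_arch(mask, _plain_axes())
        vox = mask.foreground_indices()
        pts = grid.index_to_world(vox)
        codes = labels.data[tuple(vox.T)]
        ap = pts[:, 1] * -1.0  # +AP = posterior = -y
        assert ap[codes == SEGMENT_CODES["AH"]].mean() < ap[codes == SEGMENT_CODES["PH"]].mean()

    def test_closed_annulus_rejected(self):
        grid = identity_grid((48, 48, 12))
        X = grid.world_grid()
        r = np.hypot(X[0], X[1])
        ring = (r >= 6) & (r <= 10) & (np.abs(X[2]) <= 1.5)
        with pytest.raises(TopologyError):
            partition_arch(LabelMask(ring, grid), _plain_axes())

    def test_disconnected_mask_rejected(self):
        grid = identity_grid((48, 48, 12))
        a = crescent_mask(grid, inner=6.0, outer=10.0, span_deg=120.0, opening_deg=0.0,
                          z_lo=-1.5, z_hi=1.5)
        b = crescent_mask(grid, inner=6.0, outer=10.0, span_deg=60.0, opening_deg=180.0,
                          z_lo=-1.5, z_hi=1.5)
        with pytest.raises(TopologyError):
            partition_arch(LabelMask(a | b, grid), _plain_axes())

    def test_deterministic(self):
        grid = identity_grid((48, 48, 12))
        a = crescent_mask(grid, inner=6.0, outer=10.0, span_deg=200.0, z_lo=-1.5, z_hi=1.5)
        mask = LabelMask(a, grid, "meniscus_medial")
        l1 = partition_arch(mask, _plain_axes())
        l2 = partition_arch(mask, _plain_axes())
        np.testing.assert_array_equal(l1.data, l2.data)


@pytest.fixture(scope="module")
def crescent_labels():
    grid = identity_grid((48, 48, 12))
    a = crescent_mask(grid, inner=6.0, outer=10.0, span_deg=200.0, z_lo=-1.5, z_hi=1.5)
    mask = LabelMask(a, grid, "meniscus_medial")
    labels = partition_arch(mask, _plain_axes())
    return grid, mask, labels


class TestSegmentMotion:

    def test_uniform_posterior_motion(self, crescent_labels):
        grid, mask, labels = crescent_labels
        axes = _plain_axes()
        u = np.zeros((3,) + tuple(grid.shape))
        u[1] = -2.0  # 2 mm along -y = +AP (posterior)
        out = segment_motion(DeformationField(u, grid), labels, axes, "MM")
        for sm in out:
            assert sm.avg_mm == pytest.approx(2.0)
            assert sm.ml_mm == pytest.approx(0.0, abs=1e-12)
            assert sm.ap_mm == pytest.approx(2.0)

    def test_uniform_medial_motion_sign(self, crescent_labels):
        grid, mask, labels = crescent_labels
        u = np.zeros((3,) + tuple(grid.shape))
        u[0] = -2.0  # against the ML axis: medial, so ml = -2
        out = segment_motion(DeformationField(u, grid), labels, _plain_axes(), "MM")
        for sm in out:
            assert sm.ml_mm == pytest.approx(-2.0)
            assert sm.ap_mm == pytest.approx(0.0, abs=1e-12)
            assert sm.avg_mm == pytest.approx(2.0)

    def test_rigid_rotation_matches_analytic_centroid_displacement(self, crescent_labels):
        grid, mask, labels = crescent_labels
        axes = _plain_axes()
        ang = np.radians(10.0)
        X = grid.world_grid()
        R = np.array([[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        u = np.einsum("ij,j...->i...", R - np.eye(3), X)
        out = segment_motion(DeformationField(u, grid), labels, axes, "MM")
        vox = mask.foreground_indices()
        pts = grid.index_to_world(vox)
        codes = labels.data[tuple(vox.T)]
        code_of = {"AH": 1, "IH": 2, "PH": 3}
        for sm in out:
            sel = np.ones(len(pts), bool) if sm.segment == "whole" else codes == code_of[sm.segment]
            # analytic displacement of the member voxels' mean position
            mean_disp = (pts[sel] @ (R - np.eye(3)).T).mean(axis=0)
            assert sm.avg_mm == pytest.approx(np.linalg.norm(mean_disp), rel=0.05)
            assert sm.ml_mm == pytest.approx(mean_disp @ axes.ml_axis, abs=0.05 * max(1, abs(sm.ml_mm)))
            assert sm.ap_mm == pytest.approx(mean_disp @ axes.ap_axis, abs=0.05 * max(1, abs(sm.ap_mm)))

    def test_whole_equals_weighted_mean_of_segments(self, crescent_labels):
        grid, mask, labels = crescent_labels
        rng = np.random.default_rng(7)
        u = rng.normal(0, 1, (3,) + tuple(grid.shape))
        out = {sm.segment: sm for sm in
               segment_motion(DeformationField(u, grid), labels, _plain_axes(), "MM")}
        n = sum(out[s].n_voxels for s in ("AH", "IH", "PH"))
        ml = sum(out[s].ml_mm * out[s].n_voxels for s in ("AH", "IH", "PH")) / n
        ap = sum(out[s].ap_mm * out[s].n_voxels for s in ("AH", "IH", "PH")) / n
        assert out["whole"].n_voxels == n
        assert out["whole"].ml_mm == pytest.approx(ml, rel=1e-10, abs=1e-12)
        assert out["whole"].ap_mm == pytest.approx(ap, rel=1e-10, abs=1e-12)

    def test_in_plane_projections_bounded_by_vector_norm(self, crescent_labels):
        grid, mask, labels = crescent_labels
        rng = np.random.default_rng(8)
        u = rng.normal(0, 2, (3,) + tuple(grid.shape))
        out = segment_motion(DeformationField(u, grid), labels, _plain_axes(), "MM")
        for sm in out:
            assert sm.ml_mm ** 2 + sm.ap_mm ** 2 <= sm.avg_mm ** 2 + 1e-9

    def test_projections_invariant_under_joint_rotation(self, crescent_labels):
        """Rotating displacements and axes together leaves the readout fixed."""
        grid, mask, labels = crescent_labels
        rng = np.random.default_rng(9)
        u = rng.normal(0, 1.5, (3,) + tuple(grid.shape))
        axes = _plain_axes()
        out0 = segment_motion(DeformationField(u, grid), labels, axes, "MM")
        ang = 0.6
        R = np.array([[np.cos(ang), 0, np.sin(ang)], [0, 1, 0], [-np.sin(ang), 0, np.cos(ang)]])
        u_rot = np.einsum("ij,j...->i...", R, u)
        axes_rot = MeniscusAxes(
            ml_axis=R @ axes.ml_axis, ap_axis=R @ axes.ap_axis,
            plane_normal=R @ axes.plane_normal,
        )
        out1 = segment_motion(DeformationField(u_rot, grid), labels, axes_rot, "MM")
        for a, b in zip(out0, out1):
            assert b.avg_mm == pytest.approx(a.avg_mm, abs=1e-8)
            assert b.ml_mm == pytest.approx(a.ml_mm, abs=1e-8)
            assert b.ap_mm == pytest.approx(a.ap_mm, abs=1e-8)
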