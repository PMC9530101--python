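"""Synthetic knee generator: determinism, geometry, motion ground truth."""

import numpy as np
import pytest
from dataclasses import replace

from meniscusmotion.errors import MotionError, SpecError
from meniscusmotion.grids import GridTransform, LabelMask, resample
from meniscusmotion.motion import SEGMENT_CODES, anatomical_axes, crop_field, partition_arch, segment_motion
from meniscusmotion.phantom import (
    CohortSpec,
    GroundTruthMotion,
    MeniscusGeometry,
    PhantomSpec,
    apply_motion,
    make_phantom,
    relative_motion_field,
    render_moving_position,
    simulate_cohort,
)
from meniscusmotion.registration import RigidTransform


class TestMakePhantom:
    def test_deterministic_per_seed(self, compact_spec):
        v1, t1, m1, l1 = make_phantom(compact_spec, seed=3)
        v2, t2, m2, l2 = make_phantom(compact_spec, seed=3)
        np.testing.assert_array_equal(v1.data, v2.data)
        np.testing.assert_array_equal(m1.data, m2.data)

    def test_different_seed_changes_intensities_not_masks(self, compact_spec):
        v1, _, m1, _ = make_phantom(compact_spec, seed=3)
        v2, _, m2, _ = make_phantom(compact_spec, seed=4)
        assert not np.array_equal(v1.data, v2.data)
        np.testing.assert_array_equal(m1.data, m2.data)

    def test_crescent_volume_matches_annulus_sector(self, compact_spec, compact_phantom):
        _, _, mm, lm = compact_phantom
        v = compact_spec.grid.voxel_volume
        for mask, geom in ((mm, compact_spec.mm), (lm, compact_spec.lm)):
            assert mask.n_foreground * v == pytest.approx(
                geom.analytic_volume(), rel=0.05
            )

    def test_closed_annulus_spec_rejected(self):
        with pytest.raises(SpecError):
            MeniscusGeometry(center=(0, 0), inner_radius=5, outer_radius=9,
                             span_deg=360.0, opening_deg=0.0, thickness=3.0)

    def test_out_of_bounds_menisci_rejected(self):
        with pytest.raises(SpecError):
            PhantomSpec(shape=(40, 40, 24), spacing=(0.6, 0.6, 0.5))


class TestApplyMotion:
    def test_identity_motion(self, compact_spec, compact_phantom):
        vol, tibia, mm, lm = compact_phantom
        motion = GroundTruthMotion()
        moving, masks, truth = apply_motion(vol, {"meniscus_medial": mm}, motion)
        np.testing.assert_allclose(moving.data, vol.data, atol=1e-9)
        np.testing.assert_array_equal(masks["meniscus_medial"].data, mm.data)
        assert np.abs(truth.u).max() == 0.0

    def test_pure_translation_constant_field(self, compact_phantom):
        vol, _, mm, _ = compact_phantom
        t = np.array([2.0, -1.0, 0.5])
        motion = GroundTruthMotion(
            global_rigid=RigidTransform(np.zeros(3), t)
        )
        _, _, truth = apply_motion(vol, {}, motion)
        for k in range(3):
            np.testing.assert_allclose(truth.u[k], t[k], atol=1e-12)

    def test_rotation_chord_magnitude(self, compact_phantom):
        # 10 degrees about the plateau center: a voxel 20 mm out moves
        # along a chord of length 2 * 20 * sin(5 deg) ~ 3.49 mm
        vol, _, _, _ = compact_phantom
        motion = GroundTruthMotion(tibial_rotation_deg=10.0)
        _, _, truth = apply_motion(vol, {}, motion)
        grid = vol.grid
        idx = grid.world_to_index(np.array([20.0, 0.0, 0.0]))
        i, j, k = np.round(idx).astype(int)
        pt = grid.index_to_world(np.array([i, j, k], float))
        r = np.hypot(pt[0], pt[1])
        expected = 2.0 * r * np.sin(np.radians(5.0))
        assert np.linalg.norm(truth.u[:, i, j, k]) == pytest.approx(expected, rel=1e-6)

    def test_warp_consistency_dice(self, compact_spec, compact_phantom):
        vol, _, mm, lm = compact_phantom
        motion = GroundTruthMotion(
            per_meniscus_translation={"MM": [0.5, -2.0, 0.3], "LM": [-1.0, 2.5, 0.0]},
            plateau_radius={"MM": 11.0, "LM": 9.5},
            meniscus_centers={"MM": compact_spec.meniscus_center3("MM"),
                              "LM": compact_spec.meniscus_center3("LM")},
        )
        moving, masks, truth = apply_motion(
            vol, {"meniscus_medial": mm, "meniscus_lateral": lm}, motion
        )
        for name, tmpl in (("meniscus_medial", mm), ("meniscus_lateral", lm)):
            warped = resample(
                masks[name], GridTransform("dense_field", truth, vol.grid), "nearest"
            )
            inter = (warped.data & tmpl.data).sum()
            dice = 2.0 * inter / (warped.n_foreground + tmpl.n_foreground)
            assert dice > 0.95

    def test_ground_truth_consistent_with_crop_and_project(self, compact_spec, compact_phantom):
        """Analytic segment means equal the crop/partition/project code path."""
        vol, _, mm, lm = compact_phantom
        motion = GroundTruthMotion(
            per_meniscus_translation={"MM": [0.3, -1.5, 0.2], "LM": [-0.8, 2.0, -0.1]},
            plateau_radius={"MM": 11.0, "LM": 9.5},
            meniscus_centers={"MM": compact_spec.meniscus_center3("MM"),
                              "LM": compact_spec.meniscus_center3("LM")},
        )
        rel = relative_motion_field(motion, vol.grid)
        axes = anatomical_axes(mm, lm, compact_spec.laterality)
        for men_id, mask in (("MM", mm), ("LM", lm)):
            labels = partition_arch(mask, axes)
            readout = {sm.segment: sm for sm in segment_motion(rel, labels, axes, men_id)}
            vox, disp_pairs = crop_field(rel, mask)
            pts = mask.foreground_world()
            disp = motion.smooth_displacement(pts.T).T
            codes = labels.data[tuple(vox.T)]
            for seg, code in list(SEGMENT_CODES.items()) + [("whole", None)]:
                sel = np.ones(len(pts), bool) if code is None else codes == code
                mean = disp[sel].mean(axis=0)
                sm = readout[seg]
                assert sm.ml_mm == pytest.approx(float(mean @ axes.ml_axis), abs=1e-6)
                assert sm.ap_mm == pytest.approx(float(mean @ axes.ap_axis), abs=1e-6)
                assert sm.avg_mm == pytest.approx(float(np.linalg.norm(mean)), abs=1e-6)

    def test_non_invertible_motion_rejected(self, compact_spec):
        with pytest.raises(MotionError):
            GroundTruthMotion(
                per_meniscus_translation={"MM": [0.0, 20.0, 0.0]},
                meniscus_centers={"MM": compact_spec.meniscus_center3("MM")},
            )


class TestRenderMovingPosition:
    def test_relative_field_is_translation_on_template_masks(self, compact_spec, compact_phantom):
        _, _, mm, lm = compact_phantom
        t = {"MM": np.array([0.5, -2.0, 0.0]), "LM": np.array([-1.0, 1.5, 0.2])}
        _, masks, rel = render_moving_position(
            compact_spec, 11, RigidTransform.identity(), t
        )
        np.testing.assert_allclose(rel.u[:, mm.data].T, np.tile(t["MM"], (mm.n_foreground, 1)))
        np.testing.assert_allclose(rel.u[:, lm.data].T, np.tile(t["LM"], (lm.n_foreground, 1)))

    def test_identity_rigid_zero_translation_reproduces_template_masks(
        self, compact_spec, compact_phantom
    ):
        _, tibia, mm, lm = compact_phantom
        _, masks, _ = render_moving_position(
            compact_spec, 11, RigidTransform.identity(),
            {"MM": np.zeros(3), "LM": np.zeros(3)},
        )
        np.testing.assert_array_equal(masks["tibia"].data, tibia.data)
        np.testing.assert_array_equal(masks["meniscus_medial"].data, mm.data)

    def test_tibia_moves_rigidly(self, compact_spec, compact_phantom):
        _, tibia, _, _ = compact_phantom
        rigid = RigidTransform(np.radians([0, 0, 6.0]), [1.0, -1.5, 0.5])
        _, masks, _ = render_moving_position(
            compact_spec, 11, rigid,
            {"MM": np.zeros(3), "LM": np.zeros(3)},
        )
        # voxelized comparison: render the template tibia through the rigid map
        back = resample(masks["tibia"], GridTransform("rigid", rigid, tibia.grid), "nearest")
        inter = (back.data & tibia.data).sum()
        dice = 2.0 * inter / (back.n_foreground + tibia.n_foreground)
        assert dice > 0.95


class TestSimulateCohort:
    def test_zero_sd_cohort_reproduces_means(self, tmp_path):
        params = {
            "internal": {"MM": {"ml": (0.5, 0.0), "ap": (-1.5, 0.0)},
                         "LM": {"ml": (-1.0, 0.0), "ap": (4.0, 0.0)}},
            "external": {"MM": {"ml": (1.5, 0.0), "ap": (5.0, 0.0)},
                         "LM": {"ml": (-0.5, 0.0), "ap": (-3.0, 0.0)}},
        }
        spec = CohortSpec(n_subjects=2, seed=1, condition_params=params, si_sd=0.0,
                          laterality_cycle=("right",))
        truth = simulate_cohort(spec, tmp_path / "c")
        whole = truth[truth.segment == "whole"]
        for cond, men in (("internal", "MM"), ("external", "LM")):
            sub = whole[(whole.condition == cond) & (whole.meniscus == men)]
            assert sub["ml_mm"].std() == pytest.approx(0.0, abs=1e-9)
            assert sub["ml_mm"].iloc[0] == pytest.approx(params[cond][men]["ml"][0], abs=1e-9)
            assert sub["ap_mm"].iloc[0] == pytest.approx(params[cond][men]["ap"][0], abs=1e-9)

    def test_sample_means_within_two_se(self, tmp_path):
        n = 12
        spec = CohortSpec(n_subjects=n, seed=3)
        truth = simulate_cohort(spec, tmp_path / "c2")
        whole = truth[truth.segment == "whole"]
        cell = whole[(whole.condition == "internal") & (whole.meniscus == "LM")]
        mu, sd = 4.32, 1.15  # generating AP distribution, internal LM
        assert abs(cell["ap_mm"].mean() - mu) <= 2.0 * sd / np.sqrt(n)

    def test_layout_files_exist(self, tiny_cohort_dir):
        root, truth = tiny_cohort_dir
        for cond in ("neutral", "internal", "external"):
            d = root / "subject_000" / cond
            for f in ("volume.nii.gz", "tibia.nii.gz", "meniscus_medial.nii.gz",
                      "meniscus_lateral.nii.gz"):
                assert (d / f).exists()
        assert (root / "subject_000" / "internal" / "truth_field.nii.gz").exists()
        assert (root / "subject_000" / "meta.yaml").exists()
        assert (root / "truth_motions.csv").exists()

    def test_negative_sd_rejected(self):
        params = {"internal": {"MM": {"ml": (0.0, -1.0), "ap": (0.0, 1.0)},
                               "LM": {"ml": (0.0, 1.0), "ap": (0.0, 1.0)}},
                  "external": {"MM": {"ml": (0.0, 1.0), "ap": (0.0, 1.0)},
                               "LM": {"ml": (0.0, 1.0), "ap": (0.0, 1.0)}}}
        with pytest.raises(SpecError):
            CohortSpec(n_subjects=2, condition_params=params)

    def test_single_subject_cohort_rejected(self):
        with pytest.raises(SpecError):
            CohortSpec(n_subjects=1)
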