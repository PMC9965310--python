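import numpy as np
import pytest

from rwnseg.cochlear_frame import fit_ccs
from rwnseg.errors import EmptySegmentationError, GeometryError, ParameterError
from rwnseg.niche_fill import (
    PROV_ABOVE_LEVEL,
    PROV_BONE,
    PROV_INSIDE_COCHLEA,
    PROV_KEPT,
    FillParameters,
    apply_niche_rules,
    compute_cochlea_mask,
    estimate_spill_level,
    fill_niche,
)
from rwnseg.phantom import generate_phantom

from conftest import exact_pit_spec

ROI_DIAGONAL = 10.0  # effectively unlimited level for a 5 mm ROI


def pit_centroid(gt):
    idx = np.argwhere(gt.niche_truth)
    return gt.volume.index_to_world(idx.mean(axis=0))


@pytest.fixture(scope="module")
def pit():
    gt = generate_phantom(exact_pit_spec())
    frame = fit_ccs(gt.fiducials)
    cochlea = compute_cochlea_mask(gt.volume, gt.membrane_truth, frame)
    return gt, frame, cochlea


class TestFillNiche:
    def test_unlimited_level_recovers_exact_pit(self, pit):
        gt, frame, cochlea = pit
        params = FillParameters(pit_centroid(gt), ROI_DIAGONAL)
        seg = fill_niche(gt.volume, gt.bone_truth, gt.membrane_truth, frame,
                         params, cochlea)
        assert seg.mask.sum() == 500
        np.testing.assert_array_equal(seg.mask, gt.niche_truth)

    def test_degenerate_level_keeps_at_most_seed(self, pit):
        gt, frame, cochlea = pit
        # center placed exactly on a pit voxel center
        idx = np.argwhere(gt.niche_truth)[0]
        center = gt.volume.index_to_world(idx)
        params = FillParameters(center, 0.5 * 0.1)
        seg = fill_niche(gt.volume, gt.bone_truth, gt.membrane_truth, frame,
                         params, cochlea)
        assert seg.mask.sum() == 1

    def test_all_bone_roi_raises_with_counts(self, pit):
        gt, frame, cochlea = pit
        all_bone = np.ones(gt.volume.shape, dtype=bool)
        with pytest.raises(EmptySegmentationError) as err:
            fill_niche(gt.volume, all_bone, gt.membrane_truth, frame,
                       FillParameters(pit_centroid(gt), ROI_DIAGONAL), cochlea)
        assert err.value.counts["candidates"] == 0
        assert err.value.counts["bone"] > 0

    def test_monotone_in_level(self, pit):
        gt, frame, cochlea = pit
        center = pit_centroid(gt)
        kept_prev = None
        for level in (0.2, 0.4, 0.8, 2.0):
            seg = fill_niche(gt.volume, gt.bone_truth, gt.membrane_truth, frame,
                             FillParameters(center, level), cochlea)
            if kept_prev is not None:
                assert np.all(seg.mask[kept_prev])
            kept_prev = seg.mask

    def test_monotone_in_bone_threshold(self):
        # raising the threshold shrinks bone and can only grow the fill
        from rwnseg.bone_segmentation import BoneThreshold, bone_mask

        gt = generate_phantom(exact_pit_spec(noise_sigma=50.0, seed=3))
        frame = fit_ccs(gt.fiducials)
        cochlea = compute_cochlea_mask(gt.volume, gt.membrane_truth, frame)
        center = pit_centroid(gt)
        kept_prev = None
        for t in (300.0, 700.0, 1100.0):
            bone = bone_mask(gt.volume, BoneThreshold(t, source="user"))
            seg = fill_niche(gt.volume, bone, gt.membrane_truth, frame,
                             FillParameters(center, ROI_DIAGONAL), cochlea)
            if kept_prev is not None:
                assert np.all(seg.mask[kept_prev])
            kept_prev = seg.mask

    def test_kept_never_intersects_bone_or_cochlea(self, pit):
        gt, frame, cochlea = pit
        seg = fill_niche(gt.volume, gt.bone_truth, gt.membrane_truth, frame,
                         FillParameters(pit_centroid(gt), ROI_DIAGONAL), cochlea)
        assert not np.any(seg.mask & gt.bone_truth)
        assert not np.any(seg.mask & cochlea)

    def test_provenance_covers_every_voxel(self, pit):
        gt, frame, cochlea = pit
        seg = fill_niche(gt.volume, gt.bone_truth, gt.membrane_truth, frame,
                         FillParameters(pit_centroid(gt), 0.4), cochlea)
        counts = seg.rule_counts()
        assert sum(counts.values()) == np.prod(gt.volume.shape)
        assert counts["kept"] == seg.mask.sum()
        assert (seg.provenance == PROV_KEPT).sum() == seg.mask.sum()
        assert (seg.provenance[gt.bone_truth & ~cochlea] == PROV_BONE).all()

    def test_disconnected_candidates_excluded(self):
        spec = exact_pit_spec(air_cells=True)
        gt = generate_phantom(spec)
        frame = fit_ccs(gt.fiducials)
        cochlea = compute_cochlea_mask(gt.volume, gt.membrane_truth, frame)
        seg = fill_niche(gt.volume, gt.bone_truth, gt.membrane_truth, frame,
                         FillParameters(pit_centroid(gt), ROI_DIAGONAL), cochlea)
        # air cells are candidates but not connected to the niche seed
        np.testing.assert_array_equal(seg.mask, gt.niche_truth)
        assert np.any(seg.provenance == 4)  # disconnected voxels recorded

    def test_bad_parameters(self, pit):
        gt, frame, cochlea = pit
        with pytest.raises(ParameterError):
            FillParameters(np.zeros(3), -1.0)
        with pytest.raises(ParameterError):
            FillParameters(np.zeros(3), 1.0, connectivity=7)
        with pytest.raises(GeometryError):
            fill_niche(gt.volume, np.zeros((2, 2, 2), bool), gt.membrane_truth,
                       frame, FillParameters(np.zeros(3), 1.0), cochlea)


@pytest.fixture(scope="module")
def slit_pit():
    gt = generate_phantom(exact_pit_spec(middle_ear="slit", air_gap=0.1))
    frame = fit_ccs(gt.fiducials)
    cochlea = compute_cochlea_mask(gt.volume, gt.membrane_truth, frame)
    return gt, frame, cochlea


class TestSpillLevel:
    def test_fill_at_spill_stays_in_pit_and_over_spills(self, slit_pit):
        gt, frame, cochlea = slit_pit
        center = pit_centroid(gt)
        level = estimate_spill_level(gt.volume, gt.bone_truth, gt.membrane_truth,
                                     frame, center, cochlea=cochlea)
        seg = fill_niche(gt.volume, gt.bone_truth, gt.membrane_truth, frame,
                         FillParameters(center, level), cochlea)
        assert np.all(gt.niche_truth[seg.mask])  # contained in the pit
        over = fill_niche(gt.volume, gt.bone_truth, gt.membrane_truth, frame,
                          FillParameters(center, level + 2 * 0.1), cochlea)
        boundary = np.zeros(gt.volume.shape, bool)
        for axis in range(3):
            sl = [slice(None)] * 3
            for end in (0, -1):
                sl[axis] = end
                boundary[tuple(sl)] = True
        assert np.any(over.mask & boundary)

    def test_deepening_pit_leaves_level_unchanged(self, slit_pit):
        gt, frame, cochlea = slit_pit
        center = pit_centroid(gt)
        level = estimate_spill_level(gt.volume, gt.bone_truth, gt.membrane_truth,
                                     frame, center, cochlea=cochlea)
        deeper = generate_phantom(
            exact_pit_spec(middle_ear="slit", air_gap=0.1, niche_dims=(1.0, 1.0, 0.7))
        )
        dframe = fit_ccs(deeper.fiducials)
        dcochlea = compute_cochlea_mask(deeper.volume, deeper.membrane_truth, dframe)
        dlevel = estimate_spill_level(deeper.volume, deeper.bone_truth,
                                      deeper.membrane_truth, dframe, center,
                                      cochlea=dcochlea)
        assert abs(dlevel - level) <= 0.25 * 0.1 + 1e-9

    def test_sealed_pit_returns_max_level(self):
        # pocket mode seals the niche behind a bone lid: the fill can
        # never reach the ROI faces, so the maximal level is returned
        gt = generate_phantom(exact_pit_spec(middle_ear="pocket"))
        frame = fit_ccs(gt.fiducials)
        cochlea = compute_cochlea_mask(gt.volume, gt.membrane_truth, frame)
        level = estimate_spill_level(gt.volume, gt.bone_truth, gt.membrane_truth,
                                     frame, pit_centroid(gt), cochlea=cochlea)
        diag = np.linalg.norm(np.array(gt.volume.shape) * gt.volume.spacing)
        np.testing.assert_allclose(level, diag, atol=1e-9)

    def test_center_in_open_space_raises(self, slit_pit):
        gt, frame, cochlea = slit_pit
        # center inside the middle-ear slit: even a minimal fill touches a face
        with pytest.raises(GeometryError):
            estimate_spill_level(gt.volume, gt.bone_truth, gt.membrane_truth,
                                 frame, np.array([2.45, 0.05, 0.05]),
                                 cochlea=cochlea)


class TestApplyNicheRules:
    def test_self_consistency_removes_nothing(self, pit):
        gt, frame, cochlea = pit
        params = FillParameters(pit_centroid(gt), ROI_DIAGONAL)
        seg = fill_niche(gt.volume, gt.bone_truth, gt.membrane_truth, frame,
                         params, cochlea)
        rules = apply_niche_rules(seg.mask, gt.volume, gt.bone_truth,
                                  gt.membrane_truth, frame, params, cochlea)
        for step in ("step1_inside_cochlea", "step2_bone", "step3_above_level",
                     "all_steps"):
            assert rules[step]["removed"] == 0

    def test_dilated_truth_matches_elementwise_oracle(self, pit):
        from scipy import ndimage

        gt, frame, cochlea = pit
        params = FillParameters(pit_centroid(gt), 0.6)
        dilated = ndimage.binary_dilation(gt.niche_truth, np.ones((3, 3, 3), bool),
                                          iterations=2)
        rules = apply_niche_rules(dilated, gt.volume, gt.bone_truth,
                                  gt.membrane_truth, frame, params, cochlea)
        centers = gt.volume.voxel_centers()
        above = np.linalg.norm(centers - params.fill_center, axis=-1) > 0.6
        # brute-force per-voxel evaluation of each predicate
        assert rules["step1_inside_cochlea"]["removed"] == int(
            np.count_nonzero(dilated & cochlea))
        assert rules["step2_bone"]["removed"] == int(
            np.count_nonzero(dilated & gt.bone_truth))
        assert rules["step3_above_level"]["removed"] == int(
            np.count_nonzero(dilated & above))
        assert rules["all_steps"]["removed"] == int(
            np.count_nonzero(dilated & (cochlea | gt.bone_truth | above)))

    def test_empty_input(self, pit):
        gt, frame, cochlea = pit
        rules = apply_niche_rules(
            np.zeros(gt.volume.shape, bool), gt.volume, gt.bone_truth,
            gt.membrane_truth, frame,
            FillParameters(pit_centroid(gt), 1.0), cochlea)
        assert rules["input_count"] == 0
        assert rules["all_steps"]["removed"] == 0

    def test_combined_survivors_subset_of_each_step(self, pit):
        rng = np.random.default_rng(9)
        gt, frame, cochlea = pit
        params = FillParameters(pit_centroid(gt), 0.7)
        for _ in range(5):
            mask = rng.random(gt.volume.shape) < 0.2
            rules = apply_niche_rules(mask, gt.volume, gt.bone_truth,
                                      gt.membrane_truth, frame, params, cochlea)
            combined = rules["all_steps"]["mask"]
            for step in ("step1_inside_cochlea", "step2_bone", "step3_above_level"):
                assert np.all(rules[step]["mask"][combined])
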