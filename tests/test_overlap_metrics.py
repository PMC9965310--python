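import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from rwnseg.cochlear_frame import fit_ccs
from rwnseg.errors import GeometryError, InputError
from rwnseg.niche_fill import FillParameters, compute_cochlea_mask, fill_niche
from rwnseg.overlap_metrics import (
    compare_masks,
    niche_volume,
    overlap,
    percent_smaller,
    rule_attribution,
    rwm_area,
)
from rwnseg.phantom import generate_phantom
from rwnseg.volume_io import VolumeImage

from conftest import exact_pit_spec


def vol_geom(shape=(20, 20, 20), spacing=(0.1, 0.1, 0.1)):
    return VolumeImage(np.zeros(shape), np.asarray(spacing))


def set_overlap_oracle(a, b):
    """Brute-force DSC/Jaccard from python sets of index tuples."""
    sa = {tuple(i) for i in np.argwhere(a)}
    sb = {tuple(i) for i in np.argwhere(b)}
    inter = len(sa & sb)
    union = len(sa | sb)
    return 2 * inter / (len(sa) + len(sb)), inter / union


class TestNicheVolume:
    def test_arithmetic(self):
        mask = np.zeros((20, 20, 20), bool)
        mask.ravel()[:1000] = True
        assert niche_volume(mask, vol_geom()) == pytest.approx(1.0)

    def test_empty(self):
        assert niche_volume(np.zeros((5, 5, 5), bool), vol_geom((5, 5, 5))) == 0.0

    def test_anisotropic_product_oracle(self):
        rng = np.random.default_rng(0)
        mask = rng.random((10, 10, 10)) < 0.5
        mask[:] = False
        mask.ravel()[:500] = True
        vol = vol_geom((10, 10, 10), (0.1, 0.1, 0.2))
        assert niche_volume(mask, vol) == pytest.approx(500 * 0.1 * 0.1 * 0.2)

    def test_additive_over_disjoint(self):
        rng = np.random.default_rng(1)
        a = rng.random((10, 10, 10)) < 0.3
        b = ~a & (rng.random((10, 10, 10)) < 0.3)
        v = vol_geom((10, 10, 10))
        assert niche_volume(a | b, v) == pytest.approx(
            niche_volume(a, v) + niche_volume(b, v)
        )


class TestRwmArea:
    def test_pit_floor_area(self):
        gt = generate_phantom(exact_pit_spec())
        frame = fit_ccs(gt.fiducials)
        cochlea = compute_cochlea_mask(gt.volume, gt.membrane_truth, frame)
        idx = np.argwhere(gt.niche_truth)
        center = gt.volume.index_to_world(idx.mean(axis=0))
        seg = fill_niche(gt.volume, gt.bone_truth, gt.membrane_truth, frame,
                         FillParameters(center, 10.0), cochlea)
        # 10x10 voxel membrane floor at 0.1 mm -> 100 voxels -> 1 mm^2
        assert rwm_area(seg.mask, cochlea, gt.volume) == pytest.approx(1.0)

    def test_no_contact_gives_zero(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[0, 0, 0] = True
        cochlea = np.zeros((5, 5, 5), bool)
        cochlea[4, 4, 4] = True
        assert rwm_area(mask, cochlea, vol_geom((5, 5, 5))) == 0.0

    def test_area_scales_as_spacing_squared(self):
        rng = np.random.default_rng(2)
        mask = rng.random((10, 10, 10)) < 0.4
        cochlea = ~mask & (rng.random((10, 10, 10)) < 0.4)
        a1 = rwm_area(mask, cochlea, vol_geom((10, 10, 10), (0.1,) * 3))
        a2 = rwm_area(mask, cochlea, vol_geom((10, 10, 10), (0.2,) * 3))
        assert a2 == pytest.approx(4 * a1)

    def test_count_faces_at_least_count_voxels_area(self):
        rng = np.random.default_rng(3)
        mask = rng.random((10, 10, 10)) < 0.4
        cochlea = ~mask & (rng.random((10, 10, 10)) < 0.4)
        v = vol_geom((10, 10, 10))
        assert rwm_area(mask, cochlea, v, count_faces=True) >= \
            rwm_area(mask, cochlea, v)


class TestOverlap:
    def test_identity(self):
        rng = np.random.default_rng(4)
        a = rng.random((8, 8, 8)) < 0.5
        assert overlap(a, a) == (1.0, 1.0)

    def test_disjoint(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0], b[1] = True, True
        assert overlap(a, b) == (0.0, 0.0)

    def test_half_overlap(self):
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a.ravel()[:100] = True
        b.ravel()[50:150] = True
        dsc, j = overlap(a, b)
        assert dsc == pytest.approx(0.5)
        assert j == pytest.approx(1 / 3)

    def test_both_empty_rejected(self):
        with pytest.raises(InputError):
            overlap(np.zeros((3, 3, 3), bool), np.zeros((3, 3, 3), bool))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(GeometryError):
            overlap(np.ones((2, 2, 2), bool), np.ones((3, 3, 3), bool))

    def test_100_random_pairs_match_set_oracle_exactly(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            shape = tuple(rng.integers(3, 21, size=3))
            a = rng.random(shape) < rng.uniform(0.05, 0.6)
            b = rng.random(shape) < rng.uniform(0.05, 0.6)
            if not (a.any() or b.any()):
                continue
            dsc, j = overlap(a, b)
            odsc, oj = set_overlap_oracle(a, b)
            assert dsc == odsc and j == oj
            assert abs(j - dsc / (2 - dsc)) < 1e-12
            assert 0 <= j <= dsc <= 1

    @settings(max_examples=50, deadline=None)
    @given(hnp.arrays(bool, (6, 6, 6)), hnp.arrays(bool, (6, 6, 6)))
    def test_jaccard_dice_identity_property(self, a, b):
        if not (a.any() or b.any()):
            return
        dsc, j = overlap(a, b)
        assert abs(j - dsc / (2 - dsc)) < 1e-12


class TestPercentSmaller:
    def test_convention(self):
        # manual reference 2.0, semi-automated 1.0 -> 50% smaller
        assert percent_smaller(2.0, 1.0) == pytest.approx(50.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(InputError):
            percent_smaller(0.0, 1.0)


@pytest.fixture(scope="module")
def context():
    gt = generate_phantom(exact_pit_spec(middle_ear="slit", air_gap=0.3))
    frame = fit_ccs(gt.fiducials)
    cochlea = compute_cochlea_mask(gt.volume, gt.membrane_truth, frame)
    idx = np.argwhere(gt.niche_truth)
    center = gt.volume.index_to_world(idx.mean(axis=0))
    seg = fill_niche(gt.volume, gt.bone_truth, gt.membrane_truth, frame,
                     FillParameters(center, 0.8), cochlea)
    return gt, frame, cochlea, seg


class TestRuleAttribution:
    def test_self_application_removes_zero(self, context):
        gt, frame, cochlea, seg = context
        out = rule_attribution(seg.mask, seg, gt.volume, gt.bone_truth,
                               gt.membrane_truth, frame, cochlea=cochlea)
        for step in ("step1_inside_cochlea", "step2_bone", "step3_above_level",
                     "all_steps"):
            assert out[step]["removed_fraction"] == 0.0
        assert out["residual"]["volume_difference_vs_semi"] == 0.0

    def test_constructed_band_gives_exact_step3_share(self, context):
        gt, frame, cochlea, seg = context
        centers = gt.volume.voxel_centers()
        dist = np.linalg.norm(centers - seg.params.fill_center, axis=-1)
        # air voxels above the level but in the open middle ear
        band = (~gt.bone_truth) & ~cochlea & (dist > seg.params.level) \
            & (dist <= seg.params.level + 0.2)
        assert band.any()
        manual = seg.mask | band
        out = rule_attribution(manual, seg, gt.volume, gt.bone_truth,
                               gt.membrane_truth, frame, cochlea=cochlea)
        total = int(manual.sum())
        assert out["step3_above_level"]["removed_fraction"] == \
            pytest.approx(band.sum() / total)
        assert out["step1_inside_cochlea"]["removed_fraction"] == 0.0
        assert out["step2_bone"]["removed_fraction"] == 0.0
        assert out["all_steps"]["removed_fraction"] == \
            pytest.approx(band.sum() / total)

    def test_single_step_fraction_never_exceeds_combined(self, context):
        rng = np.random.default_rng(6)
        gt, frame, cochlea, seg = context
        for _ in range(20):
            manual = rng.random(gt.volume.shape) < 0.1
            if not manual.any():
                continue
            out = rule_attribution(manual, seg, gt.volume, gt.bone_truth,
                                   gt.membrane_truth, frame, cochlea=cochlea)
            combined = out["all_steps"]["removed_fraction"]
            for step in ("step1_inside_cochlea", "step2_bone", "step3_above_level"):
                assert out[step]["removed_fraction"] <= combined + 1e-12

    def test_empty_manual_rejected(self, context):
        gt, frame, cochlea, seg = context
        with pytest.raises(InputError):
            rule_attribution(np.zeros(gt.volume.shape, bool), seg, gt.volume,
                             gt.bone_truth, gt.membrane_truth, frame,
                             cochlea=cochlea)


class TestCompareMasks:
    def test_report_fields_consistent(self):
        rng = np.random.default_rng(7)
        a = rng.random((10, 10, 10)) < 0.4
        b = rng.random((10, 10, 10)) < 0.4
        v = vol_geom((10, 10, 10))
        rep = compare_masks(a, b, v)
        assert rep.intersection_volume <= min(rep.volume_a, rep.volume_b) + 1e-12
        assert abs(rep.jaccard - rep.dsc / (2 - rep.dsc)) < 1e-12
        d = rep.to_dict()
        assert set(d) >= {"volume_a", "volume_b", "dsc", "jaccard"}
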