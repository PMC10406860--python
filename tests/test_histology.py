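"""TTC segmentation, volumetry, edema correction, exclusion, regression."""

import numpy as np
import pytest

from wfrquant.histology import (
    LesionRecord,
    SliceSet,
    analyze_lesion,
    edema_correct,
    exclude_surgical_site,
    infarct_volume,
    segment_infarct,
    segment_slice_set,
    slit_regression,
)
from wfrquant.protocols import LesionModel
from wfrquant.synthetic import generate_lesion_dataset

STAINED = (186, 62, 58)
WHITE = (235, 226, 214)


def synthetic_slice(shape=(80, 120), infarct_disc=None):
    """Hand-built stained slice with rectangular hemispheres."""
    img = np.zeros((*shape, 3), dtype=np.uint8)
    img[:] = (12, 12, 14)
    ipsi = np.zeros(shape, bool)
    contra = np.zeros(shape, bool)
    ipsi[10:70, 10:55] = True
    contra[10:70, 65:110] = True
    img[ipsi | contra] = STAINED
    if infarct_disc is not None:
        r0, c0, rad = infarct_disc
        rr = np.arange(shape[0])[:, None]
        cc = np.arange(shape[1])[None, :]
        disc = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
        img[disc & ipsi] = WHITE
    return img, {"ipsi": ipsi, "contra": contra}


def manual_slice_set(masks_and_slices, thickness=2.0, mm_per_px=0.1):
    slices = [s for s, _ in masks_and_slices]
    hemis = [h for _, h in masks_and_slices]
    return SliceSet(
        slices=slices, thickness_mm=thickness, mm_per_px=mm_per_px,
        hemisphere_masks=hemis,
    )


class TestSegmentation:
    def test_fully_stained_slice_yields_empty_mask(self):
        img, hemi = synthetic_slice()
        mask = segment_infarct(img, hemi["ipsi"] | hemi["contra"])
        assert mask.sum() == 0

    def test_painted_disc_area_recovered_within_2_percent(self):
        rad = 12
        img, hemi = synthetic_slice(infarct_disc=(40, 32, rad))
        tissue = hemi["ipsi"] | hemi["contra"]
        painted = int(
            (
                (np.arange(80)[:, None] - 40) ** 2
                + (np.arange(120)[None, :] - 32) ** 2
                <= rad**2
            )
            .sum()
        )
        mask = segment_infarct(img, tissue)
        assert mask.sum() == pytest.approx(painted, rel=0.02)

    def test_no_tissue_rejected(self):
        img, _ = synthetic_slice()
        with pytest.raises(ValueError):
            segment_infarct(img, np.zeros((80, 120), bool))

    def test_control_group_slices_show_zero_infarct(self):
        # groups 1-3 have no lesion: fully stained slice sets segment to zero
        model = LesionModel(intercept_mm3=0.0, noise_sd_mm3=0.0)
        recs, sets = generate_lesion_dataset(
            model, [0.0], seed=4, blemish_area_mm2=0.0
        )
        masks = segment_slice_set(sets[0])
        assert all(m.sum() == 0 for m in masks)


class TestVolumeArithmetic:
    def test_single_slice_product(self):
        # 10 mm2 infarct on one 2 mm slice -> 20 mm3
        img, hemi = synthetic_slice(infarct_disc=(40, 32, 10))
        ss = manual_slice_set([(img, hemi)])
        mask = np.zeros((80, 120), bool)
        mask[:10, :100] = True  # 1000 px * 0.01 mm2 = 10 mm2
        assert infarct_volume(ss, [mask]) == pytest.approx(20.0)

    def test_all_empty_masks_give_zero(self):
        img, hemi = synthetic_slice()
        ss = manual_slice_set([(img, hemi)] * 3)
        masks = [np.zeros((80, 120), bool)] * 3
        assert infarct_volume(ss, masks) == 0.0

    def test_additive_and_order_invariant(self):
        img, hemi = synthetic_slice()
        ss3 = manual_slice_set([(img, hemi)] * 3)
        ss1 = manual_slice_set([(img, hemi)])
        rng = np.random.default_rng(0)
        masks = [rng.random((80, 120)) < p for p in (0.1, 0.2, 0.3)]
        v = infarct_volume(ss3, masks)
        assert v == pytest.approx(sum(infarct_volume(ss1, [m]) for m in masks))
        assert infarct_volume(ss3, masks[::-1]) == pytest.approx(v)

    def test_multislice_synthetic_lesion_within_3_percent(self):
        recs, sets = generate_lesion_dataset(
            LesionModel(), np.linspace(1, 6, 8), seed=12
        )
        for gt, ss in zip(recs, sets):
            rec = analyze_lesion(ss, gt.subject_id, gt.slit_area_mm2, gt.exclusion_rois)
            assert rec.raw_volume_mm3 == pytest.approx(gt.volume_mm3, rel=0.03)


class TestEdemaCorrection:
    def test_equal_hemispheres_corrected_equals_raw(self):
        img, hemi = synthetic_slice(infarct_disc=(40, 32, 10))
        ss = manual_slice_set([(img, hemi)])
        masks = segment_slice_set(ss)
        assert edema_correct(ss, masks) == pytest.approx(infarct_volume(ss, masks))

    def test_inflated_ipsilateral_reduces_volume_by_swelling_exactly(self):
        img, hemi = synthetic_slice(infarct_disc=(40, 32, 10))
        # inflate the ipsilateral hemisphere by a known pixel count
        hemi = {"ipsi": hemi["ipsi"].copy(), "contra": hemi["contra"]}
        swell_px = 270
        extra = np.zeros_like(hemi["ipsi"])
        extra[70:73, 10:100] = True
        assert extra.sum() == swell_px
        hemi["ipsi"] |= extra
        ss = manual_slice_set([(img, hemi)])
        masks = segment_slice_set(ss)
        raw = infarct_volume(ss, masks)
        corrected = edema_correct(ss, masks)
        assert corrected == pytest.approx(raw - swell_px * 0.01 * 2.0)

    def test_null_case_zero(self):
        img, hemi = synthetic_slice()
        ss = manual_slice_set([(img, hemi)])
        assert edema_correct(ss, [np.zeros((80, 120), bool)]) == 0.0

    def test_generator_swelling_makes_corrected_below_raw(self):
        recs, sets = generate_lesion_dataset(
            LesionModel(noise_sd_mm3=0.0), [4.0], seed=0, swelling_frac=0.10
        )
        rec = analyze_lesion(
            sets[0], recs[0].subject_id, recs[0].slit_area_mm2, recs[0].exclusion_rois
        )
        assert rec.edema_corrected_volume_mm3 < rec.raw_volume_mm3


class TestSurgicalSiteExclusion:
    def _masks(self, with_blemish=True):
        main = np.zeros((80, 120), bool)
        main[30:60, 20:50] = True  # 9 mm2 at 0.1 mm/px
        blemish = np.zeros_like(main)
        if with_blemish:
            blemish[5:10, 5:15] = True  # 0.5 mm2, far from the lesion
        return main, blemish

    def test_distant_blemish_removed_main_intact(self):
        main, blemish = self._masks()
        roi = np.zeros_like(main)
        roi[0:15, 0:20] = True
        filtered, excluded, _ = exclude_surgical_site(
            [main | blemish], exclusion_rois=[roi], pixel_area_mm2=0.01
        )
        np.testing.assert_array_equal(filtered[0], main)
        assert excluded == pytest.approx(0.5)

    def test_size_rule_without_roi(self):
        main, blemish = self._masks()
        filtered, excluded, _ = exclude_surgical_site(
            [main | blemish], min_area_mm2=1.0, pixel_area_mm2=0.01
        )
        np.testing.assert_array_equal(filtered[0], main)
        assert excluded == pytest.approx(0.5)

    def test_no_blemish_masks_unchanged(self):
        main, _ = self._masks(with_blemish=False)
        filtered, excluded, flags = exclude_surgical_site([main], pixel_area_mm2=0.01)
        np.testing.assert_array_equal(filtered[0], main)
        assert excluded == 0.0 and flags == []

    def test_contiguous_blemish_retained_and_flagged(self):
        main, _ = self._masks(with_blemish=False)
        roi = np.zeros_like(main)
        roi[28:35, 18:25] = True  # overlaps the main lesion
        filtered, excluded, flags = exclude_surgical_site(
            [main], exclusion_rois=[roi], pixel_area_mm2=0.01
        )
        np.testing.assert_array_equal(filtered[0], main)
        assert excluded == 0.0
        assert any("retained" in f for f in flags)


def _records(pairs):
    return [
        LesionRecord(
            subject_id=f"L{i}",
            total_slit_area_mm2=x,
            infarct_area_mm2=[],
            raw_volume_mm3=y,
            edema_corrected_volume_mm3=y,
        )
        for i, (x, y) in enumerate(pairs)
    ]


class TestSlitRegression:
    def test_collinear_points_r2_is_one(self):
        res = slit_regression(_records([(0, 1), (1, 3), (2, 5), (3, 7)]))
        assert res.r2 == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)

    def test_three_point_hand_computed_ols(self):
        # normal equations by hand for (0,0), (1,1), (2,3)
        res = slit_regression(_records([(0, 0), (1, 1), (2, 3)]))
        assert res.slope == pytest.approx(1.5)
        assert res.intercept == pytest.approx(-1.0 / 6.0)
        assert res.r2 == pytest.approx(27.0 / 28.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            slit_regression(_records([(0, 0), (1, 1)]))
        with pytest.raises(ValueError):
            slit_regression(_records([(1, 0), (1, 1), (1, 2)]))
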