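"""Classification rules, thresholds, erosion and sector partition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bssfp2pt import (
    EmptyMaskError,
    ParametricMap,
    RoiSet,
    StatisticsError,
    ThresholdSpec,
    classify_delta_s,
    classify_lge,
    default_delta_s_threshold,
    derive_delta_s_threshold,
    erode_borders,
    sector_partition,
)
from bssfp2pt.segmentation import LABEL_ENHANCED


def make_rois(shape=(10, 10), myo=None):
    if myo is None:
        myo = np.ones(shape, dtype=bool)
    return RoiSet(
        myocardium=myo,
        remote_roi=myo.copy(),
        blood_roi=np.zeros(shape, dtype=bool),
        lv_center=(shape[0] / 2, shape[1] / 2),
    )


class TestClassifyLge:
    def test_hand_threshold_mean100_sd10(self):
        """The printed-value oracle: remote mean 100, SD 10, n_sd 5 ->
        threshold 150."""
        remote_vals = np.array([90.0, 100.0, 110.0, 90.0, 110.0, 100.0])
        # rescale to make the sample SD exactly 10
        remote_vals = 100.0 + (remote_vals - 100.0) * (10.0 / np.std(remote_vals, ddof=1))
        values = np.full((2, 6), 120.0)
        values[0] = remote_vals
        values[1, 0], values[1, 1] = 151.0, 150.0
        rois = RoiSet(
            myocardium=np.ones((2, 6), bool),
            remote_roi=np.array([[True] * 6, [False] * 6]),
            blood_roi=np.zeros((2, 6), bool),
            lv_center=(1, 3),
        )
        labelled, tspec = classify_lge(ParametricMap(values), rois, n_sd=5)
        assert tspec.value == pytest.approx(150.0)
        assert labelled.labels[1, 0] == LABEL_ENHANCED
        assert labelled.labels[1, 1] != LABEL_ENHANCED

    def test_constant_remote_degenerates_to_mean(self):
        values = np.full((2, 4), 100.0)
        values[1, 2] = 100.0001
        rois = RoiSet(
            myocardium=np.ones((2, 4), bool),
            remote_roi=np.array([[True] * 4, [False] * 4]),
            blood_roi=np.zeros((2, 4), bool),
            lv_center=(1, 2),
        )
        labelled, tspec = classify_lge(ParametricMap(values), rois)
        assert tspec.value == pytest.approx(100.0)
        assert labelled.labels[1, 2] == LABEL_ENHANCED
        assert labelled.enhanced_mask.sum() == 1

    def test_small_remote_roi_rejected(self):
        small = RoiSet(
            myocardium=np.ones((4, 4), bool),
            remote_roi=np.zeros((4, 4), bool),
            blood_roi=np.zeros((4, 4), bool),
            lv_center=(2, 2),
        )
        with pytest.raises(StatisticsError):
            classify_lge(ParametricMap(np.ones((4, 4))), small)

    def test_phantom_lge_recovers_truth_at_zero_noise(self, clean_phantom):
        ds = clean_phantom
        # noise-free LGE: regenerate without LGE noise
        from bssfp2pt import PhantomSpec, generate_phantom

        quiet = generate_phantom(PhantomSpec(noise_sigma=0.0, lge_noise_sigma=0.0,
                                             seed=7))
        labelled, _ = classify_lge(quiet.lge_image, quiet.rois)
        assert np.array_equal(labelled.enhanced_mask, quiet.truth.enhanced_mask)


class TestDeltaSThreshold:
    def test_hand_computed_control_cohort(self):
        """{100,110,120,130,140}: mean 120 + 3 * 15.8114 = 167.43."""
        tspec = derive_delta_s_threshold([100, 110, 120, 130, 140])
        assert tspec.value == pytest.approx(167.434, abs=0.01)
        assert tspec.rule == "mean+3SD controls"

    def test_identical_subjects_zero_sd(self):
        assert derive_delta_s_threshold([115.0] * 5).value == pytest.approx(115.0)

    def test_single_subject_rejected(self):
        with pytest.raises(StatisticsError):
            derive_delta_s_threshold([100.0])

    def test_default_fixed_threshold(self):
        tspec = default_delta_s_threshold()
        assert tspec.value == 197.0
        assert tspec.rule == "fixed"


class TestClassifyDeltaS:
    def test_uniform_below_threshold(self):
        rois = make_rois((5, 5))
        out = classify_delta_s(
            ParametricMap(np.full((5, 5), 100.0)), rois, default_delta_s_threshold()
        )
        assert out.enhanced_mask.sum() == 0

    def test_voxel_exactly_at_threshold_not_enhanced(self):
        rois = make_rois((2, 2))
        values = np.array([[197.0, 197.0001], [100.0, 100.0]])
        out = classify_delta_s(ParametricMap(values), rois, default_delta_s_threshold())
        assert not out.enhanced_mask[0, 0]
        assert out.enhanced_mask[0, 1]

    def test_invalid_voxels_excluded(self):
        rois = make_rois((2, 2))
        pm = ParametricMap(
            np.array([[300.0, np.nan], [100.0, 100.0]]),
            valid_mask=np.array([[True, False], [True, True]]),
        )
        out = classify_delta_s(pm, rois, default_delta_s_threshold())
        assert out.enhanced_mask[0, 0]
        assert out.labels[0, 1] == 0  # invalid -> background, not myocardium

    def test_no_valid_voxels_rejected(self):
        rois = make_rois((2, 2))
        pm = ParametricMap(np.full((2, 2), np.nan), valid_mask=np.zeros((2, 2), bool))
        with pytest.raises(EmptyMaskError):
            classify_delta_s(pm, rois, default_delta_s_threshold())

    @given(st.floats(min_value=50, max_value=400))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_threshold(self, thr):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 400, (8, 8))
        rois = make_rois((8, 8))
        lo = classify_delta_s(ParametricMap(values), rois,
                              ThresholdSpec(thr, "fixed"))
        hi = classify_delta_s(ParametricMap(values), rois,
                              ThresholdSpec(thr + 25, "fixed"))
        assert not np.any(hi.enhanced_mask & ~lo.enhanced_mask)


class TestErodeBorders:
    def test_zero_voxels_is_identity(self, clean_phantom):
        assert erode_borders(clean_phantom.rois, 0) is clean_phantom.rois

    def test_annulus_thickness_shrinks_by_two_per_erosion(self):
        """Eroding an annulus of radial thickness 10 by 1 voxel removes one
        voxel from each border: thickness ~8 along any radius."""
        shape = (64, 64)
        rows, cols = np.indices(shape)
        rad = np.hypot(rows - 32, cols - 32)
        annulus = (rad >= 10) & (rad < 20)
        rois = RoiSet(annulus, np.zeros(shape, bool), np.zeros(shape, bool), (32, 32))
        eroded = erode_borders(rois, 1)
        # brute-force radial thickness along the +x axis
        row = eroded.myocardium[32]
        thickness = row[33:].sum()
        assert thickness == pytest.approx(8, abs=1)
        assert eroded.myocardium.sum() < annulus.sum()
        assert not np.any(eroded.myocardium & ~annulus)

    def test_full_mask_loses_border_ring(self):
        shape = (10, 10)
        rois = make_rois(shape)
        eroded = erode_borders(rois, 1)
        expected = np.zeros(shape, bool)
        expected[1:-1, 1:-1] = True
        assert np.array_equal(eroded.myocardium, expected)

    def test_over_erosion_rejected(self):
        rois = make_rois((5, 5))
        with pytest.raises(EmptyMaskError):
            erode_borders(rois, 4)

    def test_labels_restricted(self, clean_phantom):
        from bssfp2pt import analyze_phantom

        rep = analyze_phantom(clean_phantom)
        eroded = erode_borders(rep["ds_rois"], 1)
        assert not np.any(eroded.enhanced_mask & ~eroded.myocardium)


class TestSectorPartition:
    def test_partition_covers_each_voxel_once(self, clean_phantom):
        rois = clean_phantom.rois
        pm = ParametricMap(np.zeros(rois.myocardium.shape))
        sector_map, stats = sector_partition(rois, pm, n_sectors=12)
        inside = sector_map[rois.myocardium]
        assert np.all((inside >= 0) & (inside < 12))
        assert np.all(sector_map[~rois.myocardium] == -1)
        assert stats.n_voxels.sum() == rois.myocardium.sum()

    def test_uniform_map_equal_sector_means(self, clean_phantom):
        pm = ParametricMap(np.full(clean_phantom.rois.myocardium.shape, 7.5))
        _, stats = sector_partition(clean_phantom.rois, pm, n_sectors=12)
        assert np.allclose(stats["mean"], 7.5)

    def test_single_sector_equals_global_mean(self, clean_phantom, rng):
        values = rng.normal(100, 10, clean_phantom.rois.myocardium.shape)
        pm = ParametricMap(values)
        _, stats = sector_partition(clean_phantom.rois, pm, n_sectors=1)
        assert stats.loc[0, "mean"] == pytest.approx(
            values[clean_phantom.rois.myocardium].mean()
        )

    def test_wedge_lesion_elevates_only_covering_sectors(self):
        """A lesion confined to 30-60 degrees raises the mean only in the
        sector(s) covering that arc."""
        from bssfp2pt import PhantomSpec, analyze_phantom, generate_phantom

        ds = generate_phantom(
            PhantomSpec(noise_sigma=0.0, lesion_theta=(30.0, 60.0))
        )
        rep = analyze_phantom(ds)
        _, stats = sector_partition(ds.rois, rep["dsmap"], n_sectors=12)
        elevated = set(stats[stats["mean"] > 150].sector)
        assert elevated == {1}  # sector 1 spans 30-60 degrees
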