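import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import ndimage as ndi

from punctakit import (
    AnalysisConfig,
    ConfigError,
    Scene,
    dual_threshold_profile,
    generate_scene,
    preset,
    segment_nuclei,
    segment_puncta,
)
from punctakit.config import SegmentationParams
from punctakit.segment import puncta_mask

from conftest import flood_fill_components


def scene_from_channels(nuclei, aggregate, pixel_size=0.1):
    pixels = np.stack([nuclei, aggregate])[np.newaxis].astype(np.float32)
    return Scene(pixels, ["nuclei", "aggregate"], pixel_size)


SMALL_NUCLEI = dict(
    nucleus_semiaxis_a_um=(2.0, 2.4),
    nucleus_semiaxis_b_um=(1.6, 2.0),
)


class TestSegmentNuclei:
    def test_recovers_well_separated_nuclei_centroids(self, config):
        p = preset("ala10", seed=21, n_nuclei=5, **SMALL_NUCLEI)
        scene, truth = generate_scene(p)
        rois = segment_nuclei(scene, config.nuclei)
        inner = [r for r in rois if not r.touches_border]
        assert len(inner) == 5
        found = sorted((r.centroid for r in inner))
        expected = sorted(
            zip(truth.nuclei["center_row_px"], truth.nuclei["center_col_px"])
        )
        for (fr, fc), (er, ec) in zip(found, expected):
            assert abs(fr - er) <= 1.0
            assert abs(fc - ec) <= 1.0

    def test_constant_channel_yields_empty_list(self, config):
        scene = scene_from_channels(np.full((64, 64), 5.0), np.zeros((64, 64)))
        assert segment_nuclei(scene, config.nuclei) == []

    def test_separated_nuclei_have_disjoint_rings(self, config):
        p = preset("ala10", seed=22, n_nuclei=3, **SMALL_NUCLEI)
        scene, _ = generate_scene(p)
        rois = segment_nuclei(scene, config.nuclei)
        for i, a in enumerate(rois):
            assert not (a.mask & a.perinuclear_mask).any()
            # ring touches the nucleus boundary
            assert (ndi.binary_dilation(a.mask) & a.perinuclear_mask).any()
            for b in rois[i + 1 :]:
                assert not (a.perinuclear_mask & b.perinuclear_mask).any()


class TestSegmentPuncta:
    def test_noiseless_disk_area_matches_brute_force_blur_scan(self):
        img = np.zeros((64, 64))
        yy, xx = np.mgrid[:64, :64]
        img[(yy - 32) ** 2 + (xx - 32) ** 2 <= 6**2] = 1000.0
        scene = scene_from_channels(np.zeros((64, 64)), img)
        params = SegmentationParams(
            blur_sigma_px=1.5, despeckle=False, threshold_low=400.0
        )
        labels, stubs = segment_puncta(scene, [], params, "low")
        assert len(stubs) == 1
        # independent oracle: explicit Gaussian kernel convolution + scan
        sigma = 1.5
        radius = int(4 * sigma)
        ax = np.arange(-radius, radius + 1)
        k1 = np.exp(-(ax**2) / (2 * sigma**2))
        k1 /= k1.sum()
        blurred = ndi.convolve1d(ndi.convolve1d(img, k1, axis=0, mode="nearest"), k1, axis=1, mode="nearest")
        expected = int((blurred > 400.0).sum())
        assert int(stubs["area_px"].iloc[0]) == expected

    def test_threshold_above_max_gives_no_puncta(self):
        img = np.zeros((32, 32))
        img[10:14, 10:14] = 500.0
        scene = scene_from_channels(np.zeros((32, 32)), img)
        params = SegmentationParams(blur_sigma_px=0.0, despeckle=False, threshold_low=1e6)
        labels, stubs = segment_puncta(scene, [], params, "low")
        assert len(stubs) == 0

    def test_area_filter_is_strict(self):
        # at 0.1 um/px one pixel is exactly 0.01 um^2: must be removed
        img = np.zeros((32, 32))
        img[5, 5] = 1000.0  # 0.01 um^2 -> dropped (strict >)
        img[20, 20:22] = 1000.0  # 0.02 um^2 -> kept
        scene = scene_from_channels(np.zeros((32, 32)), img)
        params = SegmentationParams(blur_sigma_px=0.0, despeckle=False, threshold_low=500.0)
        _, stubs = segment_puncta(scene, [], params, "low")
        assert len(stubs) == 1
        assert int(stubs["area_px"].iloc[0]) == 2

    def test_unset_threshold_is_config_error(self):
        scene = scene_from_channels(np.zeros((16, 16)), np.zeros((16, 16)))
        params = SegmentationParams(threshold_low=None)
        with pytest.raises(ConfigError):
            segment_puncta(scene, [], params, "low")

    def test_puncta_assigned_to_containing_nucleus(self, config):
        p = preset("ala10", seed=23)
        scene, truth = generate_scene(p)
        rois = segment_nuclei(scene, config.nuclei)
        _, stubs = segment_puncta(scene, rois, config.aggregate, "low")
        nuclear = stubs[~stubs["extranuclear"]]
        assert len(nuclear) > 0
        assert (nuclear["nucleus_id"] > 0).all()

    def test_constant_threshold_across_scenes(self, config):
        s1, _ = generate_scene(preset("ala10", seed=1))
        s2, _ = generate_scene(preset("ala16", seed=2))
        _, st1 = segment_puncta(s1, [], config.aggregate, "low")
        _, st2 = segment_puncta(s2, [], config.aggregate, "low")
        assert set(st1["threshold"]) == set(st2["threshold"]) == {120.0}


class TestOracleEquivalence:
    @given(seed=st.integers(0, 10_000))
    def test_labeling_matches_flood_fill_on_random_images(self, seed):
        rng = np.random.default_rng(seed)
        h, w = rng.integers(4, 33, size=2)
        binary = rng.random((h, w)) < rng.uniform(0.2, 0.6)
        img = binary * 1000.0
        scene = scene_from_channels(np.zeros((h, w)), img, pixel_size=0.1)
        min_area = 0.01
        params = SegmentationParams(
            blur_sigma_px=0.0, despeckle=False, threshold_low=500.0, min_area_um2=min_area
        )
        labels, _ = segment_puncta(scene, [], params, "low")
        ours = {
            frozenset(zip(*np.nonzero(labels == k)))
            for k in np.unique(labels)
            if k > 0
        }
        oracle = {
            c
            for c in flood_fill_components(binary, connectivity=8)
            if len(c) * 0.01 > min_area
        }
        assert ours == oracle


class TestThresholdMonotonicity:
    @pytest.mark.parametrize("seed", [1, 2])
    def test_supra_threshold_area_non_increasing_and_nested(self, seed):
        scene, _ = generate_scene(preset("ala16", seed=seed))
        params = AnalysisConfig().aggregate
        img = scene.channel("aggregate")
        thresholds = [50.0, 120.0, 300.0, 650.0]
        masks = [puncta_mask(img, params, 0.1, t) for t in thresholds]
        areas = [int(m.sum()) for m in masks]
        assert areas == sorted(areas, reverse=True)
        for lo, hi in zip(masks, masks[1:]):
            assert not (hi & ~lo).any()  # high mask nested in low mask


class TestDualThresholdProfile:
    def _roi(self, shape):
        from punctakit import NucleusROI

        mask = np.ones(shape, dtype=bool)
        return NucleusROI(1, mask, np.zeros(shape, bool), (0, 0), mask.sum() * 0.01)

    def make(self, img):
        return scene_from_channels(np.zeros(img.shape), img)

    def test_all_supra_low_also_supra_high_gives_one(self):
        img = np.zeros((32, 32))
        img[8:12, 8:12] = 1000.0
        params = SegmentationParams(
            blur_sigma_px=0.0, despeckle=False, threshold_low=100.0, threshold_high=700.0
        )
        prof = dual_threshold_profile(self.make(img), [self._roi(img.shape)], params)
        assert prof["aggregation_index"].iloc[0] == pytest.approx(1.0)

    def test_no_pixel_above_high_gives_zero(self):
        img = np.zeros((32, 32))
        img[8:12, 8:12] = 300.0
        params = SegmentationParams(
            blur_sigma_px=0.0, despeckle=False, threshold_low=100.0, threshold_high=700.0
        )
        prof = dual_threshold_profile(self.make(img), [self._roi(img.shape)], params)
        assert prof["aggregation_index"].iloc[0] == pytest.approx(0.0)

    def test_half_intensity_split_gives_half(self):
        # bright blob carries exactly half the supra-low intensity
        img = np.zeros((48, 48))
        img[5:9, 5:10] = 1000.0  # 20 px * 1000 = 20000, supra-high
        img[30:34, 20:30] = 500.0  # 40 px * 500 = 20000, low only
        params = SegmentationParams(
            blur_sigma_px=0.0, despeckle=False, threshold_low=100.0, threshold_high=700.0
        )
        prof = dual_threshold_profile(self.make(img), [self._roi(img.shape)], params)
        assert prof["aggregation_index"].iloc[0] == pytest.approx(0.5)

    def test_empty_low_mask_gives_nulls(self):
        img = np.zeros((32, 32))
        params = SegmentationParams(
            blur_sigma_px=0.0, despeckle=False, threshold_low=100.0, threshold_high=700.0
        )
        prof = dual_threshold_profile(self.make(img), [self._roi(img.shape)], params)
        assert prof["aggregation_index"].isna().all()

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_aggregation_index_bounded(self, config, seed):
        scene, _ = generate_scene(preset("ala16", seed=seed))
        rois = segment_nuclei(scene, config.nuclei)
        prof = dual_threshold_profile(scene, rois, config.aggregate)
        vals = prof["aggregation_index"].dropna()
        assert ((vals >= 0) & (vals <= 1)).all()
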