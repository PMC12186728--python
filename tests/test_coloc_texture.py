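import numpy as np
import pytest
from hypothesis import given, strategies as st

from punctakit import (
    NucleusROI,
    compartment_ratio,
    generate_mrna_channel,
    generate_scene,
    glcm_texture,
    manders_pearson,
    preset,
    segment_nuclei,
)
from punctakit.coloc_texture import glcm_matrix, quantize_roi
from punctakit.synth import NoiseModel


def roi_with_ring(shape=(32, 32)):
    nucleus = np.zeros(shape, dtype=bool)
    nucleus[8:24, 8:24] = True
    ring = np.zeros(shape, dtype=bool)
    ring[4:28, 4:28] = True
    ring &= ~nucleus
    return NucleusROI(1, nucleus, ring, (15.5, 15.5), float(nucleus.sum()) * 0.01)


class TestMandersPearson:
    def test_identical_channels_and_masks_give_ones(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(10, 100, size=(32, 32))
        mask = np.zeros((32, 32), dtype=bool)
        mask[10:20, 10:20] = True
        roi = roi_with_ring()
        res = manders_pearson(img, img, mask, mask, roi, 0.1)
        assert res.m1 == pytest.approx(1.0)
        assert res.m2 == pytest.approx(1.0)
        assert res.pearson_r == pytest.approx(1.0)

    def test_disjoint_masks_give_zero(self):
        rng = np.random.default_rng(1)
        img_a = rng.uniform(10, 100, size=(32, 32))
        img_b = rng.uniform(10, 100, size=(32, 32))
        mask_a = np.zeros((32, 32), dtype=bool)
        mask_a[10:14, 10:14] = True
        mask_b = np.zeros((32, 32), dtype=bool)
        mask_b[18:22, 18:22] = True
        res = manders_pearson(img_a, img_b, mask_a, mask_b, roi_with_ring(), 0.1)
        assert res.m1 == pytest.approx(0.0)
        assert res.m2 == pytest.approx(0.0)
        assert res.overlap_area_um2 == 0.0

    def test_empty_mask_gives_null_coefficient(self):
        img = np.ones((32, 32))
        empty = np.zeros((32, 32), dtype=bool)
        full = np.ones((32, 32), dtype=bool)
        res = manders_pearson(img, img, empty, full, roi_with_ring(), 0.1)
        assert res.m1 is None

    def test_background_subtraction_removes_offset_dilution(self):
        # half the signal in the mask; constant offset dilutes M2 unless removed
        img_b = np.full((32, 32), 10.0)
        mask_a = np.zeros((32, 32), dtype=bool)
        mask_a[10:14, 10:14] = True
        img_b[mask_a] += 500.0
        roi = roi_with_ring()
        comp = roi.mask | roi.perinuclear_mask
        naive = manders_pearson(img_b, img_b, mask_a, comp, roi, 0.1)
        corrected = manders_pearson(
            img_b, img_b, mask_a, comp, roi, 0.1, background_a=10.0, background_b=10.0
        )
        assert corrected.m2 == pytest.approx(1.0)
        assert naive.m2 < corrected.m2

    def test_recovers_generator_coloc_fraction(self, config):
        p = preset(
            "ala10", seed=13, mrna_coloc_fraction=0.5, noise_model=NoiseModel(0.0, False)
        )
        scene, truth = generate_scene(p)
        scene, truth = generate_mrna_channel(scene, truth, p)
        from punctakit import segment_puncta
        from punctakit.coloc_texture import estimate_background

        rois = segment_nuclei(scene, config.nuclei)
        labels, stubs = segment_puncta(scene, rois, config.aggregate, "low")
        mrna = scene.channel("mrna")
        bg = estimate_background(mrna, rois)
        with_puncta = set(stubs.loc[~stubs["extranuclear"], "nucleus_id"])
        checked = 0
        for roi in rois:
            if roi.nucleus_id not in with_puncta:
                continue
            comp = roi.mask | roi.perinuclear_mask
            croi = NucleusROI(roi.nucleus_id, comp, roi.perinuclear_mask, roi.centroid, roi.area_um2)
            res = manders_pearson(
                scene.channel("aggregate"), mrna, labels > 0, comp, croi, 0.1, background_b=bg
            )
            assert res.m2 == pytest.approx(0.5, abs=0.05)
            checked += 1
        assert checked > 0


class TestCompartmentRatio:
    def test_equal_intensity_gives_zero(self):
        res = compartment_ratio(np.full((32, 32), 50.0), roi_with_ring())
        assert res.log2_ratio == pytest.approx(0.0)

    def test_fourfold_nuclear_enrichment_gives_two(self):
        roi = roi_with_ring()
        img = np.full((32, 32), 25.0)
        img[roi.mask] = 100.0
        res = compartment_ratio(img, roi)
        assert res.log2_ratio == pytest.approx(2.0)

    def test_empty_ring_gives_null(self):
        roi = roi_with_ring()
        bare = NucleusROI(1, roi.mask, np.zeros_like(roi.mask), roi.centroid, roi.area_um2)
        res = compartment_ratio(np.ones((32, 32)), bare)
        assert res.log2_ratio is None

    def test_nuclear_retained_mrna_gives_positive_ratio(self, config):
        p = preset(
            "ala10",
            seed=14,
            mrna_cytoplasm_fraction=0.0,
            noise_model=NoiseModel(0.0, False),
        )
        scene, truth = generate_scene(p)
        scene, truth = generate_mrna_channel(scene, truth, p)
        rois = segment_nuclei(scene, config.nuclei)
        mrna = scene.channel("mrna")
        inner = [r for r in rois if not r.touches_border]
        assert inner
        for roi in inner:
            res = compartment_ratio(mrna, roi)
            assert res.log2_ratio is not None and res.log2_ratio > 0


# hand-enumerated oracle for the 4x4 toy image, offset (0, 1), 4 levels:
# 12 horizontal pairs -> symmetrized counts /24; entropy (nats) and IDM below
TOY = np.array([[0, 0, 1, 1], [0, 0, 1, 1], [0, 2, 2, 2], [2, 2, 3, 3]])
TOY_ENTROPY = 2.0947290475276487
TOY_IDM = 97.0 / 120.0


def brute_force_glcm(img, mask, offset, n_levels):
    counts = np.zeros((n_levels, n_levels))
    h, w = img.shape
    dr, dc = offset
    for r in range(h):
        for c in range(w):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and mask[r, c] and mask[rr, cc]:
                counts[img[r, c], img[rr, cc]] += 1
                counts[img[rr, cc], img[r, c]] += 1
    return counts / counts.sum()


class TestGlcmTexture:
    def _roi(self, shape):
        mask = np.ones(shape, dtype=bool)
        return NucleusROI(1, mask, np.zeros(shape, bool), (0, 0), float(mask.sum()) * 0.01)

    def test_toy_image_matches_hand_enumeration(self):
        res = glcm_texture(TOY.astype(float), self._roi(TOY.shape), offset=(0, 1), n_levels=4)
        oracle = brute_force_glcm(TOY, np.ones_like(TOY, bool), (0, 1), 4)
        np.testing.assert_allclose(res.glcm, oracle, atol=1e-15)
        assert res.entropy == pytest.approx(TOY_ENTROPY, abs=1e-12)
        assert res.idm == pytest.approx(TOY_IDM, abs=1e-12)

    def test_constant_region_gives_entropy_zero_idm_one(self):
        res = glcm_texture(np.full((8, 8), 42.0), self._roi((8, 8)), n_levels=16)
        assert res.entropy == 0.0
        assert res.idm == 1.0

    def test_checkerboard_idm_is_half(self):
        board = np.indices((8, 8)).sum(axis=0) % 2
        res = glcm_texture(board.astype(float), self._roi((8, 8)), offset=(0, 1), n_levels=2)
        assert res.idm == pytest.approx(0.5, abs=1e-12)

    def test_matches_library_glcm_on_rectangular_roi(self):
        # independent cross-check against skimage on a full-rectangle mask
        from skimage.feature import graycomatrix

        rng = np.random.default_rng(3)
        img = rng.integers(0, 8, size=(16, 16))
        roi = self._roi((16, 16))
        quant = quantize_roi(img.astype(float), roi.mask, 8)
        ours = glcm_matrix(quant, roi.mask, (0, 1), 8)
        theirs = graycomatrix(
            quant.astype(np.uint8), [1], [0], levels=8, symmetric=True, normed=True
        )[:, :, 0, 0]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    @given(seed=st.integers(0, 500))
    def test_glcm_normalized_and_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 255, size=(12, 12))
        res = glcm_texture(img, self._roi((12, 12)), n_levels=16)
        assert res.glcm.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(res.glcm, res.glcm.T, atol=1e-15)
        assert res.entropy <= np.log(16**2) + 1e-12

    def test_entropy_maximal_for_uniform_matrix(self):
        n = 8
        uniform = np.full((n, n), 1.0 / n**2)
        p = uniform[uniform > 0]
        assert -(p * np.log(p)).sum() == pytest.approx(np.log(n**2), abs=1e-12)

    def test_noise_increases_entropy_and_decreases_idm(self):
        # fixed-range quantization: level occupancy tracks noise amplitude
        roi = self._roi((32, 32))
        entropies, idms = [], []
        for sd in (1.0, 5.0, 20.0):
            es, hs = [], []
            for seed in range(10):
                rng = np.random.default_rng(seed)
                img = 100.0 + rng.normal(0, sd, size=(32, 32))
                res = glcm_texture(img, roi, n_levels=256, intensity_range=(0.0, 255.0))
                es.append(res.entropy)
                hs.append(res.idm)
            entropies.append(np.mean(es))
            idms.append(np.mean(hs))
        assert entropies[0] < entropies[1] < entropies[2]
        assert idms[0] > idms[1] > idms[2]

    def test_mask_too_small_raises(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[3, 3] = True
        roi = NucleusROI(1, mask, np.zeros((8, 8), bool), (3, 3), 0.01)
        with pytest.raises(ValueError):
            glcm_texture(np.ones((8, 8)), roi, offset=(0, 1), n_levels=4)
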