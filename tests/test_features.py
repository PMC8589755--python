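"""Texture, first-order and shape features: worked examples, invariants, and
full equivalence against the independent brute-force oracles."""

import numpy as np
import pytest

import oracles
from conftest import random_roi
from usradiomics.datatypes import AnnotatedImage, DiscretizedROI
from usradiomics.features import (
    ExtractionConfig,
    RadiomicsExtractor,
    firstorder_features,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    shape2d_features,
)
from usradiomics.features import _matrices


def _roi_from(levels, mask=None):
    levels = np.asarray(levels, dtype=np.int64)
    if mask is None:
        mask = levels > 0
    return DiscretizedROI(
        levels=levels, mask=np.asarray(mask, bool),
        n_levels=int(levels.max()), bin_width=1.0,
    )


# ---------------------------------------------------------------------------
# Worked examples
# ---------------------------------------------------------------------------

class TestWorkedExamples:
    def test_constant_roi_glcm(self):
        roi = _roi_from(np.ones((4, 4)))
        feats = glcm_features(roi)
        assert feats["Contrast"] == pytest.approx(0.0)
        assert feats["JointEnergy"] == pytest.approx(1.0)
        assert feats["Correlation"] == 1.0  # degenerate convention
        assert feats["Mcc"] == 1.0

    def test_checkerboard_glcm_horizontal(self):
        board = np.indices((4, 4)).sum(axis=0) % 2 + 1
        roi = _roi_from(board)
        # every horizontal pair alternates levels: only off-diagonal mass
        counts = _matrices.glcm(roi)[0]
        assert counts[0, 0] == 0 and counts[1, 1] == 0
        p = counts / counts.sum()
        contrast = (p * np.array([[0, 1], [1, 0]])).sum()
        assert contrast == pytest.approx(1.0)

    def test_glcm_normalization_per_angle(self, rng):
        roi = random_roi(rng)
        mats = _matrices.glcm(roi)
        for a in range(4):
            assert mats[a].sum() > 0
            assert (mats[a] / mats[a].sum()).sum() == pytest.approx(1.0)

    def test_single_row_runs(self):
        roi = _roi_from(np.full((1, 7), 2))
        feats = glrlm_features(roi)
        # horizontal direction sees one run of 7; the others see 7 runs of 1
        mats = _matrices.glrlm(roi)
        assert mats[0][1, 6] == 1  # level 2, length 7 at 0 degrees
        assert mats[2][1, 0] == 7  # 90 degrees: 7 unit runs
        # run-length non-uniformity at 0 degrees = 1 (single run)
        counts = {(2, 7): 1}
        assert oracles._rl_features(counts, 7, oracles.GLRLM_NAMES)[
            "RunLengthNonUniformity"
        ] == pytest.approx(1.0)

    def test_alternating_sequence_short_run_emphasis(self):
        seq = np.array([[1, 2] * 5])
        roi = _roi_from(seq)
        feats = glrlm_features(roi)
        assert feats["ShortRunEmphasis"] == pytest.approx(1.0)  # all runs length 1

    def test_run_conservation(self, rng):
        roi = random_roi(rng)
        mats = _matrices.glrlm(roi)
        lengths = np.arange(1, mats.shape[2] + 1)
        for a in range(4):
            assert (mats[a] * lengths).sum() == roi.mask.sum()

    def test_glszm_two_blobs(self):
        levels = np.zeros((6, 10), dtype=int)
        levels[0, 0:3] = 2  # zone of size 3
        levels[3, 5:10] = 2  # disjoint zone of size 5
        roi = _roi_from(levels)
        mat = _matrices.glszm(roi)
        sizes = sorted(np.flatnonzero(mat[1]) + 1)
        assert sizes == [3, 5]
        assert mat[1, 2] == 1 and mat[1, 4] == 1

    def test_glszm_conservation(self, rng):
        roi = random_roi(rng)
        mat = _matrices.glszm(roi)
        sizes = np.arange(1, mat.shape[1] + 1)
        assert (mat * sizes).sum() == roi.mask.sum()

    def test_gldm_constant_3x3(self):
        roi = _roi_from(np.ones((3, 3)))
        mat = _matrices.gldm(roi)
        assert mat[0, 8] == 1  # center pixel has 8 equal neighbors
        assert mat.sum() == 9  # every pixel counted once

    def test_gldm_isolated_pixel(self):
        levels = np.array([[1, 1, 1], [1, 2, 1], [1, 1, 1]])
        roi = _roi_from(levels)
        mat = _matrices.gldm(roi)
        assert mat[1, 0] == 1  # the level-2 pixel has dependence 0

    def test_firstorder_constant(self):
        img = np.full((4, 4), 9.0)
        roi = _roi_from(np.ones((4, 4)))
        feats = firstorder_features(img, roi)
        assert feats["Mean"] == 9.0
        assert feats["Variance"] == 0.0
        assert feats["Entropy"] == 0.0
        assert feats["Uniformity"] == 1.0
        assert feats["Skewness"] == 0.0

    def test_firstorder_small_example(self):
        img = np.array([[1.0, 2.0], [3.0, 4.0]])
        roi = _roi_from(np.ones((2, 2)))
        feats = firstorder_features(img, roi)
        assert feats["Mean"] == pytest.approx(2.5)
        assert feats["Range"] == pytest.approx(3.0)


# ---------------------------------------------------------------------------
# Oracle equivalence (the hard gate)
# ---------------------------------------------------------------------------

class TestOracleEquivalence:
    N_TRIALS = 100

    def test_all_families_match_brute_force(self):
        """Every texture + first-order feature equals its loop-and-dict
        brute-force recomputation on random 8x8 ROIs with <= 6 levels."""
        rng = np.random.default_rng(2024)
        for trial in range(self.N_TRIALS):
            roi = random_roi(rng)
            image = rng.uniform(0, 100, roi.levels.shape)
            pairs = [
                (glcm_features(roi), oracles.glcm_features(roi.levels, roi.mask, roi.n_levels)),
                (glrlm_features(roi), oracles.glrlm_features(roi.levels, roi.mask, roi.n_levels)),
                (glszm_features(roi), oracles.glszm_features(roi.levels, roi.mask, roi.n_levels)),
                (gldm_features(roi), oracles.gldm_features(roi.levels, roi.mask, roi.n_levels)),
                (
                    firstorder_features(image, roi),
                    oracles.firstorder_features(image, roi.levels, roi.mask, roi.n_levels),
                ),
            ]
            for ours, reference in pairs:
                assert set(ours) == set(reference)
                for name in ours:
                    assert ours[name] == pytest.approx(
                        reference[name], abs=1e-9, rel=1e-9
                    ), f"trial {trial}: {name}"


# ---------------------------------------------------------------------------
# Shape
# ---------------------------------------------------------------------------

class TestShape:
    @staticmethod
    def _disk(radius, size=None):
        size = size or int(2 * radius + 8)
        yy, xx = np.mgrid[:size, :size]
        c = (size - 1) / 2
        return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2

    def test_disk_is_extremal(self):
        feats = shape2d_features(self._disk(50))
        assert feats["Sphericity"] == pytest.approx(1.0, abs=0.05)
        assert feats["SphericalDisproportion"] == pytest.approx(1.0, abs=0.06)
        assert feats["Elongation"] == pytest.approx(1.0, abs=0.02)

    def test_rectangle_elongation(self):
        # 2:1 axis-aligned rectangle; eigenvalues of a uniform rectangle
        # give a minor/major axis ratio of 1/2 (brute-force moments)
        mask = np.zeros((70, 70), bool)
        mask[10:50, 10:30] = True
        coords = np.argwhere(mask).astype(float)
        cov = np.cov(coords.T, bias=True)
        eig = np.sort(np.linalg.eigvalsh(cov))
        expected = float(np.sqrt(eig[0] / eig[1]))
        feats = shape2d_features(mask)
        assert feats["Elongation"] == pytest.approx(expected, abs=1e-12)
        assert feats["Elongation"] == pytest.approx(0.5, abs=0.02)

    def test_sphericity_disproportion_identity(self, rng):
        from usradiomics.synthetic import DEFAULT_MALIGNANT_SPEC, generate_lesion_mask

        mask = generate_lesion_mask(DEFAULT_MALIGNANT_SPEC, 5)
        feats = shape2d_features(mask)
        assert feats["Sphericity"] <= 1.0
        assert feats["Sphericity"] * feats["SphericalDisproportion"] == pytest.approx(1.0)

    def test_scale_invariance(self):
        small = shape2d_features(self._disk(20))
        large = shape2d_features(self._disk(60))
        assert small["Sphericity"] == pytest.approx(large["Sphericity"], abs=0.03)
        assert small["Elongation"] == pytest.approx(large["Elongation"], abs=0.03)

    def test_empty_and_split_masks_rejected(self):
        with pytest.raises(ValueError):
            shape2d_features(np.zeros((5, 5), bool))
        split = np.zeros((8, 8), bool)
        split[0, 0] = split[7, 7] = True
        with pytest.raises(ValueError):
            shape2d_features(split)


# ---------------------------------------------------------------------------
# Whole-lesion extraction
# ---------------------------------------------------------------------------

class TestExtractAll:
    def _lesion(self, rng, size=48):
        mask = np.zeros((size, size), bool)
        mask[10:38, 12:36] = True
        pixels = rng.uniform(20, 200, (size, size))
        return AnnotatedImage(pixels, mask, "LX", "benign")

    def test_manifest_size_defaults(self):
        assert len(ExtractionConfig().manifest()) == 4 + 10 * 87

    def test_manifest_shrinks_without_wavelet(self):
        full = len(ExtractionConfig().manifest())
        no_wav = len(ExtractionConfig(wavelet=None).manifest())
        assert full - no_wav == 4 * 87

    def test_extraction_is_deterministic(self, rng):
        lesion = self._lesion(rng)
        ex = RadiomicsExtractor(ExtractionConfig(log_sigmas=(2.0,), wavelet=None))
        a = ex.extract(lesion)
        b = ex.extract(lesion)
        assert a == b

    def test_translation_invariance_of_texture(self, rng):
        pixels = rng.uniform(0, 255, (64, 64))
        mask = np.zeros((64, 64), bool)
        mask[8:24, 8:24] = True
        shift = (20, 25)
        pixels2 = np.roll(pixels, shift, axis=(0, 1))
        mask2 = np.roll(mask, shift, axis=(0, 1))
        cfg = ExtractionConfig(log_sigmas=(), wavelet=None, normalize=False,
                               include_shape=False)
        ex = RadiomicsExtractor(cfg)
        a = ex.extract(AnnotatedImage(pixels, mask, "A", "benign"))
        b = ex.extract(AnnotatedImage(pixels2, mask2, "B", "benign"))
        for key in a:
            assert a[key] == pytest.approx(b[key], rel=1e-12), key

    def test_rotation_invariance_of_angle_averaged_texture(self, rng):
        pixels = rng.uniform(0, 255, (64, 64))
        mask = np.zeros((64, 64), bool)
        mask[8:24, 10:30] = True
        cfg = ExtractionConfig(log_sigmas=(), wavelet=None, normalize=False,
                               include_shape=False, families=("glcm", "glrlm"))
        ex = RadiomicsExtractor(cfg)
        a = ex.extract(AnnotatedImage(pixels, mask, "A", "benign"))
        b = ex.extract(
            AnnotatedImage(np.rot90(pixels).copy(), np.rot90(mask).copy(), "B", "benign")
        )
        for key in a:
            assert a[key] == pytest.approx(b[key], rel=1e-9), key

    def test_error_annotated_with_lesion_id(self):
        flat = AnnotatedImage(np.full((32, 32), 5.0), np.ones((32, 32), bool),
                              "L777", "benign")
        ex = RadiomicsExtractor()
        with pytest.raises(RuntimeError, match="L777"):
            ex.extract(flat)
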