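import numpy as np
import pytest
from scipy import stats

from kmotion import features as feat
from kmotion import phantoms as ph
from oracles import bilinear, brute_glcm, brute_haralick_13


@pytest.fixture()
def roi32():
    return feat.ROI(0, 0, 32, 32)


class TestComputeRoi:
    def _mask(self, shape, r0, r1, c0, c1):
        m = np.zeros(shape, dtype=bool)
        m[r0:r1, c0:c1, shape[2] // 2] = True
        return ph.HeartMask(m)

    def test_single_mask_enlarged_ten_percent_total(self):
        mask = self._mask((256, 256, 8), 50, 150, 80, 160)  # bbox 100 x 80
        roi = feat.compute_roi([mask], (256, 256))
        assert (roi.height, roi.width) == (110, 88)

    def test_no_masks_means_full_image(self):
        roi = feat.compute_roi(None, (64, 48))
        assert (roi.row, roi.col, roi.height, roi.width) == (0, 0, 64, 48)

    def test_max_per_dimension_over_subjects(self):
        m1 = self._mask((256, 256, 8), 100, 160, 100, 160)  # 60 x 60
        m2 = self._mask((256, 256, 8), 80, 180, 110, 150)  # 100 x 40
        roi = feat.compute_roi([m1, m2], (256, 256))
        assert (roi.height, roi.width) == (110, 66)

    def test_empty_mask_rejected(self):
        m = np.zeros((32, 32, 8), dtype=bool)
        m[2, 2, 0] = True  # non-empty volume but empty central slice
        with pytest.raises(ValueError):
            feat.compute_roi([ph.HeartMask(m)], (32, 32))


class TestSampleFeatureSpecs:
    def test_deterministic(self, roi32):
        a = feat.sample_feature_specs(5, roi32, {"box": 10, "line": 5, "histogram_global": 2})
        b = feat.sample_feature_specs(5, roi32, {"box": 10, "line": 5, "histogram_global": 2})
        assert a == b

    def test_patches_and_lines_inside_roi(self):
        roi = feat.ROI(10, 20, 40, 30)
        specs = feat.sample_feature_specs(1, roi, {"box": 50, "line": 50, "histogram_patch": 20})
        for s in specs.specs:
            if s.kind in ("box", "histogram_patch"):
                r, c, h, w = s.geometry
                assert roi.contains(r, c) and roi.contains(r + h - 1, c + w - 1)
            elif s.kind == "line":
                r0, c0, angle, length = s.geometry
                r1 = r0 + (length - 1) * np.cos(angle)
                c1 = c0 + (length - 1) * np.sin(angle)
                assert roi.contains(r0, c0) and roi.contains(r1, c1)

    def test_patch_positions_uniform_over_feasible_region(self):
        roi = feat.ROI(0, 0, 20, 20)
        specs = feat.sample_feature_specs(2, roi, {"box": 10000}, edge_range=(4, 4))
        rows = np.array([s.geometry[0] for s in specs.specs])
        cols = np.array([s.geometry[1] for s in specs.specs])
        # with a fixed 4x4 patch, feasible top-left corners are 0..16 each axis
        for vals in (rows, cols):
            counts = np.bincount(vals, minlength=17)
            chi2 = stats.chisquare(counts)
            assert chi2.pvalue > 0.01

    def test_impossible_containment_rejected(self, roi32):
        with pytest.raises(ValueError):
            feat.sample_feature_specs(0, roi32, {"box": 1}, edge_range=(64, 128))


class TestBoxFeatures:
    def test_constant_patch(self):
        img = np.full((32, 32), 3.5)
        mean, var = feat.box_features(img, feat.FeatureSpec("box", (4, 4, 8, 8)))
        assert (mean, var) == (3.5, 0.0)

    def test_hand_arithmetic(self):
        img = np.zeros((16, 16))
        img[0, 0], img[0, 1], img[1, 0], img[1, 1] = 0, 0, 2, 2
        mean, var = feat.box_features(img, feat.FeatureSpec("box", (0, 0, 2, 2)))
        assert (mean, var) == (1.0, 1.0)

    def test_matches_two_pass_loop_oracle(self, rng):
        img = rng.random((32, 32))
        spec = feat.FeatureSpec("box", (5, 7, 11, 13))
        mean, var = feat.box_features(img, spec)
        vals = [img[r, c] for r in range(5, 16) for c in range(7, 20)]
        m = sum(vals) / len(vals)
        v = sum((x - m) ** 2 for x in vals) / len(vals)
        assert mean == pytest.approx(m, abs=1e-12)
        assert var == pytest.approx(v, abs=1e-12)


class TestLineFeatures:
    def test_constant_image(self):
        img = np.full((32, 32), 2.0)
        std, rng_ = feat.line_features(img, feat.FeatureSpec("line", (4.0, 4.0, 0.0, 10)))
        assert (std, rng_) == (0.0, 0.0)

    def test_axis_aligned_hand_arithmetic(self):
        img = np.zeros((16, 16))
        img[2:6, 3] = [0, 1, 2, 3]
        std, span = feat.line_features(img, feat.FeatureSpec("line", (2.0, 3.0, 0.0, 4)))
        assert std == pytest.approx(np.sqrt(1.25))
        assert span == 3.0

    def test_diagonal_matches_pointwise_bilinear_oracle(self, rng):
        img = rng.random((32, 32))
        angle = np.pi / 5
        spec = feat.FeatureSpec("line", (3.0, 2.0, angle, 12))
        std, span = feat.line_features(img, spec)
        pts = [
            bilinear(img, 3.0 + t * np.cos(angle), 2.0 + t * np.sin(angle)) for t in range(12)
        ]
        assert std == pytest.approx(np.std(pts), abs=1e-10)
        assert span == pytest.approx(max(pts) - min(pts), abs=1e-10)


class TestHistogramFeatures:
    def test_constant_values_degenerate_conventions(self):
        mean, var, skew, kurt, entropy, energy = feat.histogram_features(np.full(100, 0.7), 16)
        assert mean == pytest.approx(0.7)
        assert (var, skew, kurt, entropy, energy) == (0.0, 0.0, 0.0, 0.0, 1.0)

    def test_two_equal_bins(self):
        vals = np.array([0.0] * 50 + [1.0] * 50)
        *_, entropy, energy = feat.histogram_features(vals, 2)
        assert entropy == pytest.approx(1.0)
        assert energy == pytest.approx(0.5)

    def test_eight_equal_bins_entropy(self):
        vals = np.repeat(np.arange(8), 10) + 0.5
        *_, entropy, energy = feat.histogram_features(vals, 8)
        assert entropy == pytest.approx(3.0)

    def test_bin_count_matters(self, rng):
        vals = rng.random(500)
        f8 = feat.histogram_features(vals, 8)
        f64 = feat.histogram_features(vals, 64)
        assert f8[4] != f64[4]  # entropy depends on binning

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            feat.histogram_features([], 8)


class TestHaralickFeatures:
    def test_constant_roi_degenerate_vector(self):
        v = feat.haralick_features(np.full((16, 16), 0.3))
        asm, contrast, correlation = v[0], v[1], v[2]
        assert asm == pytest.approx(1.0)
        assert contrast == 0.0
        assert correlation == 0.0
        assert v[7] == 0.0 and v[8] == 0.0  # sum entropy, entropy

    def test_matches_brute_force_enumeration(self):
        img = np.array(
            [[0, 0, 1, 1], [0, 0, 1, 1], [0, 2, 2, 2], [2, 2, 3, 3]], dtype=float
        ) / 3.0
        levels = 4
        got = feat.haralick_features(img, levels=levels)
        # quantize exactly as the contract defines: min-max to `levels` bins
        lo, hi = img.min(), img.max()
        q = np.minimum((levels * (img - lo) / (hi - lo)).astype(int), levels - 1)
        stats13 = [
            brute_haralick_13(brute_glcm(q, levels, off))
            for off in [(0, 1), (1, 0), (1, 1), (1, -1)]
        ]
        want = np.mean(stats13, axis=0)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_quarter_turn_invariance(self, rng):
        img = rng.random((20, 20))
        base = feat.haralick_features(img)
        for k in (1, 2, 3):
            np.testing.assert_allclose(feat.haralick_features(np.rot90(img, k)), base, atol=1e-12)


class TestRotationInvarianceStructure:
    """Whole-ROI features are rotation invariant; localized ones are not."""

    def test_global_histogram_invariant_under_quarter_turns(self, rng):
        img = rng.random((24, 24))
        base = feat.histogram_features(img, 16)
        for k in (1, 2, 3):
            rot = feat.histogram_features(np.rot90(img, k), 16)
            np.testing.assert_allclose(rot, base, atol=1e-12)

    def test_localized_features_not_invariant(self, rng):
        img = rng.random((24, 24))
        img[:12] += 1.0  # strong asymmetry
        box = feat.FeatureSpec("box", (1, 1, 6, 6))
        line = feat.FeatureSpec("line", (2.0, 2.0, 0.3, 8))
        rot = np.rot90(img, 1).copy()
        assert feat.box_features(img, box) != feat.box_features(rot, box)
        assert feat.line_features(img, line) != feat.line_features(rot, line)

    def test_all_features_finite_even_on_constant_images(self):
        roi = feat.ROI(0, 0, 24, 24)
        specs = feat.sample_feature_specs(
            0, roi, {"box": 5, "line": 5, "histogram_global": 2, "histogram_patch": 2, "texture": 1}
        )
        vec = feat.extract_features(np.full((24, 24), 0.5), specs)
        assert np.all(np.isfinite(vec))


class TestExtractFeatureMatrix:
    def test_column_arithmetic(self, rng, roi32):
        specs = feat.sample_feature_specs(0, roi32, {"box": 10})
        images = [rng.random((32, 32)) for _ in range(4)]
        m = feat.extract_feature_matrix(images, [0, 1, 0, 1], ["a", "b", "c", "d"], specs)
        assert m.values.shape == (4, 20)

    def test_deterministic(self, rng, roi32):
        specs = feat.sample_feature_specs(0, roi32, {"box": 5, "texture": 1})
        images = [rng.random((32, 32)) for _ in range(3)]
        m1 = feat.extract_feature_matrix(images, [0, 1, 0], ["a", "b", "c"], specs)
        m2 = feat.extract_feature_matrix(images, [0, 1, 0], ["a", "b", "c"], specs)
        assert np.array_equal(m1.values, m2.values)

    def test_duplicate_subject_rejected(self, rng, roi32):
        specs = feat.sample_feature_specs(0, roi32, {"box": 5})
        images = [rng.random((32, 32)) for _ in range(2)]
        with pytest.raises(ValueError):
            feat.extract_feature_matrix(images, [0, 1], ["a", "a"], specs)

    def test_permuting_images_permutes_rows(self, rng, roi32):
        specs = feat.sample_feature_specs(0, roi32, {"box": 5, "line": 3})
        images = [rng.random((32, 32)) for _ in range(4)]
        m1 = feat.extract_feature_matrix(images, [0, 1, 0, 1], list("abcd"), specs)
        perm = [2, 0, 3, 1]
        m2 = feat.extract_feature_matrix(
            [images[i] for i in perm], [0, 0, 1, 1], ["c", "a", "d", "b"], specs
        )
        assert np.array_equal(m2.values, m1.values[perm])

    def test_frame_round_trip(self, rng, roi32):
        specs = feat.sample_feature_specs(0, roi32, {"box": 2})
        images = [rng.random((32, 32)) for _ in range(2)]
        m = feat.extract_feature_matrix(images, [0, 1], ["a", "b"], specs)
        df = m.to_frame()
        assert list(df.columns[:2]) == ["subject_id", "label"]
        assert df.shape == (2, 6)
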