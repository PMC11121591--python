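"""Texture feature extraction: normalisation, quantisation, GLCM, features."""

import numpy as np
import pytest

from radgenmap.texture import (
    DEFAULT_OFFSETS,
    FEATURE_NAMES,
    GLCM_FEATURE_NAMES,
    HISTOGRAM_FEATURE_NAMES,
    DegenerateRoiWarning,
    Glcm,
    RoiImage,
    compute_glcm,
    extract_features,
    glcm_features,
    histogram_features,
    normalize_roi,
    quantize,
)

from _oracles import (
    brute_force_glcm,
    brute_force_glcm_features,
    brute_force_moments,
)
from conftest import random_roi


def roi(values, mask=None, **kw):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones_like(values, dtype=bool)
    return RoiImage(pixels=values, mask=np.asarray(mask, dtype=bool), **kw)


class TestNormalize:
    def test_affine_map_is_forced(self):
        img = roi([[10.0, 20.0, 30.0]])
        out = normalize_roi(img)
        assert np.allclose(out.pixels, [[0.0, 0.5, 1.0]])

    def test_idempotent_on_unit_range(self, rng):
        vals = rng.random((6, 6))
        vals.flat[0], vals.flat[1] = 0.0, 1.0
        img = roi(vals)
        out = normalize_roi(normalize_roi(img))
        assert np.allclose(out.pixels, normalize_roi(img).pixels)

    def test_unmasked_pixels_untouched(self, rng):
        vals = rng.normal(50, 10, (5, 5))
        mask = np.zeros((5, 5), bool)
        mask[1:4, 1:4] = True
        out = normalize_roi(roi(vals, mask))
        assert np.array_equal(out.pixels[~mask], vals[~mask])
        assert out.pixels[mask].min() == 0.0 and out.pixels[mask].max() == 1.0

    def test_constant_region_zeroed_with_warning(self):
        img = roi([[5.0, 5.0, 5.0]])
        with pytest.warns(DegenerateRoiWarning):
            out = normalize_roi(img)
        assert np.all(out.pixels == 0)


class TestQuantize:
    def test_bin_edges(self):
        img = roi([[0.0, 0.49, 0.51, 1.0]])
        assert quantize(img, 2).tolist() == [[1, 1, 2, 2]]

    def test_top_value_goes_to_top_bin(self):
        img = roi([[0.0, 1.0]])
        assert quantize(img, 4)[0, 1] == 4

    def test_level_histogram_conserves_mass(self, rng):
        vals = rng.random((10, 10))
        mask = rng.random((10, 10)) < 0.7
        mask.flat[:2] = True
        q = quantize(roi(vals * mask, mask), 8)
        assert (q > 0).sum() == mask.sum()
        assert q[~mask].sum() == 0

    def test_rejects_single_level(self):
        with pytest.raises(ValueError):
            quantize(roi([[0.0, 1.0]]), 1)


class TestGlcm:
    def test_constant_roi_single_atom(self):
        q = np.ones((4, 4), dtype=int)
        g = compute_glcm(q, levels=3)
        assert g.p[0, 0] == 1.0 and g.p.sum() == 1.0

    def test_two_by_two_horizontal(self):
        q = np.array([[1, 2], [1, 2]])
        g = compute_glcm(q, levels=2, offsets=[(0, 1)], symmetric=True)
        assert g.p[0, 1] == 0.5 and g.p[1, 0] == 0.5

    def test_matches_brute_force_enumeration(self, rng):
        """Pooled-offset, mask-strict GLCM equals explicit pair counting."""
        for _ in range(50):
            levels = int(rng.integers(2, 5))
            size = int(rng.integers(4, 9))
            q = random_roi(rng, size=size, levels=levels)
            counts = brute_force_glcm(q, levels, DEFAULT_OFFSETS, True)
            if counts.sum() == 0:
                continue
            g = compute_glcm(q, levels=levels)
            assert np.array_equal(g.p, counts / counts.sum())

    def test_normalisation_and_symmetry(self, rng):
        for _ in range(20):
            q = random_roi(rng, size=8, levels=6)
            g = compute_glcm(q, levels=6, symmetric=True)
            assert abs(g.p.sum() - 1.0) < 1e-12
            assert np.array_equal(g.p, g.p.T)
            assert (g.p >= 0).all()

    def test_zero_valid_pairs_raises(self):
        q = np.zeros((4, 4), dtype=int)
        q[0, 0] = 1
        q[3, 3] = 2  # no neighbouring in-mask pair
        with pytest.raises(ValueError, match="no valid in-mask pixel pair"):
            compute_glcm(q, levels=2, offsets=[(0, 1)])


class TestGlcmFeatures:
    def test_constant_image_closed_form(self):
        p = np.zeros((4, 4))
        p[0, 0] = 1.0
        f = glcm_features(Glcm(p, 4, ((0, 1),)))
        assert f["AngularSecondMoment"] == 1.0
        assert f["Entropy"] == 0.0
        assert f["Contrast"] == 0.0
        assert f["InverseDifference"] == 1.0
        assert f["SumAverage"] == 2.0
        assert f["SumEntropy"] == 0.0

    def test_checkerboard_closed_form(self):
        p = np.array([[0.0, 0.5], [0.5, 0.0]])
        f = glcm_features(Glcm(p, 2, ((0, 1),)))
        assert f["Contrast"] == 1.0
        assert f["AngularSecondMoment"] == 0.5
        assert f["Entropy"] == 1.0

    def test_catalogue_has_22_features(self, rng):
        q = random_roi(rng)
        f = glcm_features(compute_glcm(q, levels=4))
        assert tuple(f) == GLCM_FEATURE_NAMES
        assert len(f) == 22
        assert all(np.isfinite(v) for v in f.values())

    def test_matches_literal_formula_oracle(self, rng):
        """Every feature agrees with an independent transcription to 1e-10."""
        for _ in range(50):
            levels = int(rng.integers(2, 5))
            q = random_roi(rng, size=8, levels=levels)
            try:
                g = compute_glcm(q, levels=levels)
            except ValueError:
                continue
            ours = glcm_features(g)
            oracle = brute_force_glcm_features(g.p)
            for name in GLCM_FEATURE_NAMES:
                assert ours[name] == pytest.approx(oracle[name], abs=1e-10), name

    def test_range_invariants(self, rng):
        for _ in range(30):
            levels = int(rng.integers(2, 6))
            q = random_roi(rng, size=8, levels=levels)
            f = glcm_features(compute_glcm(q, levels=levels))
            assert 0 < f["AngularSecondMoment"] <= 1
            assert 0 <= f["Entropy"] <= 2 * np.log2(levels) + 1e-12
            assert 0 < f["InverseDifference"] <= 1
            assert f["Contrast"] >= 0

    def test_agrees_with_skimage_on_full_mask(self, rng):
        """Cross-check against scikit-image's co-occurrence on maskless input."""
        from skimage.feature import graycomatrix

        q = rng.integers(1, 5, size=(12, 12))
        ours = compute_glcm(q, levels=4, offsets=[(0, 1)], symmetric=True)
        theirs = graycomatrix(
            (q - 1).astype(np.uint8), distances=[1], angles=[0], levels=4,
            symmetric=True, normed=True,
        )[:, :, 0, 0]
        assert np.allclose(ours.p, theirs)


class TestHistogramFeatures:
    def test_two_point_distribution(self):
        f = histogram_features(roi([[0.0, 1.0]]))
        assert f["HistogramMean"] == 0.5
        assert f["HistogramVariance"] == 0.25

    def test_symmetric_distribution_has_zero_skewness(self):
        f = histogram_features(roi([[0.0, 0.25, 0.5, 0.75, 1.0]]))
        assert abs(f["HistogramSkewness"]) < 1e-12

    def test_matches_direct_summation_oracle(self, rng):
        for _ in range(20):
            vals = rng.random((7, 7))
            f = histogram_features(roi(vals))
            oracle = brute_force_moments(vals.ravel())
            for name in HISTOGRAM_FEATURE_NAMES:
                assert f[name] == pytest.approx(oracle[name], abs=1e-10), name

    def test_constant_region_convention(self):
        with pytest.warns(DegenerateRoiWarning):
            f = histogram_features(roi([[0.3, 0.3, 0.3]]))
        assert f["HistogramSkewness"] == 0.0
        assert f["HistogramKurtosis"] == 0.0


class TestExtractFeatures:
    def test_cohort_table_shape(self, small_cohort, cohort_tables):
        features, _, _ = cohort_tables
        assert features.shape == (15, 56)
        for col in features.columns:
            assert col.endswith(("_T2WI", "_ADC"))
        long = extract_features(
            [img for p in small_cohort for img in p.images.values()], long=True
        )
        assert long.shape == (30, 28)
        assert tuple(long.columns) == FEATURE_NAMES

    def test_deterministic(self, small_cohort):
        images = [img for p in small_cohort for img in p.images.values()]
        a = extract_features(images)
        b = extract_features(images)
        assert a.equals(b)

    def test_missing_modality_errors_with_patient_ids(self, small_cohort):
        images = [
            img
            for p in small_cohort
            for img in p.images.values()
            if not (p.patient_id == "P0001" and img.modality == "ADC")
        ]
        with pytest.raises(ValueError, match="P0001"):
            extract_features(images)

    def test_affine_rescale_invariance(self, rng):
        """Positive affine intensity rescaling leaves all features unchanged."""
        vals = rng.normal(100, 25, (16, 16))
        mask = np.ones((16, 16), bool)
        imgs_a = [
            RoiImage(vals, mask, modality=m, patient_id="X") for m in ("T2WI", "ADC")
        ]
        imgs_b = [
            RoiImage(3.5 * vals + 40.0, mask, modality=m, patient_id="X")
            for m in ("T2WI", "ADC")
        ]
        a = extract_features(imgs_a)
        b = extract_features(imgs_b)
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)
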