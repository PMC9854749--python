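import numpy as np
import pytest

from ivimtex.texture import (
    COARSENESS_CAP,
    FEATURE_NAMES,
    QuantizedROI,
    glcm_features,
    global_features,
    glrlm_features,
    ngtdm_features,
    quantize_roi,
    texture_vector,
)

from oracles import (
    glcm_features_bruteforce,
    glrlm_features_bruteforce,
    glrlm_runs_bruteforce,
    global_features_bruteforce,
    ngtdm_features_bruteforce,
    quantize_equalized_bruteforce,
)


def random_roi(rng, shape=(5, 5, 5), ng=6, mask_p=0.75):
    """Small random quantized ROI with a non-trivial mask."""
    mask = rng.random(shape) < mask_p
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    q = np.zeros(shape, dtype=np.int32)
    q[mask] = rng.integers(1, ng + 1, size=int(mask.sum()))
    return QuantizedROI(q, mask, ng)


class TestQuantize:
    def test_distinct_values_bijective_at_matching_levels(self):
        rng = np.random.default_rng(0)
        vals = rng.permutation(64).astype(float)
        vol = vals.reshape(4, 4, 4)
        q = quantize_roi(vol, np.ones((4, 4, 4), bool), Ng=64)
        # rank order preserved, each value its own level
        assert sorted(q.qvol.ravel()) == list(range(1, 65))
        flat = vol.ravel()
        qflat = q.qvol.ravel()
        assert np.all(qflat[np.argsort(flat)] == np.arange(1, 65))

    def test_constant_roi_maps_to_level_one(self):
        q = quantize_roi(np.full((3, 3, 3), 2.5), np.ones((3, 3, 3), bool))
        assert np.all(q.qvol == 1)

    def test_equal_frequency_counts_match_sort_split_oracle(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=1000)
        vol = vals.reshape(10, 10, 10)
        q = quantize_roi(vol, np.ones(vol.shape, bool), Ng=64)
        expected = quantize_equalized_bruteforce(vals, 64)
        np.testing.assert_array_equal(q.qvol.ravel(), expected)

    def test_uniform_binning_equal_width(self):
        vol = np.arange(8.0).reshape(2, 2, 2)
        q = quantize_roi(vol, np.ones((2, 2, 2), bool), Ng=4, method="uniform")
        np.testing.assert_array_equal(q.qvol.ravel(), [1, 1, 2, 2, 3, 3, 4, 4])

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            quantize_roi(np.zeros((2, 2, 2)), np.ones((2, 2, 2), bool), Ng=1)


class TestFeatureFamiliesAgainstOracles:
    @pytest.mark.parametrize("seed", range(10))
    def test_glcm_matches_pair_enumeration(self, seed):
        roi = random_roi(np.random.default_rng(seed))
        np.testing.assert_allclose(
            glcm_features(roi),
            glcm_features_bruteforce(roi.qvol, roi.mask), atol=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_glrlm_matches_run_enumeration(self, seed):
        roi = random_roi(np.random.default_rng(100 + seed))
        np.testing.assert_allclose(
            glrlm_features(roi),
            glrlm_features_bruteforce(roi.qvol, roi.mask), atol=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_ngtdm_matches_neighborhood_enumeration(self, seed):
        roi = random_roi(np.random.default_rng(200 + seed))
        np.testing.assert_allclose(
            ngtdm_features(roi),
            ngtdm_features_bruteforce(roi.qvol, roi.mask), atol=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_global_matches_moment_calculator(self, seed):
        roi = random_roi(np.random.default_rng(300 + seed))
        np.testing.assert_allclose(
            global_features(roi),
            global_features_bruteforce(roi.qvol, roi.mask), atol=1e-10)


class TestHandWorkedExamples:
    def test_glcm_two_level_block(self):
        q = np.array([[[1], [1]], [[2], [2]]], dtype=np.int32)
        mask = np.ones((2, 2, 1), bool)
        roi = QuantizedROI(q, mask, 2)
        np.testing.assert_allclose(
            glcm_features(roi), glcm_features_bruteforce(q, mask), atol=1e-12)

    def test_glrlm_single_line(self):
        # 1x1x4 single-level ROI: one run of length 4 along the axis,
        # four runs of length 1 in each of the other 12 directions
        q = np.ones((1, 1, 4), dtype=np.int32)
        mask = np.ones((1, 1, 4), bool)
        runs = glrlm_runs_bruteforce(q, mask)
        assert sorted(l for _, l in runs).count(4) == 1
        assert sum(l for _, l in runs) == 4 * 13
        roi = QuantizedROI(q, mask, 1)
        np.testing.assert_allclose(
            glrlm_features(roi), glrlm_features_bruteforce(q, mask),
            atol=1e-12)

    def test_glrlm_checkerboard(self):
        q = np.indices((3, 3, 1)).sum(axis=0) % 2 + 1
        mask = np.ones((3, 3, 1), bool)
        roi = QuantizedROI(q.astype(np.int32), mask, 2)
        np.testing.assert_allclose(
            glrlm_features(roi), glrlm_features_bruteforce(q, mask),
            atol=1e-12)

    def test_glrlm_single_voxel(self):
        roi = QuantizedROI(np.ones((1, 1, 1), np.int32),
                           np.ones((1, 1, 1), bool), 1)
        f = dict(zip(("SRE", "LRE", "GLN", "RLN", "RP"), glrlm_features(roi)))
        assert f["SRE"] == 1 and f["LRE"] == 1 and f["RP"] == 1

    def test_ngtdm_center_spike(self):
        q = np.ones((3, 3, 3), dtype=np.int32)
        q[1, 1, 1] = 2
        mask = np.ones((3, 3, 3), bool)
        roi = QuantizedROI(q, mask, 2)
        np.testing.assert_allclose(
            ngtdm_features(roi), ngtdm_features_bruteforce(q, mask),
            atol=1e-12)

    def test_global_simple_sets(self):
        roi = QuantizedROI(np.array([1, 2, 3, 4], np.int32).reshape(4, 1, 1),
                           np.ones((4, 1, 1), bool), 4)
        var, skew, kurt = global_features(roi)
        assert var == pytest.approx(5 / 3)
        assert skew == pytest.approx(0.0, abs=1e-12)
        roi2 = QuantizedROI(np.array([1, 1, 1, 5], np.int32).reshape(4, 1, 1),
                            np.ones((4, 1, 1), bool), 5)
        np.testing.assert_allclose(
            global_features(roi2),
            global_features_bruteforce(roi2.qvol, roi2.mask), atol=1e-12)


class TestDegenerateAndInvariance:
    def test_constant_roi_degenerate_vector(self):
        vec = texture_vector(np.full((4, 4, 4), 7.0), np.ones((4, 4, 4), bool))
        d = vec.as_dict()
        assert d["Energy"] == 1.0
        assert d["Contrast"] == 0.0 and d["Entropy"] == 0.0
        assert d["Dissimilarity"] == 0.0 and d["Correlation"] == 0.0
        assert d["GlobalVariance"] == 0.0
        assert d["GlobalSkewness"] == 0.0 and d["GlobalKurtosis"] == 0.0
        assert d["Coarseness"] == COARSENESS_CAP
        assert d["NGTDMContrast"] == 0.0
        assert np.all(np.isfinite(vec.values))

    def test_bounds_of_normalized_features(self):
        rng = np.random.default_rng(4)
        roi = random_roi(rng, ng=8)
        f = dict(zip(FEATURE_NAMES, np.concatenate([
            glcm_features(roi), glrlm_features(roi), global_features(roi),
            ngtdm_features(roi)])))
        assert 0 < f["Energy"] <= 1
        assert 0 < f["Homogeneity"] <= 1
        assert f["Coarseness"] > 0 and f["Busyness"] >= 0

    def test_glrlm_total_run_length_is_voxels_times_directions(self):
        rng = np.random.default_rng(6)
        roi = random_roi(rng)
        runs = glrlm_runs_bruteforce(roi.qvol, roi.mask)
        assert sum(l for _, l in runs) == roi.mask.sum() * 13

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(7)
        vol = rng.normal(size=(6, 6, 4))
        mask = rng.random((6, 6, 4)) < 0.8
        v1 = texture_vector(vol, mask, Ng=16)
        v2 = texture_vector(np.exp(3 * vol) + 5, mask, Ng=16)
        np.testing.assert_array_equal(v1.values, v2.values)

    def test_determinism(self):
        rng = np.random.default_rng(8)
        vol = rng.normal(size=(10, 10, 5))
        mask = np.ones(vol.shape, bool)
        v1 = texture_vector(vol, mask)
        v2 = texture_vector(vol.copy(), mask.copy())
        np.testing.assert_array_equal(v1.values, v2.values)

    def test_canonical_order_matches_group_attribution(self):
        # indices constrained by group membership: f9 GLCM, f12/f13/f16/f21
        # GLRLM, f29 NGTDM (1-based)
        assert FEATURE_NAMES[8] == "AutoCorrelation"          # f9: GLCM
        for i in (11, 12, 15, 20):                            # f12 f13 f16 f21
            assert FEATURE_NAMES[i] in ("LRE", "GLN", "RLN", "RP", "LGRE",
                                        "HGRE", "SRLGE", "SRHGE", "LRLGE",
                                        "LRHGE", "GLV", "RLV", "SRE")
        assert FEATURE_NAMES[28] == "Complexity"              # f29: NGTDM
        assert len(FEATURE_NAMES) == 30
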