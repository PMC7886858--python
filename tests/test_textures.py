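import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from radgp import (
    CONTRASTS,
    FeatureVector,
    TextureConfig,
    extract_all,
    first_order_features,
    gabor_features,
    generate_roi_stack,
    glcm_features,
    normalize_window,
)
from radgp.textures import glcm_matrix

grids_0_255 = arrays(np.int64, (8, 8), elements=st.integers(0, 255))


class TestNormalize:
    def test_affine_map_rounds_half_up(self):
        w = np.full((8, 8), 10.0)
        w[0, 0], w[0, 1] = 20.0, 15.0
        out = normalize_window(w)
        assert out[0, 0] == 255 and out[0, 1] == 128 and out[1, 1] == 0

    def test_constant_window_maps_to_zeros(self):
        assert np.all(normalize_window(np.full((8, 8), 7.3)) == 0)

    def test_endpoints_hit_0_and_255(self, rng):
        w = rng.normal(size=(8, 8))
        out = normalize_window(w)
        assert out.flat[np.argmin(w)] == 0 and out.flat[np.argmax(w)] == 255

    def test_rank_order_preserved(self, rng):
        w = rng.normal(size=(8, 8)).ravel()
        out = normalize_window(w.reshape(8, 8)).ravel()
        order = np.argsort(w)
        assert np.all(np.diff(out[order]) >= 0)


class TestFirstOrder:
    def test_eighteen_features_in_canonical_order(self):
        fv = first_order_features(np.zeros((8, 8), dtype=int))
        assert len(fv) == 18
        assert fv.names[:5] == ("Mean", "SD", "Energy", "TotalEnergy", "Entropy")
        assert fv.names[-3:] == ("Skewness", "Kurtosis", "Uniformity")

    def test_constant_grid_conventions(self):
        d = first_order_features(np.full((8, 8), 5, dtype=int)).as_dict()
        assert d["SD"] == 0 and d["Entropy"] == 0 and d["Range"] == 0
        assert d["Uniformity"] == 1 and d["Skewness"] == 0 and d["Kurtosis"] == 0

    def test_two_level_grid_hand_values(self):
        grid = np.tile([[0, 0], [255, 255]], (4, 4))
        d = first_order_features(grid).as_dict()
        assert d["Mean"] == pytest.approx(127.5)
        assert d["Range"] == 255
        assert d["Median"] == pytest.approx(127.5)
        assert d["Minimum"] == 0 and d["Maximum"] == 255


class TestGlcm:
    def test_constant_grid_degenerate_matrix(self):
        d = glcm_features(np.zeros((8, 8), dtype=int), 1).as_dict()
        assert d["Angular.Second.Moment_Avg_1"] == pytest.approx(1.0)
        assert d["Contrast_Avg_1"] == pytest.approx(0.0)
        assert d["Entropy_Avg_1"] == pytest.approx(0.0)

    def test_matrix_normalized(self, rng):
        grid = rng.integers(0, 256, (8, 8))
        P = glcm_matrix(grid, 1)
        assert P.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(P, P.T, atol=1e-12)

    def test_stripe_contrast_matches_exhaustive_pair_counting(self):
        # vertical stripes of two gray levels; horizontal pairs alternate
        grid = np.tile([0, 255], (8, 4))
        q = grid * 16 // 256  # quantized levels, as the extractor sees them
        pairs = []
        for r in range(8):
            for c in range(7):  # 0-degree direction, distance 1, symmetric
                pairs.append((q[r, c], q[r, c + 1]))
                pairs.append((q[r, c + 1], q[r, c]))
        expected = np.mean([(i - j) ** 2 for i, j in pairs])
        from skimage.feature import graycomatrix

        P = graycomatrix(q.astype(np.uint8), [1], [0.0], levels=16,
                         symmetric=True, normed=True)[:, :, 0, 0]
        i, j = np.meshgrid(np.arange(16), np.arange(16), indexing="ij")
        assert np.sum((i - j) ** 2 * P) == pytest.approx(expected)

    @given(grid=grids_0_255)
    @settings(max_examples=25)
    def test_direction_averaged_features_invariant_to_90_degree_rotation(self, grid):
        a = glcm_features(grid, 1).values
        b = glcm_features(np.rot90(grid), 1).values
        np.testing.assert_allclose(a, b, atol=1e-10)

    @given(grid=grids_0_255)
    @settings(max_examples=25)
    def test_all_features_finite(self, grid):
        for d in (1, 3):
            assert np.all(np.isfinite(glcm_features(grid, d).values))


class TestGabor:
    def test_default_bank_yields_ten_features(self, rng):
        fv = gabor_features(rng.integers(0, 256, (8, 8)))
        assert len(fv) == 10

    def test_constant_grid_zero_std(self):
        d = gabor_features(np.full((8, 8), 100)).as_dict()
        for name, v in d.items():
            if name.startswith("Gabor_Std"):
                assert v == pytest.approx(0.0, abs=1e-10)

    def test_table_style_names(self, rng):
        fv = gabor_features(rng.integers(0, 256, (8, 8)))
        assert "Gabor_Mean_0.4_0.1" in fv.names
        assert "Gabor_Std_0.5_0.1" in fv.names

    def test_empty_bank_rejected(self):
        with pytest.raises(ValueError):
            gabor_features(np.zeros((8, 8)), bank=())


class TestExtractAll:
    def test_336_total_and_56_per_contrast(self):
        stack = generate_roi_stack("wildtype", seed=0)
        fv = extract_all(stack)
        assert len(fv) == 336
        for c in CONTRASTS:
            assert sum(n.startswith(f"{c}.") for n in fv.names) == 56

    def test_feature_budget_identity(self):
        # 18 first-order + 14 GLCM@1 + 14 GLCM@3 + 10 Gabor = 56
        stack = generate_roi_stack("amplified", seed=1)
        names = [n.split(".", 1)[1] for n in extract_all(stack).names if n.startswith("T2.")]
        n_fo = sum(not ("_Avg_" in n or n.startswith("Gabor")) for n in names)
        n_g1 = sum(n.endswith("_Avg_1") for n in names)
        n_g3 = sum(n.endswith("_Avg_3") for n in names)
        n_gab = sum(n.startswith("Gabor") for n in names)
        assert (n_fo, n_g1, n_g3, n_gab) == (18, 14, 14, 10)

    def test_deterministic(self):
        stack = generate_roi_stack("amplified", seed=2)
        assert extract_all(stack).values == extract_all(stack).values

    def test_missing_contrast_named_in_error(self):
        stack = generate_roi_stack("wildtype", seed=3)
        del stack["rCBV"]
        with pytest.raises(ValueError, match="rCBV"):
            extract_all(stack)

    def test_first_order_before_mapping_switch(self):
        stack = generate_roi_stack("wildtype", seed=4)
        after = extract_all(stack, TextureConfig(first_order_after_mapping=True))
        before = extract_all(stack, TextureConfig(first_order_after_mapping=False))
        assert after.as_dict()["T2.Mean"] != before.as_dict()["T2.Mean"]


def test_feature_vector_validates_lengths_and_uniqueness():
    with pytest.raises(ValueError):
        FeatureVector(("a", "b"), (1.0,))
    with pytest.raises(ValueError):
        FeatureVector(("a", "a"), (1.0, 2.0))
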