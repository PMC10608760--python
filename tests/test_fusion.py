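import numpy as np
import pytest

from neurofuse import (
    FeatureMap,
    FusionConfig,
    Image,
    Modality,
    SharpenParams,
    fuse,
    fuse_average,
    fuse_dwt,
    fuse_lpg,
    fuse_proposed,
    laplace_sharpen,
    max_fuse,
)
from neurofuse.fusion import activity_map, decision_weights
from ._oracles import lpg_fuse_oracle

def _fast_config(**kw):
    from neurofuse import BackboneSpec

    return FusionConfig(backbone=BackboneSpec(out_channels=8, seed=0), **kw)


class TestMaxFuse:
    def test_idempotent(self, rng):
        f = FeatureMap(rng.standard_normal((2, 4, 4)))
        np.testing.assert_array_equal(max_fuse(f, f).values, f.values)

    def test_elementwise_definition(self):
        a = FeatureMap(np.array([[[-1.0, 2.0]]]))
        b = FeatureMap(np.array([[[0.0, 1.0]]]))
        np.testing.assert_array_equal(max_fuse(a, b).values, [[[0.0, 2.0]]])

    def test_commutative_and_dominates_inputs(self, rng):
        a = FeatureMap(rng.standard_normal((3, 5, 5)))
        b = FeatureMap(rng.standard_normal((3, 5, 5)))
        ab = max_fuse(a, b).values
        np.testing.assert_array_equal(ab, max_fuse(b, a).values)
        assert np.all(ab >= a.values) and np.all(ab >= b.values)

    def test_fused_modality_tag(self, rng):
        f = FeatureMap(rng.standard_normal((1, 4, 4)), modality=Modality.MRI)
        assert max_fuse(f, f).modality is Modality.FUSED

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            max_fuse(FeatureMap(np.zeros((1, 4, 4))), FeatureMap(np.zeros((1, 5, 5))))


class TestActivityAndWeights:
    def test_zero_map_zero_activity(self):
        assert np.all(activity_map(FeatureMap(np.zeros((4, 8, 8)))) == 0.0)

    def test_l1_sum_across_channels(self):
        f = FeatureMap(np.array([[[1.0, -1.0], [0.0, 2.0]], [[0.0, 0.0], [3.0, -1.0]]]))
        np.testing.assert_array_equal(activity_map(f), [[1.0, 1.0], [3.0, 3.0]])

    def test_scaled_map_resampled_to_source_grid(self, rng):
        f = FeatureMap(rng.standard_normal((2, 16, 16)), scale=2)
        assert activity_map(f).shape == (8, 8)

    def test_tied_activities_give_half_weights(self, rng):
        a = rng.random((8, 8))
        for mode in ("hard", "soft"):
            w = decision_weights(a, a, mode=mode)
            np.testing.assert_allclose(w.values, 0.5)

    def test_soft_limit_converges_to_hard(self, rng):
        a, b = rng.random((8, 8)), rng.random((8, 8))
        hard = decision_weights(a, b, mode="hard").values
        soft = decision_weights(a, b, mode="soft", softness=1e-9).values
        ties = a == b
        np.testing.assert_allclose(soft[~ties], hard[~ties], atol=1e-12)

    def test_logistic_evaluation(self):
        w = decision_weights(np.full((8, 8), 2.0), np.full((8, 8), 1.0), "soft", 1.0)
        np.testing.assert_allclose(w.values, 1.0 / (1.0 + np.exp(-1.0)), atol=1e-12)

    def test_hard_weights_are_binary_or_half(self, rng):
        w = decision_weights(rng.random((8, 8)), rng.random((8, 8)), "hard").values
        assert set(np.unique(w)).issubset({0.0, 0.5, 1.0})


class TestFuseProposed:
    def test_identical_grayscale_inputs_yield_sharpened_input(self, gray32):
        cfg = _fast_config()
        result = fuse_proposed(gray32, gray32, cfg)
        expected = laplace_sharpen(gray32, cfg.sharpen)
        np.testing.assert_array_equal(result.fused.pixels, expected.pixels)

    def test_zero_pet_hard_mode_keeps_sharpened_mri_where_active(self, gray32):
        cfg = _fast_config(weight_mode="hard")
        pet = Image(np.zeros((32, 32, 1)), Modality.PET)
        result = fuse_proposed(gray32, pet, cfg)
        sharp = laplace_sharpen(gray32, cfg.sharpen).pixels
        w = result.weight_map.values
        mri_wins = w == 1.0
        assert mri_wins.mean() > 0.5
        np.testing.assert_array_equal(
            result.fused.pixels[mri_wins], sharp[mri_wins]
        )

    def test_bitwise_deterministic(self, phantom_pair):
        cfg = _fast_config()
        r1 = fuse_proposed(phantom_pair.mri, phantom_pair.pet, cfg)
        r2 = fuse_proposed(phantom_pair.mri, phantom_pair.pet, cfg)
        np.testing.assert_array_equal(r1.fused.pixels, r2.fused.pixels)
        np.testing.assert_array_equal(r1.weight_map.values, r2.weight_map.values)

    def test_convex_combination_of_sharpened_sources(self, phantom_pair):
        cfg = _fast_config()
        result = fuse_proposed(phantom_pair.mri, phantom_pair.pet, cfg)
        from neurofuse import to_multichannel

        mri_s = to_multichannel(laplace_sharpen(phantom_pair.mri, cfg.sharpen), 3).pixels
        pet_s = laplace_sharpen(phantom_pair.pet, cfg.sharpen).pixels
        lo = np.minimum(mri_s, pet_s) - 1e-12
        hi = np.maximum(mri_s, pet_s) + 1e-12
        f = result.fused.pixels
        assert np.all(f >= lo) and np.all(f <= hi)

    def test_intermediates_contain_max_fused_features(self, gray32):
        cfg = _fast_config()
        result = fuse_proposed(gray32, gray32, cfg)
        fm = result.intermediates
        assert set(fm) == {"mri", "pet", "fused"}
        np.testing.assert_array_equal(
            fm["fused"].values, np.maximum(fm["mri"].values, fm["pet"].values)
        )


class TestFuseDWT:
    def test_self_fusion_fixed_point(self, gray32):
        out = fuse_dwt(gray32, gray32)
        np.testing.assert_allclose(out.pixels, gray32.pixels, atol=1e-7)

    def test_constants_fuse_to_mean(self):
        a = Image(np.full((32, 32), 0.2))
        b = Image(np.full((32, 32), 0.6))
        np.testing.assert_allclose(fuse_dwt(a, b).pixels, 0.4, atol=1e-10)

    def test_step_edge_details_taken_from_edge_image(self):
        import pywt

        px = np.full((32, 32), 0.3)
        px[:, 16:] = 0.7
        step, flat = Image(px), Image(np.full((32, 32), 0.5))
        fused = fuse_dwt(step, flat, levels=1)
        ca, cd = pywt.wavedec2(px, "db2", level=1)
        fa, fd = pywt.wavedec2(fused.pixels[:, :, 0], "db2", level=1)
        # detail coefficients of the fused image equal the step image's
        for d_src, d_fused in zip(cd, fd):
            np.testing.assert_allclose(d_fused, d_src, atol=1e-7)

    def test_too_many_levels_rejected(self, gray32):
        with pytest.raises(ValueError):
            fuse_dwt(gray32, gray32, levels=10)


class TestFuseLPG:
    def test_self_fusion_fixed_point(self, gray32):
        out = fuse_lpg(gray32, gray32)
        np.testing.assert_allclose(out.pixels, gray32.pixels, atol=1e-7)

    def test_constants_fuse_to_mean(self):
        a = Image(np.full((32, 32), 0.2))
        b = Image(np.full((32, 32), 0.8))
        np.testing.assert_allclose(fuse_lpg(a, b).pixels, 0.5, atol=1e-10)

    def test_impulse_matches_pyramid_oracle(self):
        px = np.full((32, 32), 0.5)
        px[16, 16] = 1.0
        a, b = Image(px), Image(np.zeros((32, 32)))
        fused = fuse_lpg(a, b, levels=2)
        expected = np.clip(lpg_fuse_oracle(px, np.zeros((32, 32)), 2), 0, 1)
        np.testing.assert_allclose(fused.pixels[:, :, 0], expected, atol=1e-6)

    def test_levels_too_large_rejected(self, gray32):
        with pytest.raises(ValueError):
            fuse_lpg(gray32, gray32, levels=6)


class TestFuseAverage:
    def test_self_fusion_identity(self, gray32):
        np.testing.assert_array_equal(fuse_average(gray32, gray32).pixels, gray32.pixels)

    def test_extremes_average_to_half(self):
        a = Image(np.zeros((16, 16)))
        b = Image(np.ones((16, 16)))
        np.testing.assert_array_equal(fuse_average(a, b).pixels, 0.5)

    def test_commutative(self, rng):
        a = Image(rng.random((16, 16, 1)))
        b = Image(rng.random((16, 16, 3)))
        np.testing.assert_array_equal(
            fuse_average(a, b).pixels, fuse_average(b, a).pixels
        )


@pytest.mark.parametrize("method", ["proposed", "dwt", "lpg", "average"])
def test_all_methods_emit_bounded_harmonized_output(method, phantom_pair):
    from neurofuse import BackboneSpec

    cfg = FusionConfig(method=method, backbone=BackboneSpec(out_channels=8))
    fused = fuse(phantom_pair.mri, phantom_pair.pet, cfg)
    assert fused.shape == phantom_pair.mri.shape
    assert fused.channels == 3  # PET is RGB
    assert fused.pixels.min() >= 0.0 and fused.pixels.max() <= 1.0
    assert fused.modality is Modality.FUSED
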