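import math

import numpy as np
import pytest

from craniage.morphometry import (
    FEATURE_NAMES,
    FEATURE_REGISTRY,
    RegionMask,
    brightness_stats,
    component_elongations,
    dot_stats,
    elongation,
    extract_features,
    sinus_pair_features,
)
from craniage.phantom import render_scanogram


def disc_mask(cx, cy, r):
    xs, ys = np.meshgrid(np.arange(cx - r - 2, cx + r + 3),
                         np.arange(cy - r - 2, cy + r + 3), indexing="ij")
    keep = (xs - cx) ** 2 + (ys - cy) ** 2 <= r**2
    return RegionMask(np.column_stack([xs[keep], ys[keep]]).astype(float))


def ellipse_mask(cx, cy, a, b):
    xs, ys = np.meshgrid(np.arange(cx - a - 2, cx + a + 3),
                         np.arange(cy - b - 2, cy + b + 3), indexing="ij")
    keep = ((xs - cx) / a) ** 2 + ((ys - cy) / b) ** 2 <= 1
    return RegionMask(np.column_stack([xs[keep], ys[keep]]).astype(float))


class TestDotStats:
    def test_single_pixel(self):
        assert dot_stats(RegionMask([(5, 5)])) == (1, 0.0, 0.0)

    def test_two_pixel_hand_example(self):
        n, msd, md = dot_stats(RegionMask([(0, 0), (2, 0)]))
        assert (n, msd, md) == (2, 1.0, 2.0)

    def test_full_square_max_distance(self):
        pts = [(x, y) for x in range(3) for y in range(3)]
        _, _, md = dot_stats(RegionMask(pts))
        assert md == pytest.approx(2 * math.sqrt(2))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            RegionMask([])

    def test_hull_path_matches_exact(self):
        rng = np.random.default_rng(0)
        pts = rng.integers(0, 200, size=(500, 2)).astype(float)
        mask = RegionMask(pts)
        import craniage.morphometry as M
        exact = dot_stats(mask)
        old = M._MAX_DIST_EXACT_LIMIT
        try:
            M._MAX_DIST_EXACT_LIMIT = 10
            hull = dot_stats(mask)
        finally:
            M._MAX_DIST_EXACT_LIMIT = old
        assert hull == pytest.approx(exact)


class TestElongation:
    def test_horizontal_segment_direction(self):
        mask = RegionMask([(x, 0) for x in range(10)])
        with pytest.warns(UserWarning):
            direction, ratio = elongation(mask)
        assert direction == pytest.approx(0.0)
        assert math.isinf(ratio)

    def test_isotropic_disc_ratio_one(self):
        _, ratio = elongation(disc_mask(50, 50, 15))
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_ellipse_ratio_matches_axes(self):
        _, ratio = elongation(ellipse_mask(60, 60, 20, 10))
        assert ratio == pytest.approx(2.0, abs=0.1)

    def test_direction_convention_vertical(self):
        mask = ellipse_mask(60, 60, 10, 25)  # elongated along y
        direction, _ = elongation(mask)
        assert abs(direction) == pytest.approx(90.0, abs=2.0)


class TestSinusPair:
    def test_identical_masks(self):
        m = disc_mask(40, 40, 8)
        dx, dy, _, _, ratio = sinus_pair_features(m, m)
        assert (dx, dy, ratio) == (0.0, 0.0, 1.0)

    def test_pure_translation(self):
        m = disc_mask(40, 40, 8)
        shifted = RegionMask(m.pixels + np.array([0.0, 10.0]))
        _, dy, _, _, _ = sinus_pair_features(shifted, m)
        assert dy == pytest.approx(10.0)

    def test_area_ratio_is_count_ratio(self):
        frontal = RegionMask([(x, y) for x in range(30) for y in range(10)])
        sphenoid = RegionMask([(x, y) for x in range(15) for y in range(10)])
        *_, ratio = sinus_pair_features(frontal, sphenoid)
        assert ratio == pytest.approx(2.0)


class TestBrightnessStats:
    def test_constant_input_sentinels(self):
        mean, var, sd, cv, m3, skew, m4, excess = brightness_stats([100, 100, 100])
        assert (mean, var, sd) == (100.0, 0.0, 0.0)
        assert math.isnan(cv) and math.isnan(skew) and math.isnan(excess)

    def test_three_point_hand_example(self):
        mean, var, sd, cv, m3, skew, *_ = brightness_stats([100, 150, 200])
        assert mean == 150.0
        assert var == pytest.approx(5000 / 3)
        assert sd == pytest.approx(40.8248, abs=1e-4)
        assert m3 == pytest.approx(0.0)
        assert skew == pytest.approx(0.0)

    def test_symmetric_input_zero_skew(self):
        assert brightness_stats([10, 20, 30, 40, 50])[5] == pytest.approx(0.0)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            brightness_stats([7])

    def test_agrees_with_two_pass_oracle(self, rng):
        """Population moments match a brute-force oracle to 1e-9 relative."""
        for _ in range(20):
            v = rng.uniform(0, 255, size=rng.integers(2, 400))
            mean, var, sd, cv, m3, skew, m4, excess = brightness_stats(v)
            n = v.size
            om = sum(v) / n
            om2 = sum((x - om) ** 2 for x in v) / n
            om3 = sum((x - om) ** 3 for x in v) / n
            om4 = sum((x - om) ** 4 for x in v) / n
            assert mean == pytest.approx(om, rel=1e-9)
            assert var == pytest.approx(om2, rel=1e-9)
            assert m3 == pytest.approx(om3, rel=1e-9, abs=1e-6)
            assert m4 == pytest.approx(om4, rel=1e-9)
            assert skew == pytest.approx(om3 / om2**1.5, rel=1e-9, abs=1e-9)
            assert excess == pytest.approx(om4 / om2**2 - 3, rel=1e-9)

    def test_intensity_scaling_behaviour(self, rng):
        """Scaling intensities by c scales sd by c; skew/excess unchanged."""
        v = rng.uniform(10, 80, size=200)
        base = brightness_stats(v)
        scaled = brightness_stats(2.5 * v)
        assert scaled[2] == pytest.approx(2.5 * base[2], rel=1e-9)
        assert scaled[5] == pytest.approx(base[5], rel=1e-9)
        assert scaled[7] == pytest.approx(base[7], rel=1e-9)


class TestComponentElongations:
    def test_two_components_mean_differs_from_max(self):
        a = ellipse_mask(30, 30, 12, 4).pixels
        b = disc_mask(90, 90, 8).pixels
        mean_r, max_r = component_elongations(RegionMask(np.vstack([a, b])))
        assert max_r > mean_r > 1.0

    def test_single_component_mean_equals_max(self):
        mean_r, max_r = component_elongations(ellipse_mask(40, 40, 15, 6))
        assert mean_r == pytest.approx(max_r)


class TestExtractFeatures:
    def test_registry_has_26_features(self):
        assert len(FEATURE_REGISTRY) == 26
        assert FEATURE_NAMES[25] == "involution_grade"

    def test_definitional_invariants(self, mini_fixture):
        for fv in mini_fixture.features:
            assert fv["clivus_brightness_variance"] == pytest.approx(
                fv["clivus_brightness_sd"] ** 2, rel=1e-12)
            if fv["clivus_brightness_mean"] > 0:
                assert fv["clivus_brightness_cv"] == pytest.approx(
                    fv["clivus_brightness_sd"] / fv["clivus_brightness_mean"],
                    rel=1e-12)
            assert 0 <= fv["involution_grade"] <= 6

    def test_zero_noise_scanogram_recovers_latent_brightness(self, mini_fixture):
        s = mini_fixture.subjects[0]
        scan = render_scanogram(s, rng=None)
        fv = extract_features(scan, 0)
        assert fv["clivus_brightness_mean"] == pytest.approx(
            s.texture.clivus_brightness_mean, abs=2.0)
        assert fv["clivus_brightness_sd"] == pytest.approx(0.0)

    def test_missing_mask_raises_keyed_error(self, mini_fixture):
        scan = mini_fixture.scanograms[0]
        broken = type(scan)(image=scan.image,
                            masks={k: v for k, v in scan.masks.items()
                                   if k != "clivus"} | {"clivus2": scan.masks["clivus"]})
        with pytest.raises(KeyError, match="clivus"):
            extract_features(broken, 0)

    def test_translation_invariance(self, mini_fixture):
        scan = mini_fixture.scanograms[1]
        fv = extract_features(scan, 2)
        shift = (7, 11)
        img = np.roll(scan.image, shift, axis=(0, 1))
        masks = {k: np.roll(v, shift, axis=(0, 1)) for k, v in scan.masks.items()}
        fv2 = extract_features(type(scan)(image=img, masks=masks), 2)
        assert np.allclose(fv.as_array(), fv2.as_array(), rtol=1e-9, atol=1e-9)

    def test_rotation_invariance_of_rotation_free_features(self, mini_fixture):
        scan = mini_fixture.scanograms[2]
        fv = extract_features(scan, 1)
        img = np.rot90(scan.image)
        masks = {k: np.rot90(v) for k, v in scan.masks.items()}
        fv2 = extract_features(type(scan)(image=img, masks=masks), 1)
        for name in ("frontal_dot_count", "frontal_mean_sq_dist",
                     "frontal_max_dist", "frontal_avg_size",
                     "area_ratio_frontal_sphenoid"):
            assert fv2[name] == pytest.approx(fv[name], rel=1e-9)
        # the direction feature transforms by the rotation angle mod 180
        d1, d2 = fv["frontal_elongation_direction"], fv2["frontal_elongation_direction"]
        assert min(abs(d2 - d1 - 90) % 180, abs(d1 - d2 - 90) % 180) == pytest.approx(
            0.0, abs=1e-6)
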