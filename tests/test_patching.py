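"""Patch geometry: center alignment, cropping, oversampling, augmentation."""

import itertools

import numpy as np
import pytest

from murss.patching import (
    AugmentConfig,
    PatchTriplet,
    augment,
    build_sampling_plan,
    center_crop_triplet,
    extract_patch_triplet,
    extract_tile,
    random_crop_triplet,
    tile_grid,
)
from murss.synthgen import IGNORE, ImagePyramid, SyntheticSlideSpec, generate_slide


def coordinate_pyramid(base=4352):
    """Pyramid whose pixel values encode their own coordinates, so window
    placement can be verified cell by cell."""
    yy, xx = np.mgrid[0:base, 0:base]
    img = np.stack([(xx // 17) % 251, (yy // 17) % 251, (xx + yy) % 251], axis=2)
    img = img.astype(np.uint8)
    levels = [img]
    for ds in (2, 4):
        k = base // ds
        levels.append(img[::ds, ::ds][:k, :k])
    mask = ((xx + yy) % 3).astype(np.uint8)
    return ImagePyramid(levels=levels, downsamples=(1, 2, 4), truth_mask=mask)


class TestExtractPatchTriplet:
    def test_window_placement_from_center(self):
        """Level-k windows start at c//s - p//2: for center (1000, 1000) and
        544 px that is base 728, level-1 228 (base 456) and level-2 -22
        (base -88), so the low window needs padding on two sides."""
        pyr = coordinate_pyramid(4352)
        t = extract_patch_triplet(pyr, (1000, 1000), 544)
        assert np.array_equal(t.high, pyr.levels[0][728 : 728 + 544, 728 : 728 + 544])
        assert np.array_equal(t.mid, pyr.levels[1][228 : 228 + 544, 228 : 228 + 544])
        # low level: top-left -22 -> first 22 rows/cols are padding
        assert (t.low[:22] == 255).all() and (t.low[:, :22] == 255).all()
        assert np.array_equal(t.low[22:, 22:], pyr.levels[2][0:522, 0:522])
        assert np.array_equal(t.mask, pyr.truth_mask[728 : 728 + 544, 728 : 728 + 544])

    def test_centered_patch_needs_no_padding(self):
        pyr = coordinate_pyramid(4352)
        t = extract_patch_triplet(pyr, (2176, 2176), 544)
        for arr in (t.high, t.mid, t.low):
            # coordinate encoding never produces a full-white pixel
            assert not (arr == 255).all(axis=2).any()

    def test_determinism(self):
        pyr = coordinate_pyramid(2176)
        a = extract_patch_triplet(pyr, (500, 700), 128)
        b = extract_patch_triplet(pyr, (500, 700), 128)
        for f in ("high", "mid", "low", "mask"):
            assert np.array_equal(getattr(a, f), getattr(b, f))

    def test_center_outside_base_rejected(self):
        pyr = coordinate_pyramid(2176)
        with pytest.raises(ValueError, match="outside"):
            extract_patch_triplet(pyr, (5000, 10), 128)

    def test_out_of_bounds_mask_padded_with_ignore(self):
        pyr = coordinate_pyramid(2176)
        t = extract_patch_triplet(pyr, (10, 10), 128)
        assert (t.mask[0, :] == IGNORE).all()


class TestFieldOfView:
    def test_footprints_nest_and_levels_coregister(self):
        """The mid patch's central half, downscaled by two, approximates the
        high patch — the levels describe the same physical tissue."""
        pyr = generate_slide(SyntheticSlideSpec(seed=3, base_size=512))
        t = extract_patch_triplet(pyr, (256, 256), 128)
        mid_central = t.mid[32:96, 32:96].astype(float)
        mid_up = np.repeat(np.repeat(mid_central, 2, axis=0), 2, axis=1)
        diff = np.abs(mid_up - t.high.astype(float)).mean()
        assert diff < 30.0  # averaging blurs speckle; structure must agree


class TestRandomCrop:
    def make_triplet(self, p=64):
        rng = np.random.default_rng(1)
        imgs = [rng.integers(0, 255, (p, p, 3), dtype=np.uint8) for _ in range(3)]
        mask = rng.integers(0, 3, (p, p)).astype(np.uint8)
        return PatchTriplet(high=imgs[0], mid=imgs[1], low=imgs[2], mask=mask,
                            center=(0, 0))

    def test_full_size_crop_is_identity(self, rng):
        t = self.make_triplet(64)
        c = random_crop_triplet(t, 64, rng)
        for f in ("high", "mid", "low", "mask"):
            assert np.array_equal(getattr(c, f), getattr(t, f))

    def test_mask_stays_locked_to_high_patch(self, rng):
        t = self.make_triplet(64)
        for _ in range(10):
            c = random_crop_triplet(t, 48, rng)
            # locate the high crop's offset by matching content, then check
            # the mask was cropped at exactly the same offset
            found = False
            for oy, ox in itertools.product(range(17), range(17)):
                if np.array_equal(c.high, t.high[oy : oy + 48, ox : ox + 48]):
                    assert np.array_equal(c.mask, t.mask[oy : oy + 48, ox : ox + 48])
                    found = True
                    break
            assert found

    def test_oversized_crop_rejected(self, rng):
        with pytest.raises(ValueError):
            random_crop_triplet(self.make_triplet(64), 80, rng)

    def test_center_crop_deterministic(self):
        t = self.make_triplet(64)
        c1, c2 = center_crop_triplet(t, 48), center_crop_triplet(t, 48)
        assert np.array_equal(c1.high, c2.high)
        assert np.array_equal(c1.high, t.high[8:56, 8:56])


class TestSamplingPlan:
    @pytest.mark.parametrize(
        "n_dcis,n_other,ratio",
        list(itertools.product([0, 1, 3, 10], [0, 2, 7], [1, 2, 9])),
    )
    def test_plan_length_formula(self, n_dcis, n_other, ratio):
        meta = [("s", (i, 0), True) for i in range(n_dcis)]
        meta += [("s", (i, 1), False) for i in range(n_other)]
        plan = build_sampling_plan(meta, ratio)
        assert len(plan) == n_other + ratio * n_dcis

    def test_ratio_below_one_rejected(self):
        with pytest.raises(ValueError):
            build_sampling_plan([("s", (0, 0), True)], 0)

    def test_manifest_roundtrip(self, tmp_path):
        from murss.patching import SamplingPlan

        plan = build_sampling_plan(
            [("a", (1, 2), True), ("b", (3, 4), False)], 9
        )
        path = tmp_path / "plan.csv"
        plan.to_csv(path)
        back = SamplingPlan.from_csv(path, 9)
        assert back.entries == plan.entries


class TestAugment:
    def make_triplet(self, p=32):
        rng = np.random.default_rng(2)
        imgs = [rng.integers(0, 255, (p, p, 3), dtype=np.uint8) for _ in range(3)]
        mask = rng.integers(0, 3, (p, p)).astype(np.uint8)
        return PatchTriplet(high=imgs[0], mid=imgs[1], low=imgs[2], mask=mask,
                            center=(0, 0))

    def zero_config(self, **overrides):
        cfg = AugmentConfig(flip_prob=0, rot90_prob=0, blur_prob=0,
                            noise_prob=0, jitter_prob=0)
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg

    def test_all_probabilities_zero_is_identity(self, rng):
        t = self.make_triplet()
        a = augment(t, rng, self.zero_config())
        for f in ("high", "mid", "low", "mask"):
            assert np.array_equal(getattr(a, f), getattr(t, f))

    def test_geometric_transform_shared_with_mask_and_involutive(self, rng):
        t = self.make_triplet()
        cfg = self.zero_config(flip_prob=1.0)  # both flips always drawn
        a = augment(t, rng, cfg)
        assert np.array_equal(a.high, t.high[::-1, ::-1])
        assert np.array_equal(a.mask, t.mask[::-1, ::-1])
        b = augment(a, rng, cfg)
        assert np.array_equal(b.high, t.high)
        assert np.array_equal(b.mask, t.mask)

    def test_photometric_transforms_never_touch_mask(self, rng):
        t = self.make_triplet()
        cfg = self.zero_config(blur_prob=1.0, noise_prob=1.0, jitter_prob=1.0)
        a = augment(t, rng, cfg)
        assert np.array_equal(a.mask, t.mask)
        assert not np.array_equal(a.high, t.high)

    def test_mask_values_preserved(self, rng):
        t = self.make_triplet()
        t.mask[0, 0] = IGNORE
        a = augment(t, rng, AugmentConfig())
        assert set(np.unique(a.mask)) <= {0, 1, 2, IGNORE}


class TestTiling:
    def test_grid_covers_slide(self, small_pyramid):
        corners = tile_grid(small_pyramid, tile_px=64)
        assert len(corners) == 4  # 128px slide, 64px tiles
        assert (0, 0) in corners

    def test_tile_matches_direct_window(self, small_pyramid):
        t = extract_tile(small_pyramid, (64, 0), tile_px=64)
        assert np.array_equal(t.high, small_pyramid.levels[0][0:64, 64:128])
        assert np.array_equal(t.mask, small_pyramid.truth_mask[0:64, 64:128])

    def test_slide_smaller_than_tile_is_padded(self, small_pyramid):
        t = extract_tile(small_pyramid, (0, 0), tile_px=256)
        assert t.high.shape == (256, 256, 3)
        assert (t.mask[128:, :] == IGNORE).all()
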