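"""Center-aligned multi-magnification patch extraction and sampling.

The working geometry: patches of ``patch_px`` pixels are read at three
pyramid levels with downsample factors 1/2/4 (the 5.0x / 2.5x / 1.25x
analogues). All three share the same base-level *center*, so the physical
field of view doubles at each coarser level while the pixel size stays
fixed. Training patches are read at 544 px and randomly cropped to 512 px;
patches containing DCIS are oversampled (9 occurrences each by default) to
counter class imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .synthgen import IGNORE, ImagePyramid

PAD_RGB = 255  # out-of-bounds reads look like slide background (white)


@dataclass
class PatchTriplet:
    high: np.ndarray  # (p, p, 3) uint8, downsample 1
    mid: np.ndarray   # (p, p, 3) uint8, downsample 2, double field of view
    low: np.ndarray   # (p, p, 3) uint8, downsample 4, quadruple field of view
    mask: np.ndarray  # (p, p) uint8 labels aligned to `high`
    center: tuple     # (x, y) base-level coordinates
    provenance: str = ""

    def __post_init__(self):
        p = self.high.shape[:2]
        if not (self.mid.shape[:2] == p and self.low.shape[:2] == p):
            raise ValueError("high/mid/low must share pixel dimensions")
        if self.mask.shape != p:
            raise ValueError("mask must match the high patch")


@dataclass
class SamplingPlan:
    """Ordered training plan; DCIS-bearing entries repeat ``oversample_ratio``
    times, everything else once."""

    entries: list  # (slide_id, (x, y), repeats)
    oversample_ratio: int

    def __len__(self):
        return sum(r for _, _, r in self.entries)

    def expanded(self):
        for sid, center, reps in self.entries:
            for _ in range(reps):
                yield sid, center

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"slide_id": s, "x": c[0], "y": c[1], "repeats": r, "has_dcis": r > 1}
            for s, c, r in self.entries
        ]
        return pd.DataFrame(rows, columns=["slide_id", "x", "y", "repeats", "has_dcis"])

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, oversample_ratio):
        df = pd.read_csv(path)
        entries = [
            (row.slide_id, (int(row.x), int(row.y)), int(row.repeats))
            for row in df.itertuples()
        ]
        return cls(entries=entries, oversample_ratio=oversample_ratio)


def _read_window(level_img, left, top, size, fill):
    """Half-open window [left, left+size) x [top, top+size) with padding."""
    h, w = level_img.shape[:2]
    out_shape = (size, size) + level_img.shape[2:]
    out = np.full(out_shape, fill, dtype=level_img.dtype)
    x0, x1 = max(left, 0), min(left + size, w)
    y0, y1 = max(top, 0), min(top + size, h)
    if x0 < x1 and y0 < y1:
        out[y0 - top : y1 - top, x0 - left : x1 - left] = level_img[y0:y1, x0:x1]
    return out


def extract_patch_triplet(
    pyramid: ImagePyramid, center: tuple, patch_px: int = 544
) -> PatchTriplet:
    """Read the three co-centered patches plus the high-level mask.

    At downsample ``s`` the window covers ``s * patch_px`` base pixels, so
    its level-k top-left is ``center // s - patch_px // 2``. Windows
    reaching past the slide are padded with white and mask 255. Coordinates
    are 0-based, x right / y down, windows half-open.
    """
    cx, cy = int(center[0]), int(center[1])
    h0, w0 = pyramid.base_shape
    if not (0 <= cx < w0 and 0 <= cy < h0):
        raise ValueError(f"center {center} outside base level {w0}x{h0}")
    patches = []
    for lvl, ds in zip(pyramid.levels, pyramid.downsamples):
        left = cx // ds - patch_px // 2
        top = cy // ds - patch_px // 2
        patches.append(_read_window(lvl, left, top, patch_px, PAD_RGB))
    mask = _read_window(
        pyramid.truth_mask, cx - patch_px // 2, cy - patch_px // 2, patch_px, IGNORE
    )
    return PatchTriplet(
        high=patches[0], mid=patches[1], low=patches[2], mask=mask, center=(cx, cy)
    )


def random_crop_triplet(
    triplet: PatchTriplet, crop_px: int = 512, rng: np.random.Generator | None = None
) -> PatchTriplet:
    """Crop all levels to ``crop_px``.

    The high patch and its mask share one random offset (they must stay
    pixel-locked); mid and low draw independent offsets, since their
    physical footprints differ and context inputs need not be aligned to
    the pixel.
    """
    p = triplet.high.shape[0]
    if crop_px > p:
        raise ValueError(f"crop_px {crop_px} exceeds patch size {p}")
    rng = rng if rng is not None else np.random.default_rng()
    margin = p - crop_px

    def off():
        return (rng.integers(0, margin + 1), rng.integers(0, margin + 1)) if margin else (0, 0)

    ox, oy = off()
    crops = {"high": (ox, oy), "mid": off(), "low": off()}
    out = {}
    for name, (x, y) in crops.items():
        img = getattr(triplet, name)
        out[name] = img[y : y + crop_px, x : x + crop_px]
    mask = triplet.mask[oy : oy + crop_px, ox : ox + crop_px]
    return PatchTriplet(
        high=out["high"], mid=out["mid"], low=out["low"], mask=mask,
        center=triplet.center, provenance=triplet.provenance,
    )


def center_crop_triplet(triplet: PatchTriplet, crop_px: int) -> PatchTriplet:
    """Deterministic central crop (evaluation-time counterpart of the random
    crop)."""
    p = triplet.high.shape[0]
    if crop_px > p:
        raise ValueError(f"crop_px {crop_px} exceeds patch size {p}")
    o = (p - crop_px) // 2
    sl = slice(o, o + crop_px)
    return PatchTriplet(
        high=triplet.high[sl, sl], mid=triplet.mid[sl, sl], low=triplet.low[sl, sl],
        mask=triplet.mask[sl, sl], center=triplet.center, provenance=triplet.provenance,
    )


def build_sampling_plan(patches, oversample_ratio: int = 9) -> SamplingPlan:
    """Build the training plan from patch metadata.

    ``patches`` is an iterable of (slide_id, center, has_dcis) records. A
    DCIS-bearing patch occurs ``oversample_ratio`` times *in total* (not in
    addition to its single base occurrence), so the plan length is
    ``n_other + ratio * n_dcis``.
    """
    if oversample_ratio < 1:
        raise ValueError("oversample_ratio must be >= 1")
    entries = [
        (sid, tuple(center), oversample_ratio if has_dcis else 1)
        for sid, center, has_dcis in patches
    ]
    return SamplingPlan(entries=entries, oversample_ratio=oversample_ratio)


def has_dcis(mask: np.ndarray, min_pixels: int = 1) -> bool:
    return int((np.asarray(mask) == 1).sum()) >= min_pixels


@dataclass
class AugmentConfig:
    """Hard-augmentation policy. Photometric corruption is deliberately
    aggressive (blur + additive noise on most draws): the pixel-level
    speckle is class-uninformative by construction, and destroying it
    keeps the model from keying on texture fingerprints."""

    flip_prob: float = 0.5
    rot90_prob: float = 0.5
    blur_prob: float = 0.7
    blur_sigma: float = 1.2
    noise_prob: float = 0.9
    noise_sigma: float = 10.0
    jitter_prob: float = 0.5
    jitter_strength: float = 0.1


def augment(
    triplet: PatchTriplet,
    rng: np.random.Generator,
    config: AugmentConfig | None = None,
) -> PatchTriplet:
    """Geometric + photometric augmentation.

    One draw decides each geometric transform (flips, number of 90-degree
    rotations) and is applied identically to all three levels *and* the
    mask. Photometric transforms (Gaussian blur, per-channel color jitter)
    touch the images only; label values are never altered.
    """
    cfg = config or AugmentConfig()
    imgs = {k: getattr(triplet, k).copy() for k in ("high", "mid", "low")}
    mask = triplet.mask.copy()

    if rng.random() < cfg.flip_prob:
        imgs = {k: v[:, ::-1] for k, v in imgs.items()}
        mask = mask[:, ::-1]
    if rng.random() < cfg.flip_prob:
        imgs = {k: v[::-1, :] for k, v in imgs.items()}
        mask = mask[::-1, :]
    if rng.random() < cfg.rot90_prob:
        k = int(rng.integers(1, 4))
        imgs = {n: np.rot90(v, k) for n, v in imgs.items()}
        mask = np.rot90(mask, k)

    for name in imgs:
        img = imgs[name].astype(np.float64)
        if rng.random() < cfg.blur_prob:
            sigma = rng.uniform(0.3, cfg.blur_sigma)
            img = ndi.gaussian_filter(img, sigma=(sigma, sigma, 0))
        if rng.random() < cfg.noise_prob:
            img = img + rng.normal(0.0, rng.uniform(2.0, cfg.noise_sigma), img.shape)
        if rng.random() < cfg.jitter_prob:
            scale = 1.0 + rng.uniform(-cfg.jitter_strength, cfg.jitter_strength, 3)
            shift = rng.uniform(-255 * cfg.jitter_strength / 2, 255 * cfg.jitter_strength / 2, 3)
            img = img * scale + shift
        imgs[name] = np.clip(img, 0, 255).astype(np.uint8)

    return PatchTriplet(
        high=np.ascontiguousarray(imgs["high"]),
        mid=np.ascontiguousarray(imgs["mid"]),
        low=np.ascontiguousarray(imgs["low"]),
        mask=np.ascontiguousarray(mask),
        center=triplet.center,
        provenance=triplet.provenance,
    )


def tile_grid(pyramid: ImagePyramid, tile_px: int = 512, stride: int | None = None):
    """Top-left corners for full-slide tiling at the high level,
    non-overlapping by default; trailing partial tiles are included and
    padded on read."""
    stride = stride or tile_px
    h, w = pyramid.base_shape
    return [
        (left, top) for top in range(0, h, stride) for left in range(0, w, stride)
    ]


def extract_tile(pyramid: ImagePyramid, topleft: tuple, tile_px: int = 512) -> PatchTriplet:
    """Inference-time tile read anchored at a base-level top-left corner.

    Equivalent to :func:`extract_patch_triplet` at the tile's center but
    valid for corner tiles whose center falls outside the slide (everything
    out of bounds is padded).
    """
    left, top = int(topleft[0]), int(topleft[1])
    cx, cy = left + tile_px // 2, top + tile_px // 2
    patches = []
    for lvl, ds in zip(pyramid.levels, pyramid.downsamples):
        patches.append(
            _read_window(lvl, cx // ds - tile_px // 2, cy // ds - tile_px // 2, tile_px, PAD_RGB)
        )
    mask = _read_window(pyramid.truth_mask, left, top, tile_px, IGNORE)
    return PatchTriplet(
        high=patches[0], mid=patches[1], low=patches[2], mask=mask, center=(cx, cy)
    )
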