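"""Virtual-slide generator with known ground truth and annotator noise.

Real training data for this problem are gigapixel H&E whole-slide images of
breast tissue annotated for benign epithelium/stroma, ductal carcinoma in
situ (DCIS) and invasive ductal carcinoma (IDC) by several pathologists.
This module fabricates small pyramidal "virtual slides" that reproduce the
two properties the segmentation method exploits:

* DCIS and IDC lesions share the same high-frequency local texture, so a
  high-magnification patch alone cannot separate them; DCIS lesions carry a
  low-frequency enclosing duct ring that only becomes apparent with the wide
  field of view of a low-magnification patch.
* Annotator disagreement concentrates at lesion borders. Several simulated
  annotators independently flip labels inside a morphological border band,
  and the training label is their per-pixel majority vote.

Nothing here attempts photorealism; the slides exist so that every
downstream stage (patch geometry, the network, the selective loss, the
metrics) is testable without any external download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image
from scipy import ndimage as ndi

IGNORE = 255
BENIGN, DCIS, IDC = 0, 1, 2

#: RGB tones loosely evoking an H&E stain: pale pink stroma, denser purple
#: tumor cell nests.
_BENIGN_RGB = np.array([234, 210, 222], dtype=np.float64)
_LESION_RGB = np.array([150, 110, 175], dtype=np.float64)
_RING_RGB = np.array([90, 60, 120], dtype=np.float64)


@dataclass
class SyntheticSlideSpec:
    """Parameters of one virtual slide.

    Defaults give a slide where lesions cover roughly a third of the area
    and the ambiguous border band is wide enough for the selective model to
    have something to reject.
    """

    seed: int = 0
    base_size: int = 512
    n_levels: int = 3
    # benign is the remainder; DCIS is deliberately the minority class
    # (small duct-confined foci), which is what motivates oversampling it
    class_fractions: tuple = (None, 0.03, 0.25)
    n_lesions: int = 6
    duct_ring: bool = True
    band_width: int = 8
    flip_prob: float = 0.4
    n_annotators: int = 3

    def __post_init__(self):
        frac = [f for f in self.class_fractions[1:] if f is not None]
        if sum(frac) > 1.0:
            raise ValueError("class fractions exceed 1")
        if self.band_width < 0:
            raise ValueError("band_width must be >= 0")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must be in [0, 1]")

    @property
    def downsamples(self):
        return tuple(2**k for k in range(self.n_levels))


@dataclass
class ImagePyramid:
    """Co-registered multi-level RGB image plus a base-level label mask."""

    levels: list  # uint8 rasters (H, W, 3), level 0 first
    downsamples: tuple
    truth_mask: np.ndarray  # uint8 (H, W), values {0, 1, 2, 255}

    def __post_init__(self):
        h0, w0 = self.levels[0].shape[:2]
        for lvl, ds in zip(self.levels, self.downsamples):
            if lvl.shape[:2] != (h0 // ds, w0 // ds):
                raise ValueError("level dimensions inconsistent with downsamples")
        if self.truth_mask.shape != (h0, w0):
            raise ValueError("truth_mask must match level-0 dimensions")
        bad = ~np.isin(self.truth_mask, [BENIGN, DCIS, IDC, IGNORE])
        if bad.any():
            raise ValueError("mask contains labels outside {0,1,2,255}")

    @property
    def base_shape(self):
        return self.levels[0].shape[:2]


def _texture(rng, shape, amplitude=18.0, smooth=1.0):
    noise = rng.normal(0.0, amplitude, shape)
    return ndi.gaussian_filter(noise, smooth)


def generate_slide(spec: SyntheticSlideSpec) -> ImagePyramid:
    """Render one virtual slide as an :class:`ImagePyramid`.

    Lesion blobs are random ellipses. DCIS and IDC pixels get the *same*
    speckle texture; when ``spec.duct_ring`` is set, each DCIS blob is
    additionally traced with a thick dark ring at its perimeter — a
    structure too large to interpret inside a high-magnification patch but
    obvious at the lowest level. Area fractions land within about 20%
    relative of the requested ones (blob placement stops once each class
    target is met). Deterministic for a given ``spec.seed``.
    """
    if spec.base_size < 64:
        raise ValueError("base_size must be >= 64")
    if spec.n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if spec.base_size % spec.downsamples[-1]:
        raise ValueError(
            f"base_size {spec.base_size} not divisible by largest "
            f"downsample {spec.downsamples[-1]}"
        )
    rng = np.random.default_rng(spec.seed)
    n = spec.base_size
    mask = np.full((n, n), BENIGN, dtype=np.uint8)
    yy, xx = np.mgrid[0:n, 0:n]

    targets = {}
    for cls, frac in ((DCIS, spec.class_fractions[1]), (IDC, spec.class_fractions[2])):
        if frac:
            targets[cls] = frac * n * n
    ring = np.zeros((n, n), dtype=bool)

    # Lesion classes are spatially segregated: a random axis splits the
    # slide and each class's blobs stay on its own side. A wide field of
    # view around any lesion pixel is therefore dominated by one class —
    # the property that makes low-magnification context informative where
    # the local texture is not.
    axis = rng.normal(size=2)
    axis /= np.hypot(*axis)
    side_of = {DCIS: -1.0, IDC: 1.0}
    classes = [c for c in (DCIS, IDC) if c in targets]
    placed = {c: 0 for c in classes}
    attempts = 0
    while classes and attempts < 200 * max(spec.n_lesions, 1):
        attempts += 1
        cls = classes[attempts % len(classes)]
        if placed[cls] >= targets[cls]:
            classes = [c for c in classes if placed[c] < targets[c]]
            continue
        # DCIS foci are small (duct-confined); IDC masses are larger.
        r = rng.uniform(*((0.035, 0.07) if cls == DCIS else (0.08, 0.16))) * n
        # shrink the final blob to fit the remaining area budget, so the
        # realized fraction stays within the contracted 20% of the target
        remaining = targets[cls] - placed[cls]
        r = min(r, max(np.sqrt(remaining / (np.pi * 1.3**2)), 0.01 * n))
        cx, cy = rng.uniform(r, n - r, size=2)
        proj = (cx - n / 2) * axis[0] + (cy - n / 2) * axis[1]
        if proj * side_of[cls] < 0.02 * n:  # wrong side of the split
            continue
        ax = r * rng.uniform(0.7, 1.3)
        ay = r * rng.uniform(0.7, 1.3)
        blob = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
        blob &= mask == BENIGN
        mask[blob] = cls
        placed[cls] = int((mask == cls).sum())
        if cls == DCIS and spec.duct_ring:
            shell = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2
            ring |= (shell <= 1.0) & (shell >= 0.72) & blob

    img = np.empty((n, n, 3), dtype=np.float64)
    img[:] = _BENIGN_RGB
    lesion = mask != BENIGN
    img[lesion] = _LESION_RGB
    # Shared high-frequency speckle for both lesion classes (and a milder
    # one for benign tissue) — local texture is deliberately uninformative.
    img += _texture(rng, (n, n))[..., None]
    img[lesion] += _texture(rng, (n, n), amplitude=30.0, smooth=0.6)[lesion][..., None]
    if spec.duct_ring:
        img[ring] = 0.25 * img[ring] + 0.75 * _RING_RGB
    img = np.clip(img, 0, 255).astype(np.uint8)

    levels = [img]
    for ds in spec.downsamples[1:]:
        k = n // ds
        lvl = img.astype(np.float64).reshape(k, ds, k, ds, 3).mean(axis=(1, 3))
        levels.append(np.clip(lvl, 0, 255).astype(np.uint8))
    return ImagePyramid(levels=levels, downsamples=spec.downsamples, truth_mask=mask)


def boundary_band(truth: np.ndarray, band_width: int) -> np.ndarray:
    """Boolean band of total width ``band_width`` straddling class borders."""
    if band_width <= 0:
        return np.zeros_like(truth, dtype=bool)
    edges = np.zeros_like(truth, dtype=bool)
    valid = truth != IGNORE
    edges[:-1, :] |= (truth[:-1, :] != truth[1:, :]) & valid[:-1, :] & valid[1:, :]
    edges[:, :-1] |= (truth[:, :-1] != truth[:, 1:]) & valid[:, :-1] & valid[:, 1:]
    radius = max(band_width // 2, 1)
    struct = ndi.generate_binary_structure(2, 2)
    return ndi.binary_dilation(edges, structure=struct, iterations=radius) & valid


def _nearest_other_label(truth: np.ndarray) -> np.ndarray:
    """For every pixel, the label of the nearest differently-labeled pixel."""
    best = np.full(truth.shape, np.inf)
    other = np.full(truth.shape, IGNORE, dtype=np.uint8)
    for cls in (BENIGN, DCIS, IDC):
        if not (truth == cls).any():
            continue
        dist = ndi.distance_transform_edt(truth != cls)
        take = (dist < best) & (truth != cls)
        best[take] = dist[take]
        other[take] = cls
    return other


def simulate_annotations(
    truth: np.ndarray,
    band_width: int,
    flip_prob: float,
    n_annotators: int,
    seed: int,
) -> list[np.ndarray]:
    """Simulate independent annotators who waver only at lesion borders.

    Outside the border band every annotator reproduces the truth. Inside it
    each annotator, independently per pixel, swaps the label for the label
    on the far side of the border (DCIS<->IDC at tumor-tumor borders,
    lesion<->benign at rims) with probability ``flip_prob``.
    """
    truth = np.asarray(truth)
    if not np.isin(truth, [BENIGN, DCIS, IDC, IGNORE]).all():
        raise ValueError("truth contains labels outside {0,1,2,255}")
    if band_width > max(truth.shape):
        raise ValueError("band_width exceeds image extent")
    band = boundary_band(truth, band_width)
    other = _nearest_other_label(truth)
    rng = np.random.default_rng(seed)
    masks = []
    for _ in range(n_annotators):
        m = truth.copy()
        flips = band & (rng.random(truth.shape) < flip_prob) & (other != IGNORE)
        m[flips] = other[flips]
        masks.append(m)
    return masks


def majority_vote(masks: list[np.ndarray]) -> np.ndarray:
    """Per-pixel modal label; pixels without a unique mode become 255.

    With the default three annotators the only tie is the full three-way
    disagreement; with even annotator counts, two-way top-count ties are
    also sent to the ignore label.
    """
    if not masks:
        raise ValueError("majority_vote needs at least one mask")
    stack = np.stack([np.asarray(m) for m in masks])
    counts = np.stack([(stack == v).sum(axis=0) for v in (BENIGN, DCIS, IDC, IGNORE)])
    top = counts.max(axis=0)
    modal = np.array([BENIGN, DCIS, IDC, IGNORE], dtype=np.uint8)[counts.argmax(axis=0)]
    tied = (counts == top).sum(axis=0) > 1
    modal[tied] = IGNORE
    return modal


# ---------------------------------------------------------------------------
# On-disk interchange
# ---------------------------------------------------------------------------

def write_pyramid(pyramid: ImagePyramid, path: str | Path, fmt: str = "tiff") -> Path:
    """Persist a pyramid as a multi-page TIFF (page k = level k) or as
    per-level PNGs plus a JSON sidecar. The mask is a palette-free
    single-channel PNG either way."""
    path = Path(path)
    if fmt == "tiff":
        path.parent.mkdir(parents=True, exist_ok=True)
        with tifffile.TiffWriter(path) as tw:
            for lvl in pyramid.levels:
                tw.write(lvl)
        mask_path = path.with_suffix(".mask.png")
        Image.fromarray(pyramid.truth_mask).save(mask_path)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {"downsamples": list(pyramid.downsamples), "mask_path": mask_path.name}
            )
        )
        return path
    if fmt == "png":
        path.mkdir(parents=True, exist_ok=True)
        for k, lvl in enumerate(pyramid.levels):
            Image.fromarray(lvl).save(path / f"level_{k}.png")
        Image.fromarray(pyramid.truth_mask).save(path / "mask.png")
        (path / "pyramid.json").write_text(
            json.dumps(
                {"downsamples": list(pyramid.downsamples), "mask_path": "mask.png"}
            )
        )
        return path
    raise ValueError(f"unknown format {fmt!r}")


def read_pyramid(path: str | Path) -> ImagePyramid:
    path = Path(path)
    if path.is_dir():
        meta = json.loads((path / "pyramid.json").read_text())
        downs = tuple(meta["downsamples"])
        levels = [
            np.asarray(Image.open(path / f"level_{k}.png")) for k in range(len(downs))
        ]
        mask = np.asarray(Image.open(path / meta["mask_path"]))
    else:
        meta = json.loads(path.with_suffix(".json").read_text())
        downs = tuple(meta["downsamples"])
        with tifffile.TiffFile(path) as tf:
            levels = [tf.pages[k].asarray() for k in range(len(downs))]
        mask = np.asarray(Image.open(path.parent / meta["mask_path"]))
    return ImagePyramid(levels=levels, downsamples=downs, truth_mask=mask.astype(np.uint8))
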