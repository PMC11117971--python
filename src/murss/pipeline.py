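"""End-to-end orchestration: run configuration, synthetic dataset assembly,
training, tiled slide inference and rejection-aware overlay rendering."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import patching, synthgen
from .estimator import MurSSSegmenter, triplets_to_arrays
from .synthgen import IGNORE, ImagePyramid, SyntheticSlideSpec

# Overlay legend: benign carries no tint; rejection overrides class color.
OVERLAY_COLORS = {
    1: np.array([0, 200, 0], dtype=np.float64),    # DCIS -> green
    2: np.array([220, 0, 0], dtype=np.float64),    # IDC -> red
    "rejected": np.array([160, 60, 200], dtype=np.float64),  # purple
}


@dataclass
class RunConfig:
    """Everything a training/evaluation run needs, serializable to YAML."""

    # data
    slide: SyntheticSlideSpec = field(default_factory=SyntheticSlideSpec)
    n_train_slides: int = 3
    n_val_slides: int = 1
    patches_per_slide: int = 24
    patch_px: int = 544
    crop_px: int = 512
    oversample_ratio: int = 9
    augment: bool = True
    # model + loss (mirrors MurSSSegmenter params)
    coverage: float = 0.95
    lambda_: float = 32.0
    alpha: float = 0.5
    c_stem: int = 16
    c_mid: int = 32
    adain_mode: str = "split"
    selective: bool = True
    threshold: float = 0.5
    # optimization
    epochs: int = 10
    batch_size: int = 8
    lr: float = 1e-4
    select_lr_mult: float = 20.0
    seed: int = 0

    def to_yaml(self, path=None) -> str:
        d = dataclasses.asdict(self)
        s = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_yaml(cls, src) -> "RunConfig":
        text = Path(src).read_text() if Path(str(src)).exists() else str(src)
        d = yaml.safe_load(text)
        slide = d.pop("slide", None)
        cfg = cls(**d)
        if slide is not None:
            slide["class_fractions"] = tuple(slide["class_fractions"])
            cfg.slide = SyntheticSlideSpec(**slide)
        return cfg

    @classmethod
    def small(cls, seed: int = 0) -> "RunConfig":
        """Reduced-width, reduced-patch profile for CPU-scale experiments.

        72->64 px patch geometry on 512 px virtual slides, narrow backbone
        (c_mid=8), ten epochs over a few hundred oversampled triplets —
        the configuration used by the bundled end-to-end experiments.
        """
        return cls(
            slide=SyntheticSlideSpec(seed=seed),
            n_train_slides=5, n_val_slides=1, patches_per_slide=20,
            patch_px=72, crop_px=64, oversample_ratio=9,
            c_stem=4, c_mid=8, epochs=10, batch_size=4, lr=5e-3, seed=seed,
        )

    def estimator(self) -> MurSSSegmenter:
        return MurSSSegmenter(
            coverage=self.coverage, lambda_=self.lambda_, alpha=self.alpha,
            c_stem=self.c_stem, c_mid=self.c_mid, adain_mode=self.adain_mode,
            selective=self.selective, threshold=self.threshold,
            epochs=self.epochs, batch_size=self.batch_size, lr=self.lr,
            select_lr_mult=self.select_lr_mult, random_state=self.seed,
        )


def labeled_slide(spec: SyntheticSlideSpec):
    """Generate one virtual slide plus its majority-voted training label.

    Returns ``(pyramid, voted_mask)``: the pyramid keeps the clean truth
    mask; ``voted_mask`` is the per-pixel majority vote over the simulated
    annotators, which carries label noise (and occasional 255 ties) inside
    the border band — the labels a model would actually be trained on.
    """
    pyramid = synthgen.generate_slide(spec)
    annots = synthgen.simulate_annotations(
        pyramid.truth_mask, spec.band_width, spec.flip_prob,
        spec.n_annotators, seed=spec.seed + 1,
    )
    return pyramid, synthgen.majority_vote(annots)


def sample_centers(pyramid: ImagePyramid, n: int, patch_px: int, rng):
    """Uniform patch centers keeping the high window inside the base level."""
    h, w = pyramid.base_shape
    half = patch_px // 2
    if h <= patch_px or w <= patch_px:
        return [(w // 2, h // 2)] * n
    xs = rng.integers(half, w - half, size=n)
    ys = rng.integers(half, h - half, size=n)
    return list(zip(xs.tolist(), ys.tolist()))


def build_dataset(config: RunConfig, n_slides: int, seed: int, train: bool = True):
    """Assemble a patch-pair dataset from fresh virtual slides.

    Training mode follows the full protocol: random 544->512-style crop
    (sizes from the config), DCIS oversampling through a sampling plan, and
    augmentation; labels are the noisy majority votes. Evaluation mode uses
    deterministic center crops, no oversampling and no augmentation, and
    additionally returns the clean truth masks and the border-band masks of
    every patch for diagnostic enrichment measurements.
    """
    rng = np.random.default_rng(seed)
    triplets, bands, truths = [], [], []
    meta = []
    raw = {}
    for s in range(n_slides):
        spec = replace(config.slide, seed=seed + 1000 * (s + 1))
        pyramid, voted = labeled_slide(spec)
        band = synthgen.boundary_band(pyramid.truth_mask, spec.band_width)
        train_pyr = replace(pyramid, truth_mask=voted)
        centers = sample_centers(pyramid, config.patches_per_slide, config.patch_px, rng)
        for c in centers:
            t = patching.extract_patch_triplet(train_pyr, c, config.patch_px)
            key = (f"slide{s}", c)
            meta.append((*key, patching.has_dcis(t.mask)))
            if train:
                raw[key] = t
            else:
                t = patching.center_crop_triplet(t, config.crop_px)
                half = config.patch_px // 2
                crop_off = (config.patch_px - config.crop_px) // 2
                x0 = c[0] - half + crop_off
                y0 = c[1] - half + crop_off
                bands.append(
                    patching._read_window(band.astype(np.uint8), x0, y0, config.crop_px, 0)
                    .astype(bool)
                )
                truths.append(
                    patching._read_window(pyramid.truth_mask, x0, y0, config.crop_px, IGNORE)
                )
                triplets.append(t)
    if train:
        # Expand the plan first: every occurrence of an oversampled patch
        # draws its own random crop and augmentation, so repeats add
        # minority-class exposure without byte-identical duplicates.
        plan = patching.build_sampling_plan(meta, config.oversample_ratio)
        for sid, c in plan.expanded():
            t = patching.random_crop_triplet(raw[(sid, c)], config.crop_px, rng)
            if config.augment:
                t = patching.augment(t, rng)
            triplets.append(t)
        X, y = triplets_to_arrays(triplets)
        return X, y, plan
    X, y = triplets_to_arrays(triplets)
    return X, y, np.stack(bands), np.stack(truths)


def train(config: RunConfig, out_dir=None, log_path=None):
    """Run the full training protocol described by ``config``.

    Builds a training set and a held-out validation set from disjoint
    generator seeds, fits the estimator (epoch-level model selection on
    validation mIoU over covered pixels), optionally writes a checkpoint,
    the config and JSON-lines step logs, and returns the fitted estimator.
    """
    X, y, plan = build_dataset(config, config.n_train_slides, seed=config.seed, train=True)
    Xv, yv, _, _ = build_dataset(
        config, config.n_val_slides, seed=config.seed + 7717, train=False
    )
    est = config.estimator()
    log_fh = open(log_path, "w") if log_path else None
    try:
        cb = (lambda rec: log_fh.write(json.dumps(rec) + "\n")) if log_fh else None
        est.fit(X, y, validation_data=(Xv, yv), log_callback=cb)
    finally:
        if log_fh:
            log_fh.close()
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        est.save(out / "checkpoint.npz")
        config.to_yaml(out / "config.yaml")
        plan.to_csv(out / "sampling_plan.csv")
    return est


def infer_slide(
    est: MurSSSegmenter,
    pyramid: ImagePyramid,
    tile_px: int = 512,
    threshold: float | None = None,
    stride: int | None = None,
):
    """Tile a slide, run the model on every tile and stitch the results.

    Tiles are non-overlapping by default; each tile's label and accept
    patches are pasted back at its recorded top-left corner, so stitched
    output equals per-tile output by construction. Returns
    ``(label_map, accept_map)`` at base-level size.
    """
    if len(pyramid.levels) < 3:
        raise ValueError("pyramid must provide downsample-1/2/4 levels")
    h, w = pyramid.base_shape
    labels = np.zeros((h, w), dtype=np.uint8)
    accept = np.zeros((h, w), dtype=bool)
    for left, top in patching.tile_grid(pyramid, tile_px, stride):
        tile = patching.extract_tile(pyramid, (left, top), tile_px)
        X, _ = triplets_to_arrays([tile])
        lab, acc = est.predict_with_rejection(X, threshold)
        hh = min(tile_px, h - top)
        ww = min(tile_px, w - left)
        labels[top : top + hh, left : left + ww] = lab[0, :hh, :ww]
        accept[top : top + hh, left : left + ww] = acc[0, :hh, :ww]
    return labels, accept


def render_overlay(
    label_map: np.ndarray,
    accept_map: np.ndarray,
    base_image: np.ndarray,
    alpha: float = 0.45,
) -> np.ndarray:
    """Alpha-blend the class legend over the base image.

    Benign pixels keep the original image; DCIS tints green, IDC red, and
    rejected pixels purple regardless of their predicted class.
    """
    if label_map.shape != accept_map.shape or label_map.shape != base_image.shape[:2]:
        raise ValueError("label, accept and image shapes must align")
    out = base_image.astype(np.float64).copy()
    for cls, color in ((1, OVERLAY_COLORS[1]), (2, OVERLAY_COLORS[2])):
        sel = (label_map == cls) & accept_map
        out[sel] = (1 - alpha) * out[sel] + alpha * color
    rej = ~accept_map
    out[rej] = (1 - alpha) * out[rej] + alpha * OVERLAY_COLORS["rejected"]
    return np.clip(out, 0, 255).astype(np.uint8)
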