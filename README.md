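# murss — multi-resolution selective semantic segmentation

`murss` implements a dual-magnification, selective pixel classifier for
histopathology-style imagery, segmenting tissue into **benign**, **DCIS**
(ductal carcinoma in situ) and **IDC** (invasive ductal carcinoma) while
learning to **reject** ambiguous pixels under an explicit coverage budget.
It is aimed at people studying selective prediction and multi-magnification
fusion for whole-slide-image analysis who want a complete, inspectable,
CPU-runnable implementation — including a virtual-slide generator, so every
stage is testable without clinical data.

## The method in brief

Two co-centered patches enter one shared-weight convolutional encoder: a
high-magnification patch `I_high` (content) and a low-magnification patch
`I_low` covering 4× the field of view (context). The high stream yields a
mid-level feature map `M` and a deep feature that passes through a
non-local (self-attention) block into `H'`; the low stream is globally
average-pooled into a context vector `G`. Adaptive instance normalization
(AdaIN) re-normalizes each channel of the projected content `M'` to
statistics derived from `G`:

    AdaIN(M', G) = gamma(G) * (M' - mu(M')) / sigma(M') + beta(G)

and the fused map is concatenated with `H'` and fed to three heads: class
scores `O = f(...)`, selection scores `S = g(...) ∈ [0, 1]`, and an
auxiliary head `A = h(...)` used only during training. The selective
objective, with per-pixel cross-entropy `l`, coverage target `T`, penalty
weight `λ` and mixing weight `α`, is

    r        = Σ l_ij g_ij / Σ g_ij
    L_select = r + λ · max(0, T − mean g)²
    L_total  = α L_select + (1 − α) L_aux

Pixels with selection score below 0.5 at inference are *rejected* —
flagged for human review instead of being classified. Defaults: `T=0.95`,
`λ=32`, `α=0.5`.

## Worked example

Train the reduced-width profile on generated virtual slides and evaluate
on a held-out set (about five minutes on one CPU):

```python
from murss.pipeline import RunConfig, build_dataset

config = RunConfig.small(seed=1)      # 72->64 px patches, c_mid=8, T=0.95
X, y, plan = build_dataset(config, config.n_train_slides,
                           seed=config.seed, train=True)
est = config.estimator()              # sklearn-style MurSSSegmenter
est.fit(X, y)

Xt, yt, bands, truths = build_dataset(config, 3,
                                      seed=config.seed + 99991, train=False)
report = est.evaluate(Xt, yt)
print(f"rejected {report.rejection_fraction:.2f}% of pixels")
print(f"accuracy on accepted pixels {report.accuracy:.1f}%")
print(f"mIoU {report.miou:.3f}")
```

Output from this exact run:

```
rejected 5.69% of pixels
accuracy on accepted pixels 97.0%
mIoU 0.739
```

Trained at a coverage target of 0.95, the model rejects ~5% of held-out
pixels — its coverage budget — and the rejections sit almost entirely
inside the annotator-disagreement band the generator injects at lesion
borders (in-band rejection rate 0.52 vs 0.0025 elsewhere in this run).
Accuracy over the pixels the model *keeps* is higher than over all pixels:
the abstentions are the hard ones. `est.predict(X)` returns label maps,
`est.selection_scores(X)` the per-pixel selection scores, and
`murss.pipeline.infer_slide` / `render_overlay` produce full-slide label
maps and the green/red/purple (DCIS/IDC/rejected) overlays.

A command-line interface mirrors the library:

```bash
murss generate --seed 1 --base-size 512 slide.tiff
murss train --seed 1 runs/demo
murss evaluate --seed 1 runs/demo/checkpoint.npz report.json
murss infer runs/demo/checkpoint.npz slide.tiff out
murss overlay out_labels.png out_accept.png slide.tiff overlay.png
```

## Layout

| Module | Contents |
| --- | --- |
| `murss.synthgen` | virtual-slide generator, annotator simulation, majority vote, pyramid I/O |
| `murss.patching` | center-aligned multi-magnification patch triplets, crops, oversampling plan, augmentation, tiling |
| `murss.model` | the network: shared backbone, non-local block, AdaIN fusion, prediction/selection/auxiliary heads |
| `murss.losses` | coverage risk, coverage penalty, selective and total loss, selection binarization |
| `murss.metrics` | confusion matrices, accuracy, per-class IoU (two conventions), bootstrap CIs, rejection-aware reports |
| `murss.estimator` | `MurSSSegmenter`, the sklearn-style fit/predict wrapper |
| `murss.pipeline` | run configuration, dataset assembly, training, tiled slide inference, overlays |
| `murss.cli` | `murss` command-line entry point |

See `docs/methods.md` for the model's assumptions, the synthetic-data
design, and the numerical choices.
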