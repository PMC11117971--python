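# Methods

## Problem

Pixel-level segmentation of breast-cancer lesions in H&E-stained
histopathology imagery into three classes — benign tissue (0), ductal
carcinoma in situ (DCIS, 1) and invasive ductal carcinoma (IDC, 2) — with
two complications that drive the design:

1. **Local texture is not enough.** DCIS and IDC can look nearly identical
   inside a high-magnification patch; what separates them is structure at a
   much larger scale (e.g., whether tumor nests are confined within duct
   outlines). A patch-based model therefore needs an explicit wide-field
   context input, not just a bigger receptive field.
2. **Labels are genuinely ambiguous at lesion borders.** Expert annotators
   disagree substantially about DCIS extents; training pixels near class
   borders carry label noise that no classifier can resolve. Rather than
   forcing a prediction everywhere, the model learns to *reject* such
   pixels under an explicit coverage budget.

## Model

`MurSSNet` consumes two co-centered RGB patches of equal pixel size:
`I_high` at the working magnification and `I_low` at one quarter of it
(fourfold field of view). Both pass through one shared-weight residual
encoder (four stride-2 stages; mid tap at stride 4 with `c_mid` channels,
deep tap at stride 16 with `2*c_mid`).

* Content: the high stream's deep feature passes through an
  embedded-Gaussian non-local (self-attention) block whose output
  projection is zero-initialized (identity at start), is projected to
  `c_mid` channels and bilinearly upsampled to stride 4 (`H'`). The mid
  feature is projected pointwise to `M'`.
* Context: the low stream's deep feature is globally average-pooled to a
  vector `G` of `2*c_mid` channels.
* Fusion: adaptive instance normalization. Each channel of `M'` is
  standardized over its spatial extent (population variance, eps=1e-5) and
  rescaled/shifted by `(gamma, beta) = split(G)` — entirely parameter-free,
  computed per sample. The fused `M''` is concatenated with `H'` into a
  `2*c_mid`-channel trunk.
* Heads (all emitting at stride 4, bilinearly upsampled ×4 to input size):
  prediction `f` (3 class logits), selection `g` (one logit →
  batch-normalized → sigmoid, scores in [0,1]), auxiliary `h` (3 class
  logits, training only).

Where the context width cannot equal `2*c_mid` (e.g., a wider deep stage),
`adain_mode="projected"` inserts a learned pointwise projection; the
default `"split"` mode keeps the fusion parameter-free.

The whole network, including reverse-mode differentiation for every layer,
is implemented in numpy inside `murss._nn` and validated against central
finite differences in the test suite.

## Objective

With per-pixel cross-entropy `l_ij` of the prediction head, selection
scores `g_ij`, target coverage `T`, penalty weight `lambda` and mixing
weight `alpha`:

    r        = sum(l_ij * g_ij) / sum(g_ij)            (coverage risk)
    penalty  = max(0, T - mean(g_ij))^2
    L_select = r + lambda * penalty
    L_aux    = mean cross-entropy of the auxiliary head
    L_total  = alpha * L_select + (1 - alpha) * L_aux

Pixels labeled 255 are excluded from every sum. When `sum(g) < 1e-8` the
risk is defined as 0; the penalty alone restores coverage. Defaults
`T=0.95`, `lambda=32`, `alpha=0.5` (the SelectiveNet settings). At
inference a pixel is rejected when its selection score falls below a fixed
threshold of 0.5 — deliberately not recalibrated on validation data.

The incentive structure: with coverage at or above `T` the penalty
vanishes, and the risk gradient w.r.t. `g_ij` is proportional to
`l_ij - r`; pixels harder than the running average are pushed toward
rejection and easier ones toward acceptance. Below `T` the penalty pushes
all scores up. The stable equilibrium keeps training coverage slightly
below `T` by `~(l_band - r)/(2*lambda)` while concentrating the rejected
mass on the irreducibly noisy pixels.

## Training dynamics of the selection head

Three choices were needed to make that equilibrium reachable in a short
run; all are design decisions of this implementation:

* **BatchNorm before the selection sigmoid.** Without it, the penalty
  phase early in training drives every selection logit deep into sigmoid
  saturation, after which the per-pixel gradients (already scaled by
  1/sum(g)) cannot separate band from non-band pixels within the epoch
  budget; runs bifurcated between "rejects nothing" and "slowly
  recovers". Normalizing the logit distribution makes collective
  saturation impossible; the learnable shift (initialized at `logit(T)`,
  scale initialized at 2 for a sharper score distribution) gives the
  coverage level a single fast control while the conv weights shape
  *which* pixels occupy the left tail.
* **A 3×3 first convolution in the selection head.** Rejection targets
  boundary regions; boundary-ness is spatial contrast between neighboring
  trunk cells, which a pointwise head cannot measure.
* **Separate learning rates.** The trunk uses adaptive-moment updates with
  cosine decay (settling the coverage/risk balance late in training); the
  selection head runs at 20× the base rate without decay, because its
  target signal — which pixels remain hard — only emerges as the
  classifier converges.

Inputs are centered to [-1, 1]: with strictly positive inputs, He-
initialized convolution units whose weights sum negative start silent and
often never recover, which intermittently starved the content pathway.

## Patch geometry and sampling

Training patches are read at `patch_px` (544 in the full protocol) at
downsamples 1/2/4 around a shared base-level center, randomly cropped to
`crop_px` (512); the high patch and its mask share one crop offset, mid
and low draw independent offsets since their physical footprints differ.
Windows reaching past the slide pad with white and mask 255. Coordinates
are 0-based, x-right/y-down, windows half-open. Patches containing at
least one DCIS pixel occur 9 times in total in the sampling plan; every
occurrence draws its own crop and augmentation, so oversampling adds
minority-class exposure without byte-identical duplicates. Augmentation is
deliberately hard — shared geometric flips/rotations for all levels and
the mask; blur, additive Gaussian noise and color jitter for images only —
because the synthetic speckle texture is class-uninformative by
construction and destroying it prevents the model from keying on pixel
fingerprints (which would let it memorize noisy border labels instead of
rejecting them).

Full-slide inference tiles the base level non-overlapping (configurable
stride), builds each tile's context patch by center alignment, and pastes
argmax labels and accept flags back at the recorded corners.

## Synthetic data

The generator emulates exactly the properties the method exploits, and no
more:

* Three classes with H&E-like tones: pale stroma, purple lesions. DCIS and
  IDC share one high-frequency speckle; DCIS blobs are small (duct-scale)
  and carry a thick dark perimeter ring visible after 4× downsampling.
* Lesion classes are spatially segregated by a random axis per slide, so
  the wide field of view around a lesion is dominated by one class — the
  condition under which a pooled low-magnification context vector is
  informative. DCIS covers ~3% of the slide (deliberately the minority
  class, mirroring clinical rarity and motivating oversampling), IDC ~25%.
* Annotator noise: three simulated annotators copy the truth outside a
  morphological border band (default total width 8 px) and, inside it,
  independently per pixel swap the label for the nearest different class
  with probability 0.4. Training labels are the per-pixel majority vote;
  three-way ties become 255. At these settings the voted label is wrong on
  roughly a third of band pixels — an irreducible-loss region for the
  selection head to discover.

What the generator does **not** emulate: nucleus-level morphology, stain
variability between institutions, scanner artifacts, tissue folds, or
annotator biases that are spatially correlated across a slide. Passing the
behavioral tests therefore demonstrates that the architecture and loss do
what they claim under their own assumptions — not clinical performance.

## Evaluation

Predictions are per-pixel argmax (ties to the lowest class index).
Accuracy is `100 * trace / total` of the 3×3 confusion matrix over
accepted, non-ignored pixels. Class IoU is provided in two conventions:
`standard` one-vs-rest, and `paper_table1`, in which, for class k, *every*
off-diagonal cell outside column k counts as a false negative (including
confusions among the other two classes); the latter is never larger and is
the default. The rejected fraction of non-ignored pixels is reported
separately. 95% confidence intervals use the percentile bootstrap:
evaluation patches are the resampling unit, drawn with replacement to the
original count, confusion matrices pooled by summation, 1000 replicates,
2.5th/97.5th percentiles, seeded.

## Scaled-down experiment profile

`RunConfig.small(seed)` is the configuration used by the bundled
experiments and the reproduction script: 512-px virtual slides, 72→64 px
patch geometry, narrow backbone (`c_stem=4`, `c_mid=8`, ~15k parameters),
5 training slides × 20 sampled centers with 9× DCIS oversampling (typically
250–320 patch pairs after expansion), batch 4, lr 5e-3, 10 epochs, and a
held-out set from 3 fresh slides. One run takes about two minutes on one
CPU. Under this profile the held-out rejected-pixel fraction at threshold
0.5 lands near the 5% budget implied by T=0.95 (seed-to-seed spread of
roughly ±1.5 percentage points, hence experiments report three-seed
means), rejections concentrate overwhelmingly inside the injected border
band, and accuracy on accepted pixels exceeds accuracy on all pixels.

## Numerical choices and degenerate inputs

* AdaIN uses population variance with eps=1e-5 inside the square root.
* Cross-entropy uses natural log; class weights optional, uniform by
  default.
* The empirical-coverage guard (`sum g < 1e-8 -> r = 0`) keeps the loss
  finite when the selection head momentarily rejects everything.
* Upsampling interpolates logits, never hard labels; half-pixel-centered
  bilinear weights.
* `majority_vote` of an even annotator count sends two-way top-count ties
  to 255 as well.
* Empty evaluation sets (everything rejected) report NaN metrics and 100%
  rejection rather than raising.
* A non-finite training loss aborts with a diagnostic snapshot of the
  step's loss components.

## Known limitations

* Exact flip/rotation equivariance of the forward pass does not hold:
  stride-2 convolutions on even-sized inputs break the pixel alignment a
  reflection would need. The batch-permutation and determinism invariants
  are tested instead.
* The non-local block runs at stride 16; attention at finer resolution is
  quadratic in pixel count and was not pursued.
* Training is single-process and CPU-bound by design of the numpy engine;
  the full 512-px/`c_mid=32` configuration is functional (it is exercised
  by a shape test) but impractically slow to train end to end here.
* The selective mechanism assumes ambiguity is *learnable from features* —
  concentrated border noise. Uniformly scattered label noise would be
  memorized or averaged instead, and rejection would not localize.
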