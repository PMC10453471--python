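# Methods

This note documents the models implemented in `spineseg`, the synthetic
data they are exercised on, and the numerical and design choices that are
not obvious from the code.

## Problem setting

Spine CT analysis here is a two-step cascade:

1. **Spine segmentation** — a binary voxel labelling (spine vs background)
   of a Hounsfield-unit CT volume, computed slice-wise by a 2D network.
2. **Vertebra recognition** — a multi-class labelling that assigns every
   spine voxel one vertebra identity (1..N, numbered cranio-caudally),
   computed by a 3D network that consumes the CT together with the stage-1
   mask.

Both stages are evaluated with overlap metrics: dice similarity
DSC = 2|P1∩P2| / (|P1|+|P2|), IoU = TP/(TP+FN+FP),
precision = TP/(TP+FP) and recall = TP/(TP+FN).  When both masks are
empty the prediction is vacuously perfect and every metric is defined
as 1.  Multi-class scores are macro averages over the classes present in
the ground truth, because the vertebra subset visible in a scan varies;
averaging over a fixed class list would punish absent classes.

## Stage 1: CHASPP residual-attention U-Net

A U-Net-shaped encoder–decoder over 2D slices.  Per encoder level:
residual block → 2×2 max-pool → CHASPP module; a residual block forms the
bottleneck.  Per decoder level: nearest-neighbour ×2 upsampling → attention
gate on the skip connection → concatenation → residual block.  A final 1×1
convolution produces the two class logits; softmax gives per-pixel
probabilities that sum to 1.

**CHASPP** (cascaded hierarchical atrous spatial pyramid pooling) is a
two-level dilated-convolution module: one *root* 3×3 convolution at
dilation 2 feeds three parallel 3×3 *branches* at dilations (1, 2, 3),
whose outputs are concatenated and projected by a 1×1 convolution.
Composing root and branch enlarges the receptive field additively
(RF 5 root ∘ RF 7 branch → RF 11) while sampling many more distinct input
offsets than a single dilated kernel of the same extent — this densified
sampling is the module's point, and the test suite verifies both the
composed receptive field and the tap count on an impulse.  The branch
dilations and root rate are configurable; defaults (root 2, branches
1/2/3) were chosen as the smallest rates that interleave the three
branches' lattices.

**Attention gates** rescale skip features by per-position relevance.  The
decoder state is projected to a query q(x), the skip features to a key
k(x) and value v(x) (1×1 convolutions); the raw score is the dot product
e(x) = q(x)·k(x) and the weight α(x) = logistic(e(x)) ∈ (0, 1) multiplies
v(x).  A per-position logistic was chosen over a spatial softmax so the
gate outputs a spatial map rather than a pooled vector; it bounds
|output| ≤ |v| elementwise.

**Residual blocks** are two 3×3 convolutions with an additive shortcut
(identity when channels match, else a 1×1 projection).  A `norm` flag
controls whether each convolution is followed by batch normalization
(default on, bias off) or carries a plain bias (off); the norm-free
variant has the closed-form count 2(9C²+C) used as a parameter-count
oracle in the tests.  Residual blocks can be swapped for plain
convolution blocks via `residual_blocks=False` — the ablation axis.

Reference configuration: base width 16 doubling per level, depth 3 (three
pools, hence exactly three CHASPP modules and three attention gates),
dropout 0.3 in bottleneck and decoder — 841,698 trainable parameters.

## Stage 2: 3D multi-view mobile residual U-Net

Three *independent* lightweight 2D encoders process every slice of the
axial, sagittal and coronal views.  Each encoder is a width-reduced
inverted-residual (expand 1×1 → depthwise 3×3 → linear 1×1) stack in the
MobileNet-v2 style — stem stride 2, then stages (t=1,c=8,n=1,a=1),
(t=6,c=12,n=2,a=2), (t=6,c=16,n=3,a=2), a ≈0.35 width multiple of the
standard stack truncated after the stride-8 stage — with a residual block
after each stage (toggleable, the second ablation axis).  Weights are
never shared between views.

Per-slice feature maps are restacked along the slicing axis and linearly
resampled to a common fusion grid at 1/8, 1/4 and 1/2 of the input
resolution (features are taken after the stride-8, stride-4 and stride-2
stages respectively and projected per scale).  At each scale the three
views are concatenated channel-wise in fixed (axial, sagittal, coronal)
order.  The 3D decoder starts from the 1/8 fusion and performs three ×2
upsampling steps (nearest in-plane, linear along depth), consuming the
1/4 and 1/2 fusions as skips, each step followed by a 3×3×3
convolution block with dropout, ending in a 1×1×1 convolution over the
classes.

The network input is a two-channel stack: the normalized CT and the
stage-1 binary mask.  The predicted arg-max label volume is zeroed
outside the stage-1 mask, which is what makes the two stages a cascade.
Reference configuration: fused channels 32 per view at 1/8, skip
channels 8, decoder widths (32, 16, 8, 8), out_classes 25 (background +
C1–L5 + an L6/transitional allowance) — 194,909 trainable parameters.
The two-stage total of 1,036,607 stays under the 1,245,155 published for
the comparable two-stage reference, and far under the 19,069,955 of a
standard 3D U-Net.

## Autograd engine

No deep-learning framework is used: `spineseg.nn` is a compact reverse-mode
automatic-differentiation engine on numpy arrays, written for exactly the
operator set these models need (2D/3D convolution with stride, dilation
and depthwise grouping via im2col, max-pooling, nearest/linear resampling,
batch normalization, dropout, fused softmax cross-entropy).  Every
operator's gradient is verified against central finite differences in
`tests/test_autograd.py`.  All computation is float32.  Two numerical
guards matter: the logistic input is clipped to ±60 (it saturates in
float32 far earlier; the clip avoids overflow and subnormal
intermediates, which are pathologically slow on some hosts), and the
training loop releases each step's graph before building the next so peak
memory stays at one graph.

## Preprocessing

Fixed order: reorient → smooth → clamp → resize → normalize.  The
canonical frame is RAS+ world axes with array order (z, y, x) =
(superior→inferior, anterior→posterior, left→right); reorientation only
permutes and flips.  Smoothing uses a physical sigma (default 0.75 mm,
converted per axis by the voxel spacing).  Clamping is to [−1000, 800] HU
— air to dense bone.  Four normalization modes: clamped HU passed through
unchanged; per-volume zero-mean/unit-sd (constant volumes map to zero);
and affine maps of the fixed clamp window onto [0, 1] or [−1, 1].  The
range maps deliberately use the fixed clamp bounds, not per-volume
extrema, so the mapping is identical across a dataset.  Resizing is
separable and centre-aligned: linear for images, nearest for labels (no
new labels can appear); the affine is rescaled so physical extent is
preserved.

## Augmentation

Mirror flips (left–right only by default — superior–inferior flips are
anatomically impossible), in-plane rotation (default ±10°) and in-plane
scaling (default 0.9–1.1), each applied with probability 0.5.  Image and
label always receive the same sampled transform; labels use nearest
interpolation; out-of-field voxels fill with −1000 HU (air) for images
and 0 for labels.  The ranges are mild, standard values — no source
states them — and everything is configurable.

## Synthetic phantoms

A phantom is a soft-tissue elliptic cylinder (40 HU) in air (−1000 HU)
containing a cranio-caudal stack of ellipsoidal vertebra-like bodies
(700 HU, inside the clamp window so clamping is non-destructive),
separated by 3–5 mm disc gaps, on a sinusoidal lateral centreline
(amplitude 6 mm), with additive Gaussian noise (sd 25 HU).  Body radii
grow cranio-caudally from 8 to 12 mm with small jitter, mirroring the
real cervical→lumbar size progression; this matters because vertebra
*identity* must be carried by local appearance for a translation-
equivariant network to learn it — with identical bodies the only cue
would be absolute position, which convolutions cannot express (this was
confirmed empirically: with i.i.d. body sizes the recognizer cannot fit
even a single phantom).  Labels mark each body; centroids are exact
label-mass centres in world mm; the binary union of labels is the stage-1
ground truth.  Default grid 64×96×96 voxels at 2 mm isotropic.

What the phantoms do **not** emulate: vertebral processes and ribs (an
optional posterior-process flag adds one process per body), cortical/
trabecular texture, fractures, implants, partial fields of view, and
scanner artifacts.  Tests passing on phantoms therefore demonstrate that
the pipeline's geometry, losses and optimization behave correctly — not
that the trained weights transfer to clinical CT.

## Training

Loss = 0.5·(1 − soft dice) + 0.5·cross-entropy.  Soft dice is averaged
over all classes with smoothing constant 1; cross-entropy is per-voxel.
The dice term drives overlap on rare foreground classes, cross-entropy
keeps gradients dense.  Optimizer: adaptive moments (Adam) at initial
rate 0.001 with reduce-on-plateau (factor 0.5, patience 10 epochs of the
validation macro dice).  Default schedule 150 epochs, batch 8 slices
(2D) or 1 volume (3D).  Splits are per-volume (80/20) so slices of one
scan never leak across the split.  All randomness — init, shuffling,
dropout, augmentation — derives from explicit seeds; with single-threaded
execution a run is reproducible bit for bit.

Ablation axes mirroring the experiment grid: normalization mode,
augmentation on/off, residual blocks on/off, dropout value.

## Scaled-down study sizes

The self-contained evaluation (tests and `scripts/acceptance.py`) runs the
whole pipeline on 25 phantoms (80/20 → 20 train / 5 test) preprocessed to
a 32×48×48 working grid, with reduced models: stage 1 at base width 8 and
depth 2 trained 10 epochs; stage 2 with 7 classes trained 12 epochs at
rate 0.01 on ground-truth spine masks (the oracle-cascade setting), with
the test-time cascade using the stage-1 masks.  The stage-2 learning rate
is scaled up roughly in proportion to the epoch budget being ~10× below
the full schedule; stage 1, whose per-epoch step count is large, keeps
the 0.001 default.  These sizes are the package's reference small-scale
experiment; at them the cascade reaches spine dice ≈ 0.9 and vertebra
macro dice ≥ 0.6 on held-out phantoms, and repeating a run with the same
seed reproduces the metric tables exactly.

## Known limitations

- Phantom realism as above; no claim of clinical performance.
- The 2D engine favours clarity over speed: im2col convolutions cost
  memory bandwidth, and large-batch 256² training is slow on one core.
- Batch normalization with volume batches of 1 normalizes over the single
  volume's statistics; fine here, but a group-norm variant would be the
  better choice for very small 3D batches.
- `conv3d` supports stride 1 only (the 3D decoder needs nothing else).
- Orientation handling assumes orthogonal affines (the NIfTI common
  case); oblique acquisitions are reoriented to the nearest axis frame.
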