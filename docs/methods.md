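# Methods

`tubeseg` segments branching tubular structures — cerebral vessels in
TOF-MRA, airways in chest CT — from 3D grayscale volumes. This note
documents the model, the synthetic phantoms used for validation, the
numerical choices, and the limits of what the tests demonstrate.

## Problem setting

Tubular anatomy occupies a tiny fraction of a volume (arterial vessels are
about 1.5% of brain voxels), branches across scales from trunks several
voxels wide down to barely-resolved peripherals, and is mostly boundary:
a tube of radius 2–3 voxels has more surface voxels than interior ones.
Segmentation quality is therefore dominated by class imbalance and edge
localization, which is what each component below addresses.

## Pipeline

1. **Normalization** — whole-volume z-score with the population standard
   deviation, `x -> (x - mean) / std`, applied at image level before any
   cropping. A constant volume maps to zeros with a warning. ROI masks
   (skull-stripped brain, lung parenchyma), when available, zero the
   exterior; producing those masks is outside this package's scope.

2. **Patch sampling** — training patches combine a sliding-window sequence
   with random crops. The sliding convention is asymmetric by design: x/y
   origins run over multiples of the step strictly below `extent - patch`
   (the final aligned origin is excluded), z origins include it. This
   convention is reverse-engineered: it is the unique simple per-axis rule
   that reproduces all three published patch totals for 76 images of
   448×448×128 (223,896 at patch 16/step 16; 46,056 at patch 64/step 32;
   9,880 at patch 128/step 64, each plus 30 random crops per image), and it
   is pinned by a brute-force enumeration oracle in the tests. Random crops
   are rejection-sampled uniformly over the full origin lattice and
   accepted when the patch's label fraction (foreground voxels / patch
   voxels) strictly exceeds the threshold (default 0.001 in combined mode;
   0.01 when sampling randomly alone), with a cap of 1000 tries per
   requested crop.

3. **Network** — a 3D U-Net with learned stride-2 convolutions instead of
   pooling, InstanceNorm + leaky ReLU (slope 0.01), and additive residual
   shortcuts in every stage. Channel schedule C, 2C, 4C, 8C, 16C over four
   halvings, so a 64×64×32 patch at the default C=8 yields a 128-channel
   4×4×2 bottleneck. Three optional components (ablation flags):
   - **MSFA** fuses the three deepest encoder features through learned
     stride-2 downsamplers (doubling channels so elementwise products are
     well-typed) into a single-channel deep map `fmf`.
   - **Reverse attention** forms coefficients `R = 1 - sigmoid(logits)`
     that suppress confidently-foreground regions and emphasize
     background/edges. R1 derives from `fmf`; subsequent stages propagate
     the coefficient by restoring the previous weighted feature to one
     channel (1×1×1 conv), convolving, adding the previous coefficient,
     upsampling, and re-squashing. The coefficient is broadcast across the
     skip feature's channels and multiplies it before decoding. The exact
     propagation wiring is one consistent reading of an under-specified
     design; it is isolated behind `reverse_attention_step` so it can be
     revised without touching the rest of the network.
   - **Inception sparse convolution** widens the receptive field of the
     attention path with four two-layer branches (default: a 1×1×1 entry
     branch plus 3×3×3 branches at dilations 1, 2, 3), concatenated and
     fused 1×1×1. The kernel/dilation set is declared configuration, not a
     published value. The flag needs MSFA or reverse attention enabled to
     have a site; the all-off configuration is the plain baseline.
   Upsampling is trilinear interpolation (scale 2) followed by convolution;
   no transposed convolutions. The output head fuses the last three decoder
   levels at full resolution and ends in a 1×1×1 conv to two channels and a
   softmax. The head bias starts at (+1.5, −1.5), encoding a ~95%
   background prior; with ~1.5% foreground this avoids the long initial
   plateau of Dice-loss training. Dropout (default 0.3) sits on the two
   bottleneck conv blocks only; the placement is this package's choice.

4. **Training** — Adam (default lr 0.001), soft Dice loss on the
   foreground probability with eps = 1e-6 guarding the empty-empty case;
   metrics by contrast always binarize. Early stopping monitors validation
   Dice loss: a counter increments each epoch without improvement and
   training stops once it exceeds the patience (default 50), restoring the
   best-validation weights. Everything (shuffling, init, dropout, phantom
   and crop sampling) derives from integer seeds.

5. **Inference and post-processing** — full volumes are tiled with a
   separate full-coverage convention (origins at step multiples, final tile
   clamped to the edge), predicted patch-by-patch and stitched, averaging
   class probabilities where tiles overlap; binarization is argmax with
   ties to background. Two cleanup filters: conjunction with an ROI mask,
   and 26-connected component filtering (keep-largest by default for
   vessels; a min-size mode for airway trees, which can legitimately
   fragment in imperfect predictions). Both filters only remove foreground.

## Metrics

Precision, recall, Dice = 2TP/(2TP+FP+FN) and IoU = TP/(TP+FP+FN) from
voxel confusion counts, optionally restricted to an ROI; when
TP = FP = FN = 0 all metrics are 1. For any single confusion table
IoU = Dice/(2 − Dice); `dice_to_iou` exposes the identity, and the test
suite uses it to cross-check published Dice/IoU pairs (they agree to
printed precision, confirming the standard IoU definition despite one
source printing the formula upside-down). Evaluation reports both
per-image mean ± std and pooled-count metrics, since "average over the
test set" is ambiguous between the two.

## Synthetic phantoms

The phantom generator produces seeded binary trees of tubes: a trunk from a
random face, bifurcation at every non-terminal node with a fixed 35° mean
branch angle plus configurable jitter, radii decaying by a fixed factor per
generation (default 0.8 from a 3-voxel root), and segment lengths decaying
by 0.72 per generation. The foreground budget (default 1.5% of voxels) is
enforced by dropping side branches once the estimated tube volume reaches
it — the main path always reaches the configured depth, so radius realism
is preserved rather than rescaled. Rasterization marks a voxel foreground
iff its centre lies within the locally interpolated radius of some segment,
verified against a brute-force per-voxel oracle. Intensities: bright tubes
on dark background with Gaussian noise (MRA-like), or a dark lumen inside a
2-voxel dilated bright wall (CT-airway-like). Default contrast
(fg 200 / bg 50, noise sd 15, i.e. 10 noise-sd of separation) makes the
voxel-classification part of the task easy on purpose: the phantoms
exercise geometry, imbalance, and boundary behaviour, not low-contrast
detection.

What the phantoms do **not** emulate: intensity inhomogeneity and vessel
-lumen signal falloff, anisotropic voxels, partial-volume blur, anatomy
other than trees (no loops, no touching organs), and annotation noise.
Passing the recovery test therefore shows the pipeline is wired correctly
and can learn thin branching structure under heavy class imbalance — it
does not certify clinical-image accuracy.

## Problem sizes

The bundled experiments are sized for a single CPU with the network
implemented on the package's own numpy autodiff engine: recovery trains a
C=4 model on 32³ patches (2 sliding + 6 random per image) from 8 phantoms
of 64³ at 1.5% foreground, validates on 2, and evaluates on 4 held-out
phantoms with and without keep-largest filtering; the desk-scale recipe
uses lr 3e-3 for 10 epochs, which reaches held-out Dice well above 0.9 on
the default phantoms. The overfit sanity run fits 4 patches for 30 epochs
to training Dice ≥ 0.9. Shape contracts are checked at the full default
width (C=8, 64×64×32 input). Published clinical benchmark scores
(Dice ≈ 0.90 vessels / 0.93 airways) require the original datasets and
GPU-scale training and are not reproduced here; the tests instead verify
every computable contract of the method.

## Numerical choices and degenerate inputs

- float32 throughout; Dice-loss eps 1e-6; instance-norm eps 1e-5.
- Instance norm over a single spatial voxel is degenerate (output is the
  bias, no gradient); inputs must keep the bottleneck above 1×1×1, i.e.
  ≥ 32 voxels per axis for meaningful training.
- Binarization ties (fg prob exactly 0.5) go to background.
- z-score of a constant volume returns zeros and warns rather than raising.
- Conv bias is disabled wherever instance norm immediately follows (the
  norm would cancel it and its gradient would vanish).
- Augmentation defaults are mild (flips, ≤10° rotations, ±5% scaling,
  ≤1.5-voxel elastic displacement) so the thin foreground survives;
  magnitudes are declared, not published values.
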