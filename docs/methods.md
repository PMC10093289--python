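# Methods

## The model

`adverseg` performs binary segmentation of kidney-like structures in 2-D
grayscale CT slices with a pair of adversarially trained convolutional
networks.

**Generator.** A fully convolutional encoder-decoder G maps a slice
x ∈ [0,1]^{H×W} to a per-pixel foreground probability map G(x) ∈ [0,1]^{H×W}.
The encoder is a 3×3 stem convolution followed by three stages of
(dense block → 1×1 transition → 2×2 max-pool); the decoder mirrors it with
three stages of (2×2 transposed convolution → skip concatenation → dense
block) and a final 1×1 convolution with a sigmoid. A dense block with L
layers, each BN → ReLU → 3×3 convolution emitting g ("growth") channels,
concatenates every layer's output with all of its inputs, so a block maps
c channels to c + L·g. Three pooling stages mean H and W must be divisible
by 8; the builder enforces this and `predict` reflect-pads and crops
arbitrary sizes.

**Discriminator.** A six-layer multi-scale feature extractor D over the
channel-concatenation of an image and a candidate mask, each layer
convolution → BN → leaky ReLU (slope 0.2). The kernel sizes are drawn from
{7,5,4,3}; the default schedule is [7,5,4,4,3,3] with stride 2 on the first
four layers. The six per-layer activation maps form the feature pyramid
f_D(x, y); a global-average-pool plus linear head yields a scalar real/fake
score, which is exposed but not used by the default objective.

**Objective.** With a batch of N pairs (x_i, y_i), the generator minimises

    (λ/N) Σ_i E_dice(G(x_i), y_i)  +  (δ/N) Σ_i E_mae(f_D(x_i,y_i), f_D(x_i,G(x_i)))

where E_dice(p, t) = −(2 Σ p·t + ε)/(Σ p + Σ t + ε) is the smoothed negative
soft Dice of one pair (bounded in [−1, 0], equal to −1 for a perfect match
and in the empty/empty ε-limit), and E_mae is the mean absolute difference
between the two feature pyramids, averaged within each level and then
across levels so that deep small maps and shallow large maps contribute
equally. The discriminator is trained to *maximise* the feature
discrepancy, i.e. it minimises the exact negation of the δ-weighted MAE
component; the Dice term does not depend on D. The classical two-player
cross-entropy GAN value function is provided only as a documented reference
(`losses.conventional_gan_value`) and is never trained.

Defaults: λ = δ = 1 and ε = 1 (the conventional Dice smoothing constant).
Setting δ = 0 degenerates to plain Dice-loss training, which the training
loop recognises and runs without touching the discriminator.

## Training procedure

Per batch: update D (one step by default) on the negated MAE term with the
generator output detached, then update G through the updated, frozen D.
One generator forward pass per batch serves both updates since G's output
does not depend on D. The optimizer is stochastic gradient descent with
momentum — learning rate 1e-4, weight decay 1e-4, momentum 0.9 — the
package's defaults; Adam is available by config flag. Batch size defaults
to 1 (the classic U-Net setting: at a fixed learning rate, convergence at
desk scale is governed by the number of SGD steps, and per-slice updates
maximise them) and epochs to 14. Validation curves record the
soft Dice (the negated Dice term) per epoch; hard-threshold metrics are
only computed by `evaluate`. A non-finite loss aborts with a diagnostic
naming the term and epoch rather than being clipped: at desk scale,
failures should be visible.

The final 1×1 convolution's bias is initialised to −2 so the initial
probability map sits near the background class prior (foreground occupies
a few percent of a slice). This is the standard class-imbalance
initialisation for dense prediction heads; starting at p ≈ 0.5 everywhere
inflates the Dice denominator and starves early training of gradient.

All randomness — weight initialisation, batch shuffling, phantom sampling —
derives from explicit seeds, and the numpy compute stack is deterministic
on a fixed thread count, so CPU runs reproduce bit-for-bit.

### The numerical engine

The networks run on the package's own reverse-mode automatic
differentiation engine over numpy arrays (`adverseg.nn`): convolution
(evaluated as one BLAS matrix product per kernel offset), transposed
convolution, batch normalisation, max-pooling, and the elementwise algebra
the losses need. Every layer's analytic gradient is verified against
central finite differences in the test suite. Activations are float32;
loss-level reductions preserve float64 when given float64 inputs, which is
what lets the metric and loss tests assert exact agreement with oracles.

## Evaluation metrics

For one binary prediction/truth pair with confusion counts TP/FP/FN/TN:

- DSC = 2TP/(2TP+FP+FN); VOE = (1 − TP/(TP+FP+FN))·100 %;
  ACC = (TP+TN)/total; SEN = TP/(TP+FN); SPE = TN/(TN+FP).
- ASD: surface pixels are foreground pixels with at least one background
  4-neighbour (8-connectivity by flag), with the image border counting as
  background. ASD is the symmetric mean over both surfaces of the Euclidean
  nearest-surface distance, computed from a distance transform with
  anisotropic pixel spacing supported; the brute-force all-pairs oracle is
  kept in the test suite.

Degenerate-case conventions (declared, and flagged in reports rather than
silently imputed): both masks empty → DSC 1, VOE 0 %; either mask empty →
ASD undefined (NaN, excluded from aggregation with a warning); SEN/SPE are
NaN when their denominator is zero. Predictions are binarized at 0.5 by
default. Reports aggregate per-slice values to mean / sample standard
deviation / max / min over the defined values; a single slice has standard
deviation 0 by convention.

Model comparison uses the paired two-sided Wilcoxon signed-rank test on
per-slice metric values, dropping zero differences; the reported statistic
is W⁺ − W⁻, antisymmetric under swapping the models. If all differences are
zero the test is degenerate and (0, 1.0) is returned with a warning.

## The phantom generator

Phantoms emulate the statistical structure of the kidney-slice task so the
whole pipeline is testable without any external data: 64×64 slices with
zero, one or two bright elliptical "kidney" regions (randomly rotated
semi-axes 6–14 px, uniform) on a darker background (foreground mean 0.65,
background 0.25, additive Gaussian noise σ = 0.05, clipped to [0,1]). With
probability 0.5 a region encloses a hollow interior at 0.4 of its semi-axes
that takes background intensity and is excluded from the label — the
analogue of the renal collecting system, an interior cavity that must not
be segmented as kidney and the hard case for contour learning. Two-region
slices place one ellipse per image half, mimicking left/right anatomy.
Pair i is drawn from an RNG keyed on (seed, i), so datasets are
order-independent and reproducible.

What the phantoms do *not* model: anatomical shape variability, organ
context and neighbouring structures, CT reconstruction artefacts, partial
volume effects, intensity inhomogeneity and anisotropic 3-D continuity.
Passing phantom tests therefore demonstrates that the architecture, losses,
training dynamics and metrics are implemented correctly and that the model
can learn excluded-interior boundaries — not that it reaches clinical CT
accuracy; real-volume experiments enter through the NIfTI path in
`adverseg.io` (HU windowing default [−200, 300] mapped affinely to [0,1],
kidney label {1} with a flag to merge tumor voxels, bilinear image /
nearest-neighbour mask resizing).

## Problem sizes and design choices

The self-contained experiment used by the acceptance script and the
convergence tests trains on 140 of 200 phantom pairs (70/15/15
train/val/test split) at 64×64 for 14 epochs, a few minutes on one CPU.
Generator widths default to base 8 channels / growth 4 with 4-layer dense
blocks (≈30 k parameters) — sized so that desk-scale training is fast while
leaving every width configurable; the discriminator schedule defaults to
[8,16,32,32,32,32] channels.

Choices made where the design was genuinely open, as package conventions:
skip connections concatenate (U-Net convention) rather than add; each
encoder dense block is followed by a 1×1 transition halving channels
(DenseNet-style compression) to bound channel growth; the decoder's
transposed convolutions use kernel 2, stride 2 (non-overlapping, no
checkerboard artefacts); the discriminator consumes image and mask
channel-concatenated so masks are judged in the context of their image;
the update order is D-then-G at a 1:1 ratio; early stopping is not used.

## Known limitations

- 2-D slices only; no 3-D context or V-Net-style volumetric variant.
- The discriminator's scalar real/fake head is exposed but carries no
  training signal under the default objective; adding a cross-entropy term
  would change the equilibrium and is deliberately not done.
- The adversarial term at desk scale mainly regularises; on easy phantoms
  the Dice-only ablation reaches comparable accuracy (the tests assert
  parity within 0.05 DSC, not superiority).
- ASD is computed per 2-D slice in physical units and averaged, not over a
  3-D surface.
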