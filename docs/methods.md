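# Methods

## Problem and model

The package classifies the pixels of a hyperspectral reflectance cube
(rows × columns × bands) into crop/land-cover classes given a sparse
ground-truth map (label 0 = unlabeled).  The classifier input is the
s × s spatial patch around each pixel; the label of the patch is the class
of its center pixel.

The model (SGTN, "semantic-guided transformer network") is a two-stage
CNN–transformer hybrid:

1. **Spectral reduction.**  A 1×1 convolution with 64 filters and ReLU maps
   the bands to a fixed 64-channel feature map.
2. **Two feature-extraction stages.**  Each stage runs two parallel branches
   over its input and multiplies their outputs:
   - **MSIE** (multi-scale spatial–spectral information extraction): four
     parallel convolution branches — (1×1 → 3×3 average pooling), (1×1),
     (1×1 → {1×3 ∥ 3×1} summed), (1×1 → 1×3 → 3×1 with the intermediate and
     final maps summed) — all with 64 filters and ReLU, merged by
     element-wise summation.  The factorized 1×3/3×1 pairs act as cheap
     oriented edge detectors; the pooled branch aggregates local context.
   - **SGA** (semantic-guided attention): the stage input is flattened
     row-major to s² tokens of width 64, each channel is gated by
     sigmoid(w_c), a learnable pixel-weight column w_p ∈ R^{s²} is appended
     (token width d = 65), and one pre-normalized transformer encoder layer
     (single-head scaled dot-product attention, GELU MLP of hidden width
     152, layer norms, residuals, no positional encoding) updates the
     tokens.  The w_p column is read back, reshaped to s × s and squashed
     with a sigmoid; this map in (0,1) multiplicatively gates the MSIE
     output at every channel.
3. **Head.**  Global average pooling to a 64-vector, then FC 64→32 with
   ReLU and FC 32→classes producing logits.

Ablation variants: `use_sga=False` removes the gate entirely (identical to
multiplying by an all-ones map), and `use_msie=False` replaces MSIE with a
two-layer 3×3 convolution stack of the same output shape.

With the reference widths (64 filters, FC hidden 32, MLP hidden 152, one
head, depth one) the trainable-parameter totals are 222,828 (200 bands, 16
classes, s=13), 223,196 (204 bands, 16 classes, s=15) and 216,501 (103
bands, 9 classes, s=15) — all 0.22 M to two decimals.  The MLP hidden width
152 is pinned precisely so that all three configurations land in that bin.

## Numerical core

No deep-learning framework is used: the network runs on a small in-package
reverse-mode autodiff engine (`sgtn.nn`) over NumPy arrays (channels-last).
Convolutions are evaluated by im2col + BLAS matmul; the 3×3 average pooling
divides border sums by the number of valid cells so constant fields are
preserved at the borders.  Every primitive's gradient is validated against
central finite differences in the test suite.  Training arrays are float32.

## Initialization

Convolution and linear weights are Kaiming-uniform (fan-in), biases zero,
drawn from a seeded generator; layer-norm scale/shift are 1/0; the pixel
and channel weights w_p, w_c start at zero so both gates start at the
neutral 0.5.  The attention output map W_O and the MLP output projection
are initialized to zero, making each encoder layer the identity at
initialization and the extracted weight map exactly flat.  Without this,
the initial (random) weight maps can saturate near zero for entire classes,
whose gradients then vanish through the sigmoid and the class is never
learned; zero-initializing residual projections is the standard remedy and
empirically removes the pathology.

## Data handling

- **Splitting.**  Per class with n labeled pixels: n_train = ⌊f_train·n⌋,
  n_val = ⌊f_val·(n − n_train)⌋, n_test the remainder; membership is drawn
  uniformly under the seed.  Subset sizes therefore depend only on the class
  totals and fractions — the rule reproduces, class by class, the published
  sample-division tables of the Indian Pines (10%/10%), Salinas (1%/1%) and
  Pavia University (1%/1%) benchmarks.
- **Band removal.**  Water-absorption/noisy band lists for Indian Pines
  (220→200) and Salinas (224→204) are shipped as editable YAML config,
  since only the retained counts are standardized.
- **Normalization.**  Each band is independently min–max scaled to [0,1]
  over the whole cube before splitting; constant bands map to 0.  This is
  the least parameterized choice and keeps sigmoid/attention inputs bounded.
- **Patches.**  Mirror (reflect) padding at image borders, so every labeled
  pixel yields a full s × s patch without injecting zero spectra.
  Coordinates are 0-based; the center sits at offset ((s−1)/2, (s−1)/2).

## Training protocol

Cross-entropy loss, Adam (lr 0.001, β = 0.9/0.999), batch size 64, 100
epochs by default; one encoder layer and one attention head.  Per epoch the
validation overall accuracy is recorded and the best-validation checkpoint
is the model evaluated on the test set.  Repeated experiments (default
five) each redraw the stratified split and reinitialize the model under
their own seed; OA/AA/Kappa and per-class accuracies are reported as
mean ± sd.  Metrics: OA = trace/total, AA = mean per-class recall (empty
classes excluded with a warning), Kappa = (p_o − p_e)/(1 − p_e) with p_e
from the marginals.

## Synthetic scenes

The generator emulates the structure of agricultural benchmark scenes:
smooth per-class spectral signatures (sums of Gaussian bumps over the band
axis; primary bump amplitude 1.0, width bands/8, plus a secondary bump at
amplitude 0.5), spatially contiguous class regions (horizontal strips, or
Voronoi cells of random sites), additive white Gaussian noise per band, a
random unlabeled background fraction, and optional *confusable pairs* —
classes whose signature is the base class's shifted by a small band offset,
which dials the pair's spectral distance continuously to zero.  Everything
is a deterministic function of the `SceneSpec`, including its seed.

What the generator does **not** emulate: mixed pixels / endmember
abundances, spectrally correlated or signal-dependent noise, within-class
spectral variability, illumination gradients, and sensor artifacts.
Passing the synthetic studies therefore shows that the implementation
learns and that the modules interact as designed — not that benchmark-level
accuracy transfers to real sensors.

## Scaled-down study sizes

The packaged studies are sized for a workstation CPU, as the package's own
test protocol:

- *Recovery study*: 64×64 scene, 32 bands, 5 classes, noise sd 0.05,
  10%/10% split, patch side 9, 15 epochs, five seeds; the scene is easily
  separable, so a correct implementation should reach test OA ≥ 0.90 in
  nearly all seeds.
- *Ablation direction*: 48×48 scene, 32 bands, 6 classes with two
  confusable pairs, noise sd 0.1, 30 epochs, three seeds per variant.
  The confusable offset (0.3 bands) is calibrated analytically so the
  within-pair per-pixel Bayes error is ≈30% (0.5 σ separation at noise
  sd 0.1) — pairs a per-pixel spectral classifier genuinely cannot
  separate, so the comparison probes spatial/semantic context.  30 epochs
  (not fewer) because the gated model converges more slowly than the
  ablated one, and the comparison the study mirrors is between converged
  models; comparing half-trained variants measures convergence speed, not
  module value.

A caveat on the ablation study: because the generator omits exactly the
interference mechanisms the semantic gate targets, the SGA-ablated variant
— smaller and faster to converge — can match or exceed the full model on
these idealized scenes at desk-scale training budgets.  The packaged
direction test documents this honestly; the module comparison on real
benchmark cubes requires `scripts/run_benchmark.py`.

## Known limitations

- Pure-NumPy training is single-core and orders of magnitude slower than a
  GPU framework; the full 100-epoch benchmark protocol
  (`scripts/run_benchmark.py`) is provided but takes hours per dataset.
- The exact wiring of the four MSIE branches is pinned by the parameter
  budget (66,048 per block) rather than by an unambiguous diagram; the
  serial-chain branch sums its intermediate and final maps.
- The encoder's non-w_p channels are discarded after map extraction; the
  weight map is the SGA block's only product.
- `kappa` is undefined when expected agreement is 1 without perfect
  agreement; that case is unreachable for real confusion matrices and the
  single-cell perfect case returns 1.
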