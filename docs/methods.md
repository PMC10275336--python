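# Methods

This note documents the models, conventions and numerical choices behind
`fasciseg`. The toolkit targets segmentation of nerve fascicles in
microCT-style image stacks of peripheral nerve (e.g., osmium-stained human
vagus nerve imaged at 10 μm in-plane resolution), and — as importantly — the
evaluation of such segmentations at both the pixel and the fascicle level.

## The segmentation problem

A nerve cross-section shows bright fascicle bundles inside a dimmer
epineurium sheath on a dark background. Staining is uneven along and across
specimens, contrast drifts from slice to slice, and osmium precipitates
produce very bright specks. Fascicles occupy only ~5% of the pixels of a
typical frame, so a plain cross-entropy pixel classifier is dominated by
background; the segmenter therefore trains with a soft Dice loss.

## Synthetic phantoms (`fasciseg.synthetic`)

Because real microCT volumes are large, hand-labeled and external, every
stage of the toolkit is exercised on generated phantoms whose statistics
mirror the relevant properties of the real data:

- **Geometry.** An elliptical epineurium (semi-axes ~0.33–0.41 of the frame)
  containing `n_fascicles` smooth star-shaped blobs (radial harmonics 2–5,
  amplitude ≤ 15%). Blob centers drift smoothly along the stack axis;
  ground truth satisfies fascicle ⊆ epineurium by construction.
- **Sizes.** Per-fascicle areas are stratified over the four size classes
  used in evaluation (tiny < 20,000 μm², small < 90,000, medium < 300,000,
  large ≥ 300,000) and then rescaled so the mean fascicle pixel fraction
  matches `target_fascicle_fraction` (default 0.05, i.e., the ~5% class
  imbalance of real frames). Classes infeasible for a small frame (a single
  instance would exceed half the area budget) fall back to the feasible
  range.
- **Intensity.** Three-level model (background 3,000 < epineurium 7,000 <
  fascicle 12,000 on the 16-bit scale) with multiplicative per-slice
  brightness drift (default ±10%) and additive Gaussian noise. These levels
  are free parameters of the phantom recorded in the stack's sidecar
  config; they are not fitted to any dataset.
- **Artifacts.** Poisson-distributed bright specks per slice with values
  drawn above 18,000 (default 19,000–30,000), so the preprocessing
  saturation rule is always exercised; when `artifact_density > 0` at least
  one speck per stack is guaranteed.
- **Merge/split events.** Real vagus fascicles merge or split along the
  nerve roughly every 0.56 mm. The generator schedules Poisson-many events
  per `merge_split_rate` (events/mm, default 0.5 — a deliberately tunable
  stand-in, not a measured rate) and moves the two involved blob centers
  together over a ±0.25 mm window until they overlap, producing a genuine
  change in connected-component count along z.
- **Determinism.** One `numpy` RNG stream seeded from `params.seed` drives
  everything; identical parameters give bit-identical stacks.

What the phantoms do **not** model: anatomically realistic fascicle shapes
and counts, perineurium rings, partial-volume effects at fascicle borders,
spatially correlated noise, stitching seams, or staining gradients along
the nerve. Passing tests on phantoms therefore demonstrate the correctness
of the pipeline's mechanics and metrics, not expected accuracy on real
microCT data.

## Stack handling (`fasciseg.stacks`)

- Images are 16-bit TIFF (multi-page or `<nerve>_slice_<idx:04d>.tif` per
  slice, 1-based indices in filenames); masks are 8-bit 0/255 TIFFs
  binarized at >0 on read. A JSON sidecar records spacings and generator
  parameters.
- **Down-sampling along the nerve** copies every `factor`-th slice,
  keeping 1-based positions `factor, 2·factor, …` — a 512-slice volume at
  factor 10 yields 51 slices. Starting at slice 1 would yield 52; the
  convention here reproduces the 51-slice bookkeeping used with real
  5.12 mm sub-volumes.
- **Grouped cross-validation.** Leave-one-nerve-out folds keep all slices
  of a nerve on one side of every split (adjacent slices are strongly
  correlated; splitting them across train/validation would leak). An
  optional test nerve is excluded from all folds.

## Preprocessing (`fasciseg.preprocess`)

Per slice, in order:

1. **Border exclusion** removes slices whose epineurium mask touches the
   frame or is empty (their centroid/crop would be meaningless).
2. **Centering crop**: a `size × size` window (default 400) centered on the
   epineurium centroid, rounded half-away-from-zero; out-of-frame parts are
   zero-padded (zero = background in microCT).
3. **Contrast enhancement** 16 → 8 bit: values above the saturation
   threshold (default 18,000, the staining-artifact cut) are set to 0;
   tail quantiles (default 0.1%) of the *remaining* pixels map to 1 and
   255; the rest rescale linearly (rounded to nearest, ties to even).
   Excluding the zeroed artifact pixels from the quantiles keeps a large
   zero mass from corrupting the low tail. A constant (degenerate)
   non-saturated image maps to 255 with a warning.
4. **Normalization** divides by the slice mean (float32, output mean 1
   within 1e-6).
5. **Gaussian smoothing**, σ = 1 px, reflective boundaries. Smoothing is
   applied after normalization; the relative order is a fixed convention
   recorded in each slice's provenance record.

Tail quantiles are computed per slice, matching the per-image processing
of the rest of the chain.

## Augmentation (`fasciseg.augment`)

Applied on the fly to training pairs only, each transform gated by an
independent Bernoulli draw, in fixed order: rotation 0–270° (p = 0.5) →
vertical flip (p = 1/3) → horizontal flip (p = 1/3) → scaling 0.9–1.2×
(p = 2/3) → additive Gaussian noise with σ ~ U[0.001, 0.003] (always; the
input is on the mean-1 normalized scale) → multiplicative intensity field
f(x, y) = A·sin(ax) + B·sin(by) + 1 with A, B, a, b ~ U[0.001, 0.3]
(p = 0.5). Conventions fixed here:

- The intensity field *multiplies* the image: the field is centered at 1
  and an additive term of order 1 would dominate a mean-1 image.
- Sine arguments use raw pixel indices (at a = 0.3 the field oscillates
  with period ~21 px, a plausible shading scale).
- Rotation angles are uniform on [0, 270]; exact multiples of 90° take a
  lossless permutation path (`np.rot90`), other angles interpolate the
  image bilinearly and the mask by nearest neighbor.
- Geometric transforms share one parameter draw between image and mask, so
  ground truth never moves relative to its image.

## U-Net segmenter (`fasciseg.segmenter`, `fasciseg._nn`)

Standard U-Net: per level two 3×3 same-padding convolutions + ReLU, 2×2
max-pool down, nearest-neighbor upsample + 3×3 convolution up, skip
concatenation, final 1×1 convolution + sigmoid. Same-padding keeps output
size equal to input size (inputs must be divisible by 2^depth). Widths
double per level from `base_channels`.

The network runs on a small numpy engine written for this package: im2col
convolutions (forward and both backward products are single BLAS matmuls;
the input gradient is a convolution with the flipped, channel-transposed
kernel), hand-written pooling/upsampling gradients, and Adam. All layers
preserve the floating dtype, so the same graph runs in float32 for training
and float64 for the numerical-gradient tests that guard correctness.
He-normal weight init, zero biases, one seed for weights, batch shuffling
and augmentation. A note on gradient checks: with zero biases a fully dead
input patch puts a pre-activation exactly on the ReLU kink, where finite
differences pick up the subgradient; checks therefore jitter biases first.

**Loss.** Soft Dice `1 − (2Σpt + ε)/(Σp + Σt + ε)` with ε = 1 (pixel-count
units), summed over the whole mini-batch; ε stabilizes empty-mask batches.

**Schedule** (reference recipe): Adam, initial learning rate 5e-4 multiplied
by 0.75 every 8 epochs, mini-batch 20, 60 epochs. Model selection keeps the
best-validation-Dice weights (the alternative — last epoch — is noisier and
was not used).

**Stability.** Pure Dice loss has a known failure mode: its gradient scales
inversely with the predicted-plus-true foreground mass, so when the
predicted mass shrinks the gradient can spike by orders of magnitude, a few
Adam steps later the output sigmoid saturates to all-background, and from
that state the gradient is exactly zero — training never recovers. Training
therefore clips each mini-batch gradient to a global L2 norm of 1
(`TrainConfig.grad_clip_norm`, roughly 3× the typical healthy norm at desk
scale; 0 disables). Clipping changes neither the loss nor the schedule and
also speeds up early convergence by damping the oscillation that precedes
collapse.

**Scales.** Full scale is depth 4 / base 64 on 400 px crops — sized for the
real data and long CPU runs. The shipped experiments use the desk scale:
depth 2 / base 16 on 128 px phantom crops, 2 training nerves × 22 slices,
22 epochs, batch 4 — sized so a complete train/evaluate cycle finishes in
minutes on one CPU while leaving the optimization dynamics intact.

## Evaluation metrics (`fasciseg.metrics`)

- **Pixel level.** Dice `2|T∩P|/(|T|+|P|)`, precision `|T∩P|/|P|`, recall
  `|T∩P|/|T|`. Convention: both masks empty → 1 (needed for degenerate
  synthetic slices; an empty denominator against a nonempty partner → 0).
- **PR sweep.** Thresholds 0 to 1 in steps of 0.02 (51 points), metrics
  pooled over all pixels of the stack per threshold; AUC by trapezoid over
  recall; the optimal threshold is the Dice argmax on the grid. For the
  AUC integral only, a threshold with an empty prediction contributes the
  limiting precision 1 (the reported curve keeps the 0-convention above);
  with a single distinct recall value the AUC degenerates to the rectangle.
- **Instance level.** Masks are decomposed into 8-connected components
  (labels in raster order of first pixel; 8-connectivity avoids spuriously
  splitting thin diagonal structures, and is configurable). The IoU matrix
  holds `|True_i ∩ Pred_j| / |True_i ∪ Pred_j|` for every pair. At matching
  threshold t: a row whose maximum reaches t is a detected fascicle (TP),
  otherwise a miss (FN); a column whose maximum is below t is an addition
  (FP); detection F1 = TP/(TP + (FP+FN)/2). Rows (columns) with more than
  one entry above the effective overlap threshold 0.1 flag split (merged)
  fascicles; 0.1 is deliberately far below the matching threshold so that
  partial overlaps still register as merge/split evidence. At t ≤ 0.5 a
  predicted component may support two TP rows; this is not double-penalized
  because splits are tallied separately.
- **Size stratification.** Areas in μm² (pixel count × spacing²) binned
  half-open downward: exactly 300,000 μm² is large, exactly 20,000 is
  small. Misses and splits are sized by the true fascicle; additions and
  merges by the predicted one — in each case the instance that is actually
  observable.
- A brute-force pixel-set oracle (explicit coordinate sets, BFS components)
  re-implements every instance metric independently; the test suite and
  the acceptance script require exact agreement on hundreds of randomized
  mask pairs.

## Degenerate inputs

Empty fascicle masks (label count 0), single-pixel fascicles, masks or
epineurium touching the frame, and fully saturated slices are first-class
inputs: the generator produces them on demand (`generate_edge_case_slice`)
and every metric and preprocessing step has a defined, tested behavior for
them (see conventions above).

## Known limitations

- The numpy engine trains small networks in minutes but is not suited to
  the full-scale configuration on real volumes; the architecture and
  training loop are identical, only slower than a GPU framework.
- Phantom realism is deliberately limited (see above); accuracy numbers on
  phantoms (validation Dice ≈ 0.9 at desk scale) say nothing quantitative
  about real microCT performance.
- Instance matching is 2D per slice; volumetric (3D) fascicle tracking
  across slices is out of scope.
- Backend floating-point nondeterminism (BLAS threading) can perturb
  training at the last bit; tests that depend on training therefore assert
  tolerances, not exact values.
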