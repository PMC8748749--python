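# Methods

## The model

`rrlsrn` reconstructs a high-resolution (HR) 2D brain MRI slice `y` from a
low-resolution (LR) observation `x` produced by bicubic decimation,
`x = κ(y)` with a ×2 scale factor.  Writing `u` for bicubic up-sampling,
the reconstruction target is decomposed as

    y = u(x) + r,      r = y − u(x)

so the network only has to learn the *residual* `r` — the edge and texture
detail that interpolation loses — rather than the whole image.  The
network has two branches whose outputs are summed:

* **residual branch**: 13 convolutions (3×3, 64 channels, zero padding
  preserving size), each followed by a leaky rectifier with
  negative-region slope 0.2, closed by a 4×4 stride-2 transposed
  convolution mapping 64 feature maps to the single-channel residual at
  twice the resolution;
* **image branch**: a single 4×4 stride-2 transposed convolution applied
  to the input — a *learned* up-sampler, initialized to the exact
  bilinear interpolation kernel so the untrained network already behaves
  like a plain interpolator.

That gives 13 convolutions + 2 transposed convolutions (444,818
parameters at the default configuration).  Removing the image branch (the
"bottom transposed convolution" ablation) leaves the residual branch
output as the entire prediction, i.e. removes the residual formulation.

The feature branch consumes `x − 0.5`: [0,1] intensities carry a large DC
component that badly conditions first-layer gradient descent, and
centering it is a cost-free reparameterization.

Everything is implemented in numpy (forward and hand-derived backward
passes).  Convolutions run as im2col matrix products in channels-last
layout; transposed convolutions as 16-offset scatter/gather products.
The analytic gradients are validated against central finite differences
to 1e-4 in the test suite.

## Losses

* **Charbonnier** `mean(sqrt(d² + ε²))` with `ε = 1e-3` — a smooth L1
  surrogate whose bounded slope tolerates outliers.  The reduction is the
  mean over all pixels and batch items (chosen for learning-rate
  stability; the alternative per-image sum only rescales the gradient).
* **Gradient Difference Loss (GDL)** — for every vertical and horizontal
  neighbor pair, the squared difference between the absolute neighbor
  differences of target and prediction, *summed* per image and averaged
  over the batch.  It penalizes blurred edges directly.
* **Combined loss** = Charbonnier + `gdl_weight` × GDL.  The reference
  formulation adds the two with unit weights, but it also sums both
  spatially; with the averaged Charbonnier used here, unit weighting lets
  the summed GDL dominate by a factor of the pixel count, so the weight
  must be rescaled.  The desk recipe uses `gdl_weight = 16 /
  patch_pixels` (≈ 3.9e-3 for 64×64 patches), selected on held-out
  validation PSNR: a GDL term of this strength not only sharpens edges
  but dramatically accelerates from-scratch optimization — with the GDL
  term disabled the network stays on a plateau near interpolation
  quality for hundreds of steps, while with it training escapes within a
  few epochs.  `gdl_weight = 0` is the no-GDL ablation.

## Degradation model and patches

The degradation treats "bicubic down-sampling" as a single anti-aliased
decimation with the Keys kernel (a = −0.5), pixel-center alignment, edge
replication at borders, and per-output weight normalization (constants
are preserved exactly; an optional explicit Gaussian pre-blur exists but
defaults off, since no separate blur kernel is specified for the
operator).  Up-sampling uses the same kernel without stretching.  The
stored pair recomposes `hr = upsampled + residual` bit-exactly; on
isolated pixels where the subtraction rounds, the stored HR differs from
the input by one ulp (≈ 1e-16), far below any metric's resolution.

Training patches are 128×128 HR (64×64 at desk scale) cut at even HR
offsets, uniformly with replacement, so each LR patch is the co-located
half-resolution window.

## Training

The published recipe — momentum 0.9, weight decay 1e-4, batches of 64
patches of 128×128, learning rate 1e-5 halved every 50 epochs, driven by
classical momentum descent — is a *fine-tuning* recipe for a network
warm-started from a previously trained model.  That warm start is outside
this package's scope (the weights are not part of the method), so
networks here start from seeded variance-scaled random initialization
(He-type scaling for the leaky rectifier; near-unit-gain scaling for the
linear output layer; the image branch starts as the bilinear kernel).

From scratch, plain momentum descent cannot optimize the 13-layer stack
in a desk-scale budget: at every stable learning rate it fails to reach
even the bicubic baseline on its own training batch (hundreds of steps on
a fixed batch plateau above the interpolation loss).  The trainer
therefore exposes the optimizer as a config choice: `"momentum"` is the
default contract, and `"adam"` (β₁ = 0.9, β₂ = 0.99, bias-corrected,
with the same L2 weight decay) is what the desk recipe uses, together
with global gradient-norm clipping at 1.0 and a learning rate of 1e-3.
An *epoch* is one pass over the training set: each training image
contributes one batch of `batch_size` sampled patches and one optimizer
step.  With the 50-epoch halving period the learning rate is constant
within the 30-epoch desk runs; the schedule matters only for longer
training.

### Desk-scale experiment sizes

Chosen once as the package's standard phantom experiment:

* **Smoke run**: 20 phantoms (128×128), 15 training / 5 held-out test,
  30 epochs (= 450 optimizer steps), batches of 8 patches of 64×64 HR.
  One run takes a few minutes on one CPU core.
* **Ablation grid**: the same corpus and configuration at 12 epochs per
  run — past the optimization takeoff of the full recipe, and short
  enough that the three variants (full model, no GDL, no image branch)
  × three seeds stay affordable on one CPU.  Variants share the
  seed-derived patch sequence, making rows directly comparable.

## Synthetic phantoms

Phantoms are compositions of uniformly placed rotated ellipses (painted
in order, later wins — producing nested boundaries like cortical
ribbons) over a dark background, with band-limited Gaussian texture
(σ = 1.5 px, peak-to-peak 0.06) added to the foreground and clipped to
[0, 1].  Defaults: 128×128, 6 ellipses, grey levels 0.25–0.85 over a 0.0
background, hard edges.

They emulate the two features of MRI slices that matter for this method:
sharp tissue boundaries (where interpolation loss concentrates — the
residual is largest along edges) and partially recoverable high-frequency
texture (the σ = 1.5 px band survives ×2 decimation in part; a 7×7-tap
linear regression oracle gains ≈ +0.9 dB over bicubic on this corpus, so
learned methods have real headroom).  They do **not** model MR physics —
no bias fields, Rician noise, partial-volume effects, anatomical
geometry, or through-plane anisotropy.  Passing the phantom experiments
shows the implementation learns recoverable detail under the stated
degradation model; it does not certify performance on clinical data.

## Evaluation protocol

Slices are min-max normalized to [0, 1] (fixing the PSNR/SSIM data range
at 1.0), center-cropped to even dimensions, degraded internally, then
reconstructed by every registered method.  PSNR uses
`10·log10(1/MSE)` with `inf` as the identical-image sentinel; SSIM is
the standard windowed index (11×11 Gaussian window, σ = 1.5, K₁ = 0.01,
K₂ = 0.03, weighted-mean covariances, edge-cropped averaging), verified
against scikit-image's implementation to 1e-6.  Scores are averaged per
subject and summarized across subjects as mean, sample SD and two-sided
Student-t 95% confidence interval (both per-slice and grouped subject
aggregation are supported, since table conventions vary).

Baselines: plain bicubic; a bicubic spline surface through the LR
samples (scipy's `RectBivariateSpline`, clamped at the border); and a
compact non-local-means up-sampler (NMU) — bicubic initialization, then
alternating non-local-means smoothing (scikit-image's exact NLM) and a
block-mean consistency correction, which guarantees the output's
scale×scale block means equal the LR input to float accuracy.

## Numerical choices and edge cases

* Pipeline arithmetic is float64; the network runs float32 (a gradcheck
  dtype switch to float64 exists for tests).
* Odd-sized slices are center-cropped to even dimensions before pairing.
* GDL's sub-gradient at zero neighbor difference is taken as 0.
* `sign(0) = 0` ties, patch sampling with replacement, and uniform
  ellipse placement are all driven by seeded `numpy` generators; every
  experiment is a pure function of its seeds.
* The SSIM window requires images of at least 11×11; PSNR of identical
  images returns `inf`, and summaries containing `inf` report an
  undefined (NaN) spread rather than a fabricated one.

## Known limitations

* The desk-scale experiments demonstrate the method's mechanics, not
  clinical performance; absolute PSNR/SSIM values on phantoms are not
  comparable to values on real MRI corpora.
* Only the ×2 single-level network is implemented (no ×4/×8 cascading,
  no 3D convolutions).
* The NMU baseline is a faithful simplification of the non-local-means
  up-sampling idea, not a line-by-line port of any published variant.
* Training at the published full scale (thousands of slices, warm start,
  long schedules) is supported by the same code paths but has not been
  run here.
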