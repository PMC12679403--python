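# Methods

## Problem and approach

Blood vessels form sparse tubular networks in 3D microscopy and tomography
volumes; labelling them by hand is the bottleneck for quantitative vascular
analysis. `vesselseg3d` implements a two-stage strategy: a volumetric
encoder–decoder CNN is pretrained on a weighted mix of labelled volumes, and
the resulting checkpoint is specialized to a new imaging style by
fine-tuning on a single small labelled subvolume of the new data. Everything
needed to exercise that workflow at desk scale — data store, sampler,
network, losses, trainer, tiled inference, evaluation, and a synthetic
phantom generator that stands in for real multi-modal data — is part of the
package.

## Network

The model is a 3D U-Net: `n` encoder blocks of two 3×3×3 convolutions, each
followed by a leaky-ReLU activation (α = 0.2 by default) and group
normalization, with a 30% dropout at the end of each block and 2×2×2
max-pooling between resolution levels; `n − 1` decoder blocks of a
stride-2 transpose convolution (kernel 2×2×2, so upsampling is exact with no
checkerboard overlap), a skip merge with the same-resolution encoder
features, and two further convolution+activation layers with dropout.
Channels double per level from `base_filters` (default 32, six encoder
blocks, 64³ input → 2³ bottleneck). Because six poolings would collapse a
64³ input to a single voxel, pooling follows only the first `n − 1` encoder
blocks; the deepest block is the bottleneck.

The head is a 1×1×1 convolution to two channels with a voxel-wise softmax.
A softmax over a single channel is constant, so the "single filter +
softmax" reading is implemented as the equivalent two-channel softmax
(background/vessel) and the vessel channel is exported everywhere a scalar
probability map is needed.

The optional attention variant replaces plain skip concatenation with a
multiplicative (Luong-style) cross-branch gate: encoder map `q` and
upsampled decoder map `k` are each transformed by a trainable 3×3×3
convolution, combined by a channel-wise dot product, and passed through a
1×1×1 convolution + sigmoid to give a single-channel attention map in
(0, 1) which rescales `k` element-wise. The gated features are concatenated
with `q`, so both skip modes produce identical shapes level by level. With
all gate weights at zero the map is sigmoid(0) = 0.5 exactly — a useful
smoke test. The additive-attention alternative was deliberately not used;
the multiplicative (dot-product) form is the design point here.

All layers are implemented in numpy with hand-written backward passes.
Convolutions are evaluated as sums of shifted matrix products (one GEMM per
kernel offset), which keeps memory at one input copy per offset and routes
the arithmetic through BLAS. Correctness of every backward pass —
convolutions, transpose convolutions, max-pooling, group normalization,
attention gates, softmax, and the three losses — is verified against
central finite differences in float64 (relative error < 1e-3, typically
~1e-9) in the test suite. Weights are He-uniform initialised, biases zero;
the init seed is part of the network config.

## Class imbalance

Vessels occupy roughly 3–5% of tissue volume, so two mechanisms counter the
imbalance:

1. **Sampling.** Training patches (64³ by default) are drawn from randomly
   selected stores at random coordinates — which doubles as a translation
   augmentation — with per-dataset weights (e.g. 5:4:1:1 for four stores)
   so small datasets are not over-sampled. Patches whose vessel fraction is
   below 0.1% are kept only with probability `background_retain_prob`
   (default 0.1). The mechanism is rejection sampling with a cap of 1,000
   attempts, after which the last candidate is returned with a warning, so
   batch generation always terminates; batches with no vessels still occur,
   just far less often. The 0.1% criterion is evaluated on the raw label
   window, before augmentation.

2. **Losses.** Three imbalance-aware objectives, all reduced as means over
   voxels so magnitudes are independent of batch and patch size, with
   probabilities clipped to [1e-7, 1 − 1e-7] before any logarithm:
   * `wcce` — weighted categorical cross-entropy, per-voxel −log p of the
     true class scaled by a per-class weight. Weights default to inverse
     class frequency normalized so the smaller weight is 1; a background:
     vessel ratio of 1:7 corresponds to a 12.5%-vessel training mix. The
     large weight goes on the vessel class, the rare one.
   * `dice_bce` — (1 − soft DICE) + binary cross-entropy on the vessel
     channel, combined as an unweighted sum (a convex weight is exposed but
     defaults to 1:1). Soft (probabilistic) DICE with smoothing ε = 1 is
     used inside the loss; hard DICE is reserved for evaluation.
   * `focal` — cross-entropy scaled by (1 − p)^γ (default γ = 2), with no
     α class prefactor.

## Augmentation

In-plane rotation (±30°), isotropic in-plane rescale (1.0–1.25×), and
reflection in one or both in-plane axes, applied identically to image and
label. "In-plane" is the (y, x) plane of the fixed (z, y, x) axis order.
Rotation and rescale commute (the rescale is isotropic in-plane) and are
composed into a single centre-anchored affine resampling — one
interpolation pass instead of two. Images are interpolated linearly and
clamped back to [0, 1]; labels use nearest-neighbour and remain binary;
out-of-window voxels are filled with background (0). The recorded parameter
set is invertible (with the rotation sign conjugated through an odd number
of reflections), and a round trip restores a label to DICE ≥ 0.95.

## Data store

Volumes are ingested once: min–max normalized to [0, 1] with global
per-volume statistics (percentile clipping is available but off by
default; a constant volume maps to all zeros rather than dividing by
zero), optionally cropped — normalization statistics are computed before
cropping — and written as Zarr chunked arrays (64³ chunks by default, edge
chunks partial) with a human-readable JSON sidecar header (name, shape,
chunk shape, raw intensity range, voxel size, modality, label flag,
creation time, format version). Labels are binarized on ingest (any
nonzero → 1). Subvolume reads go through Zarr chunk indexing, so only
chunks intersecting the requested window are touched; a memory-traced test
confirms reads stay bounded by the window size rather than the volume
size. Multi-page TIFF and NIfTI readers are provided (NIfTI's (x, y, z)
storage is reordered to (z, y, x)).

## Training

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-7) with a continuous exponential decay
schedule `lr = lr₀ · rate^(step/decay_steps)`; defaults lr₀ = 1e-3,
rate 0.96 per 1,000 steps (the decay constants are this package's choice —
only the schedule family and initial rate are fixed requirements). Batch
size defaults to 6. Because sampling is random rather than a sweep over the
data, an "epoch" is defined as a fixed number of batches (default 100).
After each epoch the monitored metric (validation DICE by default; AUROC,
AP, or training loss are selectable) is evaluated on held-out subvolumes by
tiled inference; training stops at `max_epochs` or after `patience`
(default 10) epochs without improvement, and the weights returned are
always those of the best epoch. A non-finite loss aborts with an error
rather than continuing to diverge. Held-out validation regions are
contiguous blocks specified in the config.

Fine-tuning resumes from a checkpoint with fresh optimiser moments,
restricts sampling to the labelled region (which must admit at least one
patch), and scales the initial learning rate by 0.1 by default — standard
transfer practice, configurable.

Hyperparameter search is uniform random sampling without replacement over
the grid {1e-5, 1e-4, 1e-3} × {ReLU, leaky 0.1/0.2/0.3} × {10%, 20%, 30%}
(36 points, 15 iterations by default), each candidate trained under a fixed
small budget (default 5 epochs) and ranked by the monitored metric.

## Inference

Arbitrarily large volumes are predicted tile by tile (tile = the network's
input shape, overlap 16 by default, final tiles shifted flush with the
boundary so every voxel is covered). Overlapping predictions are combined
by weighted averaging with per-voxel weights normalized to 1 — uniform by
default, a Hann window optionally. Volumes smaller than a tile are
reflect-padded and cropped back. Tiles are processed one at a time, so
resident memory does not grow with volume size.

## Evaluation

Voxel-wise AUROC (trapezoidal ROC integral, equal to the Mann–Whitney
pairwise statistic; ties grouped into single threshold steps), average
precision (step-wise ΔR·P sum, no interpolation), and hard DICE /
precision / recall at a binarization threshold of 0.5 (the threshold is
reported alongside, since threshold-free AUROC/AP are also always
computed). Both classes must be present or an explicit error is raised.
Stored curve points are thinned to 1,024 quantile-spaced thresholds when
the score set exceeds 10⁴ unique values; scalar metrics always use the full
data. An optional mask restricts scoring to a labelled subvolume. AUROC and
AP are delegated to scikit-learn and cross-checked in the tests against
brute-force pairwise and exhaustive-threshold oracles.

## Synthetic phantoms

The phantom generator is the package's stand-in for a multi-modal training
catalogue; it emulates the statistics that matter for this pipeline, not
the physics of any instrument. Geometry is a forest of random-walk
centerline trees (bounded direction perturbation per step, stochastic
bifurcation, child radius = parent × taper 0.8, radii 2–5 voxels, growth
stopping at the boundary, minimum radius, or when the rasterized vessel
fraction reaches a target drawn from 3–5% — the typical blood volume
fraction of tissue). Labels are the union of capsules (sphere-swept
polylines with linearly interpolated radii) rasterized exactly from
point-to-segment distances; the rasterizer matches a brute-force all-voxel
oracle bit for bit, so ground truth is unambiguous. Images are rendered as
blur(fg·label + bg·(1 − label)) + artifacts + Gaussian noise, min–max
normalized and clamped; rendering never alters the labels.

Two artifact styles supply the domain shift for the transfer story:
`haze` emulates out-of-plane fluorescence (as in episcopic imaging) by
adding "ghost" vessels — copies of the dilated vessel structure shifted
along z by 8–24 voxels, lightly blurred (σ = 1.5) and scaled to 0.6× the
vessel contrast — inside randomly chosen z-slabs. Ghosts are deliberately
tubular and bright enough that a model trained without the artifact labels
them as vasculature (depressing its precision), while remaining dimmer and
softer than true vessels so a fine-tuned model can learn to reject them.
`depth_falloff` multiplies the pre-noise signal by exp(−z/τ) (two-photon
attenuation). What phantoms do **not** model:
instrument PSF anisotropy beyond a per-axis blur sigma, speckle or
structured noise, vessel wall contrast, motion artifacts, or anatomically
realistic branching statistics. Tests passing on phantoms therefore
demonstrate that the pipeline's machinery is correct and that the
pretrain → fine-tune pattern behaves as designed under a controlled domain
shift — not that any particular accuracy will be achieved on real data.

## Desk-scale benchmark

`vesselseg.benchmark` fixes the study conditions used by the acceptance
script and the slow tests: a reduced network (3 encoder blocks, 8 base
filters, 32³ patches ≈ 85k parameters), DICE-BCE, Adam at 1e-3, batch 6;
pretraining for 300 steps on two bright-vessel 96³ phantoms with a 64³
held-out phantom scored by tiled inference; then evaluation of that model
on a held-out haze phantom (where precision drops, since haze ghosts are
labelled as vessel) and fine-tuning for 100 steps at 1e-4 on a single
labelled 42×32×32 block covering 4.86% of one haze phantom. The block
spans most of the z-axis so the depth-localised artifact is represented in
the labelled data — the same reason a user labels a depth-spanning
subvolume on real data. These sizes were chosen so the
complete workflow runs in minutes on a single CPU core while still being
large enough for the transfer effect to be unambiguous.

## Numerical choices and edge cases

* float32 throughout training/inference; float64 in loss/metric reductions
  and in gradient-check tests.
* Probability clipping δ = 1e-7 guards every logarithm; gradients are
  zeroed where the clip is active.
* Max-pool backward routes the gradient to the first maximal element of a
  2×2×2 block (deterministic tie-break).
* Group-norm group count defaults to 4 and is clamped/adjusted to divide
  the channel count for narrow layers.
* Dropout is inverted (scaling at train time), disabled in inference mode;
  placed once per block after its second convolution, with an optional
  per-convolution flag.
* A global seed fans out to per-module seeds through `SeedSequence`
  spawning, so phantom generation, sampling, weight init, and training are
  independently reproducible.

## Known limitations

* Single-channel volumes only; no resampling or registration of
  anisotropic data.
* CPU-only numpy execution: fine for the desk-scale benchmark and for
  moderate inference, but full-size pretraining (6 levels, 32 base
  filters, tens of thousands of steps) wants a GPU framework; the
  declarative `NetworkConfig` is framework-agnostic by design.
* The epoch counts of a full-scale run are not reproduced; "epoch" here is
  a fixed step budget.
* No topology-aware metrics (clDice, Betti numbers) and no skeletonization;
  evaluation is purely voxel-wise.
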