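# Methods

This note records the scientific and numerical choices behind `advdefend`:
what is modelled, which knobs matter, what the synthetic benchmark does and
does not show, and where the design was genuinely open.

## Threat model and attacks

The setting is white-box and untargeted: the adversary holds the trained
3-class classifier, computes the gradient of its training loss
(categorical cross-entropy against the true label) with respect to the
input pixels, and may move each pixel by at most ε on the [0, 1] grayscale
scale (an L∞ ball around the clean image).

- **FGSM**: `x' = clip₀₁(x + ε·sign(g))`, one gradient evaluation per
  image. The tie-break `sign(0) = 0` leaves zero-gradient pixels untouched.
- **PGD**: `n_iter` steps of size `step_size`, each followed by projection
  onto the ε-ball (per-pixel clamp to `[x−ε, x+ε]`) and then to `[0, 1]`,
  in that order. Defaults `n_iter = 10`, `step_size = ε/4`,
  `random_start = False` — a conventional schedule; it is part of
  `AttackSpec` and recorded in every report. With `n_iter = 1` and
  `step_size ≥ ε` PGD is exactly FGSM, which the tests assert.

ε grid: (0.001, 0.006, 0.05, 0.1, 0.4). The two small values are
perceptually negligible and barely move a well-trained model; 0.05–0.1 is
the regime where accuracy collapses; 0.4 is far beyond clinical
plausibility and serves as a stress bound.

Attacks never mutate the clean batch, never change labels, and the
realized per-image L∞ norms are stored and validated against the budget.

## The denoising autoencoder defense

Architecture (fixed): two Conv(3×3, 32 ch, same)+ReLU / MaxPool(2×2)
stages, mirrored by two ConvTranspose(3×3, 32 ch, stride 2)+ReLU stages
and a Conv(3×3, 32→1)+Sigmoid output. Any input size divisible by 4 is
accepted; the parameter counts (320, 9 248, 9 248, 9 248, 289 — 28 353
total) are independent of the spatial size, and at 224 px the bottleneck
is (56, 56, 32).

Training reconstructs *clean* images (input = target) under MSE with Adam,
lr 10⁻³, 30 epochs, batch 128 by default. A noisy-input → clean-target
variant sits behind the `noisy_input` flag; the clean-reconstruction mode
stays the default. Early stopping (patience on validation MSE) exists but
is off by default so the fixed epoch budget is honoured. The autoencoder's
validation split is 10% of the clean training images, seeded. Weight
initialization is He-normal for convolutions and Glorot-uniform for dense
layers, from the recorded seed.

Why it works: a 4× spatially-downsampled 32-channel code can represent the
smooth anatomy (background, consolidation, haze) but not an arbitrary
per-pixel adversarial field, so reconstruction projects an attacked image
back toward the clean image manifold. This also caps what the defense can
pass through: image detail finer than the bottleneck's Nyquist scale is
attenuated, which is why defended accuracy sits well below clean accuracy
even as it recovers tens of points over the attacked accuracy — the same
partial-recovery pattern reported for full-scale CXR experiments.

## Classifiers

Every classifier consumes grayscale `(n, h, w, 1)` batches; a
channel-replication adapter inside the model boundary produces the
3-channel tensor the backbones expect. Classifying a grayscale image is
therefore bit-identical to classifying its explicit 3-channel replication,
and the attack gradient is the adjoint (channel sum) of that replication —
both are tested.

- `tinycnn` (runnable, default width 32): Conv(3→16)+ReLU+MaxPool →
  Conv(16→32)+ReLU+MaxPool → GAP → Dense(32)+ReLU → Dense(3). It needs no
  pretrained weights and trains to ≥ 90% validation accuracy on the
  synthetic benchmark in seconds.
- VGG16 / VGG19 / MobileNetV2 / DenseNet169: analytic catalogs that walk
  the published layer configurations and report output shapes and
  parameter counts exactly (MobileNetV2 feature extractor: (7, 7, 1280),
  2 257 984 parameters; DenseNet169: (7, 7, 1664)). They are summary-only:
  forward or gradient calls raise a capability error naming `tinycnn` as
  the runnable alternative, because ImageNet weights cannot be bundled
  with the package.
- Stack model: each backbone → global average pool → flatten →
  concatenate → BN → Dense(256)+ReLU → Dropout → BN → Dense(128)+ReLU →
  Dropout → Dense(3). Dropout rate defaults to 0.3 (unstated upstream;
  configurable). With the published backbone widths (1280, 1664) the head
  counts are 11 776 / 753 920 / 1 024 / 32 896 / 387; with other widths the
  builder recomputes the counts and warns. The stated loss for this model
  is a binary cross-entropy, which is incoherent with a 3-way softmax;
  categorical cross-entropy is used.
- Training: Adam on cross-entropy; the published stack recipe
  (lr 10⁻⁴, 30 epochs, batch 21) is the `ClassifierTrainConfig` default.
  Backbones are frozen and heads trainable by default for transfer models;
  the desk-scale tinycnn is trained end-to-end.

The engine (`advdefend.nn`) is plain numpy with exact adjoints for every
layer; finite-difference tests cover each layer and the composed models in
float64. Seeded training is bit-reproducible run-to-run on the same
platform (single-threaded numpy kernels; BLAS-version differences across
platforms can change results in the last few ulps, which shuffled
minibatch order can then amplify).

## Synthetic benchmark

The generator emulates three radiographic classes on a smooth thorax-like
background (vertical intensity gradient plus mild vignette):

- **bacterial**: one bright focal consolidation — a Gaussian blob with
  per-image jittered position (0.35–0.65 of the frame), width
  (σ = 0.14–0.20) and amplitude (0.50–0.65);
- **normal**: background only, with a small per-image brightness shift;
- **viral**: a diffuse perihilar haze plus fine oriented streaking with
  jittered frequency (6–9 cycles/frame), orientation and phase — an
  interstitial-pattern stand-in.

All images get additive Gaussian pixel noise. `noise_sd` defaults to 0.03
— mild quantum-mottle-scale noise: strong enough that denoising is a real
task, weak enough that the class signal lives in the structural motifs
rather than the noise field. The realized per-image noise level varies
uniformly in ±50% around `noise_sd` (exposure variation), so a classifier
cannot anchor on one exact noise energy. The generator is a pure function
of its config: each (split, class) stream has its own seed child, and the
defaults (100 images per class per split, 64×64, seed 7) are used
throughout the tests.

What the benchmark does show: the qualitative robustness pattern — a ≥ 90%
clean baseline, catastrophic accuracy loss at ε ≥ 0.05, PGD at least as
damaging as FGSM, and substantial (but partial) recovery through the
denoiser. What it does not show: real anatomy, class overlap, label noise,
JPEG artifacts, scanner variation, or the absolute accuracies of
full-scale pretrained-backbone experiments on real radiographs — those
numbers are not expected to transfer and are not asserted anywhere.

## Problem sizes and numerics

The end-to-end robustness benchmark (`advdefend.benchmark`) runs at 32×32
with 100 images per class per split, 20 classifier epochs (lr 2×10⁻³,
batch 21) and 20 denoiser epochs (lr 10⁻³, batch 32) — sizes chosen so a
full 3-seed sweep of both families over the five-ε grid completes in a few
minutes on one CPU while leaving the qualitative pattern stable across
seeds. The published 30-epoch/batch-128 recipes remain the library
defaults for full-scale use; the desk-scale numbers live only in the
benchmark/CLI config layer.

Numerical conventions: float32 tensors for training (float64 in gradient
tests); metric accumulation in float64; ε-budget checks with tolerance
10⁻⁶; weighted precision/recall/F1 define 0/0 = 0; percentages are
reported on the 0–100 scale; images are persisted as lossless 8-bit PNG by
default because lossy JPEG re-encoding perturbs ε-bounded pixels (the
codec is recorded in every manifest, and round-trips are exact up to the
8-bit quantization of ≤ 1/255 per pixel).

Degenerate inputs: empty training sets, single-class labels, non-divisible
input sizes, out-of-range percentages, mismatched shapes and pre-existing
output folders all raise typed errors (`ConfigError`, `DataError`,
`ShapeError`, `CapabilityError`, `NumericError`) that the CLI maps to exit
codes 2/3/4.

## Reproducibility

One global seed fans out to per-stage seeds via
`SeedSequence([seed, crc32(stage_name)])`, so data generation, classifier
training, denoiser training and each attack family are independently
reproducible. Every CLI run writes a manifest with the effective config,
stage seeds, package version and SHA-256 digests of emitted files.

## Known limitations

- Pretrained backbones are catalogs, not runnable models; transfer-model
  robustness numbers on real radiographs cannot be produced offline.
- The numpy engine is single-threaded and desk-scale; it is not a
  framework replacement.
- The defense is evaluated against attacks crafted on the *undefended*
  classifier; an adaptive attacker who differentiates through the
  autoencoder would do better. That evaluation protocol matches the
  defense-as-preprocessing setting this package studies.
- The synthetic classes are far better separated than real pneumonia
  subtypes; absolute accuracies here are optimistic by construction.
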