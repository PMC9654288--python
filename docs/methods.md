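# Methods

## Wavefield propagation

Free-space propagation uses the angular spectrum method: a field sampled at
pitch Δ is Fourier-transformed (unshifted FFT layout, frequencies
f = k/(NΔ)), multiplied by `H(f_x, f_y; z) = exp(i 2π z √(1/λ² − f_x² − f_y²))`
and transformed back. Conventions and consequences:

- **Evanescent handling.** Frequencies with `f_x² + f_y² ≥ 1/λ²` are zeroed
  rather than exponentially decayed; at the micrometre-to-millimetre
  distances used here the difference is below round-off, and zeroing is the
  numerically stable convention. On the propagating band `H` is unitary, so
  band-limited fields conserve energy and `propagate(z)∘propagate(−z)` is an
  exact inverse; these identities are tested to 1e−6.
- **Wrap-around.** The FFT imposes periodic boundaries. For extended,
  smooth fields this is negligible; for point-like sources `propagate`
  accepts a `pad_factor` that embeds the field in a zero grid before
  propagating (linear-convolution padding). The engine is validated against
  a brute-force evaluation of the first Rayleigh–Sommerfeld diffraction
  integral for a point source on a 16×16 grid sampled at λ/2: with
  `pad_factor=256` and z = 11 µm the amplitude maps agree to better than
  1e−3 relative L2 error; padding that large is needed because the RS kernel
  decays only as 1/r². A propagated Gaussian beam matches the closed-form
  width law w(z) = w₀√(1+(λz/πw₀²)²) within 2%.
- **Amplitude/phase codec.** Fields are stored as amplitude (modulus) and
  phase (argument in (−π, π], quadrant-aware arctangent; the −π edge folds
  to +π, and zero pixels get phase 0 so the codec is deterministic and
  exactly invertible).
- **Defaults.** λ = 0.532 µm (typical green DHM laser) and 1.0 µm object-
  plane pitch. Both are configuration fields; no physics is hard-coded to
  them.

## Synthetic hologram simulator

The simulator emulates background-subtracted in-line hologram crops of
clustering micro-algae so that the classification pipeline can be exercised
without the original (private) recordings.

- **Scenes.** A TRC-k scene draws its member count uniformly from
  k ± ⌊k/4⌋ — counts between categories belong to the geometrically nearest
  power of two, e.g. 6→8 and 12→16 — and places fusiform rods (major axis
  8–15 µm, minor 2–3 µm, amplitude transmittance 0.15–0.45, small phase
  shifts ≤ 0.15 rad) in a compact cluster whose lateral spread grows as √k,
  with ±5 µm axial jitter so large conglomerates genuinely extend out of any
  single focal plane. SP scenes hold 1–3 discs of 2–4 µm; DEBRIS scenes hold
  2–6 faint irregular blobs. Particles are mostly absorbing because strong
  phase objects act as weak lenses and displace the plane of best amplitude
  contrast — with small phase shifts the sharpest reconstruction coincides
  with the geometric focal plane, which keeps "in focus" well defined.
  Cluster depth is re-centred to mean zero (crops in the emulated pipeline
  are focused per object).
- **Recording.** The object plane is a multiplicative thin-object
  transmittance (each particle's factor propagated to its own axial offset);
  the sensor at 300 µm records intensity only; the stored hologram is
  I − |reference|², plus Gaussian sensor noise (σ = 0.01). Re-embedding adds
  the unit background back and takes √·, which discards the sensor-plane
  phase — the twin image is therefore present in every reconstruction, as in
  a real intensity recording. No phase retrieval is attempted.
- **Autofocus.** The reconstruction is refocused to the plane of maximal
  Tamura amplitude contrast (√(std/mean), a standard hologram autofocus
  score) on a fine ladder (±24 steps of 3.43/4 µm), emulating the manual
  focusing of the real crops. Consequently the stored plane maximises
  sharpness on the coarse 13-slice ladder for ≥95% of samples, and
  defocusing a sample by d moves the sharpest slice by round(−d/3.43 µm) for
  ≥90% — both are tested.
- **What it does not model.** Radiometric calibration, partial coherence,
  flow dynamics, full-frame object localisation, camera nonlinearity.
  Passing tests therefore demonstrate the pipeline's correctness and the
  *direction* of the volumetric advantage on controlled data, not absolute
  accuracy on any real instrument.
- **Defaults.** Class counts halve per doubling TRC size (320/160/80/40/20,
  SP 160, DEBRIS 80) to reproduce the characteristic class imbalance; the
  counts are arbitrary configuration defaults, not measured frequencies.

## Volumes and augmentation

`build_volume` re-embeds the stored amplitude/phase pair and propagates it
k·3.43 µm for k = −6…6, giving a (2, 13, H, W) stack whose middle slice is
the stored reconstruction. Defocus augmentation propagates the *base*
hologram by d ~ U(−13.72, +13.72) µm before the volume is built, so the
in-focus slice shifts away from the middle — the same perturbation an
autofocus error would cause. Geometric augmentation uses right-angle
rotations and flips only: they are exact on the phase channel (arbitrary-
angle interpolation would create wrap artifacts) and are applied identically
to every depth slice. Defocused *test* sets are one fixed seeded draw per
sample, reused across all models being compared.

## Architecture

Both classifiers share four ResConvBlocks (Conv–BN–LeakyReLU ×2, a
1×1(×1)-projected additive skip, then 2×2 spatial max-pooling that leaves
depth untouched) and a dense head (depth max-pool — 3D only — adaptive 2×2
spatial average-pool, flatten, dropout 0.5, Linear→LeakyReLU→Linear→
LogSoftMax). Defaults: 3×3(×3) kernels, channel plan (16, 32, 64, 128),
dense width 128, LeakyReLU slope 0.01; everything is configurable. The final
linear layer is initialised small (×0.01) so training starts from
near-uniform predictions and the initial loss is ln(n_classes). Inputs must
be spatially divisible by 16 and at least 32 (four poolings plus the 2×2
average pool).

The compute engine is a purpose-written numpy layer library
(`holoclass.nn`): channels-last layout, convolutions evaluated offset-by-
offset as contiguous GEMMs, manual backpropagation verified against finite
differences in float64, and Adam with L2-style weight decay added to the
gradient. Evaluation mode is deterministic; training determinism follows
from seeding every random draw.

## Training protocol

Stratified 85:15 train/test split, then stratified k-fold cross-validation
of the training set (default k = 5); fold i trains with seed `seed + i`.
Class weights are inverse-frequency, normalised to mean 1, computed from
each fold's training labels only. The loss reduction is the weight-
normalised mean (a plain mean is available); on log-softmax outputs this
equals weighted cross-entropy on the raw scores, which is asserted in the
tests. Adam defaults to the full-scale protocol (lr 2e−4, weight decay
0.01); early stopping monitors validation loss (smoother than accuracy on
small folds) with patience 10 and restores the best epoch's weights,
including batch-norm statistics.

## The scaled-down study

`holoclass.experiment.run_experiment` reproduces the full comparison at a
size a single CPU core can train in minutes: 4 classes (TRC1, TRC2, TRC4,
SP), 150 samples per class, 64×64 crops, channel plan (8, 16, 32, 32),
dense width 64, 2-fold cross-validation. The planar model trains from
scratch (batch 8, lr 2e−3, ≤24 epochs, patience 8); because from-scratch
training at this scale occasionally settles in a poor basin, each fold
trains two random restarts and keeps the lower validation loss (model
selection never touches the test split). The augmented planar model
fine-tunes the selected plain one under defocus augmentation (lr 1e−3, ≤10
epochs); whenever defocus augmentation is active, the validation fold
receives one fixed seeded defocus draw, so early stopping and model
selection see the input distribution the model is being trained for.
Training the volumetric model from random initialisation needs
several times more steps than the planar one before it leaves chance
level — consistent with the order-of-magnitude wall-time gap between the
two models at full scale — so the study warm-starts it instead: the trained
kernels of each fold's *augmented* planar model (the strongest planar base)
are inflated into the centre depth slab of the 3D kernels (zeros elsewhere,
batch-norm statistics and head copied), after which the volumetric model is
fine-tuned on volumes under the same defocus augmentation (batch 4, lr
2.5e−4, ≤2 epochs) — i.e. the study's volumetric condition is the
defocus-augmented variant of the 3D model. Robustness is
evaluated on five independent seeded draws of the defocused test set,
shared across models within each draw; the directional claims — the
volumetric model matches or beats the planar one on defocused inputs, and
defocus augmentation improves the planar model there — are counted as wins
across draws. Because the volumetric model inherits an augmentation-trained
base, its defocused advantage over the plain planar model mixes the
volumetric-input effect with the augmentation effect; the cleaner
single-factor contrast in the study is augmented-vs-plain planar. All
randomness derives from the single study seed.

## Known limitations

- Accuracies from the scaled study are not comparable to any full-scale
  number: dataset, resolution, class set, widths and training lengths all
  differ, and the synthetic task is cleaner than real recordings.
- The warm-started volumetric and augmented models inherit their planar
  initialisation; comparisons are between *training conditions*, not
  independent random restarts.
- Batch-norm with small batches makes individual validation curves noisy;
  the best-epoch restore absorbs most of it but per-fold accuracy can vary
  by several points between seeds.
- The simulator's thin-object, first-order recording model omits multiple
  scattering; very dense conglomerates are optically thicker in reality.
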