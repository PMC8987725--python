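# Methods

This note records the models the package implements, the defaults and the
design choices behind them, and what the synthetic benchmark does and does
not establish.

## Synthetic patch benchmark

Each of the six classes (three broadleaf weeds, three crops) is an
appearance spec: mean reflectance per channel (3 RGB channels, or 5
multispectral bands ordered blue 475, green 560, red 668, near-IR 840,
red-edge 717 nm), a Gaussian pixel-noise level, and a leaf-texture model of
Gaussian blobs (Poisson count with intensity `blob_density` per pixel,
radius uniform in `blob_radius`, amplitude N(0, 0.15)).  A patch is
base mean + blobs + i.i.d. noise, clipped to [0, 1].  Blob amplitudes are
zero-mean so the per-channel patch mean is an unbiased estimate of the
class mean; clipping bias is negligible for the default palettes, which
stay well inside the unit interval.

Defaults mirror the reference collection: per-class train counts
(370, 252, 227, 490, 490, 458) totalling 2,287, test counts
(158, 108, 97, 210, 210, 196) totalling 979, patch side 227, rotation
augmentation by quarter turns (4× the data, labels preserved).  Tests and
the acceptance script use side 32 and smaller per-class counts to keep a
full run of the suite in minutes on one CPU; side and counts are plain
arguments.  Noise sd 0.05 against palette separations of roughly 0.05–0.15
per channel makes single pixels ambiguous but patch statistics reliable —
"realistically separable" rather than trivially so.

What the generator does **not** emulate: spatial correlation between
neighboring patches, illumination/atmospheric variation, soil background,
growth stages, class imbalance beyond the fixed counts, or any geometric
structure of real canopies.  Passing tests therefore demonstrate that the
algorithms behave as specified on controllable data, not that the printed
real-field accuracies transfer.

Storage: RGB as 8-bit PNG, multispectral as 16-bit 5-band TIFF, with a CSV
manifest (filename, one-hot label code, class name, split, modality).
Round-trips are exact up to the integer quantization.

## Swarm optimizers

Both algorithms minimize a black-box fitness over a bounded box (default
[0.1, 20]² for the weight/bias learning-rate factors, which covers every
recorded run value).

**PSO** uses the standard velocity/position recursion with per-particle,
per-dimension uniform draws r₁, r₂ and the linearly decreasing inertia
ω(t) = ω_min + (ω_max − ω_min)(T − t)/T; a step at completed-iteration
count t uses ω(t), so the first step runs at ω_max.  Velocities are
clamped to [−2, 2] and positions to the box.  Defaults: 30 particles,
20 iterations, c₁ = c₂ = 2, ω ∈ [0.8, 1.2].

**Bat algorithm** (10 bats, frequency band [−1, 1], max pulse rate
r⁰ = 0.85, initial loudness A₀ = 0.1): per bat, frequency
f = f_min + (f_max − f_min)u, velocity v ← v + (x − x*)f clamped to the
box width, and candidate x + β(t)v with the time factor
β(t) = 1 + sin(π/2 − πt/2T) ∈ [1, 2] (t = 1..T, so the final step has
β = 1 exactly).  With probability 1 − rᵢ the candidate is replaced by a
local walk x* + mean-loudness · N(0, I).  A candidate that improves the
bat's own fitness is accepted with probability Aᵢ, upon which
rᵢ ← r⁰(1 − e^{−γt}) and Aᵢ ← αAᵢ; the global best absorbs any evaluated
candidate that beats it, so it never worsens.  Choices that the printed
recursions leave open:

- The frequency formula as printed, f_min + (f_max + f_min)·u, collapses to
  the constant f_min for the default symmetric band; the canonical
  f_min + (f_max − f_min)·u is used, with the printed form available
  behind `printed_frequency_form=True` for fidelity experiments.
- γ = α = 0.9 (not printed; both configurable).
- Initial pulse rates are set to the t = 1 schedule value r⁰(1 − e^{−γ});
  the schedule's t = 0 value is zero, which would route every first-iteration
  move through the local walk and disable the time-factor update entirely.
- The local-walk step scale is the population's mean loudness; the velocity
  clamp reuses the box width (neither is printed).
- Per-bat draws follow a fixed order (frequency, branch, walk normals,
  acceptance — normals always drawn) so step traces can be scripted exactly.

Run consolidation: each run's best pair is rounded half-to-even, averaged
across runs, and rounded half-to-even again — the only rounding rule that
reproduces all four recorded integer averages, (8, 8) and (4, 12), from the
recorded run values.

The fitness convention is minimization; the neural-network evaluator
returns 1 − accuracy.  Global-best history is recorded per iteration and is
non-increasing by construction.

## Transfer training

The classifier is a feature extractor plus a fresh fully connected softmax
head (F·6 + 6 parameters; 24,582 for an AlexNet-shaped F = 4096).  The
tested extractor is a small fixed random conv net (conv-pool-conv-pool-
global-average-pool, F = 32) whose output is standardized per sample; the
standardization removes the arbitrary scale of random weights and makes the
head's gradient steps well conditioned.  Any extractor with a fixed-length
deterministic `features()` satisfies the contract, including genuinely
pretrained ones.

Head training is full-batch gradient descent on softmax cross-entropy with
per-group effective rates base_lr · weight_factor and base_lr · bias_factor
(base_lr = 0.01, not tuned by the swarm — only the factors are).  One
"iteration" is one gradient step, matching the small budgets used
throughout (10 during optimization-time scoring, 72/144 for final
training).  Mini-batching is available, but at these budgets mini-batch-32
SGD stalls far below the linear-separability ceiling of the features, so
the default batch size caps at 300 (i.e., full batch for the benchmark
sizes used here).  A first-step weight change is exactly linear in the
weight factor, which the tests assert.

## MAML engine

The meta-model is the 9-layer CNN (4 × [3×3 conv, ReLU, 2×2 max-pool],
then a 6-way fully connected softmax), implemented on a flat numpy
parameter vector with explicit backprop; a fixed −0.5 input shift centers
reflectance values.  Default channels (16, 32, 64, 64); the scaled test
runs use (8, 16, 16, 16) at side 32.

Inner loop: θᵢ′ = θ − α∇L_support(θ), one step by default (step count
configurable); the meta-parameters are never mutated.  Outer loop:
θ ← θ − β Σᵢ ∇L_query(θᵢ′).  First-order treatment of the adaptation
Jacobian is the default; the exact second-order gradient
(I − αH_support)∇L_query is available, with the Hessian-vector product by
central differences on the support gradient (exact for quadratic losses,
which the analytic oracle tests exploit).

Step sizes default to α = 0.1, β = 0.01 with a global-norm cap of 10 on the
outer gradient.  These were chosen from meta-training diagnostics on the
synthetic benchmark: at desk scale (150–400 outer iterations, 4 tasks per
meta-batch) smaller canonical rates such as α = 0.01, β = 0.001 leave the
model at chance, and without the norm cap individual seeds collapse.
Episodes follow standard n-way k-shot usage with both shot counts per
class: "6-shot" = 5 support + 1 query, "2-shot" = 1 + 1.  Multi-step
adaptation at α = 0.1 overshoots on 6-sample supports, so evaluation uses
the single step it was trained for.

## HOG + SVM baseline

Descriptors come from scikit-image with the benchmark geometry (6×6 cells,
2×2-cell blocks, one-cell stride = 50 % overlap, 9 unsigned bins, L2 block
norm); a 227×227 patch yields 36·36·4·9 = 46,656 features.  Gradient input
is luminance (RGB) or the near-IR band (multispectral), configurable — the
protocol does not state a reduction.  The classifier is one-vs-rest
LinearSVC with C = 1.  Because HOG is contrast-normalized and
single-channel, it discards most of the color/spectral signal that
separates the synthetic classes; that is the mechanism behind the
CNN-over-HOG ordering the tests check.

## Density statistic

ρᵢ = Xᵢ / ΣXⱼ over per-class tallies of classified units.  Fractions are
kept exact (they sum to 1 within 1e−12); display percentages are computed
in decimal arithmetic and rounded half-up to two decimals, the convention
that reproduces every nonzero cell of the three reference farmland tables
from their integer tallies.  Report formatting leaves absent classes blank
by default (matching those tables), or prints 0.00 % on request.
`survey` composed with `density` on a perfectly classified set equals the
density of the true label histogram.

## Scaled problem sizes

Default test and acceptance runs use: side-32 patches; 50/10 per-class
train/test splits for factor fitness; 150 outer iterations, 4 tasks per
meta-batch and 100 evaluation episodes per seed (3 seeds) for
meta-learning; 30/10 per-class splits for the CNN-vs-HOG comparison; and
10 seeds for the sphere-convergence and tuned-vs-default checks.  These
sizes keep a full suite run to a few minutes while leaving every
directional comparison comfortably clear of its decision boundary.

## Known limitations

- The numpy engine is single-threaded and desk-scale; it is not a training
  framework for 227-px full-size benchmarks (the generator supports them;
  training at that size is slow).
- Synthetic classes are separable mostly by per-channel statistics;
  texture plays a secondary role.  Claims about real canopy imagery are
  out of reach of this benchmark by design.
- The bat algorithm's acceptance gate uses the canonical scheme; the
  original flowcharts admit other readings, and which integer pair
  ((8, 8) vs (4, 12)) belongs to which algorithm is reported per run and
  left to the caller.
- 2-shot vs 6-shot orderings on easy synthetic classes are close; the
  package asserts the aggregate ordering over seeds and episodes, not a
  fixed gap.
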