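# Methods

This note documents the models, estimators, numerical choices and
limitations behind `speechmanifold`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## 1. Experimental design

The unit of the experiment is a *cell*: (condition, replicate seed). For
each replicate, one synthetic dataset is generated, standardized by the
global mean and SD of its training-split cells, and duplicated into two
arms: the clean arm unchanged, and the degraded arm with iid Gaussian noise
of SD `0.1 × dataset SD` added to every cell of every train and test
spectrogram. Because standardization precedes degradation, the noise SD is
0.1 in standardized units by construction. Noise is *frozen per exemplar*
(keyed by a CRC32 of the exemplar id and the replicate's noise seed): the
degraded dataset is a fixed transformed copy, not fresh noise per
presentation, so both arms train on equally static data.

Both arms share the same model-init, data, training-shuffle and geometry
seeds; per-replicate seeds are SeedSequence children of
`(base_seed, replicate)` and are recorded in the run manifest. The pipeline
serializes each arm's model and training blocks and fails the run if they
differ (the matched-capacity audit): any performance difference between
arms is attributable only to input quality.

Assumptions worth stating: degradation is modeled as additive, iid,
mean-zero Gaussian noise on log-Mel cells — it deliberately mixes spectral
and temporal disruption and does not distinguish between them; the
condition variable is dichotomous (clean vs degraded), a simplification of
what is surely a continuum.

## 2. Synthetic spoken-word generator

The generator's job is to reproduce the two statistical properties of
spoken-word corpora that the experiment depends on, with everything else
stripped away:

* **Class structure.** Every class shares `N_SHARED_RIDGES = 3`
  high-amplitude formant-like ridges (amplitude 0.7–1.0, bandwidth 2–4
  bands) — the class-general spectral scaffold (source spectrum, tilt) that
  dominates cell variance. Each class adds `N_CLASS_RIDGES = 2` *brief*,
  low-amplitude ridges (amplitude `CLASS_CONTRAST = 0.3` ± 20%, bandwidth
  1.2–2 bands, Gaussian temporal envelope of SD 0.08–0.15 of the word
  duration) — the word-identity cue, analogous to short formant
  transitions. Cue band positions are stratified: per cue slot, the classes
  occupy a shuffled regular grid across the usable band range, so
  between-class separation is homogeneous rather than left to draw luck.

  This shared-scaffold/low-contrast-cue split is the load-bearing design
  decision. When word identity is instead carried by whole high-amplitude
  ridge layouts, a small CNN drives the task to ceiling and a 0.1-SD
  degradation has nothing to act on; accuracy differences then reflect
  optimization luck, not input quality. With identity in localized
  low-contrast detail — as in real speech — the added noise erodes
  precisely the cue the classifier needs, and the clean/degraded contrast
  becomes systematic. `CLASS_CONTRAST = 0.3` places clean test accuracy of
  the default configuration in the same mid-range regime as full-scale
  spoken-word recognition, away from both ceiling and chance.

* **Within-class variability** (`VariationParams`, applied per exemplar in
  a fixed order — time warp, band shift, amplitude jitter, background
  noise — with all draws from one seeded generator, so exemplars are pure
  functions of their seed): global rate factor SD 0.03; global band offset
  SD 0.5 bands; per-ridge log-amplitude jitter SD 0.1; additive background
  noise SD 0.15 energy units. These magnitudes keep structural variability
  (shared by both arms) from swamping the iid-noise budget in which the
  degradation lives, while still making a nearest-centroid readout clearly
  imperfect. All are config-exposed.

What the generator does **not** emulate: harmonic fine structure, prosody,
speaker identity as a factor, coarticulation beyond smooth trajectories,
variable word durations, and any nonstationary noise. Consequently, passing
tests show that the pipeline's measurements behave correctly and that the
degradation mechanism produces the expected qualitative pattern on data
with speech-like class statistics; they do not certify magnitudes on real
speech.

An optional WAV path (the `<root>/<word>/*.wav` keyword-corpus layout)
feeds real audio through the same frontend; it is exercised in tests with
synthesized WAV files only.

## 3. Audio frontend

Hann-windowed frames with no padding (a signal of L samples yields
`1 + floor((L − window) / hop)` frames), power spectrum, triangular Mel
filterbank (HTK mel scale m = 2595·log10(1 + f/700)), floored log
(`log_floor = 1e-10`). Defaults: 64 Mel bands, 25 ms window / 10 ms hop at
16 kHz, fmin 0, fmax Nyquist — conventional speech values, config-exposed.
Standardization statistics are always computed on the training split alone
and applied to both splits.

## 4. Networks and training

Two architectures share one numpy layer framework (conv / batch-norm /
ReLU / max-pool / linear, hand-written backward passes verified against
numerical gradients in the test suite):

* **resnet18** — the standard 18-layer residual network adapted to
  1-channel input. The registry of extractable conv layers is the stem
  conv + 16 block convs + 3 projection-shortcut convs = 20, in forward
  order. Geometry features are flattened post-nonlinearity outputs (blocks:
  after the block's final ReLU for conv2, after the first ReLU for conv1;
  shortcut convs: their batch-norm output, which feeds the residual sum
  directly).
* **tinyconv** — 4 conv layers (8/16/32/64 channels, 3×3, each followed by
  ReLU and 2×2 max pooling) plus a linear head. It trains in CPU-seconds
  and preserves a layer hierarchy, and is the desk-scale workhorse.

Training is SGD with momentum 0.9 and cross-entropy loss, batch 32. The
library default learning rate is the conventional 0.01, but the experiment
pipeline's default is **0.002**: at 0.01 plain SGD on this task shows
mid-training divergence (error curves that collapse and recover), which
destroys cross-arm comparisons; 0.002 learns smoothly within the 10-epoch
budget. `error_curve[e]` is the running misclassification rate over epoch
e's minibatches (the conventional training-error curve); it therefore
agrees with a post-hoc evaluation of the final parameters only
approximately. Determinism: with fixed seeds the whole pipeline is a pure
function of its configuration; `deterministic_mode` documents that
contract (numpy's sequential execution makes it hold whenever BLAS
results are reproducible, which they are on a fixed machine).

## 5. Manifold geometry

`prepare_manifolds` subsamples M exemplars per class (error, never silent
resampling, if a class has fewer), subtracts the global mean (so
homogeneous, bias-free separators are the right model and Cover's count
applies), and, when the feature dimension exceeds `N_proj`, applies a
random orthonormal projection scaled by √(N/N_proj) to preserve distances
in expectation. Library defaults M = 30, N_proj = 2000; the pipeline's
desk-scale defaults are M = 20 (matching 20 test exemplars per class in
the default dataset) and N_proj = 500 (the QR orthonormalization is the
single most expensive step on wide early layers, and the mean-field
quantities are intrinsic to each manifold's affine subspace, so they are
insensitive to the ambient projection width).

`mft_analysis` implements the anchor-point procedure per class manifold:
centered points are expressed in their thin-SVD basis (rank D ≤ M−1),
scaled by the class-center norm, and augmented with a constant coordinate;
`n_gaussian_samples` (default 150) Gaussian vectors T are projected onto
{v : v·s ≤ −κ for all manifold points s}. For κ = 0 the dual of this
projection is exactly non-negative least squares (solved by scipy's NNLS —
active-set, machine-precision); for κ > 0 it is a bound-constrained convex
QP solved by L-BFGS-B. The KKT multipliers give the anchor point
s̃ = Σαs/Σα. Capacity, dimension and radius are the moments stated in the
README; the aggregate capacity is the inverse mean inverse (the correct
aggregation for loads), with a delta-method Monte-Carlo SE. Degenerate
input (a point manifold coincident with another class) raises rather than
returning an unusable number. For singleton manifolds the estimator
reduces analytically to α = 2, D = 1, R = 0, which the acceptance suite
verifies together with the independent LP route.

`separable_fraction` / `empirical_capacity` form that independent route:
exact feasibility LPs (HiGHS) for strict homogeneous separation, random
balanced dichotomies (both signs present; a labeling and its negation are
cached as one), one seeded random orthonormal projection per probe
dimension, common dichotomies across probes, and integer bisection for the
smallest n with fraction ≥ ½; α_sim = P/n*. Two statistical facts matter
for testing against `cover_fraction`: (i) for spherically symmetric
*uncentered* point sets every fixed labeling is separable with probability
exactly C(P,n)/2^P, so sampling only mixed labelings is unbiased — but
global centering (a sum-zero constraint) breaks this for small P, so the
oracle comparison uses uncentered points; (ii) with only 2^P − 2 distinct
mixed labelings, the dichotomy outcomes within one point configuration are
clustered, so the estimator's standard error is the between-repeat
empirical SE, not the iid binomial SE over all draws.

`participation_ratio` ((Σλ)²/Σλ² of the covariance spectrum) is reported
alongside as a model-free dimensionality diagnostic.

## 6. Pipeline outputs and problem sizes

The tidy result table is keyed by (condition, seed, epoch, layer, metric).
Geometry is computed epoch-wise at the final conv layer on the *test*
split (avoiding memorization artifacts) and layer-wise across the full
registry after training; the final-epoch final-layer cell is computed once
and shared by both views. Reports: learning curves, uncertainty summaries
(correct-only and all-response, labeled), epoch geometry, layer geometry,
a JSON summary of per-condition means/SDs, and a manifest echoing the
full configuration, seeds and versions.

Default desk-scale study conditions (also the acceptance script's):
tinyconv, 8 word classes × 100 exemplars (80/20 split) at 64 bands × 32
frames, 10 epochs, clean + degraded arms, 5 replicate seeds, geometry with
M = 20, N_proj = 500, 150 Gaussian samples. This runs in a few CPU-minutes.
The full-scale recipe (ResNet-18, 35 words, 4,000/1,000, 10 epochs,
σ = 0.1) ships as `configs/fullscale_speech_commands.yaml`; it requires the
external corpus and is excluded from the test suite.

## 7. Known limitations

* The degradation and the cue structure are matched at the level of
  *qualitative* effect direction; no claim is made that desk-scale effect
  sizes translate to real speech corpora.
* Mean-field capacity assumes uncorrelated manifold centers; the
  correlated-manifold extension is out of scope, so absolute α values on
  late layers (where centers correlate) should be read comparatively, not
  literally.
* Entropy/probability measures are proxies for retrieval delay; no
  reaction-time model is fitted.
* Batch-norm running statistics make resnet18 evaluation depend mildly on
  training batch composition; all comparisons hold batch schedules fixed
  across arms by construction.
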