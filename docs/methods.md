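# Methods

This note documents the models, conventions and numerical choices
behind `ecgmpa`, in the order data flows through the package.

## Synthetic ECG model

Each beat is a sum of five Gaussians, one per P/Q/R/S/T wave, with
per-class parameters (amplitude in mV, center offset in ms relative to
the R wave, width = Gaussian sd in ms).  The class signatures are
standard clinical caricatures, not fitted morphologies:

* **N** — P wave 0.15 mV at −160 ms, narrow QRS (R sd 6 ms), upright T;
* **S** — same narrow QRS with a reduced P wave; its distinguishing
  feature is timing (below);
* **VEB** — absent P wave, wide QRS (R sd 16 ms, deep slurred S wave),
  discordant (negative) T;
* **F** — elementwise average of the N and VEB wave parameters, the
  usual fusion-beat reading.

RR structure: N and F beats draw `base_rr` (default 0.8 s) plus
Gaussian jitter (sd 0.04 s).  S and VEB beats are premature: their
pre-RR is exactly `prematurity × base_rr` (default factor 0.65) and the
following non-premature beat receives a compensatory pause of
`(2 − prematurity) × base_rr` plus jitter.  Intervals are clipped at a
0.2 s floor.  R-wave centers are snapped to the sample grid (≤ half a
sample, 1.4 ms at 360 Hz) so that annotations mark the exact R sample
and noiseless beat windows equal their class template bit for bit —
this is what makes the zero-phase and argmax contracts exactly
testable.

Disturbances: white Gaussian noise sd 0.05 mV, baseline wander 0.1 mV
at 0.3 Hz, powerline 0.02 mV at 50 Hz; all configurable.  One seeded
`numpy` generator drives label draws, RR jitter and all three noise
phases/samples, and the seed is recorded in the record metadata and the
CSV sidecar.

What the generator does **not** emulate: real intra-class morphology
variability (every N beat has the same template up to noise),
non-stationary noise (motion artifacts, electrode pops), multi-lead
structure, ST-segment pathology, and annotation errors.  Passing tests
on this data therefore demonstrate that the pipeline's mechanics are
correct and that tuning behaves as designed — not that the reported
accuracies transfer to clinical recordings, where class overlap is far
larger.

## Preprocessing

The band-pass is a linear-phase FIR (windowed-sinc design, Hamming
window, 0.5–50 Hz) applied forward-backward, so the effective response
is |H|² and R peaks are not shifted.  Default order is 128 taps at
360 Hz, scaled proportionally with the sampling rate.  At such orders a
windowed design cannot realize the 0.5 Hz edge (the transition band is
several Hz wide), so the kernel is corrected by subtracting a
window-shaped DC component, which places an exact spectral null at 0 Hz
while perturbing the response by < 1% at 10 Hz and leaving > 50 dB
single-pass attenuation at 60 Hz (360 Hz profile).  Constant offsets
are thus fully rejected; very-low-frequency drift (e.g. 0.3 Hz wander)
is attenuated to a few percent.

Segmentation windows are `[R − round(0.075·fs), R + round(0.110·fs))`
with round-half-up: 27 + 40 = 67 samples at 360 Hz, 19 + 28 = 47 at
250 Hz and at 257 Hz.  Beats whose window would cross a record
boundary are dropped and counted.  Annotated R positions are trusted
verbatim; no QRS re-detection is performed.  Filtering precedes
segmentation.

## Feature descriptors

The descriptor internals are conventions fixed behind
`DescriptorProfile`, chosen to give the block widths
60/12/1/16/{32|26}/10:

* **LBP (60)** — per interior sample, an 8-bit code from comparing the
  4 left and 4 right neighbors against the center (`neighbor ≥ center`
  → 1).  Histogram bins follow the uniform-pattern taxonomy: the 58
  codes with at most 2 circular transitions get individual bins, codes
  with exactly 4 transitions pool into one bin, codes with more into a
  last bin; the histogram is normalized to sum to 1.
* **HOS (12)** — the segment is split into 6 equal contiguous
  subsegments; each contributes sample skewness and excess (Fisher)
  kurtosis, in subsegment order.  Zero-variance subsegments yield 0 for
  both by convention.
* **CM (1)** — the 5th-order central moment of the whole segment,
  chosen odd and above 4th order so it is not redundant with the HOS
  block.
* **HBF (16)** — least-squares coefficients of the segment on the first
  16 Hermite functions (physicists' polynomials × Gaussian envelope)
  centered at the R sample; the envelope width defaults to one sixth of
  the segment length, and basis columns are normalized to unit norm
  before the solve.  A rank-deficient design (degenerate sigma) raises.
* **DWT (32/26)** — the segment is Fourier-resampled to 256 samples
  (360 Hz profile) or 208 (250/257 Hz), then a level-3 orthonormal Haar
  decomposition keeps the approximation coefficients: 256→32, 208→26.
  These resample lengths are the smallest multiples of 8 near the
  segment lengths that produce those widths cleanly.
* **RR (10)** — pre-RR, post-RR, local mean (the ~10 surrounding
  intervals), global mean, the five ratios pre/post, pre/local,
  post/local, pre/global, post/global, and the local sd, all in
  seconds.  Edge beats substitute the local mean for a missing pre- or
  post-interval.

Feature extraction is deterministic; matrices round-trip through
headered CSV at full float precision (`%.17g` + round-trip parsing).

## Marine Predator Algorithm

Minimization over a box.  With population `Py` (n×d), elite matrix `E`
(top predator replicated), step constant P = 0.5, uniform `R`,
Brownian draws `R_B ~ N(0,1)` and Lévy draws `R_L` (Mantegna algorithm,
stability 1.5, scaled by 0.05 inside the update rules):

* **t < t_max/3**: `step = R_B ⊗ (E − R_B ⊗ Py)`, `Py += P·R ⊗ step`.
  A config switch (`phase1="levy"`) substitutes Lévy draws here for the
  variant in which the exploration phase is also heavy-tailed; the
  Brownian form is the default as the motion consistent with the
  fast-patrolling narrative of the method's source formulation.
* **t_max/3 ≤ t < 2t_max/3**: the first ⌈n/2⌉ rows use the Lévy rule
  `step = R_L ⊗ (E − R_L ⊗ Py)`, `Py += P·R ⊗ step`; the rest use
  `step = R_B ⊗ (R_B ⊗ E − Py)`, `Py = E + P·CF ⊗ step` with
  `CF = (1 − t/t_max)^(2t/t_max)`.
* **t ≥ 2t_max/3**: all rows use `step = R_L ⊗ (R_L ⊗ E − Py)`,
  `Py = E + P·CF ⊗ step`.

Memory saving restores any row whose archived position was strictly
better and updates the top predator; ties keep the archive, so the
reported best fitness is non-increasing.  The FADs effect applies, with
probability 0.2 per row, a long jump
`CF·(lower + u ⊗ (upper − lower)) ⊗ B` (B a Bernoulli(0.2) mask), and to
the remaining rows a pairwise-difference jump
`(FADs(1−r) + r)·(Py[p1] − Py[p2])`.  Box feasibility is enforced by
clipping after every update — the single boundary mechanism.  Each
iteration evaluates the population twice (before and after the phase
move), and both count in the reported evaluation total.

Defaults n = 20, t_max = 50, P = 0.5, Lévy exponent 1.5, FADs 0.2
follow the original formulation's conventions.  On the 5-d sphere
(bounds ±10, n = 25, t_max = 100) the optimizer reaches ~10⁻⁸ median
best fitness across 100 seeds.

## Hyperparameter tuning

Fitness is `1 − accuracy` on a stratified 80/20 holdout split,
deterministic given data, split seed and model seed.  Features are
standardized on the training split before fitting (this matters for
the SVM and kNN distance geometry).  Search boxes: SVM C ∈ [10⁻⁴, 10³]
and RBF γ ∈ [10⁻⁴, 1], both searched in log10 space (linear search
over 7 and 4 decades would be degenerate); GBDT max_depth ∈ [1, 13]
(integer, round-half-up), min-split-loss γ ∈ [10⁻⁴, 1] (log), learning
rate ∈ [0, 1] with an effective floor of 10⁻³; RF max_depth ∈ [1, 13],
feature-subsample fraction ∈ [10⁻⁴, 1], and a tree-count fraction
∈ [0, 1] mapped affinely onto 50–200 trees; kNN K ∈ [1, 13].  The RF's
second and third dimensions are this package's semantic mapping of a
generic three-parameter box onto parameters the forest actually
possesses; the 50–200 tree image keeps ensemble variance low while
staying affordable at the data sizes the package targets, and the GBDT
wrapper uses 50 boosting rounds in both the tuned and the default arm
so comparisons stay like-for-like.  Decoded values are clipped into
range, so no out-of-box configuration can ever be evaluated; an audit
log records every decoded configuration and its fitness, and a
memoization cache avoids refitting identical decoded configurations
(integer dimensions make repeats frequent).

Classifier internals are deliberately delegated: scikit-learn for SVM
(RBF), random forest and kNN, xgboost for the boosted trees.  The
tuned model is refitted at the best decoded parameters on the training
split; because the fitness is deterministic, re-scoring the stored
model reproduces the stored holdout accuracy exactly.

## Evaluation

Per-class one-vs-rest counts feed Acc, Sn, Sp, Pr and harmonic-mean F1.
A zero denominator marks the metric undefined (NaN) and excludes it
from the macro average rather than deflating it as 0; the policy is
deliberate and localized in one helper.  The "Average" row is the
unweighted arithmetic mean over classes.  Reports are written at 4
significant figures; tests compare exact fractions.

## Experiment orchestration and seeds

`run_experiment` derives four stage seeds (simulation, split,
optimizer, models) from one experiment seed via
`numpy.random.SeedSequence(seed).spawn(4)`, records them in the
manifest, and writes every artifact to the output directory.  Problem
sizes used by the shipped checks — replicate datasets of 120 beats,
five or ten replicates, MPA budgets of n = 10, t_max = 15 for tuning
and n = 25, t_max = 100 for the sphere benchmark — are the package's
desk-scale defaults, chosen so a full verification run completes in
minutes on one CPU while every contract is still exercised at
non-trivial size.

## Known limitations

* The WFDB support is a minimal codec (text header, format-16 signal,
  text annotations); it does not parse binary `.atr` annotation files
  or non-16 signal formats.
* Holdout is the only validation scheme; no cross-validation or
  class-rebalancing is provided.
* The synthetic classes are far better separated than clinical data;
  accuracy numbers on it are mechanics checks, not clinical claims.
* The optimizer assumes a box-bounded, finite, sequentially evaluated
  objective; there is no constraint handling beyond clipping and no
  parallel evaluation.
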