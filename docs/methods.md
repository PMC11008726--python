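# Methods

## Overview

`mstate-bold` links two views of resting brain activity recorded
simultaneously: EEG microstates — quasi-stable scalp potential
topographies lasting tens of milliseconds, classically summarised by K = 4
canonical classes A–D — and the BOLD fMRI signal sampled once per TR.
The package implements the full analysis chain (microstate template
extraction, microstate-informed regressor construction, EEG-informed GLM
with permutation cluster correction, and a multi-output time-delay neural
network for bidirectional prediction) together with a synthetic
simultaneous EEG–fMRI generator with known ground truth, so every stage is
testable without access to any recording.

## Generative model of the synthetic data

The EEG generator embodies the same mixture assumption the analysis makes:
at sample t a single template is active,

    x_t = a_t * s_t * MS_{L_t} + e_t ,

where `MS_i` are unit-norm, zero-mean topographies (channels p = 32 by
default), `L_t` is a first-order Markov label sequence, `a_t > 0` a slowly
varying amplitude, `s_t ∈ {−1, +1}` a per-dwell-segment random polarity,
and `e_t` white Gaussian channel noise.  Defaults and reasons:

| parameter | default | meaning |
| --- | --- | --- |
| channels / rate | 32 @ 250 Hz | standard MR-compatible montage, downsampled rate |
| K | 4 | canonical microstate classes A–D |
| mean dwell | 50 ms | typical microstate lifetime; geometric dwell via the diagonal of the transition matrix |
| amplitude | rectified smoothed Gaussian process, mean 1, SD 0.3, 100 ms smoothing | stands in for the alpha-band envelope; no published amplitude model exists, so a smooth positive process is the simplest stand-in |
| channel noise SD | 0.2 | calibrated once so that template recovery is challenging but achievable; real-EEG SNR is not published for this setting |
| TR / volumes | 2 s / 244 | an 8-minute resting-state run |

Polarity flips are injected deliberately: scalp maps alternate sign within
a microstate, and every downstream statistic must be invariant to the sign
of the map.  Tests exercise exactly this invariance.

BOLD is generated by inverting the analysis model: ROI × TR series are a
known linear mixture of HRF-convolved, standardized, TR-resampled
regressors (`coupling` coefficients per ROI), plus a random 3rd-order
polynomial drift (exercising the GLM's drift block) and white noise
(SD 1).  The default coupling is **negative** (−0.5) from the activity
regressors onto the ROIs of the first four blocks of a 7-network style
parcellation (10 ROIs per network), mirroring the sign and network
distribution of the association this pipeline is designed to detect.
Motion traces are mean-reverting AR(1) processes (stationary SD 0.03)
with optional spikes that trip the censoring rule.

What the generator does **not** emulate: volume conduction / lead fields,
gradient and ballistocardiogram artifacts (the pipeline expects cleaned
EEG), spatially structured BOLD noise, physiological noise, and real alpha
dynamics.  Passing tests therefore demonstrate the correctness of the
computations under the stated model, not robustness to real-data artifact
structure.

## Microstate segmentation

1. **Average reference and band-pass.**  Zero-phase FIR filtering
   (delegated to MNE), default band 2–20 Hz with 1–40 Hz as the standard
   variant, both selectable in the config.
2. **GFP.**  `GFP(t) = sqrt( Σ_i (v_i(t) − v̄(t))² / p )` — the spatial SD
   of the scalp map.  Peaks of GFP carry the highest topographic SNR.
3. **Peak picking.**  Strict local maxima of the GFP after smoothing with
   a discrete Gaussian over exactly 5 samples (σ = 1 sample).  The
   convolution replicates edge values; zero padding would fabricate maxima
   at the boundaries of monotone stretches.  Peaks inside bad EEG
   intervals are dropped; up to 10 000 peaks are retained by seeded uniform
   subsampling.
4. **AAHC.**  Atomize-and-agglomerate hierarchical clustering: every peak
   map starts as its own cluster; at each step the cluster contributing
   least explained variance is dissolved and its members reassigned to the
   surviving cluster with the highest squared spatial correlation, until K
   remain.  Cluster quality and centroids use the scatter-matrix top
   eigenpair, i.e. the centroid is the first principal direction of the
   member maps — the polarity-safe choice (a plain mean would cancel
   between members of opposite sign).  Eigenvector signs are fixed by
   making the largest-magnitude component positive, and ties in the
   dissolve step break toward the lowest cluster index, so the procedure
   is deterministic.
5. **Group templates.**  Subject template sets are permuted and
   sign-flipped to maximize total |spatial correlation| with a reference
   via optimal one-to-one assignment, averaged, renormalized, and
   re-referenced to the running mean for at most 10 iterations.
6. **Backfitting.**  Every sample (not only GFP peaks) is assigned
   winner-take-all to the template with maximal absolute cosine
   similarity; samples are average-referenced and normalized by their
   Euclidean norm.  Zero-norm samples get similarity 0, are flagged, and
   inherit the previous label (label 1 if first).  Ties break to the
   lowest template index.
7. **Explained variance.**  GFP²-weighted squared cosine between each
   sample and its assigned template, reported per template and in total;
   equal to 1 on noise-free data labelled with its generating templates.

## Microstate-informed regressors

Three families at the EEG rate, then HRF-convolved, z-scored, and
TR-resampled:

* `DT_i(t) = |x_tᵀ MS_i|` ∈ [0, 1] — direct time course.
* `AT_i(t)` — number of switches out of state i within a causal window
  ending at t (default 2 s = 500 samples at 250 Hz), shifted one sample at
  a time.
* `TS_{i→j}(t)` — transition counts i→j in the same window,
  self-transitions included.

A pair (u, u+1) is counted when both endpoints lie inside the window, so a
full window contains exactly w−1 pairs; hence the identities
`AT_i = Σ_{j≠i} TS_{i→j}` and `Σ_{ij} TS_{i→j} = w−1` hold at every
position (asserted as properties).  Windows are causal and truncated at
the start — a regressor value never sees future EEG.

The HRF is the canonical double gamma: Γ-density with 6 s peak delay minus
a 16 s undershoot scaled by 1/6, dispersions 1 s, 32 s support, peak
normalized to 1; all five parameters are exposed in the config.
Convolution is causal and same-length; standardization to mean 0 / SD 1
happens at EEG rate (zero-variance series yield zeros plus a warning);
downsampling averages the samples within each TR (point-sampling the TR
onset is available as an option).

Censoring: a TR is dropped when the RMS of its motion parameters exceeds
0.2 or its acquisition interval overlaps a bad EEG interval; a subject is
flagged unusable when more than one third of TRs are censored.  Censor
files use the AFNI convention (1 = keep).

## GLM and group inference

Each microstate regressor enters its own subject GLM (the 24 regressors
are strongly intercorrelated and are never fit jointly) together with a
Legendre-polynomial drift block (orders 0–3), 12 motion parameters, and
optional precomputed ventricle-PC / local-white-matter columns.  Censored
TRs are removed row-wise; a rank-deficient design raises an error naming
the collinear columns.  Fits are ordinary least squares.

Group level: one-sample t-test of subject betas per unit (dof = n−1,
two-sided).  Family-wise error over units is controlled by a sign-flip
permutation null on the **maximum suprathreshold cluster extent**: under
the symmetric null each subject's beta map may be sign-flipped; clusters
are defined at |t| above the two-sided p < 0.005 voxel threshold
(26-connectivity on integer grids, run-adjacency in 1-D ROI mode), and a
cluster is significant when `(1 + #{null ≥ extent}) / (1 + n_perm)` falls
below 0.05.  With 2ⁿ ≤ n_perm all sign patterns are enumerated.  The
smallest extent that would reach significance is reported; on degenerate
(all-equal) data it falls back to the largest observed null extent.
Default n_perm is 10 000, reducible for desk-scale runs.  Note that for
maps with near-zero spatial smoothness the extent distribution is heavily
tied at 1–2 units and the permutation p becomes conservative; calibration
at the nominal 0.05 is checked on spatially smooth null maps, which is the
regime actual (smoothed) BOLD statistics live in.

Significant clusters are summarised as percentage overlap with each
network of the parcellation (background excluded from the numerator, so
percentages sum to ≤ 100).

## Multi-output time-delay network

A single shared hidden layer maps the tapped delay line of the r input
series (the last τ TRs) to all o outputs at once:

    z = tanh(W [x_{t−h}; …; x_{t−h−τ+1}] + b),   ŷ_t = W̃ z + b̃ ,

trained by minimizing MSE + L2 (default strength 1e−2) with analytic
gradients and L-BFGS, at most `epochs` = 100 iterations.  Biases are
included by default (removable).  Initialization is seeded, the optimizer
deterministic, so training is reproducible.  The fixed ridge penalty is
the package's stand-in for Bayesian-regularized backpropagation; the two
coincide in the fixed-hyperparameter limit.

Model selection: grid search over hidden units {5, 10, 20, 40} and delays
{1…5} on the first 30 TRs with a chronological 80/20 split, scored by the
across-output mean Pearson r on the held-out fifth.  Evaluation:
expanding-window cross-validation from 31 TRs — train on TRs 1..k, test
the prediction of TR k+1 (horizon 1) and TR k+2 (horizon 2), k growing by
one until the last TR is tested.  Horizon-2 predictions come from a
*directly trained* 2-step model whose features stop at t−2; ground-truth
t+1 values are never used.  Per-output Pearson r is pooled over all test
points, separately per horizon; censored test TRs are skipped and
counted.  The 30-TR grid window versus 31-TR CV start is kept as two
independent knobs.

Four experiments per subject: (a) dynamics (4 AT + 16 TS, r=20) → 7
network-mean BOLD series; (b) direct time courses (r=4) → BOLD; (c) BOLD
(r=7) → dynamics (o=20); (d) BOLD → DT (o=4).  A paired Wilcoxon utility
compares per-subject mean correlations between experiments.

**Known artifact of the pooled metric:** because each output series is
z-scored over the whole run, its running training mean is anticorrelated
with its future values; a model that predicts (approximately) the training
mean therefore shows a small systematically negative pooled r on null
data, shrinking as the run lengthens.  At the 120-TR problem size used in
the test suite this reaches roughly −0.1 to −0.2 for the horizon-2
reverse-prediction experiments under zero coupling; the null checks
therefore bound the 20-seed average, which stays well inside ±0.2.

## Problem sizes in tests and the acceptance script

The suite runs the study-scale geometry (32 channels, 250 Hz, TR 2 s) at
reduced durations and counts chosen as the package's own desk-scale
defaults: 300 s recordings for segmentation fixtures, 60–120 volumes and
3–6 subjects for end-to-end runs, 100-seed recovery batteries, 500
permutations × 100 repetitions for FWE calibration, and 20-seed null
batteries for the network.  All seeds are fixed; reruns are bit-identical.

## Limitations

* Cohort-bound results are **not reproducible** here and are not targets:
  the 73% group explained variance, the 136-voxel minimum cluster extent
  (a property of that dataset's smoothness and sample), reported cluster
  tables/coordinates, and the absolute correlation levels of the
  prediction experiments all depend on recordings that are not publicly
  available.  The suite instead verifies the properties that make those
  numbers meaningful: exact counting identities, polarity invariance,
  unbiased coupling recovery with the planted (negative) sign, nominal
  family-wise error, and the qualitative ordering of the prediction
  experiments (dynamics > direct time courses; 1-step ≥ 2-step).
* Upstream artifact cleaning (gradient/BCG removal, ICA) and fMRI spatial
  preprocessing are out of scope; the pipeline consumes cleaned arrays.
* The AAHC step is greedy; on small problems it is checked against an
  exhaustive-partition oracle (≥ 90% assignment agreement), but global
  optimality is not guaranteed.
* Ventricle-PC and white-matter nuisances are accepted as precomputed
  columns, never estimated from anatomy.
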