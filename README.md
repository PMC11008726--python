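# mstate-bold

EEG microstates are quasi-stable scalp potential topographies that last a
few tens of milliseconds; resting EEG is classically summarised by K = 4
canonical classes (A–D).  How their fast dynamics relate to the slow BOLD
fMRI signal recorded simultaneously is a long-standing question in
EEG–fMRI integration.  `mstate-bold` is a Python package for researchers
working with simultaneous EEG–fMRI who want to test one specific family of
hypotheses: that *switching between* microstates — rather than the mere
presence of a microstate — carries the information shared with BOLD.

The package implements the full analysis chain:

1. **Microstate segmentation** — global field power
   `GFP(t) = sqrt(Σᵢ (vᵢ(t) − v̄(t))² / p)`, Gaussian-smoothed peak
   picking, subsampling up to 10 000 peaks, polarity-invariant
   atomize-and-agglomerate hierarchical clustering (AAHC) with k = 4, and
   group template alignment.
2. **Microstate-informed regressors** — per sample t and template MSᵢ:
   the direct time course `DTᵢ = |xᵗ·MSᵢ|`; the activity `ATᵢ` (switches
   out of state i in a causal 2 s window); pairwise transition counts
   `TS_{i→j}`; each convolved with a canonical double-gamma HRF,
   standardized, and downsampled to the TR, with motion/EEG-artifact
   censoring (RMS > 0.2, > 1/3 censored ⇒ subject dropped).
3. **EEG-informed GLM** — per-subject OLS of BOLD on one regressor plus
   nuisance terms (3rd-order polynomial drift, 12 motion parameters,
   optional ventricle/white-matter columns), group one-sample t-test, and
   sign-flip permutation correction on the maximum cluster extent
   (voxel p < 0.005, cluster p < 0.05), with percentage overlap against a
   7-network parcellation.
4. **Cross-modal prediction** — a multi-output time-delay neural network
   `ŷ_t = W̃ tanh(W [x_{t−1};…;x_{t−τ}] + b) + b̃` with one shared hidden
   layer, grid-searched hidden units {5,10,20,40} and delays {1..5}, and
   expanding-window time-series cross-validation (initial 31 TRs, 1- and
   2-TR-ahead horizons), run in both directions (microstates → BOLD and
   BOLD → microstates).
5. **Synthetic ground truth** — a generator for simultaneous EEG–BOLD
   data with known templates, Markov label sequences, coupling
   coefficients, drift, noise, and motion, so the whole chain is testable
   end to end.  See `docs/methods.md` for the model and its limits.

## Worked example

```python
import numpy as np
from mstate_bold import (
    PipelineConfig, generate_templates, bandpass_filter, compute_gfp,
    detect_gfp_peaks, sample_peaks, aahc_cluster, compute_similarity,
    assign_labels, explained_variance, build_regressor_set,
)
from mstate_bold.pipeline import simulate_subject

cfg = PipelineConfig(n_subjects=1, n_volumes=150, seed=42)
templates = generate_templates(32, 4, smoothness=0.5,
                               seed=cfg.stage_seed("simulate"))
truth, eeg, bold, motion = simulate_subject(cfg, templates, 0)

filtered = bandpass_filter(eeg, 2.0, 20.0)
peaks = sample_peaks(detect_gfp_peaks(compute_gfp(filtered)), 10000, seed=0)
tset = aahc_cluster(filtered.data[:, peaks].T, k=4)

corr = np.abs(tset.templates @ truth.templates.T)
print(f"GFP peaks clustered : {peaks.size}")
print(f"template recovery   : {np.sort(corr.max(axis=1))}")

labels = assign_labels(compute_similarity(filtered, tset), sfreq=eeg.sfreq)
gev = explained_variance(filtered, tset, labels)
print(f"explained variance  : total={gev['total']:.3f} "
      f"(A={gev['A']:.3f}, B={gev['B']:.3f}, C={gev['C']:.3f}, D={gev['D']:.3f})")

regs = build_regressor_set(filtered, tset, labels=labels, window_s=2.0)
print(f"regressors built    : {len(regs.eeg_rate)} "
      f"(AT_A mean switches per 2 s window: {regs.eeg_rate['AT_A'].mean():.1f})")
```

Output:

```
GFP peaks clustered : 6596
template recovery   : [0.99966736 0.99968626 0.99980323 0.99986364]
explained variance  : total=0.685 (A=0.174, B=0.172, C=0.176, D=0.164)
regressors built    : 24 (AT_A mean switches per 2 s window: 10.5)
```

All four planted topographies are recovered from the noisy 5-minute
recording with |spatial correlation| > 0.999; the four templates jointly
explain 68.5% of the GFP-weighted variance of this noisy recording (1.0
would mean noise-free data); the activity regressor counts ~10 switches
out of state A per 2 s window, consistent with a ~50 ms mean dwell shared
among 4 states.

The same stages are scriptable from the shell:

```bash
mstate-bold simulate --out run/ --seed 1 --subjects 3
mstate-bold segment --eeg run/sub-00/eeg --band 2,20 --k 4 --out run/templates.tsv
mstate-bold run --out full_run/ --seed 1          # all five stages
```

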