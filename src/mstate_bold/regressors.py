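"""Microstate-informed fMRI regressors.

Three regressor families are built from the backfitted label sequence and
templates, then convolved with a canonical double-gamma HRF, standardized,
and downsampled to the fMRI TR:

* DT_i — direct time course: absolute cosine similarity of each EEG sample
  to template i, in [0, 1].
* AT_i — activity: number of switches out of microstate i within a causal
  sliding window (default 2 s), shifted one sample at a time.
* TS_i->j — transition count from i to j (self-transitions included) within
  the same window.

Window convention: the window ending at sample t covers samples
[t-w+1, t]; a consecutive pair (u, u+1) is counted when both endpoints lie
inside, so a full window holds exactly w-1 pairs.  Initial windows are
truncated rather than padded (no future samples are ever used).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.signal
import scipy.stats

from .microstates import (
    EEGRecording,
    LabelSequence,
    MicrostateTemplateSet,
    _unit_samples,
    assign_labels,
    compute_similarity,
)

__all__ = [
    "RegressorSet",
    "HRFKernel",
    "direct_timecourse",
    "activity_regressor",
    "transition_regressor",
    "hrf_double_gamma",
    "finalize_regressor",
    "build_censor_mask",
    "build_regressor_set",
    "finalize_regressor_set",
]

DEFAULT_WINDOW_S = 2.0


@dataclass
class HRFKernel:
    """Sampled double-gamma hemodynamic response (peak normalized to 1)."""

    sample_times: np.ndarray
    values: np.ndarray
    dt: float


@dataclass
class RegressorSet:
    """Named regressor series at EEG rate and, once finalized, at TR rate."""

    eeg_rate: dict[str, np.ndarray]
    sfreq: float
    window_s: float = DEFAULT_WINDOW_S
    tr_rate: dict[str, np.ndarray] = field(default_factory=dict)
    tr: float | None = None
    censor_mask: np.ndarray | None = None  # True = censored TR

    @property
    def names(self) -> list[str]:
        return list(self.eeg_rate)


# ---------------------------------------------------------------------------
# EEG-rate regressors
# ---------------------------------------------------------------------------

def direct_timecourse(eeg: EEGRecording, template: np.ndarray) -> np.ndarray:
    """DT = |x^T MS| per sample: polarity-invariant cosine similarity in [0,1].

    Samples are average-referenced and unit-normalized; zero-norm samples
    map to 0.
    """
    template = np.asarray(template, dtype=float)
    x, flagged = _unit_samples(eeg)
    dt = np.abs(x @ (template / np.linalg.norm(template)))
    dt[flagged] = 0.0
    return np.clip(dt, 0.0, 1.0)


def _pair_window_counts(indicator: np.ndarray, window_samples: int) -> np.ndarray:
    """Causal sliding sum of a pair indicator.

    ``indicator[u]`` refers to the consecutive pair (u, u+1); the output at
    sample t sums indicators for pairs fully inside [t-w+1, t], i.e.
    u in [max(0, t-w+1), t-1].
    """
    n = indicator.size + 1
    csum = np.concatenate([[0], np.cumsum(indicator)])
    t = np.arange(n)
    hi = t  # pairs up to u = t-1 -> csum[t]
    lo = np.maximum(t - window_samples + 1, 0)
    return (csum[hi] - csum[lo]).astype(float)


def activity_regressor(
    labels: LabelSequence, i: int, window_samples: int
) -> np.ndarray:
    """AT_i: switches out of microstate i per causal window, one per sample."""
    if not 1 <= i <= labels.k:
        raise ValueError(f"microstate index {i} outside [1, {labels.k}]")
    if window_samples < 2:
        raise ValueError("window must span at least 2 samples")
    lab = labels.labels
    pairs = (lab[:-1] == i) & (lab[1:] != i)
    return _pair_window_counts(pairs, window_samples)


def transition_regressor(
    labels: LabelSequence, i: int, j: int, window_samples: int
) -> np.ndarray:
    """TS_i->j: transitions from i to j per causal window (i=j allowed)."""
    for idx in (i, j):
        if not 1 <= idx <= labels.k:
            raise ValueError(f"microstate index {idx} outside [1, {labels.k}]")
    if window_samples < 2:
        raise ValueError("window must span at least 2 samples")
    lab = labels.labels
    pairs = (lab[:-1] == i) & (lab[1:] == j)
    return _pair_window_counts(pairs, window_samples)


# ---------------------------------------------------------------------------
# HRF convolution and TR resampling
# ---------------------------------------------------------------------------

def hrf_double_gamma(
    dt: float,
    duration: float = 32.0,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_dispersion: float = 1.0,
    undershoot_dispersion: float = 1.0,
    ratio: float = 6.0,
) -> HRFKernel:
    """Canonical double-gamma HRF: positive lobe minus a scaled undershoot.

    h(t) = Gamma(t; peak_delay/disp, disp) - Gamma(t; u_delay/u_disp, u_disp)
    / ratio, sampled on [0, duration) at step ``dt`` and normalized so the
    peak equals 1.  Defaults: 6 s peak, 16 s undershoot, dispersions 1 s,
    peak:undershoot 6, 32 s support.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    for name, val in [
        ("duration", duration),
        ("peak_delay", peak_delay),
        ("undershoot_delay", undershoot_delay),
        ("peak_dispersion", peak_dispersion),
        ("undershoot_dispersion", undershoot_dispersion),
        ("ratio", ratio),
    ]:
        if val <= 0:
            raise ValueError(f"{name} must be positive")
    t = np.arange(0.0, duration, dt)
    peak = scipy.stats.gamma.pdf(t, peak_delay / peak_dispersion, scale=peak_dispersion)
    under = scipy.stats.gamma.pdf(
        t, undershoot_delay / undershoot_dispersion, scale=undershoot_dispersion
    )
    h = peak - under / ratio
    h = h / h.max()
    return HRFKernel(sample_times=t, values=h, dt=dt)


def finalize_regressor(
    series: np.ndarray,
    sfreq: float,
    tr: float,
    n_tr: int,
    hrf: HRFKernel | None = None,
    downsample: str = "average",
) -> np.ndarray:
    """HRF-convolve, z-score, and downsample an EEG-rate series to TR rate.

    Convolution is causal and same-length (the BOLD response trails the EEG
    event).  Standardization is to mean 0 / SD 1 at EEG rate; a
    zero-variance series cannot be standardized and yields all zeros with a
    warning.  Downsampling either averages the samples within each TR
    interval (default) or point-samples the TR onset (``downsample="onset"``).
    """
    series = np.asarray(series, dtype=float)
    spt = tr * sfreq  # samples per TR
    if series.size < spt:
        raise ValueError("series shorter than one TR")
    if hrf is None:
        hrf = hrf_double_gamma(dt=1.0 / sfreq)
    if series.std() == 0:
        warnings.warn("zero-variance regressor cannot be standardized; returning zeros")
        return np.zeros(n_tr)
    conv = scipy.signal.fftconvolve(series, hrf.values)[: series.size]
    sd = conv.std()
    if sd == 0:
        warnings.warn("zero-variance regressor cannot be standardized; returning zeros")
        return np.zeros(n_tr)
    conv = (conv - conv.mean()) / sd
    starts = np.round(np.arange(n_tr) * spt).astype(int)
    stops = np.round((np.arange(n_tr) + 1) * spt).astype(int)
    if starts[-1] >= series.size:
        raise ValueError(f"series too short for {n_tr} TRs")
    stops = np.minimum(stops, series.size)
    if downsample == "average":
        return np.array([conv[a:b].mean() for a, b in zip(starts, stops)])
    if downsample == "onset":
        return conv[starts]
    raise ValueError(f"unknown downsample mode '{downsample}'")


# ---------------------------------------------------------------------------
# censoring
# ---------------------------------------------------------------------------

def build_censor_mask(
    motion: np.ndarray,
    eeg_bad_intervals: list[tuple[int, int]],
    sfreq: float,
    tr: float,
    n_tr: int | None = None,
    rms_threshold: float = 0.2,
    max_censored_fraction: float = 1.0 / 3.0,
) -> tuple[np.ndarray, bool]:
    """Censor TRs with severe motion or EEG artifact; flag unusable subjects.

    A TR is censored when the RMS of its motion parameters exceeds
    ``rms_threshold`` or its acquisition interval overlaps any bad EEG
    interval.  Returns ``(censored, usable)`` where ``censored`` is a
    boolean mask (True = drop) and ``usable`` is False when more than
    ``max_censored_fraction`` of TRs are censored.
    """
    motion = np.atleast_2d(np.asarray(motion, dtype=float))
    if motion.shape[0] < motion.shape[1] and motion.shape[0] in (6, 12):
        motion = motion.T  # accept either orientation for 6/12-column tables
    if n_tr is None:
        n_tr = motion.shape[0]
    if motion.shape[0] != n_tr:
        raise ValueError("motion table not aligned with TRs")
    rms = np.sqrt((motion**2).mean(axis=1))
    censored = rms > rms_threshold
    spt = tr * sfreq
    for start, stop in eeg_bad_intervals:
        first = int(np.floor(start / spt))
        last = int(np.ceil(stop / spt))
        censored[max(first, 0) : min(last, n_tr)] = True
    usable = censored.mean() <= max_censored_fraction
    return censored, bool(usable)


# ---------------------------------------------------------------------------
# convenience builders used by the pipeline
# ---------------------------------------------------------------------------

def regressor_names(template_labels: list[str]) -> list[str]:
    names = [f"DT_{a}" for a in template_labels]
    names += [f"AT_{a}" for a in template_labels]
    names += [f"TS_{a}{b}" for a in template_labels for b in template_labels]
    return names


def build_regressor_set(
    eeg: EEGRecording,
    templates: MicrostateTemplateSet,
    labels: LabelSequence | None = None,
    window_s: float = DEFAULT_WINDOW_S,
) -> RegressorSet:
    """All DT/AT/TS series at EEG rate (4 + 4 + 16 names for K=4)."""
    if labels is None:
        labels = assign_labels(compute_similarity(eeg, templates), sfreq=eeg.sfreq)
    w = int(round(window_s * eeg.sfreq))
    series: dict[str, np.ndarray] = {}
    for i, name in enumerate(templates.labels, start=1):
        series[f"DT_{name}"] = direct_timecourse(eeg, templates.templates[i - 1])
    for i, name in enumerate(templates.labels, start=1):
        series[f"AT_{name}"] = activity_regressor(labels, i, w)
    for i, a in enumerate(templates.labels, start=1):
        for j, b in enumerate(templates.labels, start=1):
            series[f"TS_{a}{b}"] = transition_regressor(labels, i, j, w)
    return RegressorSet(eeg_rate=series, sfreq=eeg.sfreq, window_s=window_s)


def finalize_regressor_set(
    regset: RegressorSet,
    tr: float,
    n_tr: int,
    hrf: HRFKernel | None = None,
    motion: np.ndarray | None = None,
    eeg_bad_intervals: list[tuple[int, int]] | None = None,
    downsample: str = "average",
) -> RegressorSet:
    """HRF-convolve/standardize/downsample every series and attach a censor
    mask (all-clear when no motion table is provided)."""
    if hrf is None:
        hrf = hrf_double_gamma(dt=1.0 / regset.sfreq)
    regset.tr_rate = {
        name: finalize_regressor(s, regset.sfreq, tr, n_tr, hrf, downsample)
        for name, s in regset.eeg_rate.items()
    }
    regset.tr = tr
    if motion is not None:
        censored, _ = build_censor_mask(
            motion, eeg_bad_intervals or [], regset.sfreq, tr, n_tr
        )
        regset.censor_mask = censored
    else:
        regset.censor_mask = np.zeros(n_tr, dtype=bool)
    return regset
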