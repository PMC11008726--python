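"""EEG microstate extraction and backfitting.

Microstates are quasi-stable scalp potential topographies lasting tens of
milliseconds; resting EEG is classically summarised by K=4 canonical classes
(A-D).  The extraction pipeline implemented here follows the standard
spatially-independent route: band-pass the average-referenced EEG, compute
global field power (GFP), pick GFP peaks (high-SNR topographies), subsample
up to 10 000 peaks, cluster the peak maps with the polarity-invariant
atomize-and-agglomerate hierarchical clustering (AAHC), and align subject
template sets into a group template.  Backfitting assigns every sample to
the template with the highest absolute cosine similarity (winner-take-all).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg
import scipy.ndimage
from scipy.optimize import linear_sum_assignment

__all__ = [
    "EEGRecording",
    "GFPSeries",
    "MicrostateTemplateSet",
    "SimilarityMatrix",
    "LabelSequence",
    "average_reference",
    "bandpass_filter",
    "compute_gfp",
    "detect_gfp_peaks",
    "sample_peaks",
    "aahc_cluster",
    "align_and_average_templates",
    "compute_similarity",
    "assign_labels",
    "explained_variance",
]

CANONICAL_NAMES = ("A", "B", "C", "D")


def microstate_names(k: int) -> list[str]:
    """Canonical A..D for k=4, else MS1..MSk."""
    if k <= len(CANONICAL_NAMES):
        return list(CANONICAL_NAMES[:k])
    return [f"MS{i + 1}" for i in range(k)]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class EEGRecording:
    """Multichannel EEG: ``data`` is channels (p) x samples (n), in microvolts.

    ``bad_intervals`` are half-open ``[start, stop)`` sample ranges flagged as
    unusable (residual artifacts); they are excluded from peak picking and
    mapped onto the fMRI censor mask downstream.
    """

    data: np.ndarray
    sfreq: float
    channel_names: list[str] = field(default_factory=list)
    bad_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError("EEG data must be 2-D with at least 2 channels")
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.data.shape[0])]
        n = self.data.shape[1]
        for start, stop in self.bad_intervals:
            if not (0 <= start < stop <= n):
                raise ValueError(f"bad interval [{start}, {stop}) outside [0, {n})")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class GFPSeries:
    """Global field power: the spatial SD of the scalp map at each sample."""

    values: np.ndarray
    sfreq: float


@dataclass
class MicrostateTemplateSet:
    """K unit-norm, zero-mean template topographies (rows of ``templates``)."""

    templates: np.ndarray  # K x p
    labels: list[str]
    level: str = "subject"  # "subject" | "group"

    def __post_init__(self) -> None:
        self.templates = np.asarray(self.templates, dtype=float)
        if self.templates.ndim != 2:
            raise ValueError("templates must be K x p")
        if len(self.labels) != self.templates.shape[0]:
            raise ValueError("one label per template required")

    @property
    def k(self) -> int:
        return self.templates.shape[0]

    @property
    def n_channels(self) -> int:
        return self.templates.shape[1]


@dataclass
class SimilarityMatrix:
    """n x K absolute cosine similarities; ``flagged`` marks zero-norm samples."""

    values: np.ndarray
    flagged: np.ndarray  # boolean, length n


@dataclass
class LabelSequence:
    """Winner-take-all microstate labels, 1-based integers in [1, K]."""

    labels: np.ndarray
    sfreq: float
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and (self.labels.min() < 1 or self.labels.max() > self.k):
            raise ValueError(f"labels must lie in [1, {self.k}]")

    @property
    def n_samples(self) -> int:
        return self.labels.size


# ---------------------------------------------------------------------------
# preprocessing: reference, filter, GFP
# ---------------------------------------------------------------------------

def average_reference(eeg: EEGRecording) -> EEGRecording:
    """Re-reference to the instantaneous channel mean (zero-mean maps)."""
    data = eeg.data - eeg.data.mean(axis=0, keepdims=True)
    return replace(eeg, data=data)


def bandpass_filter(eeg: EEGRecording, low: float, high: float) -> EEGRecording:
    """Zero-phase FIR band-pass; default analysis band is 2-20 Hz (alt 1-40)."""
    nyq = eeg.sfreq / 2.0
    if not (0.0 < low < high < nyq):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < Nyquist ({nyq} Hz); "
            f"got [{low}, {high}]"
        )
    import mne.filter

    data = mne.filter.filter_data(
        np.ascontiguousarray(eeg.data), eeg.sfreq, low, high, verbose="error"
    )
    return replace(eeg, data=data)


def compute_gfp(eeg: EEGRecording) -> GFPSeries:
    """GFP(t) = sqrt( sum_i (v_i(t) - vbar(t))^2 / p ) — spatial SD per sample."""
    return GFPSeries(values=eeg.data.std(axis=0, ddof=0), sfreq=eeg.sfreq)


def _gaussian_kernel(window: int, sigma: float = 1.0) -> np.ndarray:
    half = window // 2
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def detect_gfp_peaks(
    gfp: GFPSeries,
    smooth_window: int = 5,
    bad_intervals: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Strict local maxima of the Gaussian-smoothed GFP series.

    Smoothing uses a discrete Gaussian over exactly ``smooth_window`` samples
    (sigma = 1 sample).  Peaks inside bad intervals are dropped.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd and >= 1")
    v = np.asarray(gfp.values, dtype=float)
    if v.size < smooth_window:
        raise ValueError("series shorter than smoothing window")
    if smooth_window > 1:
        # edge-replicating convolution: zero padding would fabricate maxima
        # next to the boundaries of monotone series
        sm = scipy.ndimage.convolve1d(v, _gaussian_kernel(smooth_window), mode="nearest")
    else:
        sm = v
    interior = (sm[1:-1] > sm[:-2]) & (sm[1:-1] > sm[2:])
    peaks = np.flatnonzero(interior) + 1
    if bad_intervals:
        keep = np.ones(peaks.size, dtype=bool)
        for start, stop in bad_intervals:
            keep &= ~((peaks >= start) & (peaks < stop))
        peaks = peaks[keep]
    return peaks


def sample_peaks(indices, max_n: int = 10000, seed: int = 0) -> np.ndarray:
    """Uniform subsample without replacement when more than ``max_n`` peaks."""
    idx = np.asarray(indices, dtype=int)
    if idx.size <= max_n:
        return idx.copy()
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(idx, size=max_n, replace=False))


# ---------------------------------------------------------------------------
# AAHC clustering
# ---------------------------------------------------------------------------

def _principal_direction(scatter: np.ndarray) -> tuple[np.ndarray, float]:
    """Top eigenpair of a symmetric scatter matrix, sign-fixed for determinism."""
    p = scatter.shape[0]
    w, v = scipy.linalg.eigh(scatter, subset_by_index=[p - 1, p - 1])
    vec = v[:, 0]
    pivot = np.argmax(np.abs(vec))
    if vec[pivot] < 0:
        vec = -vec
    return vec, float(w[0])


def _normalize_maps(maps: np.ndarray) -> np.ndarray:
    maps = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(maps, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return maps / norms


def aahc_cluster(maps: np.ndarray, k: int = 4) -> MicrostateTemplateSet:
    """Atomize-and-agglomerate hierarchical clustering of peak topographies.

    Every map starts as its own cluster.  At each step the cluster with the
    lowest contribution to global explained variance (the top eigenvalue of
    its scatter matrix, i.e. the sum over members of squared correlation
    with the cluster's principal direction) is atomized, and each orphaned
    map is reassigned to the surviving cluster with the highest squared
    spatial correlation.  The sign-indifferent scatter/eigenvector
    formulation makes the whole procedure polarity invariant.  Cluster
    centroids are the first principal direction of their member maps.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 2:
        raise ValueError("maps must be m x p")
    m, p = maps.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if m <= k:
        raise ValueError(f"need more maps ({m}) than clusters ({k})")
    maps = _normalize_maps(maps)

    centroids = maps.copy()  # slot per initial cluster
    quality = np.ones(m)  # top eigenvalue; +inf marks dead slots
    active = np.ones(m, dtype=bool)
    members: list[list[int] | None] = [[i] for i in range(m)]
    scatter = [np.outer(maps[i], maps[i]) for i in range(m)]

    n_active = m
    while n_active > k:
        q = np.where(active, quality, np.inf)
        worst = int(np.argmin(q))  # ties -> lowest slot index
        orphans = members[worst]
        active[worst] = False
        members[worst] = None
        scatter[worst] = None  # type: ignore[call-overload]
        n_active -= 1

        alive = np.flatnonzero(active)
        cent = centroids[alive]  # frozen during this atomization
        scores = (cent @ maps[orphans].T) ** 2  # n_alive x n_orphans
        best = alive[np.argmax(scores, axis=0)]

        for slot in np.unique(best):
            new = [orphans[i] for i in np.flatnonzero(best == slot)]
            members[slot].extend(new)  # type: ignore[union-attr]
            sub = maps[new]
            scatter[slot] = scatter[slot] + sub.T @ sub
            centroids[slot], quality[slot] = _principal_direction(scatter[slot])

    alive = np.flatnonzero(active)
    order = alive[np.argsort(-quality[alive], kind="stable")]
    templates = centroids[order]
    # centroids are eigenvectors of zero-mean maps, hence zero-mean; re-center
    # and renormalize to guard against accumulated round-off
    templates = _normalize_maps(templates)
    return MicrostateTemplateSet(
        templates=templates, labels=microstate_names(k), level="subject"
    )


# ---------------------------------------------------------------------------
# group template alignment
# ---------------------------------------------------------------------------

def _align_to_reference(
    templates: np.ndarray, reference: np.ndarray
) -> np.ndarray:
    """Reorder and sign-flip rows to best match the reference one-to-one."""
    corr = templates @ reference.T  # unit-norm rows -> cosine
    row, col = linear_sum_assignment(-np.abs(corr))
    aligned = np.empty_like(reference)
    for r, c in zip(row, col):
        sign = 1.0 if corr[r, c] >= 0 else -1.0
        aligned[c] = sign * templates[r]
    return aligned


def align_and_average_templates(
    subject_sets: list[MicrostateTemplateSet],
    reference: MicrostateTemplateSet | None = None,
    max_iter: int = 10,
) -> MicrostateTemplateSet:
    """Group template = renormalized mean of order/sign-aligned subject sets.

    Each subject's templates are permuted and sign-flipped to maximize total
    absolute spatial correlation with the reference (optimal assignment),
    averaged, and the procedure re-references to the running mean until the
    assignment is stable (at most ``max_iter`` refinement passes).  With no
    explicit reference the first subject's set seeds the iteration.
    """
    if not subject_sets:
        raise ValueError("at least one subject set required")
    p = subject_sets[0].n_channels
    k = subject_sets[0].k
    for s in subject_sets:
        if s.n_channels != p or s.k != k:
            raise ValueError("all template sets must share channels and K")
    ref = (reference or subject_sets[0]).templates
    labels = (reference or subject_sets[0]).labels

    prev = None
    aligned = None
    for _ in range(max_iter):
        aligned = np.stack([_align_to_reference(s.templates, ref) for s in subject_sets])
        mean = _normalize_maps(aligned.mean(axis=0))
        if prev is not None and np.allclose(mean, prev, atol=1e-12):
            break
        prev = mean
        ref = mean
    return MicrostateTemplateSet(templates=ref, labels=list(labels), level="group")


# ---------------------------------------------------------------------------
# backfitting
# ---------------------------------------------------------------------------

def _unit_samples(eeg: EEGRecording) -> tuple[np.ndarray, np.ndarray]:
    """Average-referenced, per-sample unit-norm maps (n x p) + zero-norm flags."""
    x = (eeg.data - eeg.data.mean(axis=0, keepdims=True)).T
    norms = np.linalg.norm(x, axis=1)
    flagged = norms == 0
    safe = np.where(flagged, 1.0, norms)
    return x / safe[:, None], flagged


def compute_similarity(
    eeg: EEGRecording, templates: MicrostateTemplateSet
) -> SimilarityMatrix:
    """f = |x^T MS|: absolute cosine similarity of every sample to every template.

    Zero-norm samples (possible after filtering or censoring) get an all-zero
    row and are flagged.
    """
    if eeg.n_channels != templates.n_channels:
        raise ValueError("EEG and templates disagree on channel count")
    x, flagged = _unit_samples(eeg)
    f = np.abs(x @ templates.templates.T)
    f[flagged] = 0.0
    return SimilarityMatrix(values=np.clip(f, 0.0, 1.0), flagged=flagged)


def assign_labels(f: SimilarityMatrix, sfreq: float = 1.0) -> LabelSequence:
    """Winner-take-all labels (1-based); ties -> lowest index; flagged samples
    carry the previous label forward (label 1 if the first sample is flagged)."""
    labels = np.argmax(f.values, axis=1) + 1
    for t in np.flatnonzero(f.flagged):
        labels[t] = labels[t - 1] if t > 0 else 1
    return LabelSequence(labels=labels, sfreq=sfreq, k=f.values.shape[1])


def explained_variance(
    eeg: EEGRecording,
    templates: MicrostateTemplateSet,
    labels: LabelSequence,
) -> dict[str, float]:
    """GFP-weighted squared-cosine explained variance, per template and total.

    GEV_i = sum_{t: L_t=i} GFP_t^2 cos^2(x_t, MS_i) / sum_t GFP_t^2; the
    total is the sum of the per-template parts and equals 1 for noise-free
    data labelled with its generating templates.
    """
    if labels.n_samples != eeg.n_samples:
        raise ValueError("labels must align with EEG samples")
    x, flagged = _unit_samples(eeg)
    gfp2 = compute_gfp(eeg).values ** 2
    denom = gfp2.sum()
    if denom == 0:
        return {name: 0.0 for name in templates.labels} | {"total": 0.0}
    cos2 = (np.einsum("tp,tp->t", x, templates.templates[labels.labels - 1])) ** 2
    cos2[flagged] = 0.0
    out: dict[str, float] = {}
    total = 0.0
    for i, name in enumerate(templates.labels):
        sel = labels.labels == i + 1
        part = float((gfp2[sel] * cos2[sel]).sum() / denom)
        out[name] = part
        total += part
    out["total"] = total
    return out
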