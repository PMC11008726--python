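"""Synthetic simultaneous EEG-fMRI with known microstate ground truth.

The generative model mirrors the assumptions the analysis pipeline tests:

* EEG: at each sample one of K unit-norm, zero-mean template topographies is
  active (a first-order Markov chain with mean dwell ~50 ms), scaled by a
  slowly varying positive amplitude and corrupted by white channel noise,
  i.e. ``x_t = a_t * s_t * MS_{L_t} + eps_t`` with a random polarity
  ``s_t`` in {-1, +1} redrawn per dwell segment (microstate analysis is
  polarity invariant, so the generator exercises that invariance).
* BOLD: ROI x TR series built by mixing HRF-convolved, TR-rate regressor
  time courses with known per-ROI coupling coefficients, plus a weak cubic
  polynomial drift and white noise.

Defaults follow a 32-channel / 250 Hz EEG montage with TR = 2 s and 244
volumes, and a 7-network style ROI parcellation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .microstates import EEGRecording, LabelSequence, microstate_names

__all__ = [
    "SyntheticGroundTruth",
    "BOLDDataset",
    "generate_templates",
    "generate_state_sequence",
    "generate_amplitude",
    "generate_eeg",
    "generate_bold",
    "generate_motion",
    "uniform_transition_matrix",
    "seven_network_parcellation",
]

# study-condition defaults
N_CHANNELS = 32
SFREQ = 250.0
TR = 2.0
N_VOLUMES = 244
MEAN_DWELL_MS = 50.0
AMPLITUDE_MEAN = 1.0
AMPLITUDE_SD = 0.3
EEG_NOISE_SD = 0.2
BOLD_NOISE_SD = 1.0
N_NETWORKS = 7
ROIS_PER_NETWORK = 10


@dataclass
class SyntheticGroundTruth:
    """Everything the generators planted, for downstream recovery checks."""

    templates: np.ndarray  # K x p, unit-norm zero-mean rows
    state_sequence: np.ndarray  # per-sample labels in [1, K]
    amplitude: np.ndarray  # per-sample positive scale
    noise_sd: float
    transition_matrix: np.ndarray
    mean_dwell_ms: float
    coupling: dict[str, np.ndarray] = field(default_factory=dict)  # name -> per-ROI
    bold_noise_sd: float = BOLD_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        tm = np.asarray(self.transition_matrix, dtype=float)
        if not np.allclose(tm.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        k = self.templates.shape[0]
        seq = np.asarray(self.state_sequence)
        if seq.size and (seq.min() < 1 or seq.max() > k):
            raise ValueError("state_sequence values must lie in [1, K]")


@dataclass
class BOLDDataset:
    """ROI (or voxel) x TR matrix plus acquisition/censoring metadata."""

    data: np.ndarray
    tr: float
    censor: np.ndarray | None = None  # True = censored TR
    unit_coords: np.ndarray | None = None  # units x 3 integer grid coords
    parcellation: np.ndarray | None = None  # per-unit network id (0 = background)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.censor is None:
            self.censor = np.zeros(self.data.shape[1], dtype=bool)
        self.censor = np.asarray(self.censor, dtype=bool)
        if self.censor.size != self.data.shape[1]:
            raise ValueError("censor length must equal the number of TRs")

    @property
    def n_units(self) -> int:
        return self.data.shape[0]

    @property
    def n_tr(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

def generate_templates(
    n_channels: int, k: int, smoothness: float = 0.5, seed: int = 0
) -> np.ndarray:
    """Draw k zero-mean, unit-norm pseudo-topographies (k x n_channels).

    Raw maps are spatially smoothed Gaussian noise over the channel axis.
    ``smoothness`` in [0, 1] blends each raw map with its Gram-Schmidt
    orthogonalized counterpart: 0 gives a fully orthogonal set, 1 keeps the
    raw (possibly correlated) maps.  The blend is shrunk toward orthogonal
    until every pair satisfies |cosine| < 0.8, so templates are always
    distinguishable.
    """
    if not 1 <= k <= n_channels:
        raise ValueError(f"need 1 <= k <= n_channels, got k={k}, p={n_channels}")
    if not 0.0 <= smoothness <= 1.0:
        raise ValueError("smoothness must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((k, n_channels))
    if n_channels >= 8:
        raw = gaussian_filter1d(raw, sigma=1.0 + 2.0 * smoothness, axis=1, mode="wrap")
    # the zero-mean subspace has dimension p-1, so k orthogonal zero-mean
    # maps only exist for k <= p-1; at k = p orthogonality wins over centering
    center = k <= n_channels - 1
    if center:
        raw -= raw.mean(axis=1, keepdims=True)
    raw /= np.linalg.norm(raw, axis=1, keepdims=True)

    # Gram-Schmidt (within the zero-mean subspace when centered: linear
    # combinations of zero-mean maps stay zero-mean)
    ortho = np.empty_like(raw)
    for i in range(k):
        v = raw[i].copy()
        for j in range(i):
            v -= (v @ ortho[j]) * ortho[j]
        ortho[i] = v / np.linalg.norm(v)

    w = smoothness
    for _ in range(32):
        t = w * raw + (1.0 - w) * ortho
        if center:
            t -= t.mean(axis=1, keepdims=True)
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        gram = np.abs(t @ t.T) - np.eye(k)
        if gram.max() < 0.8:
            return t
        w *= 0.5
    return ortho


def uniform_transition_matrix(k: int, p_stay: float = 0.0) -> np.ndarray:
    """Row-stochastic matrix with diagonal p_stay and uniform off-diagonal."""
    if k == 1:
        return np.ones((1, 1))
    tm = np.full((k, k), (1.0 - p_stay) / (k - 1))
    np.fill_diagonal(tm, p_stay)
    return tm


# ---------------------------------------------------------------------------
# state sequence and amplitude
# ---------------------------------------------------------------------------

def _dwell_adjusted(tm: np.ndarray, mean_dwell_ms: float, sfreq: float) -> np.ndarray:
    """Set each row's stay probability to 1 - 1/d (d = dwell in samples)."""
    d = mean_dwell_ms / 1000.0 * sfreq
    if d < 1.0:
        raise ValueError("mean dwell must be at least one sample")
    p_switch = 1.0 / d
    out = tm.copy()
    k = tm.shape[0]
    for i in range(k):
        off = tm[i].copy()
        off[i] = 0.0
        total = off.sum()
        if total == 0.0:  # absorbing row (e.g. identity): leave untouched
            continue
        out[i] = off / total * p_switch
        out[i, i] = 1.0 - p_switch
    return out


def generate_state_sequence(
    transition_matrix: np.ndarray,
    mean_dwell_ms: float | None,
    sfreq: float,
    duration_s: float,
    seed: int = 0,
) -> LabelSequence:
    """Markov-chain microstate label sequence at the EEG sampling rate.

    Dwell times are geometric; when ``mean_dwell_ms`` is given, the diagonal
    of each row is overridden so the expected dwell matches it (off-diagonal
    switch targets keep their relative weights).  ``mean_dwell_ms=None``
    uses the matrix verbatim.
    """
    tm = np.asarray(transition_matrix, dtype=float)
    if tm.ndim != 2 or tm.shape[0] != tm.shape[1]:
        raise ValueError("transition matrix must be square")
    if tm.min() < 0 or not np.allclose(tm.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix must be row-stochastic")
    if sfreq <= 0:
        raise ValueError("sfreq must be positive")
    if mean_dwell_ms is not None:
        tm = _dwell_adjusted(tm, mean_dwell_ms, sfreq)
    k = tm.shape[0]
    n = int(round(duration_s * sfreq))
    rng = np.random.default_rng(seed)
    labels = np.empty(n, dtype=int)
    cdf = np.cumsum(tm, axis=1)
    state = int(rng.integers(k))
    u = rng.random(n)
    for t in range(n):
        labels[t] = state + 1
        state = int(np.searchsorted(cdf[state], u[t], side="right"))
        state = min(state, k - 1)  # guard float round-off at the top edge
    return LabelSequence(labels=labels, sfreq=sfreq, k=k)


def generate_amplitude(
    n_samples: int,
    sfreq: float,
    mean: float = AMPLITUDE_MEAN,
    sd: float = AMPLITUDE_SD,
    smooth_s: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Rectified smoothed Gaussian process standing in for the alpha envelope.

    White noise is low-passed with a Gaussian kernel (sigma ``smooth_s``
    seconds), rescaled to the requested mean/SD, and clipped at a small
    positive floor so the active template never vanishes.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n_samples)
    x = gaussian_filter1d(x, sigma=max(smooth_s * sfreq, 1e-9), mode="reflect")
    x = (x - x.mean()) / max(x.std(), 1e-12)
    return np.maximum(mean + sd * x, 0.05 * mean)


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def _segment_ids(labels: np.ndarray) -> np.ndarray:
    """0-based dwell-segment index per sample (increments at every switch)."""
    switches = np.empty(labels.size, dtype=bool)
    switches[0] = False
    switches[1:] = labels[1:] != labels[:-1]
    return np.cumsum(switches)


def generate_eeg(truth: SyntheticGroundTruth, sfreq: float = SFREQ) -> EEGRecording:
    """Superpose the active template per sample with noise (one term of the
    K-template mixture is active at a time, the rest fold into the noise).

    A random polarity in {-1, +1} is drawn per dwell segment: scalp maps
    alternate polarity within a microstate, and every downstream statistic
    must be invariant to it.
    """
    labels = np.asarray(truth.state_sequence, dtype=int)
    amp = np.asarray(truth.amplitude, dtype=float)
    if amp.size != labels.size:
        raise ValueError("amplitude and state_sequence lengths differ")
    rng = np.random.default_rng(truth.seed)
    seg = _segment_ids(labels)
    polarity = rng.choice([-1.0, 1.0], size=seg[-1] + 1)[seg]
    active = truth.templates[labels - 1]  # n x p
    data = (amp * polarity)[:, None] * active
    if truth.noise_sd > 0:
        data = data + rng.normal(0.0, truth.noise_sd, size=data.shape)
    return EEGRecording(data=data.T, sfreq=sfreq)


# ---------------------------------------------------------------------------
# BOLD, parcellation, motion
# ---------------------------------------------------------------------------

def seven_network_parcellation(
    n_networks: int = N_NETWORKS, rois_per_network: int = ROIS_PER_NETWORK
) -> np.ndarray:
    """Per-ROI network ids 1..n_networks in contiguous blocks."""
    return np.repeat(np.arange(1, n_networks + 1), rois_per_network)


def generate_bold(
    regressors: dict[str, np.ndarray],
    coupling: dict[str, np.ndarray],
    bold_noise_sd: float,
    n_rois: int,
    seed: int = 0,
    tr: float = TR,
    drift_scale: float = 0.5,
    parcellation: np.ndarray | None = None,
) -> BOLDDataset:
    """Mix TR-rate regressors into ROI series with known coupling.

    ``data = sum_r coupling[r] (x) regressor[r] + cubic drift + noise``; the
    regressors are expected to be already HRF-convolved and standardized at
    TR rate.  The drift is a random 3rd-order polynomial with coefficient SD
    ``drift_scale``, exercising the GLM's polynomial nuisance block.
    """
    if not regressors:
        raise ValueError("at least one regressor required")
    n_tr = len(next(iter(regressors.values())))
    rng = np.random.default_rng(seed)
    data = np.zeros((n_rois, n_tr))
    for name, beta in coupling.items():
        if name not in regressors:
            raise ValueError(f"coupling refers to unknown regressor '{name}'")
        series = np.asarray(regressors[name], dtype=float)
        if series.size != n_tr:
            raise ValueError("regressor lengths differ")
        beta = np.broadcast_to(np.asarray(beta, dtype=float), (n_rois,))
        data += beta[:, None] * series[None, :]
    if drift_scale > 0:
        t = np.linspace(-1.0, 1.0, n_tr)
        basis = np.polynomial.legendre.legvander(t, 3)[:, 1:]  # orders 1..3
        coeffs = rng.normal(0.0, drift_scale, size=(n_rois, 3))
        data += coeffs @ basis.T
    if bold_noise_sd > 0:
        data += rng.normal(0.0, bold_noise_sd, size=data.shape)
    return BOLDDataset(data=data, tr=tr, parcellation=parcellation)


def generate_motion(
    n_tr: int,
    seed: int = 0,
    n_params: int = 12,
    baseline_sd: float = 0.03,
    ar_coef: float = 0.95,
    n_spikes: int = 0,
    spike_size: float = 0.5,
) -> np.ndarray:
    """Slow mean-reverting motion traces (n_tr x n_params), optionally spiked.

    An AR(1) process with stationary SD ``baseline_sd`` keeps quiescent
    traces well below the RMS > 0.2 censoring rule; spikes model abrupt
    head movements that should trip it.
    """
    rng = np.random.default_rng(seed)
    innov_sd = baseline_sd * np.sqrt(1.0 - ar_coef**2)
    motion = np.empty((n_tr, n_params))
    motion[0] = rng.normal(0.0, baseline_sd, size=n_params)
    for t in range(1, n_tr):
        motion[t] = ar_coef * motion[t - 1] + rng.normal(0.0, innov_sd, size=n_params)
    if n_spikes > 0:
        at = rng.choice(n_tr, size=min(n_spikes, n_tr), replace=False)
        motion[at] += spike_size * rng.choice([-1.0, 1.0], size=(at.size, n_params))
    return motion
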