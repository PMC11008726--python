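"""Shared synthetic fixtures: one default ground-truth EEG recording.

The default fixture mirrors the study conditions the pipeline targets:
32 channels at 250 Hz, four templates with ~50 ms mean dwell, amplitude
mean 1 / SD 0.3, channel noise SD 0.2, 300 s duration.
"""

import numpy as np
import pytest

from mstate_bold.microstates import LabelSequence
from mstate_bold.synthetic import (
    SyntheticGroundTruth,
    generate_amplitude,
    generate_eeg,
    generate_state_sequence,
    generate_templates,
    uniform_transition_matrix,
)

FIXTURE_SEED = 7
SFREQ = 250.0
DURATION_S = 300.0
NOISE_SD = 0.2


def make_truth(
    noise_sd: float = NOISE_SD,
    duration_s: float = DURATION_S,
    seed: int = FIXTURE_SEED,
    constant_amplitude: bool = False,
) -> SyntheticGroundTruth:
    templates = generate_templates(32, 4, 0.5, seed=seed)
    tm = uniform_transition_matrix(4)
    seq = generate_state_sequence(tm, 50.0, SFREQ, duration_s, seed=seed + 1)
    if constant_amplitude:
        amp = np.ones(seq.n_samples)
    else:
        amp = generate_amplitude(seq.n_samples, SFREQ, seed=seed + 2)
    return SyntheticGroundTruth(
        templates=templates,
        state_sequence=seq.labels,
        amplitude=amp,
        noise_sd=noise_sd,
        transition_matrix=tm,
        mean_dwell_ms=50.0,
        seed=seed + 3,
    )


@pytest.fixture(scope="session")
def default_truth() -> SyntheticGroundTruth:
    return make_truth()


@pytest.fixture(scope="session")
def default_eeg(default_truth):
    return generate_eeg(default_truth, sfreq=SFREQ)


@pytest.fixture(scope="session")
def true_labels(default_truth) -> LabelSequence:
    return LabelSequence(
        labels=default_truth.state_sequence, sfreq=SFREQ, k=4
    )
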