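"""Shared fixtures: small deterministic signals and synthetic studies."""

import numpy as np
import pytest

from sleepmem import EpochSignal, FNNConfig, SyntheticStudyConfig, generate_dataset

FS = 125.0
EPOCH_SECONDS = 30.0
N = int(FS * EPOCH_SECONDS)  # 3750 samples


def make_epoch(samples, fs=FS, epoch_seconds=EPOCH_SECONDS):
    return EpochSignal(samples=np.asarray(samples, dtype=float), fs=fs,
                       epoch_seconds=epoch_seconds)


def sine_epoch(freq_hz, amplitude=1.0, fs=FS, epoch_seconds=EPOCH_SECONDS, phase=0.0):
    t = np.arange(int(fs * epoch_seconds)) / fs
    return make_epoch(amplitude * np.sin(2 * np.pi * freq_hz * t + phase), fs,
                      epoch_seconds)


def noise_epoch(seed=0, scale=1.0, fs=FS, epoch_seconds=EPOCH_SECONDS):
    rng = np.random.default_rng(seed)
    return make_epoch(scale * rng.standard_normal(int(fs * epoch_seconds)), fs,
                      epoch_seconds)


@pytest.fixture(scope="session")
def tiny_study():
    """4 subjects x 120 epochs of well-separated synthetic PSG."""
    return generate_dataset(SyntheticStudyConfig(n_subjects=4,
                                                 epochs_per_subject=120,
                                                 seed=42))


@pytest.fixture(scope="session")
def small_fnn_config():
    """A scaled-down network for fast training in unit tests."""
    return FNNConfig(hidden_sizes=(32, 16), max_epochs=80, batch_size=32, seed=0)
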