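"""Synthetic polysomnography: Markov hypnograms + stage-conditioned EEG.

Real expert-scored frontopolar EEG lives in access-restricted archives,
so everything in this package is exercised on a synthetic study that
reproduces the two properties the method relies on:

* hypnograms follow a "sticky" first-order Markov chain (large
  self-transition probabilities, remaining mass on physiologically
  adjacent stages), giving each stage an autocorrelation time of many
  epochs;
* epoch waveforms have stage-dependent band-power profiles:
  delta-dominant N3, alpha-rich wake, theta-rich N1/REM, and N2 with
  sigma-band spindle bursts.

An epoch is synthesized as a sum of independent band-limited Gaussian
noise components (4th-order Butterworth band-pass per EEG band), scaled
so the expected power proportions equal the requested band weights,
plus Gaussian-windowed 13 Hz sinusoid bursts at a Poisson rate for N2
spindles, plus a broadband noise floor. Amplitudes are in microvolts.

The generator deliberately omits artifacts (EOG blinks, EMG bursts),
non-stationarity within an epoch beyond spindles, and multi-channel
structure; see the methods note for what this does and does not let the
test suite demonstrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .epochs import EpochSignal, SubjectRecord
from .errors import InvalidInputError
from .stages import STAGES, STAGE_INDEX
from .temporal import TransitionMatrix

__all__ = [
    "StageEmissionSpec",
    "SyntheticStudyConfig",
    "DEFAULT_TRANSITION_MATRIX",
    "default_emissions",
    "overlapping_emissions",
    "simulate_hypnogram",
    "synthesize_epoch",
    "generate_dataset",
]

#: Frequency bands available to the emission model (Hz). "full" is not a
#: component band; it is only meaningful for feature extraction.
EMISSION_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "sigma": (11.0, 16.0),
    "beta": (13.0, 30.0),
}

#: Sticky five-state transition matrix used as the default ground truth.
#: Diagonals 0.85-0.92 with the off-diagonal mass on physiologically
#: adjacent stages (W<->N1, N1<->N2, N2<->N3, REM reachable from N1/N2).
DEFAULT_TRANSITION_MATRIX = TransitionMatrix(
    probs=np.array(
        [
            # W      N1     N2     N3     REM
            [0.900, 0.070, 0.020, 0.005, 0.005],  # W
            [0.050, 0.850, 0.080, 0.005, 0.015],  # N1
            [0.020, 0.030, 0.900, 0.030, 0.020],  # N2
            [0.005, 0.005, 0.060, 0.920, 0.010],  # N3
            [0.020, 0.030, 0.030, 0.005, 0.915],  # REM
        ]
    ),
    stages=STAGES,
)


@dataclass(frozen=True)
class StageEmissionSpec:
    """Spectral recipe for one stage's epochs.

    band_weights are relative expected power fractions per band (any
    positive scale; they are normalized internally). spindle_rate is the
    expected number of spindle bursts per epoch (nonzero for N2 only, by
    default). noise_floor is broadband white noise RMS in microvolts,
    rms_uv the target RMS of the band mixture.
    """

    stage: str
    band_weights: dict[str, float]
    spindle_rate: float = 0.0
    noise_floor: float = 2.0
    rms_uv: float = 30.0

    def __post_init__(self):
        if self.stage not in STAGES:
            raise InvalidInputError(f"unknown stage {self.stage!r}")
        unknown = set(self.band_weights) - set(EMISSION_BANDS)
        if unknown:
            raise InvalidInputError(f"unknown emission bands: {sorted(unknown)}")
        if any(w < 0 for w in self.band_weights.values()):
            raise InvalidInputError("band weights must be nonnegative")
        if sum(self.band_weights.values()) <= 0:
            raise InvalidInputError("band weights must sum to a positive number")
        if self.spindle_rate < 0 or self.noise_floor < 0:
            raise InvalidInputError("spindle_rate and noise_floor must be >= 0")


def default_emissions() -> dict[str, StageEmissionSpec]:
    """Well-separated stage profiles mirroring textbook sleep EEG.

    Wake is alpha-dominant, N1 and REM theta-rich (REM with more beta),
    N2 mixed with spindles, N3 strongly delta-dominant.
    """
    return {
        "W": StageEmissionSpec("W", {"delta": 1.0, "theta": 0.6, "alpha": 2.5,
                                     "sigma": 0.4, "beta": 0.9}),
        "N1": StageEmissionSpec("N1", {"delta": 1.2, "theta": 2.2, "alpha": 0.8,
                                       "sigma": 0.3, "beta": 0.4}),
        "N2": StageEmissionSpec("N2", {"delta": 2.0, "theta": 1.0, "alpha": 0.5,
                                       "sigma": 1.3, "beta": 0.3}, spindle_rate=3.0),
        "N3": StageEmissionSpec("N3", {"delta": 6.0, "theta": 1.0, "alpha": 0.3,
                                       "sigma": 0.2, "beta": 0.2}),
        "REM": StageEmissionSpec("REM", {"delta": 1.0, "theta": 1.9, "alpha": 0.7,
                                         "sigma": 0.3, "beta": 0.8}),
    }


def overlapping_emissions(separation: float = 0.1) -> dict[str, StageEmissionSpec]:
    """Heavily overlapping stage profiles for memory-benefit experiments.

    Each stage's weights are a convex blend of its well-separated profile
    with the stage-averaged profile: ``separation = 1`` recovers
    :func:`default_emissions`, ``separation = 0`` makes all stages
    spectrally identical. The default 0.1 makes the waveform only weakly
    informative - the no-memory baseline lands near the accuracy real
    frontopolar single-channel stagers reach - so temporal context
    carries a meaningful share of the attainable signal, the regime the
    memory feature is designed for. Spindle rate is blended the same
    way.
    """
    base = default_emissions()
    keys = list(EMISSION_BANDS)
    # normalize each profile before averaging so no stage dominates the mean
    norm = {
        s: np.array([spec.band_weights.get(b, 0.0) for b in keys], dtype=float)
        for s, spec in base.items()
    }
    norm = {s: v / v.sum() for s, v in norm.items()}
    mean = np.mean(list(norm.values()), axis=0)
    out = {}
    for s, spec in base.items():
        blended = separation * norm[s] + (1 - separation) * mean
        out[s] = replace(
            spec,
            band_weights=dict(zip(keys, blended.tolist())),
            spindle_rate=separation * spec.spindle_rate,
        )
    return out


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Shape and conditions of a synthetic study."""

    n_subjects: int = 10
    epochs_per_subject: int = 600
    epoch_seconds: float = 30.0
    fs: float = 125.0
    T_true: TransitionMatrix = DEFAULT_TRANSITION_MATRIX
    emissions: dict[str, StageEmissionSpec] = field(default_factory=default_emissions)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1 or self.epochs_per_subject < 1:
            raise InvalidInputError("n_subjects and epochs_per_subject must be >= 1")
        n = self.fs * self.epoch_seconds
        if abs(n - round(n)) > 1e-9:
            raise InvalidInputError("fs * epoch_seconds must be an integer sample count")
        missing = set(STAGES) - set(self.emissions)
        if missing:
            raise InvalidInputError(f"missing emission specs for stages: {sorted(missing)}")


def simulate_hypnogram(T_true: TransitionMatrix, n_epochs: int,
                       initial_stage: str = "W", rng_seed: int = 0) -> list[str]:
    """Draw a stage-label sequence from a first-order Markov chain.

    The first element is ``initial_stage``; identical seeds give
    identical sequences.
    """
    if n_epochs < 1:
        raise InvalidInputError("n_epochs must be >= 1")
    if initial_stage not in T_true.stages:
        raise InvalidInputError(f"initial stage {initial_stage!r} not in stage set")
    rng = np.random.default_rng(rng_seed)
    k = T_true.k
    state = T_true.stages.index(initial_stage)
    out = [initial_stage]
    # draw all uniforms up front; inverse-CDF step per epoch
    cdf = np.cumsum(T_true.probs, axis=1)
    u = rng.random(n_epochs - 1)
    for t in range(n_epochs - 1):
        state = int(np.searchsorted(cdf[state], u[t], side="right"))
        state = min(state, k - 1)  # guard against roundoff at u ~ 1
        out.append(T_true.stages[state])
    return out


from functools import lru_cache


@lru_cache(maxsize=64)
def _bandpass_sos(fs: float, low: float, high: float) -> np.ndarray:
    return signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")


def _band_component(rng: np.random.Generator, n: int, fs: float,
                    low: float, high: float) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise (4th-order Butterworth)."""
    sos = _bandpass_sos(fs, low, high)
    # pad so the filter transient does not bias the epoch's band power
    pad = int(2 * fs)
    x = signal.sosfilt(sos, rng.standard_normal(n + pad))[pad:]
    rms = np.sqrt(np.mean(x**2))
    return x / rms


def _spindle_bursts(rng: np.random.Generator, n: int, fs: float, rate: float,
                    amplitude: float) -> np.ndarray:
    """Gaussian-windowed 13 Hz bursts at Poisson rate ``rate`` per epoch."""
    out = np.zeros(n)
    n_bursts = rng.poisson(rate)
    t = np.arange(n) / fs
    for _ in range(n_bursts):
        center = rng.uniform(0, n / fs)
        width = rng.uniform(0.25, 0.5)  # seconds (bursts last ~0.5-1 s)
        phase = rng.uniform(0, 2 * np.pi)
        env = np.exp(-0.5 * ((t - center) / width) ** 2)
        out += amplitude * env * np.sin(2 * np.pi * 13.0 * t + phase)
    return out


def synthesize_epoch(stage: str, spec: StageEmissionSpec, fs: float = 125.0,
                     epoch_seconds: float = 30.0,
                     rng_seed: int | np.random.Generator = 0) -> EpochSignal:
    """Generate one stage-conditioned EEG epoch (microvolts).

    Deterministic for a fixed integer seed; a ``numpy.random.Generator``
    may be passed instead for streaming use.
    """
    if spec.stage != stage:
        raise InvalidInputError(f"spec is for stage {spec.stage!r}, not {stage!r}")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    n = int(round(fs * epoch_seconds))
    weights = {b: w for b, w in spec.band_weights.items() if w > 0}
    total = sum(weights.values())
    x = np.zeros(n)
    for band, w in weights.items():
        low, high = EMISSION_BANDS[band]
        # unit-RMS components summed with sqrt(power fraction) amplitudes
        x += np.sqrt(w / total) * _band_component(rng, n, fs, low, high)
    x *= spec.rms_uv / max(np.sqrt(np.mean(x**2)), 1e-12)
    if spec.spindle_rate > 0:
        x += _spindle_bursts(rng, n, fs, spec.spindle_rate,
                             amplitude=1.5 * spec.rms_uv)
    if spec.noise_floor > 0:
        x += spec.noise_floor * rng.standard_normal(n)
    return EpochSignal(samples=x, fs=fs, epoch_seconds=epoch_seconds)


def generate_hypnograms(config: SyntheticStudyConfig) -> list[list[str]]:
    """Per-subject hypnograms only (initial stage W), with the same
    seed derivation :func:`generate_dataset` uses."""
    return [
        simulate_hypnogram(config.T_true, config.epochs_per_subject,
                           initial_stage="W",
                           rng_seed=(config.seed + 100_003 * (i + 1)) % (2**31))
        for i in range(config.n_subjects)
    ]


def generate_dataset(config: SyntheticStudyConfig) -> list[SubjectRecord]:
    """Generate a full synthetic study: per subject, a hypnogram (initial
    stage W) and one epoch waveform per label.

    Per-subject randomness derives from the master seed by fixed integer
    offsets, so subjects differ but the study is reproducible.
    """
    hypnograms = generate_hypnograms(config)
    study = []
    for i, labels in enumerate(hypnograms):
        sig_seed = (config.seed + 200_003 * (i + 1)) % (2**31)
        rng = np.random.default_rng(sig_seed)
        epochs = [
            synthesize_epoch(lab, config.emissions[lab], config.fs,
                             config.epoch_seconds, rng_seed=rng)
            for lab in labels
        ]
        study.append(SubjectRecord(subject_id=f"S{i:03d}", epochs=epochs,
                                   labels=labels,
                                   epoch_seconds=config.epoch_seconds))
    return study
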