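"""Recordings, epoch segmentation, resampling, and subject-level QC.

The pipeline consumes non-overlapping fixed-length epochs of a single
frontopolar derivation (Fp1-Fp2, obtained by subtracting two forehead
channels that share a linked-ear reference), resampled to 125 Hz. Beyond
the resampler's anti-alias low-pass, no filtering is applied; feature
extraction works on the raw derivation.

Subject-level quality control excludes whole recordings whose feature
summaries are gross outliers (further than 1.5 interquartile ranges from
the study median) or whose hypnograms churn implausibly fast (more than
40 stage transitions per hour), which usually indicates scoring or
recording errors rather than physiology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as _sig

from .errors import (
    AlignmentError,
    ChannelNotFoundError,
    InvalidInputError,
    UnsupportedResamplingError,
)
from .stages import merge_n4, validate_labels

logger = logging.getLogger(__name__)

__all__ = [
    "EpochSignal",
    "SubjectRecord",
    "Recording",
    "derive_frontopolar",
    "resample_to_target",
    "segment_epochs",
    "qc_exclude_subjects",
    "read_edf_recording",
]


@dataclass(frozen=True)
class EpochSignal:
    """One fixed-length single-channel EEG epoch (samples in microvolts)."""

    samples: np.ndarray
    fs: float
    epoch_seconds: float

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        expected = int(round(self.fs * self.epoch_seconds))
        if len(samples) != expected:
            raise InvalidInputError(
                f"epoch has {len(samples)} samples, expected fs*seconds = {expected}"
            )
        if not np.all(np.isfinite(samples)):
            raise InvalidInputError("epoch contains non-finite samples")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class SubjectRecord:
    """All scored epochs of one subject, aligned with stage labels."""

    subject_id: str
    epochs: list[EpochSignal]
    labels: list[str]
    epoch_seconds: float

    def __post_init__(self):
        if len(self.epochs) != len(self.labels):
            raise InvalidInputError("epochs and labels must have equal length")
        validate_labels(self.labels)

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    @property
    def hours(self) -> float:
        return self.n_epochs * self.epoch_seconds / 3600.0

    @property
    def transition_rate(self) -> float:
        """Stage changes between consecutive epochs, per hour of scoring."""
        changes = sum(a != b for a, b in zip(self.labels[:-1], self.labels[1:]))
        return changes / self.hours if self.hours > 0 else 0.0


@dataclass(frozen=True)
class Recording:
    """A raw multi-channel recording with optional stage annotations.

    ``annotations`` is a list of ``(onset_s, duration_s, stage)`` tuples.
    """

    channel_names: list[str]
    fs: float
    samples: np.ndarray  # shape (n_channels, n_samples), microvolts
    annotations: list[tuple[float, float, str]] | None = None

    def __post_init__(self):
        samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        object.__setattr__(self, "samples", samples)
        if samples.shape[0] != len(self.channel_names):
            raise InvalidInputError("one sample row per channel required")
        if self.fs <= 0:
            raise InvalidInputError("fs must be positive")

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.samples[self.channel_names.index(name)]
        except ValueError:
            raise ChannelNotFoundError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None


def derive_frontopolar(recording: Recording, fp1_name: str = "Fp1",
                       fp2_name: str = "Fp2") -> np.ndarray:
    """Fp1-Fp2 bipolar derivation: elementwise difference of the two
    referential channels (the shared reference cancels)."""
    return recording.channel(fp1_name) - recording.channel(fp2_name)


def resample_to_target(x: np.ndarray, fs_in: float, fs_out: float = 125.0) -> np.ndarray:
    """Anti-aliased polyphase downsampling from fs_in to fs_out.

    The rational ratio fs_out/fs_in drives ``scipy.signal.resample_poly``
    (e.g. 256 -> 125 Hz uses up/down = 125/256). Upsampling is refused.
    """
    if fs_out > fs_in:
        raise UnsupportedResamplingError(
            f"cannot upsample {fs_in} Hz -> {fs_out} Hz"
        )
    x = np.asarray(x, dtype=float)
    if fs_out == fs_in:
        return x.copy()
    ratio = Fraction(fs_out / fs_in).limit_denominator(10_000)
    y = _sig.resample_poly(x, ratio.numerator, ratio.denominator)
    n_out = int(len(x) * fs_out / fs_in)
    return y[:n_out]


def segment_epochs(x: np.ndarray, fs: float, epoch_seconds: float,
                   labels, subject_id: str = "subject") -> SubjectRecord:
    """Cut a signal into contiguous non-overlapping labeled epochs.

    Epochs are 0-based half-open sample windows starting at the beginning
    of the signal; trailing unlabeled samples are discarded. R&K N4
    labels are merged into N3.
    """
    labels = merge_n4(list(labels))
    n_per = int(round(fs * epoch_seconds))
    needed = n_per * len(labels)
    x = np.asarray(x, dtype=float)
    if len(x) < needed:
        raise AlignmentError(
            f"signal has {len(x)} samples but {len(labels)} labels need {needed}"
        )
    epochs = [
        EpochSignal(samples=x[i * n_per:(i + 1) * n_per], fs=fs,
                    epoch_seconds=epoch_seconds)
        for i in range(len(labels))
    ]
    return SubjectRecord(subject_id=subject_id, epochs=epochs, labels=labels,
                         epoch_seconds=epoch_seconds)


@dataclass(frozen=True)
class QCReport:
    """Which subjects were excluded and by which rule."""

    excluded: list[tuple[str, str, str]] = field(default_factory=list)
    # (subject_id, rule in {"feature-outlier", "transition-rate"}, detail)
    kept_ids: list[str] = field(default_factory=list)
    all_excluded: bool = False


def qc_exclude_subjects(study: list[SubjectRecord],
                        feature_summaries: np.ndarray | None = None,
                        iqr_factor: float = 1.5,
                        max_transition_rate: float = 40.0
                        ) -> tuple[list[SubjectRecord], QCReport]:
    """Apply subject-level quality-control exclusions.

    A subject is dropped if any of its feature summaries lies more than
    ``iqr_factor`` interquartile ranges from the study-wide median of
    that summary, or if its stage-transition rate exceeds
    ``max_transition_rate`` per hour. ``feature_summaries`` is an
    (n_subjects, n_summaries) array, by default the per-subject mean of
    each extracted feature (computed lazily to avoid a circular import).
    A zero IQR disables the corresponding outlier rule (identical
    subjects are all kept).
    """
    if len(study) < 3:
        raise InvalidInputError("QC needs >= 3 subjects for meaningful quartiles")
    if feature_summaries is None:
        from .features import FeatureSpec, extract_features

        spec = FeatureSpec()
        feature_summaries = np.array([
            np.mean([extract_features(e, spec) for e in rec.epochs], axis=0)
            for rec in study
        ])
    feature_summaries = np.asarray(feature_summaries, dtype=float)
    if feature_summaries.shape[0] != len(study):
        raise InvalidInputError("one summary row per subject required")

    med = np.median(feature_summaries, axis=0)
    q1, q3 = np.percentile(feature_summaries, [25, 75], axis=0)
    iqr = q3 - q1

    excluded: list[tuple[str, str, str]] = []
    kept: list[SubjectRecord] = []
    for row, rec in zip(feature_summaries, study):
        with np.errstate(invalid="ignore"):
            mask = (iqr > 0) & (np.abs(row - med) > iqr_factor * iqr)
        if mask.any():
            j = int(np.flatnonzero(mask)[0])
            excluded.append((rec.subject_id, "feature-outlier",
                             f"summary {j}: |{row[j]:.4g} - {med[j]:.4g}| > "
                             f"{iqr_factor} * IQR({iqr[j]:.4g})"))
        elif rec.transition_rate > max_transition_rate:
            excluded.append((rec.subject_id, "transition-rate",
                             f"{rec.transition_rate:.1f}/h > {max_transition_rate}/h"))
        else:
            kept.append(rec)
    report = QCReport(excluded=excluded, kept_ids=[r.subject_id for r in kept],
                      all_excluded=(len(kept) == 0))
    if report.all_excluded:
        logger.warning("QC excluded every subject")
    return kept, report


def read_edf_recording(path: str, channels: list[str] | None = None) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (requires ``mne``).

    Stage annotations, if present in the EDF+ annotation track, are
    passed through verbatim as ``(onset, duration, description)``.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise ImportError("EDF support requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, include=channels, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    ann = [(float(a["onset"]), float(a["duration"]), str(a["description"]))
           for a in raw.annotations] or None
    return Recording(channel_names=list(raw.ch_names), fs=float(raw.info["sfreq"]),
                     samples=data, annotations=ann)
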