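"""The fixed 37-feature vector computed per EEG epoch.

Feature blocks, in order:

1. time domain (3): skewness, kurtosis (Pearson, non-excess: a Gaussian
   scores 3), Higuchi fractal dimension;
2. Hjorth parameters (3): activity (variance; z-scored within subject in
   a separate pass), mobility, complexity;
3. band-power ratios (8): delta/alpha, delta/beta, delta/theta,
   theta/alpha, theta/beta, sigma/delta, delta/(alpha+beta),
   (delta+theta)/(alpha+beta);
4. spectral shape (3): normalized spectral entropy, spectral centroid,
   95% spectral roll-off, all over the 0.5-30 Hz band;
5. wavelet sub-bands (20): 5-level db4 decomposition; per detail band
   D1..D5: relative energy, coefficient entropy, Hjorth mobility and
   complexity of the coefficient sequence.

Every feature except Hjorth activity is invariant to amplitude scaling
of the epoch. Band powers are plain sums of squared DFT magnitudes of
the untapered epoch - no windowing or detrending is applied anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import stats

from .epochs import EpochSignal
from .errors import DegenerateSignalError, InsufficientDataError, InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSpec",
    "FEATURE_NAMES",
    "time_domain_features",
    "higuchi_fd",
    "hjorth_features",
    "zscore_activity_within_subject",
    "band_powers",
    "power_ratios",
    "spectral_shape",
    "wavelet_features",
    "extract_features",
]

#: Standard EEG bands (Hz); intervals are half-open [low, high).
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "sigma": (11.0, 16.0),
    "beta": (13.0, 30.0),
    "full": (0.5, 30.0),
}

#: The eight power ratios, as (numerator bands, denominator bands).
RATIO_DEFS: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...] = (
    (("delta",), ("alpha",)),
    (("delta",), ("beta",)),
    (("delta",), ("theta",)),
    (("theta",), ("alpha",)),
    (("theta",), ("beta",)),
    (("sigma",), ("delta",)),
    (("delta",), ("alpha", "beta")),
    (("delta", "theta"), ("alpha", "beta")),
)

_WAVELET_BANDS = ("D1", "D2", "D3", "D4", "D5")

FEATURE_NAMES: tuple[str, ...] = (
    "skewness", "kurtosis", "hfd",
    "hjorth_activity", "hjorth_mobility", "hjorth_complexity",
    *(f"ratio_{i}" for i in range(1, 9)),
    "spectral_entropy", "spectral_centroid", "spectral_rolloff",
    *(f"{b}_{suffix}" for b in _WAVELET_BANDS
      for suffix in ("relative_energy", "wavelet_entropy",
                     "wavelet_mobility", "wavelet_complexity")),
)
assert len(FEATURE_NAMES) == 37


@dataclass(frozen=True)
class FeatureSpec:
    """Tunable knobs of the extractor (defaults follow standard practice)."""

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS))
    rolloff_fraction: float = 0.95
    hfd_kmax: int = 10
    wavelet_name: str = "db4"
    wavelet_levels: int = 5
    #: denominator of relative wavelet energy: detail bands only (the
    #: approximation band is excluded); set True to include it.
    include_approximation_energy: bool = False


def _check_nonconstant(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateSignalError("constant epoch has no defined features")
    return x


def higuchi_fd(x: np.ndarray, kmax: int = 10) -> float:
    """Higuchi fractal dimension via the curve-length regression.

    For each scale k and offset m, the normalized curve length is

        L_m(k) = [ sum_i |x(m+ik) - x(m+(i-1)k)| * (N-1) / (floor((N-m)/k) k) ] / k

    and the HFD is the slope of log(mean_m L_m(k)) against log(1/k).
    Values near 1 indicate smooth curves, near 2 noise-like ones.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n <= kmax:
        raise InsufficientDataError(f"epoch length {n} must exceed kmax={kmax}")
    lk = np.empty(kmax)
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if len(idx) < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / ((len(idx) - 1) * k)
            lengths.append(dist * norm / k)
        lk[k - 1] = np.mean(lengths)
    log_k = np.log(1.0 / np.arange(1, kmax + 1))
    slope, _ = np.polyfit(log_k, np.log(lk), 1)
    return float(slope)


def time_domain_features(epoch: EpochSignal, hfd_kmax: int = 10
                         ) -> tuple[float, float, float]:
    """Skewness, kurtosis (non-excess), and Higuchi fractal dimension."""
    x = _check_nonconstant(epoch.samples)
    skew = float(stats.skew(x, bias=True))
    kurt = float(stats.kurtosis(x, fisher=False, bias=True))
    return skew, kurt, higuchi_fd(x, hfd_kmax)


def hjorth_features(x) -> tuple[float, float, float]:
    """Hjorth activity, mobility, complexity of a sample sequence.

    Activity is the (population) variance; mobility the square root of
    var(first difference)/var(signal); complexity the ratio of the first
    difference's mobility to the signal's. Accepts an EpochSignal or a
    plain array (the wavelet block reuses this on coefficient
    sequences).
    """
    samples = x.samples if isinstance(x, EpochSignal) else np.asarray(x, dtype=float)
    samples = _check_nonconstant(samples)
    d1 = np.diff(samples)
    d2 = np.diff(d1)
    var0 = samples.var()
    var1 = d1.var()
    var2 = d2.var()
    mobility = float(np.sqrt(var1 / var0))
    mobility_d1 = np.sqrt(var2 / var1) if var1 > 0 else 0.0
    complexity = float(mobility_d1 / mobility) if mobility > 0 else 0.0
    return float(var0), mobility, complexity


def zscore_activity_within_subject(activity: np.ndarray) -> np.ndarray:
    """Standardize one subject's activity values to mean 0, SD 1.

    Population-SD convention. Zero dispersion yields all zeros with a
    logged warning instead of an error, keeping the pipeline total.
    """
    activity = np.asarray(activity, dtype=float)
    if len(activity) < 2:
        raise InsufficientDataError("z-scoring needs >= 2 epochs")
    sd = activity.std()
    if sd == 0:
        logger.warning("zero dispersion in activity; z-scores set to 0")
        return np.zeros_like(activity)
    return (activity - activity.mean()) / sd


def _spectrum(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided squared-magnitude DFT spectrum and its bin frequencies."""
    mag = np.abs(np.fft.rfft(x))
    return np.fft.rfftfreq(len(x), d=1.0 / fs), mag**2


def band_powers(epoch: EpochSignal, bands: dict[str, tuple[float, float]] | None = None
                ) -> dict[str, float]:
    """Per-band power: sum of squared DFT magnitudes over [low, high)."""
    bands = dict(DEFAULT_BANDS) if bands is None else bands
    freqs, power = _spectrum(np.asarray(epoch.samples, dtype=float), epoch.fs)
    return {
        name: float(power[(freqs >= low) & (freqs < high)].sum())
        for name, (low, high) in bands.items()
    }


def power_ratios(powers: dict[str, float], eps: float = 1e-12) -> np.ndarray:
    """The eight band-power ratios, in the fixed order of RATIO_DEFS.

    A zero denominator is guarded by ``eps`` (with a logged warning)
    rather than dropping the epoch.
    """
    out = np.empty(len(RATIO_DEFS))
    for i, (num, den) in enumerate(RATIO_DEFS):
        numerator = sum(powers[b] for b in num)
        denominator = sum(powers[b] for b in den)
        if denominator == 0:
            logger.warning("zero denominator in ratio %d; using eps guard", i + 1)
            denominator = eps
        out[i] = numerator / denominator
    return out


def spectral_shape(epoch: EpochSignal, rolloff_fraction: float = 0.95,
                   band: tuple[float, float] = (0.5, 30.0)
                   ) -> tuple[float, float, float]:
    """Normalized spectral entropy, centroid (Hz), roll-off (Hz).

    All three are computed on the normalized power spectrum restricted to
    the full EEG band. Entropy is divided by log(bin count) so a flat
    in-band spectrum scores 1. Roll-off is the smallest bin frequency at
    which the cumulative in-band power reaches ``rolloff_fraction`` of
    the total.
    """
    x = _check_nonconstant(epoch.samples)
    freqs, power = _spectrum(x, epoch.fs)
    mask = (freqs >= band[0]) & (freqs < band[1])
    f, p = freqs[mask], power[mask]
    total = p.sum()
    if total <= 0:
        raise DegenerateSignalError("zero in-band power")
    prob = p / total
    nz = prob[prob > 0]
    entropy = float(-(nz * np.log(nz)).sum() / np.log(len(prob)))
    centroid = float((f * prob).sum())
    rolloff = float(f[np.searchsorted(np.cumsum(prob), rolloff_fraction)])
    return entropy, centroid, rolloff


def _band_entropy(coeffs: np.ndarray) -> float:
    """Shannon entropy (nats) of the normalized squared coefficients."""
    energy = coeffs**2
    total = energy.sum()
    if total == 0:
        return 0.0
    p = energy / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def wavelet_features(epoch: EpochSignal, spec: FeatureSpec | None = None) -> np.ndarray:
    """20 wavelet features: (relative energy, entropy, mobility,
    complexity) per detail band D1..D5 of a 5-level db4 decomposition.

    At 125 Hz the detail bands approximate the classical EEG bands:
    D1 ~31-62 Hz, D2 ~16-31 Hz (beta), D3 ~8-16 Hz (alpha/sigma),
    D4 ~4-8 Hz (theta), D5 ~2-4 Hz (delta). Periodized boundary handling
    keeps the transform orthogonal. Relative energies are normalized by
    the total detail energy (the approximation band is excluded by
    default). A band with all-zero coefficients reports 0 for its
    entropy, mobility and complexity.
    """
    spec = spec or FeatureSpec()
    x = _check_nonconstant(epoch.samples)
    if len(x) < 2**spec.wavelet_levels:
        raise InsufficientDataError("epoch shorter than 2**levels samples")
    coeffs = pywt.wavedec(x, spec.wavelet_name, mode="periodization",
                          level=spec.wavelet_levels)
    approx, details = coeffs[0], coeffs[1:]  # details: [D5, D4, ..., D1]
    details = details[::-1]  # -> D1..D5
    energies = np.array([float((d**2).sum()) for d in details])
    denom = energies.sum()
    if spec.include_approximation_energy:
        denom += float((approx**2).sum())
    out = []
    for d, e in zip(details, energies):
        rel = e / denom if denom > 0 else 0.0
        if e == 0 or np.ptp(d) == 0:
            logger.warning("all-zero/constant wavelet band; features set to 0")
            out.extend([rel, 0.0, 0.0, 0.0])
            continue
        _, mob, comp = hjorth_features(d)
        out.extend([rel, _band_entropy(d), mob, comp])
    return np.array(out)


def extract_features(epoch: EpochSignal, spec: FeatureSpec | None = None) -> np.ndarray:
    """The full ordered 37-feature vector of one epoch.

    Hjorth activity is returned raw here; the within-subject z-scoring is
    a separate subject-level pass (:func:`zscore_activity_within_subject`).
    """
    spec = spec or FeatureSpec()
    skew, kurt, hfd = time_domain_features(epoch, spec.hfd_kmax)
    act, mob, comp = hjorth_features(epoch)
    powers = band_powers(epoch, spec.bands)
    ratios = power_ratios(powers)
    ent, cen, roll = spectral_shape(epoch, spec.rolloff_fraction,
                                    band=spec.bands["full"])
    wav = wavelet_features(epoch, spec)
    vec = np.concatenate([[skew, kurt, hfd, act, mob, comp], ratios,
                          [ent, cen, roll], wav])
    if vec.shape != (37,):
        raise InvalidInputError(f"feature vector has shape {vec.shape}, expected (37,)")
    return vec
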