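"""Hypnogram temporal statistics and Markov transition machinery.

Two things live here. First, the autocovariance analysis that quantifies
how long a sleep stage "remembers" itself: the binary indicator series of
a stage, its (biased, 1/n-normalized) autocovariance :math:`\\gamma(\\tau)`,
the variance-normalized profile :math:`\\rho(\\tau)`, and the discrete
autocorrelation time

.. math:: t_c = \\Delta t \\sum_{\\tau=0}^{\\tau_{max}} \\rho(\\tau),

truncated at the last lag before the first non-positive value of
:math:`\\rho` (only positive autocorrelation reflects persistence of a
stage). Second, the first-order Markov model of stage progression: a
row-stochastic transition matrix T estimated from training hypnograms by
normalized transition counts, and the transition vector
:math:`v_t = p_{t-1} \\cdot T` that feeds the memory-augmented classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateSignalError, InsufficientDataError, InvalidInputError
from .stages import STAGES, validate_labels

logger = logging.getLogger(__name__)

__all__ = [
    "StageIndicatorSeries",
    "AutocovProfile",
    "TransitionMatrix",
    "indicator_series",
    "autocovariance",
    "normalize_autocov",
    "autocorrelation_time",
    "autocov_profile",
    "group_average_autocov",
    "estimate_transition_matrix",
    "transition_vector",
    "initial_distribution",
]


@dataclass(frozen=True)
class StageIndicatorSeries:
    """Binary indicator of one stage along a hypnogram, with its mean."""

    values: np.ndarray  # int array in {0, 1}
    mean: float
    delta_t: float  # seconds per epoch
    stage: str

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class AutocovProfile:
    """Autocovariance/autocorrelation summary of one stage indicator."""

    gamma: np.ndarray  # gamma(tau), tau = 0..max_lag
    rho: np.ndarray  # gamma(tau) / gamma(0)
    tau_max: int  # last lag before the first non-positive rho
    t_c: float  # autocorrelation time, seconds
    delta_t: float  # seconds per epoch


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic K x K matrix of stage-to-stage probabilities.

    ``probs[i, j]`` is P(stage_t = stages[j] | stage_{t-1} = stages[i]).
    """

    probs: np.ndarray
    stages: tuple[str, ...] = STAGES

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        k = len(self.stages)
        if probs.shape != (k, k):
            raise InvalidInputError(
                f"transition matrix shape {probs.shape} does not match {k} stages"
            )
        if np.any(probs < -1e-12) or np.any(probs > 1 + 1e-12):
            raise InvalidInputError("transition probabilities must lie in [0, 1]")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise InvalidInputError("each transition-matrix row must sum to 1")

    @property
    def k(self) -> int:
        return len(self.stages)

    def row(self, stage: str) -> np.ndarray:
        return self.probs[self.stages.index(stage)]


def indicator_series(labels, stage: str, delta_t: float = 30.0) -> StageIndicatorSeries:
    """Binary indicator I_t = 1 where the hypnogram carries ``stage``."""
    labels = list(labels)
    if not labels:
        raise InvalidInputError("empty label sequence")
    values = np.fromiter((1 if l == stage else 0 for l in labels), dtype=int)
    return StageIndicatorSeries(values=values, mean=float(values.mean()),
                                delta_t=float(delta_t), stage=stage)


def autocovariance(series: StageIndicatorSeries, max_lag: int = 120) -> np.ndarray:
    """Biased autocovariance gamma(tau) of an indicator series.

    Uses the 1/n convention: gamma(tau) = (1/n) * sum_{t} (I_{t+tau} - mean)(I_t - mean)
    with the sum running over the n - tau overlapping pairs, so gamma(0)
    is the population variance of the indicator.
    """
    n = len(series)
    if n <= 1:
        raise InsufficientDataError("need at least 2 epochs for autocovariance")
    if max_lag >= n:
        max_lag = n - 1
    dev = series.values.astype(float) - series.mean
    gamma = np.empty(max_lag + 1)
    for tau in range(max_lag + 1):
        gamma[tau] = np.dot(dev[tau:], dev[: n - tau]) / n
    return gamma


def normalize_autocov(gamma: np.ndarray) -> np.ndarray:
    """rho(tau) = gamma(tau) / gamma(0)."""
    gamma = np.asarray(gamma, dtype=float)
    if gamma[0] <= 0:
        raise DegenerateSignalError("gamma(0) must be positive to normalize")
    return gamma / gamma[0]


def autocorrelation_time(rho: np.ndarray, delta_t: float) -> tuple[float, int]:
    """Discrete autocorrelation time t_c and its truncation lag tau_max.

    tau_max is the largest lag such that rho(0..tau_max) are all strictly
    positive (i.e. the sum stops just before the first non-positive lag);
    t_c = delta_t * sum_{tau=0}^{tau_max} rho(tau). tau_max = 0 (t_c =
    delta_t) is valid and arises for memoryless series.
    """
    rho = np.asarray(rho, dtype=float)
    if not np.isclose(rho[0], 1.0):
        raise InvalidInputError("rho must be normalized (rho[0] == 1)")
    nonpos = np.flatnonzero(rho <= 0)
    tau_max = int(nonpos[0] - 1) if nonpos.size else len(rho) - 1
    t_c = float(delta_t * rho[: tau_max + 1].sum())
    return t_c, tau_max


def autocov_profile(labels, stage: str, delta_t: float = 30.0,
                    max_lag: int = 120) -> AutocovProfile:
    """Full gamma / rho / t_c summary for one stage of one hypnogram."""
    series = indicator_series(labels, stage, delta_t)
    gamma = autocovariance(series, max_lag)
    rho = normalize_autocov(gamma)
    t_c, tau_max = autocorrelation_time(rho, delta_t)
    return AutocovProfile(gamma=gamma, rho=rho, tau_max=tau_max, t_c=t_c,
                          delta_t=delta_t)


def group_average_autocov(gammas: list[np.ndarray],
                          max_lag: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Group-level normalized autocovariance with per-lag standard errors.

    Subject gamma profiles are averaged lag-wise, then the mean profile is
    normalized by its own zero-lag value (this is not the average of the
    individual rho profiles). Subjects with zero variance are skipped.

    Returns ``(rho, se)`` where ``se`` is the standard error of the mean
    of the normalized per-subject profiles (normalized by the group
    zero-lag value, so it is on the same scale as ``rho``).
    """
    usable = []
    for g in gammas:
        g = np.asarray(g, dtype=float)
        if g[0] <= 0:
            logger.warning("skipping subject with zero-variance indicator")
            continue
        usable.append(g)
    if len(usable) < 2:
        raise InsufficientDataError("need >= 2 usable subjects for a group profile")
    if max_lag is None:
        max_lag = min(len(g) for g in usable) - 1
    stacked = np.stack([g[: max_lag + 1] for g in usable])
    mean_gamma = stacked.mean(axis=0)
    rho = mean_gamma / mean_gamma[0]
    se = stacked.std(axis=0, ddof=1) / np.sqrt(len(usable)) / mean_gamma[0]
    return rho, se


def estimate_transition_matrix(hypnograms, stages=STAGES,
                               smoothing: float = 0.0) -> TransitionMatrix:
    """Estimate a first-order transition matrix from hypnograms.

    Transitions are counted within each hypnogram only (never across
    subject boundaries) and pooled; each row of counts (+ optional
    additive smoothing) is normalized to conditional probabilities. A
    stage never observed as a predecessor gets a uniform row so the
    matrix stays stochastic.
    """
    stages = tuple(stages)
    idx = {s: i for i, s in enumerate(stages)}
    k = len(stages)
    counts = np.zeros((k, k))
    total = 0
    for hyp in hypnograms:
        hyp = list(hyp)
        validate_labels(hyp, stages)
        for a, b in zip(hyp[:-1], hyp[1:]):
            counts[idx[a], idx[b]] += 1
            total += 1
    if total == 0:
        raise InsufficientDataError("no transitions observed in any hypnogram")
    counts += smoothing
    probs = np.empty_like(counts)
    row_sums = counts.sum(axis=1)
    for i in range(k):
        if row_sums[i] > 0:
            probs[i] = counts[i] / row_sums[i]
        else:
            logger.warning("stage %s never observed as predecessor; uniform row", stages[i])
            probs[i] = 1.0 / k
    return TransitionMatrix(probs=probs, stages=stages)


def transition_vector(p_prev: np.ndarray, T: TransitionMatrix) -> np.ndarray:
    """Memory feature v_t = p_{t-1} . T (row vector times matrix)."""
    p_prev = np.asarray(p_prev, dtype=float)
    if p_prev.shape != (T.k,):
        raise InvalidInputError(
            f"distribution length {p_prev.shape} does not match {T.k} stages"
        )
    return p_prev @ T.probs


def initial_distribution(stages=STAGES) -> np.ndarray:
    """One-hot prior at wake, used for the first epoch of every subject."""
    stages = tuple(stages)
    if "W" not in stages:
        raise InvalidInputError("stage set must contain W (wake)")
    p0 = np.zeros(len(stages))
    p0[stages.index("W")] = 1.0
    return p0
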