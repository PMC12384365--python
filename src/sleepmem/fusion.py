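"""Confidence-gated fusion of the two models, with a reject option.

Per epoch, each model's confidence is its maximum softmax probability.
The more confident model's prediction is accepted if that confidence
reaches the threshold (boundary inclusive; default 0.7); otherwise the
epoch is marked NC (not classified). Each decision records its source:

* ``mem_dominant`` / ``nomem_dominant`` - both models reached the
  threshold, the named one was more confident (exact ties go to the
  memory model);
* ``mem_only`` / ``nomem_only`` - only the named model reached it;
* ``not_classified`` - neither did.

The five categories partition all epochs. NC epochs are excluded from
accuracy/kappa/F1; rejection trades coverage for reliability, since
low-confidence epochs are enriched with stage transitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .stages import NC, STAGES

__all__ = [
    "SOURCES",
    "DecisionRecord",
    "ThresholdSweepRow",
    "combine",
    "combine_sequences",
    "decision_source_distribution",
    "nc_composition",
    "threshold_sweep",
]

SOURCES = ("mem_dominant", "nomem_dominant", "mem_only", "nomem_only",
           "not_classified")

DEFAULT_THRESHOLD = 0.7


@dataclass(frozen=True)
class DecisionRecord:
    """Fused outcome for one epoch."""

    prediction: str  # stage label or NC
    source: str  # one of SOURCES
    conf_mem: float
    conf_nomem: float

    def __post_init__(self):
        if (self.prediction == NC) != (self.source == "not_classified"):
            raise InvalidInputError("NC prediction iff not_classified source")


@dataclass(frozen=True)
class ThresholdSweepRow:
    threshold: float
    accuracy: float  # nan when every epoch is rejected
    kappa: float
    rejected_fraction: float


def _check_simplex(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or np.any(p < -1e-9) or not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise InvalidInputError("softmax distribution must be a probability vector")
    return p


def combine(p_mem: np.ndarray, p_nomem: np.ndarray,
            threshold: float = DEFAULT_THRESHOLD,
            stages=STAGES) -> DecisionRecord:
    """Apply the confidence rule to one epoch's pair of distributions."""
    if not 0 < threshold < 1:
        raise InvalidInputError("threshold must lie in (0, 1)")
    p_mem = _check_simplex(p_mem)
    p_nomem = _check_simplex(p_nomem)
    c_m, c_n = float(p_mem.max()), float(p_nomem.max())
    mem_ok, nomem_ok = c_m >= threshold, c_n >= threshold
    if not (mem_ok or nomem_ok):
        return DecisionRecord(NC, "not_classified", c_m, c_n)
    if mem_ok and nomem_ok:
        use_mem = c_m >= c_n  # tie goes to the memory model
        source = "mem_dominant" if use_mem else "nomem_dominant"
    else:
        use_mem = mem_ok
        source = "mem_only" if mem_ok else "nomem_only"
    winner = p_mem if use_mem else p_nomem
    return DecisionRecord(stages[int(np.argmax(winner))], source, c_m, c_n)


def combine_sequences(p_mem_seq: np.ndarray, p_nomem_seq: np.ndarray,
                      threshold: float = DEFAULT_THRESHOLD,
                      stages=STAGES) -> list[DecisionRecord]:
    """Vector version of :func:`combine` over aligned rows."""
    p_mem_seq = np.asarray(p_mem_seq, dtype=float)
    p_nomem_seq = np.asarray(p_nomem_seq, dtype=float)
    if p_mem_seq.shape != p_nomem_seq.shape:
        raise InvalidInputError("model output sequences must align")
    return [combine(m, n, threshold, stages)
            for m, n in zip(p_mem_seq, p_nomem_seq)]


def decision_source_distribution(records) -> dict[str, float]:
    """Fractions of epochs per decision source (sums to 1)."""
    records = list(records)
    if not records:
        raise InvalidInputError("empty decision sequence")
    n = len(records)
    return {s: sum(r.source == s for r in records) / n for s in SOURCES}


def nc_composition(records, true_labels, stages=STAGES) -> dict[str, float]:
    """Ground-truth stage distribution among rejected (NC) epochs.

    Empty dict when nothing was rejected.
    """
    records = list(records)
    true_labels = list(true_labels)
    if len(records) != len(true_labels):
        raise InvalidInputError("records and labels must align")
    nc_true = [t for r, t in zip(records, true_labels) if r.prediction == NC]
    if not nc_true:
        return {}
    n = len(nc_true)
    return {s: nc_true.count(s) / n for s in stages}


def threshold_sweep(p_mem_seq, p_nomem_seq, true_labels,
                    thresholds, stages=STAGES) -> list[ThresholdSweepRow]:
    """Coverage/reliability trade-off across confidence thresholds.

    Accuracy and kappa are computed over non-NC epochs only (nan when a
    threshold rejects everything); the rejected fraction is over all
    epochs and is non-decreasing in the threshold.
    """
    from .evaluation import accuracy as _acc, cohen_kappa as _kappa

    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise InvalidInputError("thresholds must be sorted ascending")
    rows = []
    for th in thresholds:
        records = combine_sequences(p_mem_seq, p_nomem_seq, th, stages)
        preds = [r.prediction for r in records]
        rejected = sum(p == NC for p in preds) / len(preds)
        rows.append(ThresholdSweepRow(
            threshold=float(th),
            accuracy=_acc(preds, true_labels),
            kappa=_kappa(preds, true_labels),
            rejected_fraction=float(rejected),
        ))
    return rows
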