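"""Canonical sleep-stage vocabulary.

The five-class AASM set is used everywhere: wake (W), the three NREM
stages N1-N3, and REM. Six-class R&K scorings are folded into this set
by merging N4 into N3 at load time. ``NC`` ("not classified") is the
reject label emitted by the confidence-gated fusion rule; it is never a
training label.
"""

from __future__ import annotations

STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "REM")
"""Fixed stage order used for transition matrices and softmax outputs."""

STAGE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STAGES)}

NC = "NC"
"""Reject label for epochs where neither model reaches the confidence threshold."""

N_STAGES = len(STAGES)


def validate_labels(labels, stages=STAGES) -> None:
    """Raise ``ValueError`` if any label is outside the stage set."""
    bad = sorted({l for l in labels} - set(stages))
    if bad:
        raise ValueError(f"unknown stage labels: {bad}; expected subset of {stages}")


def merge_n4(labels) -> list[str]:
    """Map R&K six-class labels onto the five-class set (N4 -> N3)."""
    return ["N3" if l == "N4" else l for l in labels]
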