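"""Leave-one-subject-out evaluation, metrics, and feature importance.

Each fold holds one subject out; the feature scaler, the transition
matrix T, and both networks are fitted on the remaining subjects only,
then the test subject is decoded causally (memory model self-fed) and
the two output streams are fused at the confidence threshold. Metrics -
accuracy, Cohen's kappa, per-class and macro F1 - are computed over
non-rejected epochs only, aggregated as per-subject means with standard
errors (SD / sqrt(n_subjects)); pooled-epoch versions are also reported.
Undefined quantities (e.g. kappa when chance agreement is 1, F1 of a
stage absent from the test truth) are NaN markers, never 0.

Per-fold SHA-256 checksums of the fitted scaler and T support a
no-leakage audit: they must be invariant to any perturbation of the
held-out subject's data.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score as _sk_f1

from .epochs import SubjectRecord
from .errors import InvalidInputError
from .features import FEATURE_NAMES, FeatureSpec, extract_features, \
    zscore_activity_within_subject
from .fusion import DEFAULT_THRESHOLD, DecisionRecord, SOURCES, \
    combine_sequences, decision_source_distribution, nc_composition
from .models import FNNConfig, TrainedFNN, assemble_memory_inputs_train, \
    fit_scaler, predict_proba, sequential_predict_memory, train_model
from .stages import NC, STAGES
from .temporal import estimate_transition_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "FoldResult",
    "EvalReport",
    "loso_split",
    "extract_study_features",
    "run_loso",
    "accuracy",
    "cohen_kappa",
    "f1_per_class",
    "macro_f1",
    "permutation_importance",
]


def loso_split(subject_ids) -> list[tuple[list, object]]:
    """All (train ids, test id) leave-one-subject-out folds."""
    subject_ids = list(subject_ids)
    if len(subject_ids) < 2:
        raise InvalidInputError("LOSO needs >= 2 subjects")
    return [([s for s in subject_ids if s != test], test) for test in subject_ids]


def _mask_nc(pred, true):
    pairs = [(p, t) for p, t in zip(pred, true) if p != NC]
    if len(pred) != len(true):
        raise InvalidInputError("prediction and truth must align")
    return pairs


def accuracy(pred, true) -> float:
    """Fraction correct over non-NC epochs (NaN if all rejected)."""
    pairs = _mask_nc(pred, true)
    if not pairs:
        return float("nan")
    return sum(p == t for p, t in pairs) / len(pairs)


def cohen_kappa(pred, true) -> float:
    """Cohen's kappa over non-NC epochs: (p_o - p_e) / (1 - p_e).

    Chance agreement p_e comes from the marginal products. NaN when all
    epochs are rejected or p_e = 1 (a single class on both sides).
    """
    pairs = _mask_nc(pred, true)
    if not pairs:
        return float("nan")
    n = len(pairs)
    p_o = sum(p == t for p, t in pairs) / n
    classes = {c for pair in pairs for c in pair}
    p_e = sum(
        (sum(p == c for p, _ in pairs) / n) * (sum(t == c for _, t in pairs) / n)
        for c in classes
    )
    if np.isclose(p_e, 1.0):
        return float("nan")
    return (p_o - p_e) / (1 - p_e)


def f1_per_class(pred, true, stages=STAGES) -> dict[str, float]:
    """Per-stage F1 = 2PR/(P+R) over non-NC epochs.

    A stage absent from both truth and predictions gets NaN; a stage
    present in the truth but never predicted gets 0.
    """
    pairs = _mask_nc(pred, true)
    if not pairs:
        return {s: float("nan") for s in stages}
    p, t = zip(*pairs)
    scores = _sk_f1(t, p, labels=list(stages), average=None, zero_division=np.nan)
    return dict(zip(stages, (float(v) for v in scores)))


def macro_f1(pred, true, stages=STAGES) -> float:
    """Unweighted mean F1 over the stages present in the (non-NC) truth."""
    pairs = _mask_nc(pred, true)
    if not pairs:
        return float("nan")
    present = [s for s in stages if s in {t for _, t in pairs}]
    scores = f1_per_class(pred, true, stages)
    return float(np.mean([scores[s] for s in present]))


@dataclass(frozen=True)
class FoldResult:
    """Everything measured on one held-out subject."""

    test_subject: str
    decisions: list[DecisionRecord]
    true_labels: list[str]
    accuracy: float
    kappa: float
    f1_per_class: dict[str, float]
    macro_f1: float
    rejected_fraction: float
    accuracy_nomem_raw: float  # argmax of the no-memory model, no rejection
    accuracy_mem_seq: float  # argmax of the self-fed memory model, no rejection
    scaler_checksum: str
    transition_checksum: str


@dataclass(frozen=True)
class EvalReport:
    """Study-level LOSO results."""

    folds: list[FoldResult]
    summary: dict[str, tuple[float, float]]  # metric -> (mean, SE over subjects)
    f1_summary: dict[str, tuple[float, float]]  # stage -> (mean, SE)
    pooled: dict[str, float]  # pooled-epoch accuracy/kappa/macro_f1/rejected
    pooled_f1: dict[str, float]
    source_distribution: dict[str, float]
    nc_composition: dict[str, float]
    threshold: float


def _checksum(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a, dtype=float).tobytes())
    return h.hexdigest()


def extract_study_features(study: list[SubjectRecord],
                           spec: FeatureSpec | None = None) -> pd.DataFrame:
    """Feature table for a whole study: one row per epoch.

    Columns: subject_id, epoch_index, label, then the 37 features with
    Hjorth activity already z-scored within each subject (a per-subject
    unsupervised pass, applied identically to train and test subjects).
    """
    spec = spec or FeatureSpec()
    frames = []
    for rec in study:
        mat = np.array([extract_features(e, spec) for e in rec.epochs])
        act_col = FEATURE_NAMES.index("hjorth_activity")
        if len(rec.epochs) >= 2:
            mat[:, act_col] = zscore_activity_within_subject(mat[:, act_col])
        df = pd.DataFrame(mat, columns=list(FEATURE_NAMES))
        df.insert(0, "label", rec.labels)
        df.insert(0, "epoch_index", np.arange(len(rec.epochs)))
        df.insert(0, "subject_id", rec.subject_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _mean_se(values) -> tuple[float, float]:
    v = np.asarray([x for x in values if np.isfinite(x)], dtype=float)
    if v.size == 0:
        return float("nan"), float("nan")
    se = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else float("nan")
    return float(v.mean()), float(se)


def run_loso(study: list[SubjectRecord],
             fnn_config: FNNConfig | None = None,
             feature_spec: FeatureSpec | None = None,
             threshold: float = DEFAULT_THRESHOLD,
             features: pd.DataFrame | None = None) -> EvalReport:
    """Full LOSO evaluation of the combined framework on a study.

    ``features`` may carry a precomputed table from
    :func:`extract_study_features`; otherwise features are extracted
    here. Deterministic for a fixed study and ``fnn_config.seed``.
    """
    fnn_config = fnn_config or FNNConfig()
    if len(study) < 2:
        raise InvalidInputError("LOSO needs >= 2 subjects")
    if features is None:
        features = extract_study_features(study, feature_spec)
    # contiguous copies so downstream numerics are layout-independent
    by_subject = {
        rec.subject_id: (
            np.ascontiguousarray(
                features.loc[features.subject_id == rec.subject_id,
                             list(FEATURE_NAMES)].to_numpy(), dtype=float),
            rec.labels,
        )
        for rec in study
    }

    folds = []
    for train_ids, test_id in loso_split([r.subject_id for r in study]):
        x_test, y_test = by_subject[test_id]
        if len(y_test) < 2:
            logger.warning("skipping fold %s: test subject has < 2 epochs", test_id)
            continue
        x_train = np.vstack([by_subject[s][0] for s in train_ids])
        y_train = [l for s in train_ids for l in by_subject[s][1]]
        scaler = fit_scaler(x_train)
        T = estimate_transition_matrix([by_subject[s][1] for s in train_ids])
        mem_train = np.vstack([
            assemble_memory_inputs_train(by_subject[s][1], T) for s in train_ids
        ])
        nomem = train_model(x_train, y_train, fnn_config, scaler=scaler)
        mem = train_model(x_train, y_train, fnn_config, memory_inputs=mem_train,
                          scaler=scaler)
        p_nomem = predict_proba(nomem, x_test)
        p_mem = sequential_predict_memory(mem, x_test, T)
        records = combine_sequences(p_mem, p_nomem, threshold)
        preds = [r.prediction for r in records]
        folds.append(FoldResult(
            test_subject=test_id,
            decisions=records,
            true_labels=list(y_test),
            accuracy=accuracy(preds, y_test),
            kappa=cohen_kappa(preds, y_test),
            f1_per_class=f1_per_class(preds, y_test),
            macro_f1=macro_f1(preds, y_test),
            rejected_fraction=sum(p == NC for p in preds) / len(preds),
            accuracy_nomem_raw=accuracy(
                [STAGES[i] for i in p_nomem.argmax(axis=1)], y_test),
            accuracy_mem_seq=accuracy(
                [STAGES[i] for i in p_mem.argmax(axis=1)], y_test),
            scaler_checksum=_checksum(scaler.mean_, scaler.scale_),
            transition_checksum=_checksum(T.probs),
        ))

    summary = {
        name: _mean_se(getattr(f, name) for f in folds)
        for name in ("accuracy", "kappa", "macro_f1", "rejected_fraction",
                     "accuracy_nomem_raw", "accuracy_mem_seq")
    }
    f1_summary = {
        s: _mean_se(f.f1_per_class[s] for f in folds) for s in STAGES
    }
    all_records = [r for f in folds for r in f.decisions]
    all_true = [t for f in folds for t in f.true_labels]
    all_preds = [r.prediction for r in all_records]
    pooled = {
        "accuracy": accuracy(all_preds, all_true),
        "kappa": cohen_kappa(all_preds, all_true),
        "macro_f1": macro_f1(all_preds, all_true),
        "rejected_fraction": sum(p == NC for p in all_preds) / len(all_preds),
    }
    return EvalReport(
        folds=folds,
        summary=summary,
        f1_summary=f1_summary,
        pooled=pooled,
        pooled_f1=f1_per_class(all_preds, all_true),
        source_distribution=decision_source_distribution(all_records),
        nc_composition=nc_composition(all_records, all_true),
        threshold=threshold,
    )


def permutation_importance(model: TrainedFNN, features: np.ndarray, labels,
                           n_repeats: int = 10, seed: int = 0
                           ) -> pd.DataFrame:
    """Permutation feature importance of a no-memory model.

    Importance of feature j is the mean drop in accuracy over
    ``n_repeats`` seeded shufflings of column j (holding all other
    columns fixed). ``share`` normalizes the positive importances to
    fractions of their total.
    """
    if model.memory_mode:
        raise InvalidInputError("permutation importance uses the no-memory model")
    if n_repeats < 1:
        raise InvalidInputError("n_repeats must be >= 1")
    features = np.asarray(features, dtype=float)
    labels = np.asarray(list(labels))
    rng = np.random.default_rng(seed)
    base_pred = np.array(model.stage_order)[
        predict_proba(model, features).argmax(axis=1)]
    base_acc = float((base_pred == labels).mean())
    n_feat = features.shape[1]
    drops = np.empty((n_feat, n_repeats))
    for j in range(n_feat):
        for r in range(n_repeats):
            x = features.copy()
            x[:, j] = rng.permutation(x[:, j])
            pred = np.array(model.stage_order)[
                predict_proba(model, x).argmax(axis=1)]
            drops[j, r] = base_acc - (pred == labels).mean()
    mean_drop = drops.mean(axis=1)
    sd = drops.std(axis=1, ddof=1) if n_repeats > 1 else np.zeros(n_feat)
    positive = np.clip(mean_drop, 0, None)
    shares = positive / positive.sum() if positive.sum() > 0 else positive
    names = list(FEATURE_NAMES) if n_feat == len(FEATURE_NAMES) else [
        f"feature_{j}" for j in range(n_feat)]
    return pd.DataFrame({
        "feature": names,
        "importance": mean_drop,
        "importance_sd": sd,
        "share": shares,
    }).sort_values("importance", ascending=False, ignore_index=True)
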