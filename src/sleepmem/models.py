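"""The paired feedforward classifiers (no-memory and memory-augmented).

Both models share one architecture: input -> dense 128 -> 64 -> 32 (ReLU)
-> softmax over the K = 5 stages, trained with Adam (learning rate
0.001) on cross-entropy loss with early stopping (patience 10 epochs on
a held-out validation fraction, best weights restored). The no-memory
model sees the scaled 37-feature vector of the current epoch only; the
memory model additionally receives the K-dimensional transition vector
v_t = p_{t-1} . T.

Training uses teacher forcing: v_t is computed from the one-hot true
label of the previous epoch (wake prior for each subject's first epoch).
At test time prediction is strictly causal and self-fed: v_t comes from
the model's own softmax output at t-1, mirroring deployment where no
labels exist. Feature scaling is fit on training subjects only; the
transition-vector inputs are probabilities already in [0, 1] and bypass
the scaler by default.

The networks are scikit-learn ``MLPClassifier`` instances, which provide
exactly this regime; everything around them (scaling policy, memory
input assembly, causal decoding, class-alignment of softmax outputs) is
this module's surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .errors import InvalidInputError
from .stages import STAGES
from .temporal import TransitionMatrix, initial_distribution, transition_vector

logger = logging.getLogger(__name__)

__all__ = [
    "FNNConfig",
    "TrainedFNN",
    "fit_scaler",
    "train_model",
    "assemble_memory_inputs_train",
    "predict_proba",
    "sequential_predict_memory",
]


@dataclass(frozen=True)
class FNNConfig:
    """Architecture and training hyperparameters."""

    hidden_sizes: tuple[int, ...] = (128, 64, 32)
    activation: str = "relu"
    n_classes: int = 5
    learning_rate: float = 0.001
    patience: int = 10
    max_epochs: int = 100
    batch_size: int = 128
    val_fraction: float = 0.1
    seed: int = 0
    scale_memory_inputs: bool = False

    def __post_init__(self):
        if not self.hidden_sizes:
            raise InvalidInputError("hidden_sizes must be non-empty")
        if not 0 < self.val_fraction < 0.5:
            raise InvalidInputError("val_fraction must lie in (0, 0.5)")


@dataclass
class TrainedFNN:
    """A fitted network plus everything needed to apply it."""

    net: MLPClassifier
    scaler: StandardScaler
    stage_order: tuple[str, ...]
    memory_mode: bool
    config: FNNConfig

    @property
    def k(self) -> int:
        return len(self.stage_order)


def fit_scaler(features: np.ndarray) -> StandardScaler:
    """Per-column standardizer fitted on training rows only.

    Zero-dispersion columns keep scale 1 (the scaler's convention) so
    transformed values are finite; a warning notes which columns.
    """
    features = np.asarray(features, dtype=float)
    if features.shape[0] < 2:
        raise InvalidInputError("scaler needs >= 2 training rows")
    scaler = StandardScaler().fit(features)
    zero = np.flatnonzero(scaler.var_ == 0)
    if zero.size:
        logger.warning("zero-dispersion feature columns %s; SD treated as 1",
                       zero.tolist())
    return scaler


def assemble_memory_inputs_train(labels, T: TransitionMatrix) -> np.ndarray:
    """Teacher-forced transition vectors for one subject's epochs.

    Row t is onehot(label_{t-1}) . T for t >= 1; row 0 uses the wake
    prior. Rows must come from a single subject - never concatenate
    subjects before calling this.
    """
    labels = list(labels)
    rows = np.empty((len(labels), T.k))
    rows[0] = transition_vector(initial_distribution(T.stages), T)
    for t in range(1, len(labels)):
        onehot = np.zeros(T.k)
        onehot[T.stages.index(labels[t - 1])] = 1.0
        rows[t] = transition_vector(onehot, T)
    return rows


def _encode_labels(labels, stage_order) -> np.ndarray:
    index = {s: i for i, s in enumerate(stage_order)}
    return np.fromiter((index[l] for l in labels), dtype=int, count=len(labels))


def _model_inputs(model_or_cfg, scaler, features, memory_inputs):
    features = scaler.transform(np.asarray(features, dtype=float))
    if memory_inputs is None:
        return features
    memory_inputs = np.asarray(memory_inputs, dtype=float)
    if memory_inputs.shape[0] != features.shape[0]:
        raise InvalidInputError("memory inputs must align row-wise with features")
    return np.hstack([features, memory_inputs])


def train_model(features: np.ndarray, labels, config: FNNConfig | None = None,
                memory_inputs: np.ndarray | None = None,
                stage_order=STAGES,
                scaler: StandardScaler | None = None) -> TrainedFNN:
    """Fit one classifier (no-memory if ``memory_inputs`` is None).

    A pre-fitted scaler may be passed (e.g. one shared between the two
    model variants of a fold); otherwise one is fitted on ``features``.
    Deterministic under a fixed ``config.seed``.
    """
    config = config or FNNConfig()
    features = np.asarray(features, dtype=float)
    labels = list(labels)
    if features.shape[0] != len(labels):
        raise InvalidInputError("features and labels must align row-wise")
    missing = set(stage_order) - set(labels)
    if missing:
        logger.warning("classes absent from training labels: %s", sorted(missing))
    if scaler is None:
        scaler = fit_scaler(features)
    # the stratified early-stopping split needs >= 2 rows per class;
    # singleton stages are dropped (the model can still emit them)
    singletons = {s for s in set(labels) if labels.count(s) < 2}
    if singletons:
        logger.warning("dropping singleton training classes: %s",
                       sorted(singletons))
        keep = [i for i, l in enumerate(labels) if l not in singletons]
        features = features[keep]
        labels = [labels[i] for i in keep]
        if memory_inputs is not None:
            memory_inputs = np.asarray(memory_inputs)[keep]
    if memory_inputs is not None and config.scale_memory_inputs:
        mem_scaler = fit_scaler(memory_inputs)
        memory_inputs = mem_scaler.transform(memory_inputs)
    x = _model_inputs(config, scaler, features, memory_inputs)
    y = _encode_labels(labels, stage_order)
    net = MLPClassifier(
        hidden_layer_sizes=tuple(config.hidden_sizes),
        activation=config.activation,
        solver="adam",
        alpha=0.0,
        batch_size=min(config.batch_size, x.shape[0]),
        learning_rate_init=config.learning_rate,
        max_iter=config.max_epochs,
        shuffle=True,
        random_state=config.seed,
        early_stopping=True,
        validation_fraction=config.val_fraction,
        n_iter_no_change=config.patience,
    )
    net.fit(x, y)
    return TrainedFNN(net=net, scaler=scaler, stage_order=tuple(stage_order),
                      memory_mode=memory_inputs is not None, config=config)


def _aligned_proba(model: TrainedFNN, x: np.ndarray) -> np.ndarray:
    """Softmax outputs aligned to the full stage order (absent classes 0)."""
    raw = model.net.predict_proba(x)
    out = np.zeros((x.shape[0], model.k))
    out[:, model.net.classes_.astype(int)] = raw
    return out


def predict_proba(model: TrainedFNN, features: np.ndarray,
                  memory_inputs: np.ndarray | None = None) -> np.ndarray:
    """Per-epoch softmax distributions, one row per input epoch."""
    if model.memory_mode and memory_inputs is None:
        raise InvalidInputError("memory-mode model requires memory inputs")
    if not model.memory_mode and memory_inputs is not None:
        raise InvalidInputError("no-memory model accepts no memory inputs")
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[1] != model.scaler.n_features_in_:
        raise InvalidInputError(
            f"feature width {features.shape[1]}, scaler expects "
            f"{model.scaler.n_features_in_}")
    x = _model_inputs(model, model.scaler, features, memory_inputs)
    expected = model.net.n_features_in_
    if x.shape[1] != expected:
        raise InvalidInputError(f"input width {x.shape[1]}, model expects {expected}")
    return _aligned_proba(model, x)


def sequential_predict_memory(model: TrainedFNN, features: np.ndarray,
                              T: TransitionMatrix) -> np.ndarray:
    """Causal self-fed prediction over one subject's time-ordered epochs.

    v_t is built from the model's own previous softmax output (wake
    prior at t = 0); the output at epoch t depends only on epochs <= t.
    """
    if not model.memory_mode:
        raise InvalidInputError("sequential decoding requires a memory-mode model")
    features = model.scaler.transform(np.asarray(features, dtype=float))
    n = features.shape[0]
    out = np.empty((n, model.k))
    p_prev = initial_distribution(model.stage_order)
    for t in range(n):
        v = transition_vector(p_prev, T)
        x = np.hstack([features[t], v])[None, :]
        out[t] = _aligned_proba(model, x)[0]
        p_prev = out[t]
    return out
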