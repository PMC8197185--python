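"""Sequence-to-label gait classification.

Two classifiers share this module:

* the LSTM sequence classifier — variable-length envelope sequences are
  zero-padded per mini-batch to the batch maximum length (no masking by
  default), pushed through a single LSTM layer, a fully connected layer and a
  softmax, and trained with Adam under a step learning-rate decay; and

* the velocity-parameter SVM baseline — twelve summary statistics of the
  three envelopes (mean, standard deviation, max, min of each) feed an
  RBF-kernel support vector machine.  The exact parameter set of the earlier
  velocity-parameter literature is not fully enumerated anywhere, so this
  concrete twelve-feature set is a clearly labelled stand-in.

Default hyper-parameters (400 hidden cells, batch 128, initial learning rate
1e-4, x0.9 decay every 30 epochs) are the reference operating point for
cohort-scale data; the test suite uses a documented reduced scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import GridSearchCV
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .envelopes import EnvelopeSet
from .lstm import SequenceLSTM, cross_entropy, softmax

logger = logging.getLogger(__name__)

#: Fixed label ordering; ties in the softmax break toward the first class.
CLASSES = ("young", "elderly")


@dataclass
class LabeledSequence:
    """A multichannel velocity sequence with an optional class label.

    ``channels`` is (n_channels, n_frames) with 1-3 channels of velocities
    in m/s.
    """

    channels: np.ndarray
    label: str | None = None
    id: str = ""

    def __post_init__(self) -> None:
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        if not 1 <= self.channels.shape[0] <= 3:
            raise ValueError(
                f"expected 1-3 channels, got {self.channels.shape[0]}"
            )
        if self.channels.shape[1] < 1:
            raise ValueError("sequence length must be >= 1")
        if self.label is not None and self.label not in CLASSES:
            raise ValueError(f"label must be one of {CLASSES}, got {self.label!r}")

    @property
    def length(self) -> int:
        return self.channels.shape[1]

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]


@dataclass
class LSTMConfig:
    """Training hyper-parameters of the LSTM classifier.

    The learning rate is ``initial_lr * lr_decay ** (epoch // decay_every)``.
    ``grad_clip`` bounds the global gradient norm per update (LSTM training
    intermittently explodes without it).  ``sort_batches`` groups sequences
    of similar length into the same mini-batch each epoch, keeping the
    per-batch zero padding small.  ``masking`` switches the
    classification read-out from the last padded
    step (the default, matching plain right-zero-padding) to each sequence's
    own final step.  ``standardize`` z-scores each channel with training-set
    statistics; ``class_weighting`` reweights the loss inversely to class
    frequency.  All three default off.
    """

    hidden_units: int = 400
    batch_size: int = 128
    initial_lr: float = 1e-4
    lr_decay: float = 0.9
    decay_every: int = 30
    max_epochs: int = 150
    rng_seed: int = 0
    grad_clip: float = 1.0
    sort_batches: bool = True
    masking: bool = False
    standardize: bool = False
    class_weighting: bool = False

    def __post_init__(self) -> None:
        if self.hidden_units <= 0:
            raise ValueError("hidden_units must be positive")
        if not 0 < self.lr_decay <= 1:
            raise ValueError("lr_decay must be in (0, 1]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def lr_at(self, epoch: int) -> float:
        return self.initial_lr * self.lr_decay ** (epoch // self.decay_every)


@dataclass
class TrainedModel:
    """A trained LSTM classifier with its config snapshot and training log."""

    network: SequenceLSTM
    config: LSTMConfig
    n_channels: int
    classes: tuple = CLASSES
    training_log: list = field(default_factory=list)  # per-epoch mean loss
    channel_mean: np.ndarray | None = None
    channel_sd: np.ndarray | None = None


def _pad_batch(sequences) -> tuple[np.ndarray, np.ndarray]:
    """Right-zero-pad a list of sequences to the batch maximum length."""
    lengths = np.array([s.length for s in sequences])
    B, T = len(sequences), int(lengths.max())
    C = sequences[0].n_channels
    X = np.zeros((B, T, C))
    for k, s in enumerate(sequences):
        X[k, : s.length] = s.channels.T
    return X, lengths


def train_lstm(train, config: LSTMConfig | None = None) -> TrainedModel:
    """Train the LSTM sequence classifier.

    Parameters
    ----------
    train : sequence of LabeledSequence
        At least two sequences with both classes present and a common
        channel count.
    config : LSTMConfig, optional

    Returns
    -------
    TrainedModel with the per-epoch mean cross-entropy in ``training_log``.
    Fully reproducible under a fixed ``config.rng_seed``.
    """
    config = config or LSTMConfig()
    train = list(train)
    if len(train) < 2:
        raise ValueError("need at least two training sequences")
    channel_counts = {s.n_channels for s in train}
    if len(channel_counts) != 1:
        raise ValueError(f"mixed channel counts in training set: {sorted(channel_counts)}")
    labels_present = {s.label for s in train}
    if None in labels_present or len(labels_present) < 2:
        raise ValueError("training set must contain labelled sequences of both classes")
    n_channels = channel_counts.pop()

    targets = np.array([CLASSES.index(s.label) for s in train])
    if config.class_weighting:
        counts = np.bincount(targets, minlength=len(CLASSES))
        class_w = len(targets) / (len(CLASSES) * counts)
    else:
        class_w = np.ones(len(CLASSES))

    mean = sd = None
    if config.standardize:
        stacked = np.hstack([s.channels for s in train])
        mean = stacked.mean(axis=1)
        sd = stacked.std(axis=1)
        sd[sd == 0] = 1.0
        train = [
            replace(s, channels=(s.channels - mean[:, None]) / sd[:, None])
            for s in train
        ]

    rng = np.random.default_rng(config.rng_seed)
    net = SequenceLSTM(n_channels, config.hidden_units, len(CLASSES),
                       rng_seed=config.rng_seed)
    log = []
    n = len(train)
    lengths_all = np.array([s.length for s in train])
    for epoch in range(config.max_epochs):
        lr = config.lr_at(epoch)
        order = rng.permutation(n)
        if config.sort_batches:
            # group similar lengths so per-batch padding stays small (the
            # read-out sits at the last padded step when masking is off)
            order = order[np.argsort(lengths_all[order], kind="stable")]
        batch_starts = np.arange(0, n, config.batch_size)
        rng.shuffle(batch_starts)
        losses = []
        for start in batch_starts:
            idx = order[start : start + config.batch_size]
            batch = [train[i] for i in idx]
            X, lengths = _pad_batch(batch)
            logits, cache = net.forward(X, lengths if config.masking else None)
            loss, dlogits = cross_entropy(logits, targets[idx],
                                          sample_weights=class_w[targets[idx]])
            grads = net.backward(dlogits, cache)
            if config.grad_clip:
                grads = net.clip_gradients(grads, config.grad_clip)
            net.adam_step(grads, lr)
            losses.append(loss)
        log.append(float(np.mean(losses)))
    return TrainedModel(
        network=net, config=config, n_channels=n_channels,
        training_log=log, channel_mean=mean, channel_sd=sd,
    )


def predict(model: TrainedModel, seq: LabeledSequence):
    """Classify one sequence; returns ``(label, probabilities)``.

    Inference is per-sequence and unpadded, so the prediction cannot depend
    on how sequences were batched.  Softmax ties break toward the first
    class in the fixed ordering.
    """
    if seq.n_channels != model.n_channels:
        raise ValueError(
            f"sequence has {seq.n_channels} channels but the model was trained "
            f"with {model.n_channels}"
        )
    channels = seq.channels
    if model.channel_mean is not None:
        channels = (channels - model.channel_mean[:, None]) / model.channel_sd[:, None]
    X = channels.T[None]  # (1, T, C)
    logits, _ = model.network.forward(X)
    probs = softmax(logits.astype(np.float64))[0]
    return model.classes[int(np.argmax(probs))], probs


def velocity_parameters(env: EnvelopeSet) -> np.ndarray:
    """Summary velocity parameters of the three envelopes (baseline features).

    Twelve features in fixed order: mean, population standard deviation,
    max, min — of v_u, then v_m, then v_l.  This concrete set stands in for
    the velocity parameters of the earlier SVM-based approach, whose exact
    feature list is not enumerated.
    """
    if env.n_frames == 0:
        raise ValueError("empty envelope set")
    features = []
    for name in ("v_u", "v_m", "v_l"):
        series = getattr(env, name)
        if np.any(~np.isfinite(series)):
            raise ValueError(f"{name} contains undefined frames; cannot build features")
        features += [series.mean(), series.std(), series.max(), series.min()]
    return np.array(features)


VELOCITY_PARAMETER_NAMES = tuple(
    f"{env}_{stat}" for env in ("v_u", "v_m", "v_l")
    for stat in ("mean", "sd", "max", "min")
)


@dataclass
class SVMBaselineModel:
    """The velocity-parameter SVM baseline: scaler + RBF-SVC pipeline."""

    pipeline: Pipeline
    kept_features: np.ndarray
    classes: tuple = CLASSES
    best_params: dict = field(default_factory=dict)

    def predict(self, features: np.ndarray):
        features = np.atleast_2d(features)[:, self.kept_features]
        return self.pipeline.predict(features)


def train_svm_baseline(features, labels, rng_seed: int = 0,
                       cv: int = 3) -> SVMBaselineModel:
    """Train the RBF-kernel SVM on velocity-parameter features.

    Features are standardized with training-set statistics; ``C`` and
    ``gamma`` are chosen by an internal cross-validated grid search (logged).
    Zero-variance features are dropped with a warning.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D (n_samples, n_features) array")
    unique, counts = np.unique(y, return_counts=True)
    if len(unique) < 2:
        raise ValueError("need samples of both classes to train the baseline")
    if counts.min() < 2:
        raise ValueError("need at least two samples per class")

    variances = X.var(axis=0)
    kept = np.flatnonzero(variances > 0)
    if kept.size < X.shape[1]:
        warnings.warn(
            f"dropping {X.shape[1] - kept.size} zero-variance feature(s)",
            stacklevel=2,
        )
    X = X[:, kept]

    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svc", SVC(kernel="rbf", random_state=rng_seed)),
    ])
    grid = {
        "svc__C": [0.1, 1.0, 10.0, 100.0],
        "svc__gamma": ["scale", 0.01, 0.1, 1.0],
    }
    n_folds = min(cv, int(counts.min()))
    if n_folds >= 2:
        search = GridSearchCV(pipe, grid, cv=n_folds, n_jobs=1)
        search.fit(X, y)
        best, best_params = search.best_estimator_, search.best_params_
        logger.info("SVM grid search selected %s", best_params)
    else:
        pipe.fit(X, y)
        best, best_params = pipe, {}
    return SVMBaselineModel(pipeline=best, kept_features=kept, best_params=best_params)
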