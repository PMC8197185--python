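"""Hold-out evaluation protocol for the gait classifiers.

The dataset is split at random into 70% training and 30% test data
(stratified by class by default), the classifier is trained from scratch and
scored on the held-out part, and the whole procedure is repeated over
independent trials (30 in the reference protocol) whose accuracies are
averaged.  Confusion matrices pool the test predictions of all trials and
are row-normalized with rows = predicted class.

When several input conditions are compared, every condition reuses the same
per-trial split seeds, so trial *k* sees identical train/test partitions
across conditions (a paired comparison that removes split-to-split variance
from the between-condition contrast).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from sklearn.model_selection import train_test_split

from .classify import (
    CLASSES,
    LabeledSequence,
    LSTMConfig,
    predict,
    train_lstm,
    train_svm_baseline,
    velocity_parameters,
)
from .envelopes import CONDITION_CHANNELS, EnvelopeSet, build_condition_input, extract_envelopes
from .spectrogram import compute_spectrogram, select_analysis_interval

SVM_BASELINE = "svm_baseline"


@dataclass
class EnvelopeRecord:
    """One trial's extracted envelopes with its class label and identifier."""

    env: EnvelopeSet
    label: str
    id: str = ""


def extract_envelope_dataset(
    dataset,
    window_len: int = 128,
    hop: int = 8,
    rho: float = 0.2,
    n_cycles: int = 2,
) -> list:
    """Run the spectrogram + interval-selection + envelope pipeline on a
    simulated dataset, returning one :class:`EnvelopeRecord` per trial."""
    from .radar_model import RadarConfig

    radar = RadarConfig(
        f0=dataset.config["radar"]["f0"], fs=dataset.config["radar"]["fs"]
    )
    records = []
    for rec in dataset:
        spec = compute_spectrogram(rec.signal, window_len=window_len, hop=hop, config=radar)
        spec = select_analysis_interval(spec, n_cycles=n_cycles)
        env = extract_envelopes(spec, rho=rho)
        records.append(EnvelopeRecord(env=env, label=rec.label, id=rec.id))
    return records


def sequences_for_condition(records, condition: int) -> list:
    """Turn envelope records into labelled classifier inputs for a condition."""
    return [
        LabeledSequence(
            channels=build_condition_input(r.env, condition), label=r.label, id=r.id
        )
        for r in records
    ]


def holdout_split(dataset, ratio: float = 0.7, stratified: bool = True,
                  rng_seed: int = 0):
    """Random disjoint, exhaustive train/test split.

    ``ratio`` is the training fraction; the training size is
    ``round(ratio * n)`` exactly (so 300 items at 7:3 give 210 and 90).
    ``stratified`` preserves the class proportions in both parts; items must
    expose a ``.label`` attribute for stratification.
    """
    items = list(dataset)
    n = len(items)
    if n < 2:
        raise ValueError("dataset must contain at least two items")
    if not 0 < ratio < 1:
        raise ValueError(f"train fraction must be in (0, 1), got {ratio}")
    n_train = int(round(ratio * n))
    labels = [getattr(item, "label", None) for item in items]
    train_idx, test_idx = train_test_split(
        np.arange(n),
        train_size=n_train,
        random_state=rng_seed % (2**32),
        stratify=labels if stratified else None,
        shuffle=True,
    )
    return [items[i] for i in train_idx], [items[i] for i in test_idx]


@dataclass
class EvalReport:
    """Result of repeated hold-out evaluation of one input condition.

    ``confusion`` is row-normalized percentages with rows = predicted class
    and columns = true class, in the order (young, elderly), pooled over all
    trials; ``confusion_counts`` holds the raw pooled counts.
    """

    condition: object
    per_trial_accuracy: list
    confusion_counts: np.ndarray
    n_trials: int
    split_ratio: tuple
    seeds: list
    trial_test_ids: list = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_trial_accuracy))

    @property
    def confusion(self) -> np.ndarray:
        """Row-normalized confusion percentages (rows sum to 100)."""
        counts = np.asarray(self.confusion_counts, dtype=float)
        row_sums = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * counts / row_sums

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "mean_accuracy": self.mean_accuracy,
            "per_trial_accuracy": list(map(float, self.per_trial_accuracy)),
            "confusion_percent_rows_predicted": self.confusion.tolist(),
            "confusion_counts": np.asarray(self.confusion_counts).tolist(),
            "n_trials": self.n_trials,
            "split_ratio": list(self.split_ratio),
            "seeds": list(map(int, self.seeds)),
            "classes": list(CLASSES),
            "trial_test_ids": self.trial_test_ids,
        }

    def to_text(self) -> str:
        lines = [
            f"condition {self.condition}: mean accuracy "
            f"{100 * self.mean_accuracy:.1f}% over {self.n_trials} trial(s)",
            "confusion (rows = predicted, cols = true, %):",
            f"            {CLASSES[0]:>8} {CLASSES[1]:>8}",
        ]
        conf = self.confusion
        for i, cls in enumerate(CLASSES):
            lines.append(f"  {cls:>9} {conf[i, 0]:8.1f} {conf[i, 1]:8.1f}")
        return "\n".join(lines)


def _trial_seeds(master_seed: int, n_trials: int) -> np.ndarray:
    return np.random.SeedSequence(master_seed).generate_state(n_trials) % (2**31)


def _condition_label(condition) -> str:
    if condition == SVM_BASELINE:
        return SVM_BASELINE
    if condition in CONDITION_CHANNELS:
        return f"condition {condition}"
    raise ValueError(
        f"condition must be 1..7 or {SVM_BASELINE!r}, got {condition!r}"
    )


def evaluate_condition(
    records,
    condition,
    n_trials: int = 30,
    config: LSTMConfig | None = None,
    master_seed: int = 0,
    ratio: float = 0.7,
    stratified: bool = True,
    split_seeds=None,
) -> EvalReport:
    """Repeated hold-out evaluation of one input condition.

    ``records`` are :class:`EnvelopeRecord` items; ``condition`` is an
    integer 1..7 (LSTM input combination) or ``"svm_baseline"``.  Each trial
    draws an independent split and retrains the classifier from scratch; all
    per-trial seeds, accuracies and test identifiers are kept in the report
    so any cell is re-derivable.
    """
    _condition_label(condition)
    config = config or LSTMConfig()
    records = list(records)
    if not records:
        raise ValueError("empty dataset")
    if len({r.label for r in records}) < 2:
        raise ValueError("dataset must contain both classes")
    if split_seeds is None:
        split_seeds = _trial_seeds(master_seed, n_trials)
    split_seeds = list(split_seeds)[:n_trials]

    accuracies = []
    counts = np.zeros((2, 2), dtype=int)
    test_ids = []
    for seed in split_seeds:
        train_recs, test_recs = holdout_split(
            records, ratio=ratio, stratified=stratified, rng_seed=int(seed)
        )
        true = [r.label for r in test_recs]
        if condition == SVM_BASELINE:
            X_train = np.vstack([velocity_parameters(r.env) for r in train_recs])
            y_train = np.array([r.label for r in train_recs])
            model = train_svm_baseline(X_train, y_train, rng_seed=int(seed))
            X_test = np.vstack([velocity_parameters(r.env) for r in test_recs])
            pred = list(model.predict(X_test))
        else:
            train_seqs = sequences_for_condition(train_recs, condition)
            test_seqs = sequences_for_condition(test_recs, condition)
            model = train_lstm(train_seqs, dc_replace(config, rng_seed=int(seed)))
            pred = [predict(model, s)[0] for s in test_seqs]
        accuracies.append(float(np.mean(np.array(pred) == np.array(true))))
        for p, t in zip(pred, true):
            counts[CLASSES.index(p), CLASSES.index(t)] += 1
        test_ids.append([r.id for r in test_recs])
    return EvalReport(
        condition=condition,
        per_trial_accuracy=accuracies,
        confusion_counts=counts,
        n_trials=len(split_seeds),
        split_ratio=(ratio, 1 - ratio),
        seeds=[int(s) for s in split_seeds],
        trial_test_ids=test_ids,
    )


def compare_conditions(
    records,
    conditions,
    n_trials: int = 30,
    config: LSTMConfig | None = None,
    master_seed: int = 0,
    ratio: float = 0.7,
    stratified: bool = True,
) -> dict:
    """Evaluate several input conditions with paired split seeds.

    Every condition sees identical trial-k train/test partitions, making the
    between-condition accuracy differences a paired comparison.  Returns a
    dict mapping condition to :class:`EvalReport`.
    """
    seeds = _trial_seeds(master_seed, n_trials)
    return {
        cond: evaluate_condition(
            records, cond, n_trials=n_trials, config=config,
            ratio=ratio, stratified=stratified, split_seeds=seeds,
        )
        for cond in conditions
    }


def render_table(reports: dict) -> str:
    """Render a per-condition accuracy table from compare_conditions output."""
    lines = ["Condition            Mean accuracy"]
    for cond, report in reports.items():
        lines.append(f"{_condition_label(cond):<20} {100 * report.mean_accuracy:6.1f}%")
    return "\n".join(lines)


def write_report(reports, path) -> None:
    """Write one report or a dict of reports as machine-readable JSON."""
    if isinstance(reports, EvalReport):
        payload = reports.to_dict()
    else:
        payload = {str(cond): rep.to_dict() for cond, rep in reports.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
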