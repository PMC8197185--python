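"""LSTM sequence classifier and velocity-parameter SVM baseline."""

import numpy as np
import pytest

import gaitdoppler as gd
from gaitdoppler.classify import LabeledSequence, LSTMConfig

#: Reduced-scale training configuration used throughout the test suite; the
#: reference operating point (400 hidden cells, 150 epochs) behaves the same
#: but takes far longer on small hardware.
TEST_CONFIG = dict(hidden_units=24, batch_size=32, initial_lr=1e-3,
                   max_epochs=30, decay_every=30)


def toy_sequences(n_per_class, rng, means=(1.3, 0.9), sd=0.05, lengths=(30, 60)):
    """Two classes of noisy constant sequences with distinct channel means."""
    seqs = []
    for label, mu in zip(gd.CLASSES, means):
        for i in range(n_per_class):
            T = int(rng.integers(*lengths))
            seqs.append(
                LabeledSequence(rng.normal(mu, sd, size=(1, T)), label, f"{label}{i}")
            )
    return seqs


class TestLabeledSequence:
    def test_channel_count_bounds(self):
        with pytest.raises(ValueError, match="1-3 channels"):
            LabeledSequence(np.zeros((4, 10)))

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            LabeledSequence(np.zeros((1, 0)))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="label"):
            LabeledSequence(np.zeros((1, 5)), label="middle-aged")


class TestLSTMConfigValidation:
    def test_bad_values_rejected(self):
        with pytest.raises(ValueError):
            LSTMConfig(hidden_units=0)
        with pytest.raises(ValueError):
            LSTMConfig(lr_decay=1.5)
        with pytest.raises(ValueError):
            LSTMConfig(batch_size=0)

    def test_learning_rate_schedule(self):
        cfg = LSTMConfig(initial_lr=1e-4, lr_decay=0.9, decay_every=30)
        assert cfg.lr_at(0) == 1e-4
        assert cfg.lr_at(29) == 1e-4
        assert cfg.lr_at(30) == pytest.approx(0.9e-4)
        assert cfg.lr_at(60) == pytest.approx(0.81e-4)


class TestTrainLSTM:
    def test_guards(self):
        rng = np.random.default_rng(0)
        seqs = toy_sequences(5, rng)
        with pytest.raises(ValueError, match="both classes"):
            gd.train_lstm([s for s in seqs if s.label == "young"])
        with pytest.raises(ValueError, match="at least two"):
            gd.train_lstm(seqs[:1])
        mixed = seqs[:4] + [LabeledSequence(np.zeros((2, 10)), "elderly")]
        with pytest.raises(ValueError, match="channel counts"):
            gd.train_lstm(mixed)

    def test_separable_classes_learned(self):
        accs = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            seqs = toy_sequences(30, rng)
            train, test = gd.holdout_split(seqs, rng_seed=seed)
            model = gd.train_lstm(train, LSTMConfig(rng_seed=seed, **TEST_CONFIG))
            accs.append(np.mean([gd.predict(model, s)[0] == s.label for s in test]))
        assert np.mean(accs) >= 0.95

    def test_permuted_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(3)
        seqs = toy_sequences(30, rng)
        labels = [s.label for s in seqs]
        rng.shuffle(labels)
        shuffled = [
            LabeledSequence(s.channels, label, s.id) for s, label in zip(seqs, labels)
        ]
        train, test = gd.holdout_split(shuffled, rng_seed=3, stratified=False)
        model = gd.train_lstm(train, LSTMConfig(rng_seed=3, **TEST_CONFIG))
        acc = np.mean([gd.predict(model, s)[0] == s.label for s in test])
        se = np.sqrt(0.25 / len(test))
        assert abs(acc - 0.5) <= 3 * se

    def test_training_is_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(4)
        seqs = toy_sequences(10, rng, lengths=(20, 30))
        cfg = LSTMConfig(rng_seed=9, hidden_units=12, max_epochs=5, batch_size=8)
        a = gd.train_lstm(seqs, cfg)
        b = gd.train_lstm(seqs, cfg)
        assert a.training_log == b.training_log
        for key in a.network.params:
            assert np.array_equal(a.network.params[key], b.network.params[key])

    def test_loss_decreases_over_first_decay_period(self):
        rng = np.random.default_rng(5)
        seqs = toy_sequences(20, rng)
        cfg = LSTMConfig(rng_seed=5, hidden_units=24, batch_size=32,
                         initial_lr=1e-3, max_epochs=20, decay_every=20)
        model = gd.train_lstm(seqs, cfg)
        assert model.training_log[-1] < model.training_log[0]


class TestPredict:
    @pytest.fixture(scope="class")
    @staticmethod
    def model_and_data():
        rng = np.random.default_rng(6)
        seqs = toy_sequences(20, rng)
        model = gd.train_lstm(seqs, LSTMConfig(rng_seed=6, **TEST_CONFIG))
        return model, seqs

    def test_probabilities_sum_to_one(self, model_and_data):
        model, seqs = model_and_data
        _, probs = gd.predict(model, seqs[0])
        assert probs.shape == (2,)
        assert np.all(probs >= 0)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_training_sequences_get_their_own_label(self, model_and_data):
        model, seqs = model_and_data
        acc = np.mean([gd.predict(model, s)[0] == s.label for s in seqs])
        assert acc >= 0.95

    def test_channel_mismatch_rejected(self, model_and_data):
        model, _ = model_and_data
        with pytest.raises(ValueError, match="channels"):
            gd.predict(model, LabeledSequence(np.zeros((2, 10))))

    def test_prediction_independent_of_other_calls(self, model_and_data):
        """Inference is per-sequence and unpadded: the result for one
        sequence cannot depend on what else was classified around it."""
        model, seqs = model_and_data
        _, before = gd.predict(model, seqs[0])
        for other in seqs[1:5]:
            gd.predict(model, other)
        _, after = gd.predict(model, seqs[0])
        assert np.array_equal(before, after)


class TestVelocityParameters:
    @staticmethod
    def env_from(v_u, v_m, v_l):
        n = len(v_u)
        return gd.EnvelopeSet(
            frame_times=np.arange(n, dtype=float),
            v_u=np.asarray(v_u, dtype=float),
            v_m=np.asarray(v_m, dtype=float),
            v_l=np.asarray(v_l, dtype=float),
        )

    def test_constant_envelopes(self):
        env = self.env_from([1.0] * 4, [1.0] * 4, [1.0] * 4)
        f = gd.velocity_parameters(env)
        assert f.shape == (12,)
        assert np.allclose(f, [1.0, 0.0, 1.0, 1.0] * 3)

    def test_population_sd_convention(self):
        env = self.env_from([3, 3, 3], [2, 2, 2], [0, 1, 2])
        f = gd.velocity_parameters(env)
        # v_l block: mean, sd, max, min
        assert f[8] == pytest.approx(1.0)
        assert f[9] == pytest.approx(np.sqrt(2.0 / 3.0))  # ~0.8165, divide by n
        assert f[10] == 2.0 and f[11] == 0.0

    def test_undefined_frames_rejected(self):
        env = self.env_from([1.0, 1.0], [np.nan, 1.0], [0.0, 0.0])
        with pytest.raises(ValueError, match="undefined"):
            gd.velocity_parameters(env)


class TestSVMBaseline:
    def test_linearly_separable_training_accuracy(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(0, 0.1, (20, 2)), rng.normal(3, 0.1, (20, 2))])
        y = np.array(["young"] * 20 + ["elderly"] * 20)
        model = gd.train_svm_baseline(X, y, rng_seed=0)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_heldout_accuracy_beats_majority(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(0, 0.5, (40, 3)), rng.normal(1.5, 0.5, (60, 3))])
        y = np.array(["young"] * 40 + ["elderly"] * 60)
        idx = rng.permutation(100)
        train, test = idx[:70], idx[70:]
        model = gd.train_svm_baseline(X[train], y[train], rng_seed=1)
        acc = np.mean(model.predict(X[test]) == y[test])
        assert acc > np.mean(y[test] == "elderly")

    def test_single_class_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError, match="both classes"):
            gd.train_svm_baseline(X, np.array(["young"] * 5))

    def test_zero_variance_feature_dropped_with_warning(self):
        rng = np.random.default_rng(9)
        X = np.column_stack([rng.normal(size=20), np.full(20, 7.0)])
        X[10:, 0] += 3
        y = np.array(["young"] * 10 + ["elderly"] * 10)
        with pytest.warns(UserWarning, match="zero-variance"):
            model = gd.train_svm_baseline(X, y, rng_seed=2)
        assert list(model.kept_features) == [0]
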