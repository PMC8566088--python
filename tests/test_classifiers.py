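import numpy as np
import pytest

from gaitmark.classifiers import (
    ClassifierSpec,
    DEFAULT_HYPERPARAMS,
    ShapeAuditError,
    _CnnNet,
    _LstmNet,
    _softmax,
    load_model,
    predict,
    save_model,
    train,
)
from gaitmark.preprocess import STANCE, SWING, LabeledWindow


def _gaussian_windows(rng, n_per_class, n_classes=2, sep=6.0,
                      phase=STANCE):
    windows = []
    for label in range(1, n_classes + 1):
        mean = np.zeros((30, 10))
        mean[:, label % 10] = sep * label
        for _ in range(n_per_class):
            windows.append(LabeledWindow(
                features=mean + rng.normal(size=(30, 10)),
                label=label, phase=phase))
    return windows


class TestTrainPredict:
    @pytest.mark.parametrize("kind", ["QDA", "SVM", "CNN", "LSTM"])
    def test_separable_classes_reach_perfect_training_accuracy(self, rng,
                                                               kind):
        windows = _gaussian_windows(rng, 40)
        model = train(ClassifierSpec(kind, seed=0), windows)
        pred = predict(model, windows)
        assert np.mean(pred == [w.label for w in windows]) == 1.0

    def test_prediction_length_and_order(self, rng):
        windows = _gaussian_windows(rng, 20)
        model = train(ClassifierSpec("QDA", seed=0), windows)
        assert len(predict(model, windows[:7])) == 7
        assert len(predict(model, [])) == 0

    def test_single_class_input_rejected(self, rng):
        windows = _gaussian_windows(rng, 10, n_classes=1)
        with pytest.raises(ValueError, match="2 classes"):
            train(ClassifierSpec("QDA", seed=0), windows)

    def test_determinism_same_seed_same_predictions(self, rng):
        windows = _gaussian_windows(rng, 25, n_classes=3, sep=1.0)
        probe = _gaussian_windows(np.random.default_rng(99), 5,
                                  n_classes=3, sep=1.0)
        a = predict(train(ClassifierSpec("LSTM", seed=5), windows), probe)
        b = predict(train(ClassifierSpec("LSTM", seed=5), windows), probe)
        assert np.array_equal(a, b)

    def test_phase_models_are_separate_and_routed(self, rng):
        # stance windows say class 1 vs 2; swing windows carry the
        # *opposite* geometry, so routing errors would be visible
        stance = _gaussian_windows(rng, 30, phase=STANCE)
        swing = []
        for w in _gaussian_windows(rng, 30, phase=SWING):
            swing.append(LabeledWindow(features=-w.features,
                                       label=3 - w.label, phase=SWING))
        model = train(ClassifierSpec("QDA", seed=0), stance + swing)
        assert set(model.submodels) == {STANCE, SWING}
        pred_st = predict(model, stance)
        pred_sw = predict(model, swing)
        assert np.mean(pred_st == [w.label for w in stance]) == 1.0
        assert np.mean(pred_sw == [w.label for w in swing]) == 1.0

    def test_save_load_round_trip(self, tmp_path, rng):
        windows = _gaussian_windows(rng, 15)
        model = train(ClassifierSpec("SVM", seed=0), windows)
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        assert np.array_equal(predict(model, windows),
                              predict(back, windows))
        assert (tmp_path / "m" / "spec.json").exists()


class TestSvmStructure:
    def test_one_vs_one_instantiates_ten_binary_classifiers(self, rng):
        windows = _gaussian_windows(rng, 15, n_classes=5)
        model = train(ClassifierSpec("SVM", seed=0), windows)
        assert model.submodels[STANCE].n_binary_classifiers == 10


class TestCnnShapes:
    def test_default_architecture_shape_audit(self, rng):
        net = _CnnNet(5, (30, 10), DEFAULT_HYPERPARAMS["CNN"], rng)
        assert net.shapes["C1"] == (26, 9, 5)
        assert net.shapes["S1"] == (13, 9, 5)
        assert net.shapes["C2"] == (10, 8, 40)
        assert net.shapes["S2"] == (5, 8, 40)
        logits = net.forward(rng.normal(size=(3, 30, 10)))
        assert logits.shape == (3, 5)

    def test_bad_configuration_fails_loudly(self, rng):
        hp = dict(DEFAULT_HYPERPARAMS["CNN"], kernel1=(5, 11))
        with pytest.raises(ShapeAuditError):
            _CnnNet(5, (30, 10), hp, rng)
        hp = dict(DEFAULT_HYPERPARAMS["CNN"], pool1=(4, 1))
        with pytest.raises(ShapeAuditError):  # 26 not divisible by 4
            _CnnNet(5, (30, 10), hp, rng)


class TestGradients:
    """Central-difference checks of the NumPy backpropagation."""

    @staticmethod
    def _loss(net, X, y):
        p = _softmax(net.forward(X))
        return -np.mean(np.log(p[np.arange(len(y)), y]))

    @pytest.mark.parametrize("arch", ["CNN", "LSTM"])
    def test_backward_matches_numerical_gradient(self, rng, arch):
        hp = dict(DEFAULT_HYPERPARAMS[arch])
        if arch == "LSTM":
            hp["hidden"] = 6
            net = _LstmNet(3, (30, 10), hp, rng)
        else:
            net = _CnnNet(3, (30, 10), hp, rng)
        X = rng.normal(size=(4, 30, 10))
        y = rng.integers(0, 3, 4)
        logits, cache = net.forward(X, cache=True)
        p = _softmax(logits)
        dlog = (p - np.eye(3)[y]) / len(y)
        grads = net.backward(X, cache, dlog)
        eps = 1e-6
        for param, grad in zip(net.params, grads):
            flat, gflat = param.reshape(-1), np.asarray(grad).reshape(-1)
            for j in rng.choice(param.size, size=min(4, param.size),
                                replace=False):
                old = flat[j]
                flat[j] = old + eps
                lp = self._loss(net, X, y)
                flat[j] = old - eps
                lm = self._loss(net, X, y)
                flat[j] = old
                num = (lp - lm) / (2 * eps)
                assert gflat[j] == pytest.approx(num, rel=1e-4, abs=1e-8)


class TestBenchmark:
    """Held-out accuracy of all four classifiers on one synthetic task.

    Frozen regression baselines for the fixed seed; the deep models'
    relative ordering against the kernel machine is asserted with slack.
    On this Gaussian-noise task PCA+QDA is close to Bayes-optimal, so no
    ordering against QDA is asserted.
    """

    BASELINES = {"QDA": 0.982, "SVM": 0.982, "CNN": 0.904, "LSTM": 0.988}

    @pytest.fixture(scope="class")
    def accuracies(self):
        from gaitmark.experiments import labeled_windows
        from gaitmark.synthgait import GeneratorConfig, generate_day

        rng = np.random.default_rng(1)
        cfg = GeneratorConfig(seed=1, noise_sd=0.6, pattern_separation=0.35)
        rec, _ = generate_day(cfg, 12, schedule="grouped")
        by = {}
        for w in labeled_windows(rec):
            by.setdefault(w.label, []).append(w)
        train_w, test_w = [], []
        for lst in by.values():
            idx = rng.permutation(len(lst))
            train_w += [lst[i] for i in idx[:200]]
            test_w += [lst[i] for i in idx[200:300]]
        truth = np.array([w.label for w in test_w])
        acc = {}
        for kind in ("QDA", "SVM", "CNN", "LSTM"):
            model = train(ClassifierSpec(kind, seed=1), train_w)
            acc[kind] = float(np.mean(predict(model, test_w) == truth))
        return acc

    def test_no_regression_against_recorded_baselines(self, accuracies):
        for kind, base in self.BASELINES.items():
            assert accuracies[kind] >= base - 0.03, (kind, accuracies)

    def test_deep_vs_kernel_ordering(self, accuracies):
        assert accuracies["LSTM"] >= accuracies["SVM"] - 0.02
        assert accuracies["SVM"] >= accuracies["CNN"] - 0.02
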