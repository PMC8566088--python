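"""The four window classifiers behind one train/predict interface.

Stance and swing phases are trained and tested separately: ``train``
returns a phased model holding one submodel per gait phase, and
``predict`` routes each window to the submodel of its phase.

* QDA — quadratic discriminant analysis on the flattened 300-vector
  (scikit-learn, with covariance regularization).
* SVM — C-SVC with a polynomial kernel, one-vs-one multiclass strategy
  (scikit-learn; 5 classes instantiate C(5,2) = 10 binary classifiers).
* CNN — a small convolutional network implemented here in NumPy:
  C1 (5 kernels, 5x2) -> S1 (2x1 average pool) -> C2 (8 kernels, 4x2,
  applied per feature map) -> S2 (2x1 average pool) -> softmax.  On a
  30x10 window the feature maps are 26x9x5 -> 13x9x5 -> 10x8x40 ->
  5x8x40; the constructor audits these shapes and fails loudly when a
  configuration breaks them.  Pooling is plain averaging over
  non-overlapping blocks; convolutions are valid (no padding).
* LSTM — a single-layer LSTM over the 30-frame window (hidden size 64)
  with a softmax head on the last step, also implemented in NumPy with
  full backpropagation through time.

The NumPy networks train with Adam on cross-entropy, a held-out
validation split and early stopping; all randomness is routed through the
spec's seed, so identical spec + seed + data reproduce identical models.
"""

from __future__ import annotations

import dataclasses
import json
import pickle
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC

from .preprocess import STANCE, SWING, LabeledWindow

KINDS = ("QDA", "SVM", "CNN", "LSTM")

DEFAULT_HYPERPARAMS = {
    "QDA": {"reg_param": 0.1, "pca_components": 40},
    "SVM": {"C": 1.0, "degree": 3, "coef0": 1.0},
    "CNN": {"n_kernels1": 5, "kernel1": (5, 2), "pool1": (2, 1),
            "n_kernels2": 8, "kernel2": (4, 2), "pool2": (2, 1),
            "lr": 3e-3, "epochs": 40, "batch_size": 64,
            "val_frac": 0.1, "patience": 8},
    "LSTM": {"hidden": 64, "lr": 3e-3, "epochs": 40, "batch_size": 64,
             "val_frac": 0.1, "patience": 8},
}


class ShapeAuditError(ValueError):
    """A network configuration breaks the layer-shape contract."""


@dataclasses.dataclass
class ClassifierSpec:
    kind: str
    hyperparams: dict = dataclasses.field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        merged = dict(DEFAULT_HYPERPARAMS[self.kind])
        merged.update(self.hyperparams)
        self.hyperparams = merged


def _windows_to_arrays(windows: Sequence[LabeledWindow]):
    X = np.stack([w.features for w in windows]).astype(float)
    y = np.array([w.label for w in windows], dtype=int)
    return X, y


class _Scaler:
    """Per-channel standardization fitted on the training windows."""

    def fit(self, X: np.ndarray) -> "_Scaler":
        flat = X.reshape(-1, X.shape[-1])
        self.mean = flat.mean(axis=0)
        sd = flat.std(axis=0)
        self.sd = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


# ---------------------------------------------------------------------------
# CNN

class _CnnNet:
    """Valid convolutions, non-overlapping average pooling, softmax head.

    The second convolution stage applies each of its kernels to every
    incoming feature map separately, so n1 maps and n2 kernels yield
    n1 * n2 maps (5 x 8 = 40 for the default configuration).
    """

    def __init__(self, n_classes: int, window_shape: tuple[int, int],
                 hp: dict, rng: np.random.Generator):
        T, C = window_shape
        self.k1 = tuple(hp["kernel1"])
        self.p1 = tuple(hp["pool1"])
        self.k2 = tuple(hp["kernel2"])
        self.p2 = tuple(hp["pool2"])
        self.n1 = hp["n_kernels1"]
        self.n2 = hp["n_kernels2"]
        c1 = (T - self.k1[0] + 1, C - self.k1[1] + 1)
        self._audit("C1", c1)
        self._audit_pool("S1", c1, self.p1)
        s1 = (c1[0] // self.p1[0], c1[1] // self.p1[1])
        c2 = (s1[0] - self.k2[0] + 1, s1[1] - self.k2[1] + 1)
        self._audit("C2", c2)
        self._audit_pool("S2", c2, self.p2)
        s2 = (c2[0] // self.p2[0], c2[1] // self.p2[1])
        self.shapes = {"input": (T, C), "C1": c1 + (self.n1,), "S1": s1 + (self.n1,),
                       "C2": c2 + (self.n1 * self.n2,),
                       "S2": s2 + (self.n1 * self.n2,)}
        flat = self.n1 * self.n2 * s2[0] * s2[1]
        self.K1 = rng.normal(0, np.sqrt(1.0 / (self.k1[0] * self.k1[1])),
                             (self.n1,) + self.k1)
        self.b1 = np.zeros(self.n1)
        self.K2 = rng.normal(0, np.sqrt(1.0 / (self.k2[0] * self.k2[1])),
                             (self.n2,) + self.k2)
        self.b2 = np.zeros(self.n2)
        self.W = rng.normal(0, np.sqrt(1.0 / flat), (flat, n_classes))
        self.c = np.zeros(n_classes)

    @staticmethod
    def _audit(layer: str, shape: tuple[int, int]) -> None:
        if min(shape) < 1:
            raise ShapeAuditError(f"{layer}: non-positive output shape {shape}")

    @staticmethod
    def _audit_pool(layer: str, shape: tuple[int, int],
                    pool: tuple[int, int]) -> None:
        if shape[0] % pool[0] or shape[1] % pool[1]:
            raise ShapeAuditError(
                f"{layer}: pool {pool} does not tile input {shape}")

    @property
    def params(self) -> list[np.ndarray]:
        return [self.K1, self.b1, self.K2, self.b2, self.W, self.c]

    def forward(self, X: np.ndarray, cache: bool = False):
        from numpy.lib.stride_tricks import sliding_window_view

        sw1 = sliding_window_view(X, self.k1, axis=(1, 2))  # (B,u,v,a,b)
        z1 = np.einsum("xuvab,fab->xfuv", sw1, self.K1) + self.b1[:, None, None]
        a1 = np.tanh(z1)
        B, f1, u1, v1 = a1.shape
        p1 = a1.reshape(B, f1, u1 // self.p1[0], self.p1[0],
                        v1 // self.p1[1], self.p1[1]).mean(axis=(3, 5))
        sw2 = sliding_window_view(p1, self.k2, axis=(2, 3))  # (B,f,u,v,a,b)
        z2 = (np.einsum("xfuvab,gab->xfguv", sw2, self.K2)
              + self.b2[None, None, :, None, None])
        a2 = np.tanh(z2)
        _, _, _, u2, v2 = a2.shape
        p2 = a2.reshape(B, f1, self.n2, u2 // self.p2[0], self.p2[0],
                        v2 // self.p2[1], self.p2[1]).mean(axis=(4, 6))
        flat = p2.reshape(B, -1)
        logits = flat @ self.W + self.c
        if cache:
            return logits, (sw1, a1, p1, sw2, a2, flat)
        return logits

    def backward(self, X: np.ndarray, cache, dlogits: np.ndarray):
        sw1, a1, p1, sw2, a2, flat = cache
        B = X.shape[0]
        dW = flat.T @ dlogits
        dc = dlogits.sum(axis=0)
        dflat = dlogits @ self.W.T
        u2, v2 = a2.shape[3], a2.shape[4]
        dp2 = dflat.reshape(B, self.n1, self.n2,
                            u2 // self.p2[0], v2 // self.p2[1])
        da2 = (np.repeat(np.repeat(dp2, self.p2[0], axis=3), self.p2[1], axis=4)
               / (self.p2[0] * self.p2[1]))
        dz2 = da2 * (1 - a2 ** 2)
        dK2 = np.einsum("xfuvab,xfguv->gab", sw2, dz2)
        db2 = dz2.sum(axis=(0, 1, 3, 4))
        dp1 = np.zeros_like(p1)
        tmp = np.einsum("xfguv,gab->xfuvab", dz2, self.K2)
        for a in range(self.k2[0]):
            for b in range(self.k2[1]):
                dp1[:, :, a:a + dz2.shape[3], b:b + dz2.shape[4]] += tmp[..., a, b]
        u1, v1 = a1.shape[2], a1.shape[3]
        dp1r = dp1.reshape(B, self.n1, u1 // self.p1[0], v1 // self.p1[1])
        da1 = (np.repeat(np.repeat(dp1r, self.p1[0], axis=2), self.p1[1], axis=3)
               / (self.p1[0] * self.p1[1]))
        dz1 = da1 * (1 - a1 ** 2)
        dK1 = np.einsum("xuvab,xfuv->fab", sw1, dz1)
        db1 = dz1.sum(axis=(0, 2, 3))
        return [dK1, db1, dK2, db2, dW, dc]


# ---------------------------------------------------------------------------
# LSTM

class _LstmNet:
    """Single-layer LSTM, softmax on the last hidden state."""

    def __init__(self, n_classes: int, window_shape: tuple[int, int],
                 hp: dict, rng: np.random.Generator):
        T, C = window_shape
        H = hp["hidden"]
        self.H = H
        self.Wx = rng.normal(0, np.sqrt(1.0 / C), (C, 4 * H))
        self.Wh = rng.normal(0, np.sqrt(1.0 / H), (H, 4 * H))
        self.b = np.zeros(4 * H)
        self.b[H:2 * H] = 1.0  # forget-gate bias
        self.Wo = rng.normal(0, np.sqrt(1.0 / H), (H, n_classes))
        self.bo = np.zeros(n_classes)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.Wx, self.Wh, self.b, self.Wo, self.bo]

    @staticmethod
    def _sigmoid(z):
        return 1.0 / (1.0 + np.exp(-z))

    def forward(self, X: np.ndarray, cache: bool = False):
        B, T, _ = X.shape
        H = self.H
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        steps = []
        for t in range(T):
            z = X[:, t] @ self.Wx + h @ self.Wh + self.b
            i = self._sigmoid(z[:, :H])
            f = self._sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = self._sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            if cache:
                steps.append((X[:, t], h, c, i, f, g, o, c_new))
            h, c = h_new, c_new
        logits = h @ self.Wo + self.bo
        if cache:
            return logits, (steps, h)
        return logits

    def backward(self, X: np.ndarray, cache, dlogits: np.ndarray):
        steps, h_last = cache
        H = self.H
        dWo = h_last.T @ dlogits
        dbo = dlogits.sum(axis=0)
        dh = dlogits @ self.Wo.T
        dc = np.zeros_like(dh)
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        for x_t, h_prev, c_prev, i, f, g, o, c_new in reversed(steps):
            tc = np.tanh(c_new)
            do = dh * tc
            dc = dc + dh * o * (1 - tc ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            dWx += x_t.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dh = dz @ self.Wh.T
            dc = dc * f
        return [dWx, dWh, db, dWo, dbo]


def _fit_net(net, X: np.ndarray, y_idx: np.ndarray, n_classes: int,
             hp: dict, rng: np.random.Generator) -> None:
    """Adam + cross-entropy with a validation split and early stopping."""
    n = len(X)
    order = rng.permutation(n)
    n_val = max(1, int(round(hp["val_frac"] * n))) if n >= 10 else 0
    val_idx, tr_idx = order[:n_val], order[n_val:]
    Xtr, ytr = X[tr_idx], y_idx[tr_idx]
    onehot = np.eye(n_classes)[ytr]
    opt = _Adam(net.params, hp["lr"])
    best_loss, best_params, patience = np.inf, None, 0
    for _ in range(hp["epochs"]):
        perm = rng.permutation(len(Xtr))
        for s in range(0, len(Xtr), hp["batch_size"]):
            idx = perm[s:s + hp["batch_size"]]
            logits, cache = net.forward(Xtr[idx], cache=True)
            probs = _softmax(logits)
            dlogits = (probs - onehot[idx]) / len(idx)
            grads = net.backward(Xtr[idx], cache, dlogits)
            opt.step(net.params, grads)
        if n_val:
            probs = _softmax(net.forward(X[val_idx]))
            loss = -np.mean(np.log(probs[np.arange(n_val), y_idx[val_idx]]
                                   + 1e-12))
        else:
            probs = _softmax(net.forward(Xtr))
            loss = -np.mean(np.log(probs[np.arange(len(Xtr)), ytr] + 1e-12))
        if loss < best_loss - 1e-5:
            best_loss = loss
            best_params = [p.copy() for p in net.params]
            patience = 0
        else:
            patience += 1
            if patience > hp["patience"]:
                break
    if best_params is not None:
        for p, bp in zip(net.params, best_params):
            p[...] = bp


# ---------------------------------------------------------------------------
# Single-phase models and the phased wrapper

class _PhaseModel:
    """One classifier trained on the windows of a single gait phase."""

    def __init__(self, spec: ClassifierSpec, phase: str):
        self.spec = spec
        self.phase = phase
        self.classes_: np.ndarray = np.empty(0, dtype=int)
        self.scaler = _Scaler()
        self._impl = None
        self._net = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_PhaseModel":
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError(
                f"{self.phase} phase: need >= 2 classes, got {self.classes_}")
        Xs = self.scaler.fit(X).transform(X)
        hp = self.spec.hyperparams
        kind = self.spec.kind
        if kind == "QDA":
            # PCA keeps each class's covariance full-rank: quadratic
            # discriminants need more samples per class than features.
            counts = np.bincount(y)
            n_comp = min(hp["pca_components"], Xs[0].size,
                         int(counts[counts > 0].min()) - 1)
            self._impl = Pipeline([
                ("pca", PCA(n_components=n_comp, random_state=0)),
                ("qda", QuadraticDiscriminantAnalysis(
                    reg_param=hp["reg_param"]))])
            self._impl.fit(Xs.reshape(len(Xs), -1), y)
        elif kind == "SVM":
            self._impl = SVC(kernel="poly", C=hp["C"], degree=hp["degree"],
                             coef0=hp["coef0"], gamma="scale")
            self._impl.fit(Xs.reshape(len(Xs), -1), y)
        else:
            rng = np.random.default_rng(
                np.random.SeedSequence([self.spec.seed,
                                        0 if self.phase == STANCE else 1]))
            y_idx = np.searchsorted(self.classes_, y)
            cls = _CnnNet if kind == "CNN" else _LstmNet
            self._net = cls(len(self.classes_), X.shape[1:], hp, rng)
            _fit_net(self._net, Xs, y_idx, len(self.classes_), hp, rng)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if len(X) == 0:
            return np.empty(0, dtype=int)
        Xs = self.scaler.transform(X)
        if self._impl is not None:
            return self._impl.predict(Xs.reshape(len(Xs), -1))
        logits = self._net.forward(Xs)
        return self.classes_[np.argmax(logits, axis=1)]

    @property
    def n_binary_classifiers(self) -> Optional[int]:
        """Number of one-vs-one binary classifiers (SVM only)."""
        if self.spec.kind != "SVM" or self._impl is None:
            return None
        s = len(self._impl.classes_)
        return s * (s - 1) // 2


class PhasedModel:
    """Stance and swing submodels behind one predict() surface."""

    def __init__(self, spec: ClassifierSpec,
                 submodels: dict[str, _PhaseModel]):
        self.spec = spec
        self.submodels = submodels

    def predict(self, windows: Sequence[LabeledWindow]) -> np.ndarray:
        out = np.empty(len(windows), dtype=int)
        by_phase: dict[str, list[int]] = {}
        for idx, w in enumerate(windows):
            if w.phase is None:
                raise ValueError(f"window {idx} has no gait phase")
            by_phase.setdefault(w.phase, []).append(idx)
        for phase, indices in by_phase.items():
            if phase not in self.submodels:
                raise ValueError(f"no model trained for phase {phase!r}")
            X = np.stack([windows[i].features for i in indices]).astype(float)
            out[np.asarray(indices)] = self.submodels[phase].predict(X)
        return out


def train(spec: ClassifierSpec,
          windows: Sequence[LabeledWindow]) -> PhasedModel:
    """Train one submodel per gait phase on the labeled windows."""
    groups: dict[str, list[LabeledWindow]] = {}
    for w in windows:
        if w.label is None or w.phase is None:
            continue
        groups.setdefault(w.phase, []).append(w)
    if not groups:
        raise ValueError("no labeled windows to train on")
    submodels = {}
    for phase in (STANCE, SWING):
        if phase in groups:
            X, y = _windows_to_arrays(groups[phase])
            submodels[phase] = _PhaseModel(spec, phase).fit(X, y)
    return PhasedModel(spec, submodels)


def predict(model: PhasedModel,
            windows: Sequence[LabeledWindow]) -> np.ndarray:
    """One label per window, in input order."""
    if len(windows) == 0:
        return np.empty(0, dtype=int)
    return model.predict(windows)


def save_model(model: PhasedModel, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "spec.json").write_text(json.dumps(
        {"kind": model.spec.kind, "seed": model.spec.seed,
         "hyperparams": {k: (list(v) if isinstance(v, tuple) else v)
                         for k, v in model.spec.hyperparams.items()}},
        indent=2))
    with open(directory / "model.pkl", "wb") as fh:
        pickle.dump(model, fh)


def load_model(directory) -> PhasedModel:
    with open(Path(directory) / "model.pkl", "rb") as fh:
        return pickle.load(fh)
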