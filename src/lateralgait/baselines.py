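"""Comparison classifiers over the shared 48-feature matrix.

Six reference models with their published hyperparameters: SVM (RBF kernel,
gamma 0.01, C 1.0), KNN (k=8, Euclidean, majority vote), a dense NN, a
small CNN (2x1 kernels), an LSTM (48 hidden units), and a CNN-LSTM.  SVM
and KNN distance search are delegated to scikit-learn; the neural kinds
run on the package's own network core so they share the training loop and
determinism contract with the main model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from . import _nn
from ._nn import LSTM, Conv2dH, Dense, MaxPool2, softmax, train_network
from .features import FeatureScaler

BASELINE_KINDS = ("svm", "knn", "nn", "cnn", "lstm", "cnn_lstm")


@dataclass
class BaselineSpec:
    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.kind = self.kind.lower()
        if self.kind not in BASELINE_KINDS:
            raise ValueError(f"unknown baseline kind {self.kind!r}")


_DEFAULTS = {
    "svm": {"gamma": 0.01, "C": 1.0},
    "knn": {"k": 8},
    "nn": {"hidden": (64, 16), "epochs": 400, "lr": 0.001,
           "batch_size": 128},
    "cnn": {"epochs": 400, "lr": 0.001, "lr_drop_factor": 0.1,
            "lr_drop_period": 200, "l2": 4e-4, "batch_size": 128},
    "lstm": {"hidden": 48, "epochs": 400, "lr": 0.01, "lr_drop_factor": 0.1,
             "lr_drop_period": 150, "batch_size": 128},
    "cnn_lstm": {"epochs": 400, "lr": 0.001, "lr_drop_factor": 0.1,
                 "lr_drop_period": 200, "batch_size": 128},
}


class _KNN:
    """k-nearest-neighbour vote with a documented tie-break: ties go to the
    class with the smallest mean neighbour distance, then the lowest class
    index."""

    def __init__(self, k: int = 8) -> None:
        self.k = k

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_KNN":
        self._nn = NearestNeighbors(n_neighbors=self.k).fit(X)
        self._y = np.asarray(y, int)
        self.classes_ = np.unique(self._y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        dist, idx = self._nn.kneighbors(np.asarray(X, float))
        labels = self._y[idx]
        out = np.empty(len(X), int)
        for i in range(len(X)):
            counts = np.bincount(labels[i], minlength=4)
            best = counts.max()
            tied = np.flatnonzero(counts == best)
            if len(tied) == 1:
                out[i] = tied[0]
            else:
                means = [dist[i][labels[i] == c].mean() for c in tied]
                out[i] = tied[int(np.argmin(means))]
        return out

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        _, idx = self._nn.kneighbors(np.asarray(X, float))
        labels = self._y[idx]
        return np.stack([np.bincount(row, minlength=4) / self.k
                         for row in labels])


class _NetClassifier:
    """Wraps a network from the core as a fitted 4-class classifier."""

    def __init__(self, net, scaler: FeatureScaler, reshape=None) -> None:
        self._net = net
        self._scaler = scaler
        self._reshape = reshape

    def _prep(self, X):
        X = self._scaler.transform(np.asarray(X, float))
        return self._reshape(X) if self._reshape else X

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return softmax(self._net.forward(self._prep(X)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


class _MLPNet:
    def __init__(self, dims, rng):
        self.layers = [Dense(dims[i], dims[i + 1], rng,
                             relu=i < len(dims) - 2, name=f"dense{i+1}")
                       for i in range(len(dims) - 1)]

    def params(self):
        return [p for lay in self.layers for p in lay.params()]

    def forward(self, x):
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, d):
        for lay in reversed(self.layers):
            d = lay.backward(d)
        return d


class _CNNNet:
    """Two 2x1-kernel conv layers, 2x1 max-pool, dense-4 softmax head."""

    def __init__(self, rng, c1=16, c2=32, n_in=48):
        self.conv1 = Conv2dH(2, 1, 1, c1, rng, name="conv1")
        self.conv2 = Conv2dH(2, 1, c1, c2, rng, name="conv2")
        self.pool = MaxPool2()
        h_out = (n_in - 2) // 2  # after two valid 2x1 convs and one pool
        self.head = Dense(h_out * c2, 4, rng, name="output")
        self._n_in = n_in

    def params(self):
        return self.conv1.params() + self.conv2.params() + self.head.params()

    def forward(self, x):
        n = x.shape[0]
        h = self.pool.forward(
            self.conv2.forward(self.conv1.forward(x.reshape(n, self._n_in, 1))))
        self._hshape = h.shape
        return self.head.forward(h.reshape(n, -1))

    def backward(self, d):
        dh = self.head.backward(d).reshape(self._hshape)
        return self.conv1.backward(
            self.conv2.backward(self.pool.backward(dh)))


class _LSTMNet:
    """Features as a 48-step scalar sequence -> LSTM(48) -> dense-4."""

    def __init__(self, rng, hidden=48):
        self.lstm = LSTM(1, hidden, rng, name="lstm")
        self.relu = Dense(hidden, hidden, rng, relu=True, name="relu_fc")
        self.head = Dense(hidden, 4, rng, name="output")

    def params(self):
        return self.lstm.params() + self.relu.params() + self.head.params()

    def forward(self, x):
        h = self.lstm.forward(x[:, :, None])
        return self.head.forward(self.relu.forward(h))

    def backward(self, d):
        return self.lstm.backward(
            self.relu.backward(self.head.backward(d)))[:, :, 0]


class _CNNLSTMNet:
    """Conv stack feeding the pooled maps to an LSTM, as a sequence."""

    def __init__(self, rng, c1=16, c2=32, hidden=48, n_in=48):
        self.conv1 = Conv2dH(3, 1, 1, c1, rng, name="conv1")
        self.conv2 = Conv2dH(3, 1, c1, c2, rng, name="conv2")
        self.pool = MaxPool2()
        self.lstm = LSTM(c2, hidden, rng, name="lstm")
        self.head = Dense(hidden, 4, rng, name="output")
        self._n_in = n_in

    def params(self):
        return (self.conv1.params() + self.conv2.params()
                + self.lstm.params() + self.head.params())

    def forward(self, x):
        n = x.shape[0]
        h = self.pool.forward(
            self.conv2.forward(self.conv1.forward(x.reshape(n, self._n_in, 1))))
        return self.head.forward(self.lstm.forward(h))

    def backward(self, d):
        dh = self.lstm.backward(self.head.backward(d))
        return self.conv1.backward(
            self.conv2.backward(self.pool.backward(dh)))


def fit_baseline(spec: BaselineSpec, train_features: np.ndarray,
                 train_labels: np.ndarray):
    """Fit one comparison classifier; returns an object with ``predict``
    (and ``predict_proba`` / ``decision_function`` where available)."""
    X = np.asarray(train_features, float)
    y = np.asarray(train_labels, int)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate training set: a single class")
    p = {**_DEFAULTS[spec.kind], **spec.params}
    if spec.kind == "svm":
        clf = SVC(kernel="rbf", gamma=p["gamma"], C=p["C"],
                  decision_function_shape="ovo")
        scaler = FeatureScaler()
        clf.fit(scaler.fit_transform(X), y)
        return _SkWrapper(clf, scaler)
    if spec.kind == "knn":
        scaler = FeatureScaler()
        return _KNN(k=p["k"]).fit(scaler.fit_transform(X), y), scaler
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 30]))
    scaler = FeatureScaler()
    Xn = scaler.fit_transform(X)
    if spec.kind == "nn":
        net = _MLPNet([X.shape[1], *p["hidden"], 4], rng)
    elif spec.kind == "cnn":
        net = _CNNNet(rng, n_in=X.shape[1])
    elif spec.kind == "lstm":
        net = _LSTMNet(rng, hidden=p["hidden"])
    else:
        net = _CNNLSTMNet(rng, n_in=X.shape[1])
    train_network(net, Xn, y, loss="softmax_ce", epochs=p["epochs"],
                  lr=p["lr"], batch_size=p["batch_size"],
                  lr_drop_factor=p.get("lr_drop_factor", 0.1),
                  lr_drop_period=p.get("lr_drop_period"), seed=spec.seed)
    return _NetClassifier(net, scaler)


class _SkWrapper:
    def __init__(self, clf, scaler):
        self._clf = clf
        self._scaler = scaler

    def predict(self, X):
        return self._clf.predict(self._scaler.transform(np.asarray(X, float)))

    def decision_function(self, X):
        return self._clf.decision_function(
            self._scaler.transform(np.asarray(X, float)))


def predict_baseline(fitted, features: np.ndarray):
    """(labels, scores-or-None) for any fitted baseline.

    Scores are class-probability rows (summing to 1) for the probabilistic
    kinds, ``None`` for the margin-based SVM.
    """
    if isinstance(fitted, tuple):  # (KNN, scaler)
        knn, scaler = fitted
        X = scaler.transform(np.asarray(features, float))
        if X.shape[0] == 0:
            return np.empty(0, int), np.empty((0, 4))
        return knn.predict(X), knn.predict_proba(X)
    X = np.asarray(features, float)
    if X.shape[0] == 0:
        return np.empty(0, int), None
    labels = fitted.predict(X)
    scores = fitted.predict_proba(X) if hasattr(fitted, "predict_proba") \
        else None
    return labels, scores
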