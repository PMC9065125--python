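"""Reference mortality classifiers behind a uniform contract.

The contract every downstream stage relies on:

* ``fit(X, y, seed)`` trains in place (all randomness flows through the seed),
* ``predict_proba(X)`` returns the positive-class probability per sample,
* ``input_gradient(X)`` returns d p(positive) / d x for each input entry
  (only if ``gradient_available``),
* ``glassbox_importance()`` returns nonnegative per-feature weights summing
  to 1 (only if ``glassbox_available``).

Models are deliberately small (a few thousand parameters) so that
remove-and-retrain evaluation, which retrains once per feature-drop ratio,
stays cheap.  Sequence models accept a flattened (T*F) vector and reshape
internally.  Gradients are taken with respect to the pre-threshold positive
class probability, consistently across all attribution methods.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "ModelContract",
    "SplitSpec",
    "PredictionSet",
    "split_dataset",
    "make_model",
    "binary_metrics",
    "LinearModel",
    "MLPModel",
    "RecurrentModel",
    "AttentionGlassboxModel",
]

MODEL_KINDS = ("linear", "mlp", "recurrent", "attention_glassbox")


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


class ModelContract(abc.ABC):
    gradient_available: bool = False
    glassbox_available: bool = False

    @abc.abstractmethod
    def fit(self, X: np.ndarray, y: np.ndarray, seed: int = 0) -> "ModelContract":
        ...

    @abc.abstractmethod
    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        ...

    def input_gradient(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError("model does not expose input gradients")

    def glassbox_importance(self) -> np.ndarray:
        raise NotImplementedError("model does not expose glassbox importance")


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions (default 60/20/20) plus a split seed."""

    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self):
        if any(f <= 0 for f in self.fractions):
            raise ValueError("split fractions must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class PredictionSet:
    sample_ids: np.ndarray
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        if not (len(self.sample_ids) == len(self.scores) == len(self.labels)):
            raise ValueError("sample_ids, scores and labels must be aligned")


def split_dataset(n: int, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint train/valid/test index sets of sizes (floor(f1 n), floor(f2 n), rest)."""
    if n < 5:
        raise ValueError("need at least 5 samples to split")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(spec.fractions[0] * n))
    n_valid = int(np.floor(spec.fractions[1] * n))
    return perm[:n_train], perm[n_train : n_train + n_valid], perm[n_train + n_valid :]


def binary_metrics(preds: PredictionSet) -> tuple[float, float]:
    """(AUPRC, AUROC); raises on single-class labels."""
    labels = np.asarray(preds.labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("binary metrics undefined: labels contain a single class")
    return (
        float(average_precision_score(labels, preds.scores)),
        float(roc_auc_score(labels, preds.scores)),
    )


# ---------------------------------------------------------------------------
# shared bits
# ---------------------------------------------------------------------------

class _Scaler:
    """Column standardizer fitted on training data; constant columns untouched."""

    def fit(self, X):
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd_ = np.where(sd > 1e-12, sd, 1.0)
        return self

    def transform(self, X):
        return (X - self.mean_) / self.sd_


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


# ---------------------------------------------------------------------------
# linear
# ---------------------------------------------------------------------------

class LinearModel(ModelContract):
    """L2-regularized logistic regression (sklearn backend, analytic gradient)."""

    gradient_available = True

    def __init__(self, C: float = 1.0, max_iter: int = 500):
        self.C = C
        self.max_iter = max_iter
        self._clf = None
        self._scaler = None

    def fit(self, X, y, seed: int = 0):
        X = np.asarray(X, dtype=float)
        self._scaler = _Scaler().fit(X)
        if len(np.unique(y)) < 2:
            self._clf = None
            self._const = float(np.mean(y)) if len(y) else 0.5
            return self
        self._clf = LogisticRegression(C=self.C, max_iter=self.max_iter, random_state=seed)
        self._clf.fit(self._scaler.transform(X), np.asarray(y, dtype=int))
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        if self._clf is None:
            return np.full(len(X), getattr(self, "_const", 0.5))
        return self._clf.predict_proba(self._scaler.transform(X))[:, 1]

    def input_gradient(self, X):
        X = np.asarray(X, dtype=float)
        if self._clf is None:
            return np.zeros_like(X)
        p = self.predict_proba(X)
        w = self._clf.coef_[0] / self._scaler.sd_
        return (p * (1 - p))[:, None] * w[None, :]


# ---------------------------------------------------------------------------
# mlp
# ---------------------------------------------------------------------------

class MLPModel(ModelContract):
    """One-hidden-layer tanh network trained full-batch with Adam."""

    gradient_available = True

    def __init__(self, hidden: int = 16, epochs: int = 250, lr: float = 0.02, l2: float = 1e-2):
        self.hidden = hidden
        self.epochs = epochs
        self.lr = lr
        self.l2 = l2

    def fit(self, X, y, seed: int = 0):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self._scaler = _Scaler().fit(X)
        Xs = self._scaler.transform(X)
        n, d = Xs.shape
        rng = np.random.default_rng(seed)
        h = self.hidden
        self.W1 = rng.normal(0, 1 / np.sqrt(d), size=(d, h))
        self.b1 = np.zeros(h)
        self.w2 = rng.normal(0, 1 / np.sqrt(h), size=h)
        self.b2 = np.zeros(1)
        opt = _Adam([self.W1, self.b1, self.w2, self.b2], self.lr)
        for _ in range(self.epochs):
            A1 = np.tanh(Xs @ self.W1 + self.b1)
            p = _sigmoid(A1 @ self.w2 + self.b2[0])
            dz2 = (p - y) / n
            gw2 = A1.T @ dz2 + self.l2 * self.w2
            gb2 = np.array([dz2.sum()])
            dZ1 = np.outer(dz2, self.w2) * (1 - A1 * A1)
            gW1 = Xs.T @ dZ1 + self.l2 * self.W1
            gb1 = dZ1.sum(axis=0)
            opt.step([gW1, gb1, gw2, gb2])
        return self

    def _forward(self, X):
        Xs = self._scaler.transform(np.asarray(X, dtype=float))
        A1 = np.tanh(Xs @ self.W1 + self.b1)
        return A1, _sigmoid(A1 @ self.w2 + self.b2[0])

    def predict_proba(self, X):
        return self._forward(X)[1]

    def input_gradient(self, X):
        A1, p = self._forward(X)
        # dp/dx = p(1-p) * W1 @ diag(1-A1^2) @ w2, divided by the scaler sd
        inner = ((1 - A1 * A1) * self.w2) @ self.W1.T
        return (p * (1 - p))[:, None] * inner / self._scaler.sd_


# ---------------------------------------------------------------------------
# recurrent
# ---------------------------------------------------------------------------

class RecurrentModel(ModelContract):
    """Plain tanh RNN over (T, F) inputs; prediction from the last hidden state."""

    gradient_available = True

    def __init__(self, input_shape: tuple[int, int], hidden: int = 8, epochs: int = 120, lr: float = 0.02):
        self.T, self.F = input_shape
        self.hidden = hidden
        self.epochs = epochs
        self.lr = lr

    def _seq(self, X):
        X = np.asarray(X, dtype=float)
        return X.reshape(len(X), self.T, self.F)

    def fit(self, X, y, seed: int = 0):
        Xf = np.asarray(X, dtype=float)
        self._scaler = _Scaler().fit(Xf)
        S = self._scaler.transform(Xf).reshape(len(Xf), self.T, self.F)
        y = np.asarray(y, dtype=float)
        n = len(y)
        rng = np.random.default_rng(seed)
        h, f = self.hidden, self.F
        self.U = rng.normal(0, 1 / np.sqrt(f), size=(f, h))
        self.W = rng.normal(0, 1 / np.sqrt(h), size=(h, h))
        self.b = np.zeros(h)
        self.v = rng.normal(0, 1 / np.sqrt(h), size=h)
        self.c = np.zeros(1)
        opt = _Adam([self.U, self.W, self.b, self.v, self.c], self.lr)
        for _ in range(self.epochs):
            H = np.zeros((n, self.T + 1, h))
            for t in range(self.T):
                H[:, t + 1] = np.tanh(S[:, t] @ self.U + H[:, t] @ self.W + self.b)
            p = _sigmoid(H[:, -1] @ self.v + self.c[0])
            dlast = np.outer((p - y) / n, self.v)
            gv = H[:, -1].T @ ((p - y) / n)
            gc = np.array([((p - y) / n).sum()])
            gU, gW, gb = np.zeros_like(self.U), np.zeros_like(self.W), np.zeros_like(self.b)
            delta = dlast
            for t in range(self.T - 1, -1, -1):
                dz = delta * (1 - H[:, t + 1] ** 2)
                gU += S[:, t].T @ dz
                gW += H[:, t].T @ dz
                gb += dz.sum(axis=0)
                delta = dz @ self.W.T
            opt.step([gU, gW, gb, gv, gc])
        return self

    def _forward(self, X):
        Xf = np.asarray(X, dtype=float)
        S = self._scaler.transform(Xf).reshape(len(Xf), self.T, self.F)
        n = len(Xf)
        H = np.zeros((n, self.T + 1, self.hidden))
        for t in range(self.T):
            H[:, t + 1] = np.tanh(S[:, t] @ self.U + H[:, t] @ self.W + self.b)
        p = _sigmoid(H[:, -1] @ self.v + self.c[0])
        return S, H, p

    def predict_proba(self, X):
        return self._forward(X)[2]

    def input_gradient(self, X):
        S, H, p = self._forward(X)
        n = len(S)
        grad = np.zeros((n, self.T, self.F))
        delta = np.outer(p * (1 - p), self.v)
        for t in range(self.T - 1, -1, -1):
            dz = delta * (1 - H[:, t + 1] ** 2)
            grad[:, t] = dz @ self.U.T
            delta = dz @ self.W.T
        grad = grad.reshape(n, self.T * self.F) / self._scaler.sd_
        return grad


# ---------------------------------------------------------------------------
# attention glassbox
# ---------------------------------------------------------------------------

class AttentionGlassboxModel(ModelContract):
    """Logistic model with a softmax attention gate exposing its own importance.

    p = sigmoid(sum_j a_j w_j x_j + b) with a = softmax(u); the published
    glassbox importance is a .* |w| normalized to sum 1, combining where the
    model attends with how strongly the attended value moves the output.
    """

    gradient_available = True
    glassbox_available = True

    def __init__(self, epochs: int = 300, lr: float = 0.05, l2: float = 1e-4):
        self.epochs = epochs
        self.lr = lr
        self.l2 = l2

    def fit(self, X, y, seed: int = 0):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self._scaler = _Scaler().fit(X)
        Xs = self._scaler.transform(X)
        n, d = Xs.shape
        rng = np.random.default_rng(seed)
        self.u = np.zeros(d)
        self.w = rng.normal(0, 0.1, size=d)
        self.b = np.zeros(1)
        opt = _Adam([self.u, self.w, self.b], self.lr)
        for _ in range(self.epochs):
            a = _softmax(self.u)
            s = Xs @ (a * self.w) + self.b[0]
            p = _sigmoid(s)
            ds = (p - y) / n
            gw = Xs.T @ ds * a + self.l2 * self.w
            gb = np.array([ds.sum()])
            # ds/du_k = a_k (w_k x_k - x.(a*w))
            core = Xs * self.w[None, :] - (Xs @ (a * self.w))[:, None]
            gu = a * (core.T @ ds)
            opt.step([gu, gw, gb])
        return self

    def _att(self):
        return _softmax(self.u)

    def predict_proba(self, X):
        Xs = self._scaler.transform(np.asarray(X, dtype=float))
        return _sigmoid(Xs @ (self._att() * self.w) + self.b[0])

    def input_gradient(self, X):
        p = self.predict_proba(X)
        eff = self._att() * self.w / self._scaler.sd_
        return (p * (1 - p))[:, None] * eff[None, :]

    def glassbox_importance(self):
        raw = self._att() * np.abs(self.w)
        total = raw.sum()
        if total <= 0:
            return np.full_like(raw, 1.0 / len(raw))
        return raw / total


def _softmax(z):
    e = np.exp(z - z.max())
    return e / e.sum()


def make_model(kind: str, **config) -> ModelContract:
    """Factory for the reference classifiers.

    ``recurrent`` requires ``input_shape=(T, F)``; all models consume flattened
    inputs and sequence models reshape internally.
    """
    if kind == "linear":
        return LinearModel(**config)
    if kind == "mlp":
        return MLPModel(**config)
    if kind == "recurrent":
        if "input_shape" not in config:
            raise ValueError("recurrent model requires input_shape=(T, F)")
        return RecurrentModel(**config)
    if kind == "attention_glassbox":
        return AttentionGlassboxModel(**config)
    raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")
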