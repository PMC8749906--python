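"""MLP disfluency classifier: 171 inputs, one tanh hidden layer (8 units),
4 softmax outputs, categorical cross-entropy, full-batch BFGS training.

The network maps a 171-long feature vector (residual distances or SOM
winner indices over an utterance's frames) to class-membership
probabilities for {block, repetition, prolongation, fluent}.  Inputs are
z-scored with training-set statistics; weights start uniform in
[-0.1, 0.1]; training runs quasi-Newton BFGS with an analytic gradient for
at most 100 iterations, and the weights with the best validation loss seen
along the way are retained.  A momentum-SGD fallback (lr 0.1, momentum 0.3)
is available.

Also provides the stratified train/validation/test split plan of the
reference corpus (blocks 37/9/9, repetitions 36/5/5, prolongations
42/5/12, fluent 25/10/3; totals 140/29/29) and the evaluation report:
confusion matrix, per-class and overall accuracy ``acc = N_c / N_t``,
error rate ``eps = 1 - acc`` and per-case certainty (maximum output
probability).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, ClassifierMixin

from .synth import CLASSES

__all__ = [
    "SplitPlan",
    "TABLE_SPLIT_PLAN",
    "split_indices",
    "split_dataset",
    "MLPDisfluencyClassifier",
    "train_mlp",
    "predict_proba",
    "ClassificationReport",
    "evaluate",
]


# ---------------------------------------------------------------------------
# stratified split
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    """Per-class (train, validation, test) counts."""

    counts: dict[str, tuple[int, int, int]]

    def totals(self) -> tuple[int, int, int]:
        agg = np.sum([list(v) for v in self.counts.values()], axis=0)
        return tuple(int(v) for v in agg)

    def class_totals(self) -> dict[str, int]:
        return {k: sum(v) for k, v in self.counts.items()}

    @classmethod
    def proportional(cls, class_counts: dict[str, int],
                     fractions=(0.70, 0.15, 0.15)) -> "SplitPlan":
        plan = {}
        for label, n in class_counts.items():
            tr = int(round(fractions[0] * n))
            va = int(round(fractions[1] * n))
            te = n - tr - va
            if n >= 3 and min(tr, va, te) < 1:
                tr, va, te = n - 2, 1, 1
            plan[label] = (tr, va, te)
        return cls(counts=plan)


#: The reference corpus split (per-class train/validation/test).
TABLE_SPLIT_PLAN = SplitPlan(counts={
    "block": (37, 9, 9),
    "repetition": (36, 5, 5),
    "prolongation": (42, 5, 12),
    "fluent": (25, 10, 3),
})


def split_indices(labels, plan: SplitPlan, seed: int = 0):
    """Stratified random assignment matching the plan exactly; returns
    (train_idx, val_idx, test_idx) index arrays."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(int(seed))
    train, val, test = [], [], []
    for label, (n_tr, n_va, n_te) in plan.counts.items():
        idx = np.flatnonzero(labels == label)
        if len(idx) < n_tr + n_va + n_te:
            raise ValueError(
                f"class {label!r}: have {len(idx)} samples, "
                f"plan needs {n_tr + n_va + n_te}")
        perm = rng.permutation(idx)
        train.append(perm[:n_tr])
        val.append(perm[n_tr:n_tr + n_va])
        test.append(perm[n_tr + n_va:n_tr + n_va + n_te])
    return (np.sort(np.concatenate(train)), np.sort(np.concatenate(val)),
            np.sort(np.concatenate(test)))


def split_dataset(features, labels, plan: SplitPlan, seed: int = 0):
    """As :func:`split_indices` but returning ((X, y), ...) triples."""
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    tr, va, te = split_indices(y, plan, seed)
    return (X[tr], y[tr]), (X[va], y[va]), (X[te], y[te])


# ---------------------------------------------------------------------------
# network internals
# ---------------------------------------------------------------------------

def _unpack(params, n_in, n_hidden, n_out):
    p = 0
    W1 = params[p:p + n_in * n_hidden].reshape(n_in, n_hidden)
    p += n_in * n_hidden
    b1 = params[p:p + n_hidden]
    p += n_hidden
    W2 = params[p:p + n_hidden * n_out].reshape(n_hidden, n_out)
    p += n_hidden * n_out
    b2 = params[p:p + n_out]
    return W1, b1, W2, b2


def _softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(params, X, n_hidden, n_out):
    W1, b1, W2, b2 = _unpack(params, X.shape[1], n_hidden, n_out)
    H = np.tanh(X @ W1 + b1)
    return _softmax(H @ W2 + b2), H


def _loss_grad(params, X, T, n_hidden, n_out):
    """Mean categorical cross-entropy and its gradient."""
    n = X.shape[0]
    W1, b1, W2, b2 = _unpack(params, X.shape[1], n_hidden, n_out)
    H = np.tanh(X @ W1 + b1)
    P = _softmax(H @ W2 + b2)
    loss = -np.sum(T * np.log(np.clip(P, 1e-300, None))) / n
    dlogits = (P - T) / n
    gW2 = H.T @ dlogits
    gb2 = dlogits.sum(axis=0)
    dH = dlogits @ W2.T * (1 - H**2)
    gW1 = X.T @ dH
    gb1 = dH.sum(axis=0)
    grad = np.concatenate([gW1.ravel(), gb1, gW2.ravel(), gb2])
    return loss, grad


def _ce_loss(params, X, T, n_hidden, n_out):
    P, _ = _forward(params, X, n_hidden, n_out)
    return -np.sum(T * np.log(np.clip(P, 1e-300, None))) / X.shape[0]


class MLPDisfluencyClassifier(BaseEstimator, ClassifierMixin):
    """One-hidden-layer softmax MLP trained with full-batch BFGS.

    Parameters
    ----------
    hidden_units : int, default 8
    max_iter : int, default 100
        Optimizer iteration cap ("epochs" of the full-batch trainer).
    solver : {"bfgs", "sgd"}, default "bfgs"
        "sgd" is a plain momentum gradient-descent fallback using
        ``learning_rate`` / ``momentum``.
    learning_rate, momentum : float
        Used by the "sgd" solver only.
    init_scale : float, default 0.1
        Weights start uniform in [-init_scale, init_scale].
    random_state : int, default 0

    Fitted attributes: ``classes_``, ``coefs_``/``intercepts_``,
    ``loss_curve_`` (training loss per iteration), ``validation_curve_``
    (when a validation set is supplied to ``fit``; the weights with the
    best validation loss are retained).
    """

    def __init__(self, hidden_units: int = 8, max_iter: int = 100,
                 solver: str = "bfgs", learning_rate: float = 0.1,
                 momentum: float = 0.3, init_scale: float = 0.1,
                 random_state: int = 0):
        self.hidden_units = hidden_units
        self.max_iter = max_iter
        self.solver = solver
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.init_scale = init_scale
        self.random_state = random_state

    # -- fitting ----------------------------------------------------------
    def fit(self, X, y, validation=None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training set contains a single class")
        self._class_index = {c: i for i, c in enumerate(self.classes_)}
        n_out = len(self.classes_)

        self.input_means_ = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.ones(X.shape[1])
        self.input_sds_ = np.where(sds > 0, sds, 1.0)
        Xs = (X - self.input_means_) / self.input_sds_
        T = np.eye(n_out)[[self._class_index[c] for c in y]]

        val = None
        if validation is not None:
            Xv, yv = validation
            Xv = (np.asarray(Xv, float) - self.input_means_) / self.input_sds_
            Tv = np.eye(n_out)[[self._class_index[c] for c in np.asarray(yv)]]
            val = (Xv, Tv)

        rng = np.random.default_rng(int(self.random_state))
        n_params = (X.shape[1] + 1) * self.hidden_units \
            + (self.hidden_units + 1) * n_out
        x0 = rng.uniform(-self.init_scale, self.init_scale, n_params)

        if self.solver == "bfgs":
            params = self._fit_bfgs(x0, Xs, T, val, n_out)
        elif self.solver == "sgd":
            params = self._fit_sgd(x0, Xs, T, val, n_out)
        else:
            raise ValueError(f"unknown solver {self.solver!r}")

        W1, b1, W2, b2 = _unpack(params, X.shape[1], self.hidden_units, n_out)
        self.coefs_ = [W1, W2]
        self.intercepts_ = [b1, b2]
        self._params = params
        self.n_features_in_ = X.shape[1]
        return self

    def _track(self, params, Xs, T, val, n_out, state):
        loss = _ce_loss(params, Xs, T, self.hidden_units, n_out)
        state["train"].append(loss)
        if val is not None:
            vloss = _ce_loss(params, val[0], val[1], self.hidden_units, n_out)
            state["val"].append(vloss)
            if vloss < state["best_val"]:
                state["best_val"] = vloss
                state["best_params"] = params.copy()

    def _fit_bfgs(self, x0, Xs, T, val, n_out):
        state = {"train": [], "val": [], "best_val": np.inf,
                 "best_params": None}
        self._track(x0, Xs, T, val, n_out, state)
        res = minimize(
            _loss_grad, x0, args=(Xs, T, self.hidden_units, n_out),
            method="BFGS", jac=True,
            callback=lambda xk: self._track(xk, Xs, T, val, n_out, state),
            options={"maxiter": self.max_iter, "gtol": 1e-8})
        self.loss_curve_ = np.asarray(state["train"])
        self.validation_curve_ = np.asarray(state["val"])
        self.n_iter_ = int(res.nit)
        if val is not None and state["best_params"] is not None:
            return state["best_params"]
        return res.x

    def _fit_sgd(self, x0, Xs, T, val, n_out):
        state = {"train": [], "val": [], "best_val": np.inf,
                 "best_params": None}
        params = x0.copy()
        velocity = np.zeros_like(params)
        for _ in range(self.max_iter):
            _, grad = _loss_grad(params, Xs, T, self.hidden_units, n_out)
            velocity = self.momentum * velocity - self.learning_rate * grad
            params += velocity
            self._track(params, Xs, T, val, n_out, state)
        self.loss_curve_ = np.asarray(state["train"])
        self.validation_curve_ = np.asarray(state["val"])
        self.n_iter_ = self.max_iter
        if val is not None and state["best_params"] is not None:
            return state["best_params"]
        return params

    # -- inference --------------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError("feature dimension mismatch")
        Xs = (X - self.input_means_) / self.input_sds_
        P, _ = _forward(self._params, Xs, self.hidden_units,
                        len(self.classes_))
        return P

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    # -- persistence ------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "classes": self.classes_.tolist(),
            "hidden_units": self.hidden_units,
            "params": self._params.tolist(),
            "input_means": self.input_means_.tolist(),
            "input_sds": self.input_sds_.tolist(),
            "n_features_in": self.n_features_in_,
            "loss_curve": self.loss_curve_.tolist(),
        }, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MLPDisfluencyClassifier":
        obj = json.loads(text)
        est = cls(hidden_units=obj["hidden_units"])
        est.classes_ = np.asarray(obj["classes"])
        est._class_index = {c: i for i, c in enumerate(est.classes_)}
        est._params = np.asarray(obj["params"])
        est.input_means_ = np.asarray(obj["input_means"])
        est.input_sds_ = np.asarray(obj["input_sds"])
        est.n_features_in_ = int(obj["n_features_in"])
        est.loss_curve_ = np.asarray(obj["loss_curve"])
        n_out = len(est.classes_)
        W1, b1, W2, b2 = _unpack(est._params, est.n_features_in_,
                                 est.hidden_units, n_out)
        est.coefs_ = [W1, W2]
        est.intercepts_ = [b1, b2]
        return est


def train_mlp(train, validation=None, hidden: int = 8, iters: int = 100,
              seed: int = 0, solver: str = "bfgs") -> MLPDisfluencyClassifier:
    """Functional wrapper: ``train``/``validation`` are (X, y) pairs."""
    X, y = train
    est = MLPDisfluencyClassifier(hidden_units=hidden, max_iter=iters,
                                  random_state=seed, solver=solver)
    return est.fit(X, y, validation=validation)


def predict_proba(model: MLPDisfluencyClassifier, features) -> np.ndarray:
    return model.predict_proba(features)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    """Test-set summary: confusion matrix (rows = true class), per-class
    and overall accuracy, error rate, per-case certainty."""

    labels: list[str]
    confusion: np.ndarray
    accuracy: float
    error_rate: float
    per_class_accuracy: dict[str, float]
    certainty: np.ndarray = field(repr=False, default=None)
    n_test: int = 0

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "error_rate": self.error_rate,
            "per_class_accuracy": dict(self.per_class_accuracy),
            "certainty": [round(float(c), 10) for c in self.certainty],
            "n_test": self.n_test,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    def __str__(self) -> str:
        lines = [f"overall accuracy acc = {self.accuracy:.4f}  "
                 f"(error rate eps = {self.error_rate:.4f}, "
                 f"n = {self.n_test})"]
        for lab in self.labels:
            lines.append(f"  {lab:<13s} accuracy "
                         f"{self.per_class_accuracy[lab]:.4f}")
        return "\n".join(lines)


def evaluate(model: MLPDisfluencyClassifier, test_features, test_labels,
             labels: list[str] | None = None) -> ClassificationReport:
    """Confusion matrix and accuracy metrics on a held-out test set."""
    y = np.asarray(test_labels)
    if y.size == 0:
        raise ValueError("empty test set")
    P = model.predict_proba(np.asarray(test_features, float))
    pred = model.classes_[np.argmax(P, axis=1)]
    if labels is None:
        labels = [c for c in CLASSES if c in set(y) | set(model.classes_)]
    lut = {c: i for i, c in enumerate(labels)}
    conf = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(y, pred):
        conf[lut[t], lut[p]] += 1
    n_correct = int(np.trace(conf))
    acc = n_correct / y.size
    per_class = {}
    for lab in labels:
        row = conf[lut[lab]]
        per_class[lab] = float(row[lut[lab]] / row.sum()) if row.sum() else \
            float("nan")
    return ClassificationReport(
        labels=list(labels), confusion=conf, accuracy=acc,
        error_rate=1.0 - acc, per_class_accuracy=per_class,
        certainty=P.max(axis=1), n_test=int(y.size))
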