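"""Small feed-forward networks with dropout, balanced loss and early stopping.

All supervised heads in this package (clinical-score regression, target and
tractability classification, PPI and compound-target link prediction) share
one architecture family: an input layer of concatenated embeddings, 0-3
ReLU hidden layers, inverted dropout, an Adam optimiser, a class-balanced
loss for the classifiers, and patience-based early stopping on a validation
split.  Hyperparameter grids are expressed as :class:`MLPSpec` values whose
canonical names (e.g. ``H100-N2-D0.2``) round-trip through :func:`MLPSpec.parse`.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MLPSpec:
    """One grid point: number of hidden layers, hidden size, dropout rate."""

    hidden_layers: int
    hidden_size: int
    dropout: float

    @property
    def name(self) -> str:
        return f"H{self.hidden_size}-N{self.hidden_layers}-D{self.dropout:g}"

    @classmethod
    def parse(cls, name: str) -> "MLPSpec":
        """Parse ``H100-N2-D0.2`` (fractional dropout) or ``D40-N2-S60``
        (percent dropout with S for size)."""
        m = re.fullmatch(r"H(\d+)-N(\d+)-D([\d.]+)", name)
        if m:
            return cls(hidden_layers=int(m.group(2)), hidden_size=int(m.group(1)),
                       dropout=float(m.group(3)))
        m = re.fullmatch(r"D(\d+)-N(\d+)-S(\d+)", name)
        if m:
            return cls(hidden_layers=int(m.group(2)), hidden_size=int(m.group(3)),
                       dropout=int(m.group(1)) / 100.0)
        raise ValueError(f"unrecognised model name: {name!r}")


def hyperparameter_grid(
    hidden_layers: tuple[int, ...] = (1, 2),
    hidden_sizes: tuple[int, ...] = (1, 5, 10, 20, 50, 100),
    dropouts: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4),
) -> list[MLPSpec]:
    """The standard tuning grid: 2 layer counts x 6 sizes x 5 dropouts = 60."""
    return [MLPSpec(n, h, d) for n, h, d in
            itertools.product(hidden_layers, hidden_sizes, dropouts)]


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


class FeedForward:
    """Minimal dense network: ReLU hiddens, sigmoid/linear head, Adam.

    ``task`` is ``"classify"`` (sigmoid outputs, binary cross-entropy,
    optionally class-balanced per output column) or ``"regress"`` (linear
    outputs, mean squared error).  ``hidden_layers=0`` yields a logistic /
    linear model on the raw features.
    """

    def __init__(self, n_inputs: int, hidden_layers: int = 1, hidden_size: int = 32,
                 n_outputs: int = 1, dropout: float = 0.0, task: str = "classify",
                 seed: int = 0):
        if task not in ("classify", "regress"):
            raise ValueError(f"unknown task {task!r}")
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        self.task = task
        self.dropout = dropout
        self.seed = seed
        sizes = [n_inputs] + [hidden_size] * hidden_layers + [n_outputs]
        rng = np.random.default_rng(seed)
        self.W = [rng.normal(0.0, np.sqrt(2.0 / sizes[i]), (sizes[i], sizes[i + 1]))
                  for i in range(len(sizes) - 1)]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self._rng = rng

    @classmethod
    def from_spec(cls, n_inputs: int, spec: MLPSpec, n_outputs: int = 1,
                  task: str = "classify", seed: int = 0) -> "FeedForward":
        return cls(n_inputs, hidden_layers=spec.hidden_layers,
                   hidden_size=spec.hidden_size, n_outputs=n_outputs,
                   dropout=spec.dropout, task=task, seed=seed)

    def _forward(self, X: np.ndarray, train: bool) -> tuple[list, np.ndarray]:
        acts = [X]
        a = X
        n_layers = len(self.W)
        masks = []
        for i in range(n_layers - 1):
            a = _relu(a @ self.W[i] + self.b[i])
            if train and self.dropout > 0:
                m = (self._rng.random(a.shape) >= self.dropout) / (1.0 - self.dropout)
                a = a * m
                masks.append(m)
            else:
                masks.append(None)
            acts.append(a)
        z = a @ self.W[-1] + self.b[-1]
        out = _sigmoid(z) if self.task == "classify" else z
        self._masks = masks
        return acts, out

    def _loss(self, out: np.ndarray, y: np.ndarray, sw: np.ndarray) -> float:
        if self.task == "classify":
            eps = 1e-12
            ll = -(y * np.log(out + eps) + (1 - y) * np.log(1 - out + eps))
            return float(np.mean(ll * sw))
        return float(np.mean(((out - y) ** 2) * sw))

    def fit(self, X: np.ndarray, y: np.ndarray,
            X_val: np.ndarray | None = None, y_val: np.ndarray | None = None,
            epochs: int = 100, batch_size: int = 64, lr: float = 1e-3,
            patience: int = 2, balanced: bool = True,
            validation_fraction: float = 0.1) -> "FeedForward":
        """Train with Adam; stop when validation loss fails to improve for
        ``patience`` consecutive epochs; restore the best weights.

        With ``balanced=True`` (classification) each example is weighted
        inversely to its class frequency, per output column, so a 9:1
        imbalance does not collapse the minority class.
        """
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if y.ndim == 1:
            y = y[:, None]
        if self.task == "classify":
            for j in range(y.shape[1]):
                if len(np.unique(y[:, j])) < 2:
                    raise ValueError(f"single-class labels in output column {j}")
        if X_val is None:
            n_val = max(1, int(round(validation_fraction * len(X))))
            perm = np.random.default_rng(self.seed + 1).permutation(len(X))
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            X_val, y_val = X[val_idx], y[val_idx]
            X, y = X[tr_idx], y[tr_idx]
        else:
            y_val = np.asarray(y_val, dtype=np.float64)
            if y_val.ndim == 1:
                y_val = y_val[:, None]

        if self.task == "classify" and balanced:
            sw = np.empty_like(y)
            for j in range(y.shape[1]):
                pos = max(y[:, j].sum(), 1.0)
                neg = max(len(y) - y[:, j].sum(), 1.0)
                sw[:, j] = np.where(y[:, j] == 1, len(y) / (2 * pos), len(y) / (2 * neg))
        else:
            sw = np.ones_like(y)
        sw_val = np.ones_like(y_val)

        mW = [np.zeros_like(w) for w in self.W]
        vW = [np.zeros_like(w) for w in self.W]
        mb = [np.zeros_like(b) for b in self.b]
        vb = [np.zeros_like(b) for b in self.b]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_loss = np.inf
        best_weights = None
        bad = 0
        order_rng = np.random.default_rng(self.seed + 2)
        for _epoch in range(epochs):
            order = order_rng.permutation(len(X))
            for start in range(0, len(X), batch_size):
                idx = order[start:start + batch_size]
                xb, yb, swb = X[idx], y[idx], sw[idx]
                acts, out = self._forward(xb, train=True)
                n = len(xb)
                # d(loss)/dz at the head is (out - y) for both BCE+sigmoid and MSE
                scale = 1.0 if self.task == "classify" else 2.0
                delta = scale * (out - yb) * swb / (n * yb.shape[1])
                grads_W, grads_b = [], []
                for i in range(len(self.W) - 1, -1, -1):
                    grads_W.append(acts[i].T @ delta)
                    grads_b.append(delta.sum(axis=0))
                    if i > 0:
                        delta = delta @ self.W[i].T
                        if self._masks[i - 1] is not None:
                            delta = delta * self._masks[i - 1]
                        delta = delta * (acts[i] > 0)
                grads_W.reverse()
                grads_b.reverse()
                step += 1
                for i in range(len(self.W)):
                    mW[i] = beta1 * mW[i] + (1 - beta1) * grads_W[i]
                    vW[i] = beta2 * vW[i] + (1 - beta2) * grads_W[i] ** 2
                    mb[i] = beta1 * mb[i] + (1 - beta1) * grads_b[i]
                    vb[i] = beta2 * vb[i] + (1 - beta2) * grads_b[i] ** 2
                    corr1 = 1 - beta1 ** step
                    corr2 = 1 - beta2 ** step
                    self.W[i] -= lr * (mW[i] / corr1) / (np.sqrt(vW[i] / corr2) + eps)
                    self.b[i] -= lr * (mb[i] / corr1) / (np.sqrt(vb[i] / corr2) + eps)
            _, val_out = self._forward(X_val, train=False)
            val_loss = self._loss(val_out, y_val, sw_val)
            if val_loss < best_loss - 1e-9:
                best_loss = val_loss
                best_weights = ([w.copy() for w in self.W], [b.copy() for b in self.b])
                bad = 0
            else:
                bad += 1
                if bad >= patience:
                    break
        if best_weights is not None:
            self.W, self.b = best_weights
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        _, out = self._forward(np.asarray(X, dtype=np.float64), train=False)
        return out

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        out = self.predict_proba(X)
        if self.task == "regress":
            return out
        return (out >= threshold).astype(int)


def matthews_corrcoef(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """MCC in [-1, 1]; defined as 0 when the denominator vanishes."""
    y_true = np.asarray(y_true).ravel().astype(int)
    y_pred = np.asarray(y_pred).ravel().astype(int)
    tp = float(np.sum((y_true == 1) & (y_pred == 1)))
    tn = float(np.sum((y_true == 0) & (y_pred == 0)))
    fp = float(np.sum((y_true == 0) & (y_pred == 1)))
    fn = float(np.sum((y_true == 1) & (y_pred == 0)))
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def classification_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    y_true = np.asarray(y_true).ravel().astype(int)
    y_pred = np.asarray(y_pred).ravel().astype(int)
    tp = float(np.sum((y_true == 1) & (y_pred == 1)))
    fp = float(np.sum((y_true == 0) & (y_pred == 1)))
    fn = float(np.sum((y_true == 1) & (y_pred == 0)))
    acc = float(np.mean(y_true == y_pred)) if len(y_true) else 0.0
    prec = tp / (tp + fp) if tp + fp > 0 else 0.0
    rec = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
    return {"accuracy": acc, "precision": prec, "recall": rec, "f1": f1,
            "mcc": matthews_corrcoef(y_true, y_pred)}
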