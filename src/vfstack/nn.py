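"""A small, fully seeded feed-forward network for tabular binary targets.

This engine exists because the stacked-weight construction needs direct
access to the penultimate-layer activations and the output-layer weight
matrix of the base networks, plus training options (softmax hidden
activation, RMSprop, batch normalization, dropout, decoupled epochs with
early stopping) that no single off-the-shelf estimator exposes together.
It supports multi-head binary outputs (one sigmoid unit per head) with
equal head weighting under binary cross-entropy.

Everything is plain NumPy with float64 parameters; training is
deterministic given the seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["MiniMLP"]

_EPS = 1e-8


def _act_forward(name: str, z: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    if name == "softmax":
        e = np.exp(z - z.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)
    if name == "identity":
        return z
    raise ValueError(f"unknown activation {name!r}")


def _act_backward(name: str, a: np.ndarray, z: np.ndarray, grad: np.ndarray) -> np.ndarray:
    if name == "relu":
        return grad * (z > 0)
    if name == "sigmoid":
        return grad * a * (1.0 - a)
    if name == "softmax":
        return a * (grad - (grad * a).sum(axis=1, keepdims=True))
    if name == "identity":
        return grad
    raise ValueError(f"unknown activation {name!r}")


@dataclass
class _Dense:
    W: np.ndarray
    b: np.ndarray
    activation: str
    batch_norm: bool = False
    gamma: Optional[np.ndarray] = None
    beta: Optional[np.ndarray] = None
    run_mean: Optional[np.ndarray] = None
    run_var: Optional[np.ndarray] = None


class MiniMLP:
    """Feed-forward binary classifier with one sigmoid output per head.

    Parameters mirror the conventions of the field's tabular MLPs: hidden
    layer sizes, a single hidden activation, optional batch normalization
    and dropout between hidden layers, SGD/RMSprop/Adam optimizers with L2
    weight decay, minibatch training with early stopping on a held-out
    validation fraction (patience in epochs, best weights restored).
    """

    def __init__(
        self,
        n_in: int,
        hidden: Sequence[int] = (128, 64),
        n_out: int = 1,
        activation: str = "sigmoid",
        batch_norm: bool = False,
        dropout: float = 0.0,
        optimizer: str = "adam",
        lr: float = 1e-3,
        weight_decay: float = 0.0,
        batch_size: int = 32,
        max_epochs: int = 25,
        patience: int = 3,
        validation_fraction: float = 0.1,
        seed: int = 0,
    ) -> None:
        if optimizer not in ("sgd", "rmsprop", "adam"):
            raise ValueError(f"unknown optimizer {optimizer!r}")
        self.n_in = int(n_in)
        self.hidden = tuple(int(h) for h in hidden)
        self.n_out = int(n_out)
        self.activation = activation
        self.batch_norm = batch_norm
        self.dropout = float(dropout)
        self.optimizer = optimizer
        self.lr = float(lr)
        self.weight_decay = float(weight_decay)
        self.batch_size = int(batch_size)
        self.max_epochs = int(max_epochs)
        self.patience = int(patience)
        self.validation_fraction = float(validation_fraction)
        self.seed = int(seed)
        self._rng = np.random.default_rng(seed)
        self.layers: List[_Dense] = []
        sizes = (self.n_in, *self.hidden, self.n_out)
        for i in range(len(sizes) - 1):
            fan_in, fan_out = sizes[i], sizes[i + 1]
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            W = self._rng.uniform(-limit, limit, size=(fan_in, fan_out))
            last = i == len(sizes) - 2
            layer = _Dense(
                W=W,
                b=np.zeros(fan_out),
                activation="sigmoid" if last else activation,
                batch_norm=batch_norm and not last,
            )
            if layer.batch_norm:
                layer.gamma = np.ones(fan_out)
                layer.beta = np.zeros(fan_out)
                layer.run_mean = np.zeros(fan_out)
                layer.run_var = np.ones(fan_out)
            self.layers.append(layer)
        self._opt_state: dict = {}
        self._t = 0
        self.fitted_ = False
        self.n_epochs_run_ = 0
        self.best_epoch_ = 0
        self.train_log_: List[dict] = []

    # ------------------------------------------------------------- forward

    def _forward(self, X: np.ndarray, training: bool, rng: Optional[np.random.Generator] = None):
        cache = []
        a = X
        for li, layer in enumerate(self.layers):
            z = a @ layer.W + layer.b
            entry = {"a_in": a, "z": z}
            if layer.batch_norm:
                if training:
                    mu = z.mean(axis=0)
                    var = z.var(axis=0)
                    layer.run_mean = 0.9 * layer.run_mean + 0.1 * mu
                    layer.run_var = 0.9 * layer.run_var + 0.1 * var
                else:
                    mu, var = layer.run_mean, layer.run_var
                istd = 1.0 / np.sqrt(var + _EPS)
                zn = (z - mu) * istd
                zb = layer.gamma * zn + layer.beta
                entry.update({"zn": zn, "istd": istd})
            else:
                zb = z
            act = _act_forward(layer.activation, zb)
            entry["zb"] = zb
            entry["act"] = act
            if training and self.dropout > 0.0 and li < len(self.layers) - 1:
                mask = (rng.random(act.shape) >= self.dropout) / (1.0 - self.dropout)
                act = act * mask
                entry["drop_mask"] = mask
            entry["out"] = act
            cache.append(entry)
            a = act
        return a, cache

    def _backward(self, cache, Y: np.ndarray):
        n = Y.shape[0]
        grads = []
        # output: sigmoid + BCE with equal head weighting
        p = cache[-1]["out"]
        delta = (p - Y) / (n * self.n_out)
        for li in range(len(self.layers) - 1, -1, -1):
            layer = self.layers[li]
            entry = cache[li]
            if li == len(self.layers) - 1:
                dz_bn = delta  # already d loss / d zb via sigmoid-BCE shortcut
            else:
                g = delta
                if "drop_mask" in entry:
                    g = g * entry["drop_mask"]
                dz_bn = _act_backward(layer.activation, entry["act"], entry["zb"], g)
            if layer.batch_norm:
                zn, istd = entry["zn"], entry["istd"]
                dgamma = (dz_bn * zn).sum(axis=0)
                dbeta = dz_bn.sum(axis=0)
                m = dz_bn.shape[0]
                dz = (layer.gamma * istd / m) * (
                    m * dz_bn - dz_bn.sum(axis=0) - zn * (dz_bn * zn).sum(axis=0)
                )
            else:
                dgamma = dbeta = None
                dz = dz_bn
            dW = entry["a_in"].T @ dz + self.weight_decay * layer.W
            db = dz.sum(axis=0)
            grads.append((li, dW, db, dgamma, dbeta))
            delta = dz @ layer.W.T
        return grads

    # ------------------------------------------------------------ optimizer

    def _update(self, grads):
        self._t += 1
        for li, dW, db, dgamma, dbeta in grads:
            layer = self.layers[li]
            parts = [("W", layer.W, dW), ("b", layer.b, db)]
            if dgamma is not None:
                parts += [("gamma", layer.gamma, dgamma), ("beta", layer.beta, dbeta)]
            for pname, param, grad in parts:
                key = (li, pname)
                if self.optimizer == "sgd":
                    param -= self.lr * grad
                elif self.optimizer == "rmsprop":
                    s = self._opt_state.setdefault(key, np.zeros_like(param))
                    s *= 0.9
                    s += 0.1 * grad * grad
                    param -= self.lr * grad / (np.sqrt(s) + _EPS)
                else:  # adam
                    m, v = self._opt_state.setdefault(
                        key, (np.zeros_like(param), np.zeros_like(param))
                    )
                    m *= 0.9
                    m += 0.1 * grad
                    v *= 0.999
                    v += 0.001 * grad * grad
                    mhat = m / (1.0 - 0.9 ** self._t)
                    vhat = v / (1.0 - 0.999 ** self._t)
                    param -= self.lr * mhat / (np.sqrt(vhat) + _EPS)

    # ------------------------------------------------------------- training

    def _loss(self, X: np.ndarray, Y: np.ndarray) -> float:
        p, _ = self._forward(X, training=False)
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        return float(-(Y * np.log(p) + (1 - Y) * np.log(1 - p)).mean())

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "MiniMLP":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if X.shape[1] != self.n_in or Y.shape[1] != self.n_out:
            raise ValueError("feature/target dimensions do not match the network")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
            raise ValueError("non-finite values in training inputs")
        n = X.shape[0]
        rng = self._rng
        n_val = int(round(n * self.validation_fraction))
        use_val = 0 < n_val < n
        perm = rng.permutation(n)
        if use_val:
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
        else:
            val_idx, tr_idx = np.array([], dtype=int), perm
        Xtr, Ytr = X[tr_idx], Y[tr_idx]
        Xval, Yval = X[val_idx], Y[val_idx]

        best_loss = np.inf
        best_state = None
        stall = 0
        for epoch in range(1, self.max_epochs + 1):
            order = rng.permutation(len(Xtr))
            for start in range(0, len(Xtr), self.batch_size):
                idx = order[start:start + self.batch_size]
                if len(idx) < 2 and self.batch_norm:
                    continue  # batch statistics undefined on a single sample
                _, cache = self._forward(Xtr[idx], training=True, rng=rng)
                grads = self._backward(cache, Ytr[idx])
                self._update(grads)
            self.n_epochs_run_ = epoch
            monitor = self._loss(Xval, Yval) if use_val else self._loss(Xtr, Ytr)
            self.train_log_.append({"epoch": epoch, "monitor_loss": monitor})
            if monitor < best_loss - 1e-5:
                best_loss = monitor
                best_state = self._snapshot()
                self.best_epoch_ = epoch
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
        if best_state is not None:
            self._restore(best_state)
        self.fitted_ = True
        return self

    def _snapshot(self):
        return copy.deepcopy(
            [(l.W, l.b, l.gamma, l.beta, l.run_mean, l.run_var) for l in self.layers]
        )

    def _restore(self, state):
        for layer, (W, b, gamma, beta, rm, rv) in zip(self.layers, state):
            layer.W, layer.b = W, b
            layer.gamma, layer.beta = gamma, beta
            layer.run_mean, layer.run_var = rm, rv

    # ------------------------------------------------------------ inference

    def _check_fitted(self) -> None:
        if not self.fitted_:
            raise RuntimeError("model is not fitted")

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        self._check_fitted()
        p, _ = self._forward(np.asarray(X, dtype=float), training=False)
        return p

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)

    def score(self, X: np.ndarray, Y: np.ndarray) -> float:
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        return float((self.predict(X) == Y).mean())

    def hidden_activations(self, X: np.ndarray) -> np.ndarray:
        """Penultimate-layer activations (no dropout, eval-mode BN)."""
        self._check_fitted()
        _, cache = self._forward(np.asarray(X, dtype=float), training=False)
        return cache[-2]["out"]

    @property
    def output_weights(self) -> np.ndarray:
        """Output-layer weight matrix, shape (penultimate_width, n_out)."""
        return self.layers[-1].W
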