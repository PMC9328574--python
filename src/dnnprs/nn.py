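"""A small feed-forward network engine on numpy.

This is the compute kernel behind both the per-gene screening networks and the
stacked transfer model: fully-connected ReLU layers with a linear output head,
inverted dropout after the first hidden layer, Adam updates, and analytic
backpropagation (verified against finite differences in the test suite).

Everything is deterministic given an explicit seed / Generator: weight
initialisation, minibatch order and dropout masks all draw from caller-supplied
streams, and inference applies no dropout, so repeated forward passes on the
same inputs are bitwise identical.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "FeedForward",
    "Adam",
    "train_network",
    "per_sample_loss",
    "sigmoid",
    "auto_batch_size",
]

FULL_BATCH_LIMIT = 1024  # full-batch updates at or below this many training rows
DEFAULT_MINIBATCH = 256


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def auto_batch_size(n: int) -> int:
    return n if n <= FULL_BATCH_LIMIT else DEFAULT_MINIBATCH


class FeedForward:
    """Multi-layer perceptron ``sizes[0] -> ... -> sizes[-1]`` (linear head).

    Hidden layers use ReLU; the output layer is linear (a logistic transform is
    applied outside when the outcome is binary, so the head always produces the
    linear predictor). ``dropout_rate`` > 0 enables inverted dropout after the
    first hidden layer during training only.
    """

    def __init__(self, sizes: list[int], seed: int, dropout_rate: float = 0.0):
        if len(sizes) < 2 or any(s <= 0 for s in sizes):
            raise ValueError(f"invalid layer sizes {sizes}")
        if not 0.0 <= dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {dropout_rate}")
        self.sizes = list(sizes)
        self.dropout_rate = float(dropout_rate)
        rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for n_in, n_out in zip(sizes[:-1], sizes[1:]):
            # He initialisation for ReLU stacks
            self.weights.append(rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in))
            self.biases.append(np.zeros(n_out))

    # -- parameter access ---------------------------------------------------

    @property
    def parameters(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for w, b in zip(self.weights, self.biases):
            out.extend((w, b))
        return out

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters)

    @property
    def n_hidden_parameters(self) -> int:
        """Parameters excluding the output head (the transferable part)."""
        return sum(p.size for p in self.parameters[:-2])

    def checksum(self) -> float:
        """A scalar fingerprint of all parameters (used by freeze contracts)."""
        return float(sum(np.sum(np.abs(p)) + np.sum(p * p) for p in self.parameters))

    # -- forward / backward -------------------------------------------------

    def _forward(
        self,
        X: np.ndarray,
        n_layers: int,
        train: bool,
        drop_rng: np.random.Generator | None,
    ) -> tuple[np.ndarray, dict]:
        a = np.asarray(X, dtype=float)
        acts = [a]
        drop_mask = None
        for l in range(n_layers):
            z = a @ self.weights[l] + self.biases[l]
            if l < len(self.sizes) - 2:  # hidden layer -> ReLU
                a = np.maximum(z, 0.0)
                if l == 0 and train and self.dropout_rate > 0.0:
                    if drop_rng is None:
                        raise ValueError("training forward pass needs a dropout Generator")
                    drop_mask = (drop_rng.random(a.shape) >= self.dropout_rate) / (
                        1.0 - self.dropout_rate
                    )
                    a = a * drop_mask
            else:
                a = z  # output head (or requested stop at a linear layer)
            acts.append(a)
        cache = {"acts": acts, "drop_mask": drop_mask, "n_layers": n_layers}
        return a, cache

    def forward(
        self,
        X: np.ndarray,
        train: bool = False,
        drop_rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """Full forward pass; returns ``(output of shape (n,), cache)``."""
        out, cache = self._forward(X, len(self.sizes) - 1, train, drop_rng)
        return out[:, 0] if out.shape[1] == 1 else out, cache

    def hidden_forward(
        self,
        X: np.ndarray,
        train: bool = False,
        drop_rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """Forward through hidden layers only (dropout active only if ``train``)."""
        return self._forward(X, len(self.sizes) - 2, train=train, drop_rng=drop_rng)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic output of the linear head, shape (n,)."""
        return self.forward(X)[0]

    def last_hidden(self, X: np.ndarray) -> np.ndarray:
        """Activation of the last hidden layer, shape (n, sizes[-2])."""
        return self.hidden_forward(X)[0]

    def backward(self, cache: dict, grad_out: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        """Gradients for a cached forward pass.

        ``grad_out`` is dLoss/d(final activation of that pass), shaped (n,) for
        a full pass or (n, width) for a hidden pass. Returns gradients aligned
        with ``parameters[: 2 * n_layers]`` and the gradient w.r.t. the input.
        """
        acts = cache["acts"]
        n_layers = cache["n_layers"]
        g = np.asarray(grad_out, dtype=float)
        if g.ndim == 1:
            g = g[:, None]
        w_grads: list[np.ndarray] = [np.empty(0)] * n_layers
        b_grads: list[np.ndarray] = [np.empty(0)] * n_layers
        for l in range(n_layers - 1, -1, -1):
            a_out = acts[l + 1]
            is_hidden = l < len(self.sizes) - 2
            if is_hidden:
                if l == 0 and cache["drop_mask"] is not None:
                    # a_out = relu(z) * mask; relu active where a_out != 0
                    g = g * cache["drop_mask"]
                    g = g * (acts[1] != 0.0)
                else:
                    g = g * (a_out > 0.0)
            w_grads[l] = acts[l].T @ g
            b_grads[l] = g.sum(axis=0)
            g = g @ self.weights[l].T
        grads: list[np.ndarray] = []
        for wg, bg in zip(w_grads, b_grads):
            grads.extend((wg, bg))
        return grads, g


class Adam:
    """Adam updates over a list of parameter arrays (updated in place)."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * (g * g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def per_sample_loss(out: np.ndarray, y: np.ndarray, outcome_type: str) -> np.ndarray:
    """Per-subject loss given the linear-head output.

    Squared error for continuous outcomes; cross entropy (on the logistic
    transform of the head) for binary ones.
    """
    if outcome_type == "continuous":
        return (y - out) ** 2
    if outcome_type == "binary":
        p = np.clip(sigmoid(out), 1e-12, 1.0 - 1e-12)
        return -(y * np.log(p) + (1.0 - y) * np.log1p(-p))
    raise ValueError(f"unknown outcome_type {outcome_type!r}")


def _loss_grad(out: np.ndarray, y: np.ndarray, outcome_type: str) -> tuple[float, np.ndarray]:
    """Mean loss and its gradient w.r.t. the linear-head output."""
    n = len(y)
    if outcome_type == "continuous":
        resid = out - y
        return float(np.mean(resid**2)), 2.0 * resid / n
    p = sigmoid(out)
    loss = float(np.mean(per_sample_loss(out, y, "binary")))
    return loss, (p - y) / n


def train_network(
    net: FeedForward,
    X: np.ndarray,
    y: np.ndarray,
    outcome_type: str,
    epochs: int,
    learning_rate: float = 1e-3,
    batch_size: int | None = None,
    seed: int = 0,
) -> list[float]:
    """Train ``net`` in place with Adam; returns the mean training loss per epoch.

    Full-batch updates when the training set is small, minibatches of 256
    otherwise; batch order and dropout masks come from ``seed``.
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    bs = batch_size or auto_batch_size(n)
    rng = np.random.default_rng(seed)
    opt = Adam(net.parameters, lr=learning_rate)
    history: list[float] = []
    for _ in range(epochs):
        order = np.arange(n) if bs >= n else rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            out, cache = net.forward(X[idx], train=True, drop_rng=rng)
            loss, gout = _loss_grad(out, y[idx], outcome_type)
            grads, _ = net.backward(cache, gout)
            opt.step(grads)
            epoch_loss += loss * len(idx)
        history.append(epoch_loss / n)
    return history
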