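"""Minimal feed-forward network trainer used by the surrogate models.

Dense/ReLU stacks with inverted dropout, a sigmoid or linear head, Adam
updates, and patience-based early stopping that restores the best
checkpoint seen under a caller-supplied validation monitor. Sized for the
small tabular problems of this package (a few features in, at most a
hundred outputs); everything is plain numpy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.special import expit

__all__ = ["FeedForwardNet", "TrainingResult", "train_network"]

LayerPlan = Sequence[Union[int, Tuple[str, float]]]


def _parse_plan(plan: LayerPlan):
    widths, dropouts = [], []
    for item in plan:
        if isinstance(item, int):
            widths.append(item)
            dropouts.append(0.0)
        else:
            kind, rate = item
            if kind != "dropout":
                raise ValueError(f"unknown layer kind {kind!r}")
            if not widths:
                raise ValueError("dropout cannot precede the first dense layer")
            dropouts[-1] = float(rate)
    return widths, dropouts


class FeedForwardNet:
    """A dense ReLU network with optional per-layer dropout.

    ``hidden_plan`` lists hidden widths in order, with ``("dropout", rate)``
    entries attaching a dropout mask to the preceding dense layer, e.g.
    ``[10, 100, 100, ("dropout", 0.5), 10]``. The output layer applies
    ``output_activation`` ("sigmoid" or "linear").
    """

    def __init__(self, n_inputs: int, hidden_plan: LayerPlan, n_outputs: int,
                 output_activation: str = "linear", seed: int = 0) -> None:
        if output_activation not in ("sigmoid", "linear"):
            raise ValueError("output_activation must be 'sigmoid' or 'linear'")
        widths, dropouts = _parse_plan(hidden_plan)
        self.n_inputs = int(n_inputs)
        self.n_outputs = int(n_outputs)
        self.hidden_widths = widths
        self.dropout_rates = dropouts
        self.output_activation = output_activation
        rng = np.random.default_rng(seed)
        dims = [self.n_inputs] + widths + [self.n_outputs]
        # He initialization, appropriate for ReLU stacks
        self.weights = [
            rng.normal(0.0, np.sqrt(2.0 / dims[i]), size=(dims[i], dims[i + 1]))
            for i in range(len(dims) - 1)
        ]
        self.biases = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]

    # -- inference ---------------------------------------------------------
    def forward(self, X: np.ndarray, rng: Optional[np.random.Generator] = None):
        """Forward pass. With ``rng`` given, dropout is active (training mode)
        and the per-layer caches needed for backprop are returned."""
        a = np.asarray(X, dtype=float)
        caches = []
        n_layers = len(self.weights)
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            last = i == n_layers - 1
            if last:
                out = expit(z) if self.output_activation == "sigmoid" else z
                mask = None
            else:
                out = np.maximum(z, 0.0)
                rate = self.dropout_rates[i]
                if rng is not None and rate > 0.0:
                    mask = (rng.random(out.shape) >= rate) / (1.0 - rate)
                    out = out * mask
                else:
                    mask = None
            caches.append((a, z, mask))
            a = out
        return (a, caches) if rng is not None else a

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)

    # -- training step -----------------------------------------------------
    def _gradients(self, caches, delta):
        """Backpropagate ``delta`` = dLoss/d(pre-activation of output)."""
        grads_W, grads_b = [None] * len(self.weights), [None] * len(self.weights)
        for i in range(len(self.weights) - 1, -1, -1):
            a_in, z, mask = caches[i]
            grads_W[i] = a_in.T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.weights[i].T
                a_prev, z_prev, mask_prev = caches[i - 1]
                if mask_prev is not None:
                    delta = delta * mask_prev
                delta = delta * (z_prev > 0.0)
        return grads_W, grads_b

    def get_state(self):
        return ([W.copy() for W in self.weights], [b.copy() for b in self.biases])

    def set_state(self, state) -> None:
        self.weights = [W.copy() for W in state[0]]
        self.biases = [b.copy() for b in state[1]]

    def to_dict(self) -> dict:
        return {
            "n_inputs": self.n_inputs,
            "n_outputs": self.n_outputs,
            "hidden_widths": self.hidden_widths,
            "dropout_rates": self.dropout_rates,
            "output_activation": self.output_activation,
            "weights": [W.tolist() for W in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeedForwardNet":
        plan: List = []
        for w, r in zip(d["hidden_widths"], d["dropout_rates"]):
            plan.append(int(w))
            if r > 0:
                plan.append(("dropout", float(r)))
        net = cls(d["n_inputs"], plan, d["n_outputs"], d["output_activation"])
        net.weights = [np.asarray(W, dtype=float) for W in d["weights"]]
        net.biases = [np.asarray(b, dtype=float) for b in d["biases"]]
        return net


@dataclass
class TrainingResult:
    """Outcome of a training run: epochs run, best epoch and monitor score."""

    epochs: int
    best_epoch: int
    best_score: float
    history: List[float]


def train_network(
    net: FeedForwardNet,
    X: np.ndarray,
    y: np.ndarray,
    loss: str,
    monitor: Callable[[FeedForwardNet], float],
    higher_is_better: bool,
    batch_size: int = 32,
    max_epochs: int = 4000,
    patience: int = 200,
    learning_rate: float = 1.0e-3,
    seed: int = 0,
) -> TrainingResult:
    """Mini-batch Adam training with best-checkpoint early stopping.

    ``loss`` is "bce" (binary cross-entropy on a sigmoid head) or "mae"
    (mean absolute error on a linear head). After every epoch ``monitor``
    scores the current network on held-out data; training stops once the
    monitor has not improved for ``patience`` epochs, and the weights of
    the best epoch are restored.
    """
    if loss not in ("bce", "mae"):
        raise ValueError("loss must be 'bce' or 'mae'")
    if loss == "bce" and net.output_activation != "sigmoid":
        raise ValueError("bce loss requires a sigmoid output")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)

    mW = [np.zeros_like(W) for W in net.weights]
    vW = [np.zeros_like(W) for W in net.weights]
    mb = [np.zeros_like(b) for b in net.biases]
    vb = [np.zeros_like(b) for b in net.biases]
    beta1, beta2, eps = 0.9, 0.999, 1.0e-8
    t = 0

    sign = 1.0 if higher_is_better else -1.0
    best_score = -np.inf
    best_state = net.get_state()
    best_epoch = 0
    history: List[float] = []

    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb, yb = X[idx], y[idx]
            pred, caches = net.forward(xb, rng=rng)
            m = xb.shape[0]
            if loss == "bce":
                delta = (pred - yb) / m  # sigmoid + log-loss gradient
            else:
                delta = np.sign(pred - yb) / (m * net.n_outputs)
            gW, gb = net._gradients(caches, delta)
            t += 1
            corr1 = 1.0 - beta1**t
            corr2 = 1.0 - beta2**t
            for i in range(len(net.weights)):
                mW[i] = beta1 * mW[i] + (1 - beta1) * gW[i]
                vW[i] = beta2 * vW[i] + (1 - beta2) * gW[i] ** 2
                net.weights[i] -= learning_rate * (mW[i] / corr1) / (np.sqrt(vW[i] / corr2) + eps)
                mb[i] = beta1 * mb[i] + (1 - beta1) * gb[i]
                vb[i] = beta2 * vb[i] + (1 - beta2) * gb[i] ** 2
                net.biases[i] -= learning_rate * (mb[i] / corr1) / (np.sqrt(vb[i] / corr2) + eps)

        score = sign * float(monitor(net))
        history.append(sign * score)
        if score > best_score:
            best_score = score
            best_state = net.get_state()
            best_epoch = epoch
        else:
            if score == best_score:
                # tie: prefer the most-trained checkpoint, but do not
                # extend patience (a saturated monitor must still stop)
                best_state = net.get_state()
            if epoch - best_epoch >= patience:
                break

    net.set_state(best_state)
    return TrainingResult(
        epochs=len(history),
        best_epoch=best_epoch,
        best_score=sign * best_score,
        history=history,
    )
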