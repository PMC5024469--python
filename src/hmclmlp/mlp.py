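"""Single-hidden-layer perceptron trained by stochastic backpropagation.

This is the per-level learner of the HMC-LMLP architecture: one hidden layer,
logistic activations in both layers, per-instance gradient updates with a
momentum term, and distinct learning rates/momenta for the hidden and output
layers.  It is implemented directly (rather than through a generic neural
network library) because the training loop's semantics — seeded per-epoch
shuffling, per-layer rates, momentum buffers that persist across epochs —
are part of the method's contract and are verified by a finite-difference
gradient oracle in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["LevelNet", "TrainHyper", "init_net", "hidden_size", "forward",
           "forward_batch", "train_epoch", "save_net", "load_net"]


@dataclass
class TrainHyper:
    """Backpropagation hyperparameters (per-layer rates and momenta)."""

    lr_hidden: float = 0.05
    lr_output: float = 0.03
    mom_hidden: float = 0.03
    mom_output: float = 0.01
    weight_range: tuple[float, float] = (-0.1, 0.1)
    max_epochs: int = 200

    def __post_init__(self):
        lo, hi = self.weight_range
        if not (lo <= hi):
            raise ValueError("weight_range bounds out of order")
        for v in (self.lr_hidden, self.lr_output, self.mom_hidden, self.mom_output):
            if not np.isfinite(v) or v < 0:
                raise ValueError("rates and momenta must be finite and >= 0")


class LevelNet:
    """Weights of one per-level MLP.

    ``W1`` is (inputs+1) × H with the bias in the last row; ``W2`` is
    (H+1) × O likewise.  ``mom1``/``mom2`` hold the previous weight updates
    for the momentum term.
    """

    def __init__(self, W1: np.ndarray, W2: np.ndarray):
        self.W1 = np.asarray(W1, dtype=float)
        self.W2 = np.asarray(W2, dtype=float)
        if self.W1.shape[1] + 1 != self.W2.shape[0]:
            raise ValueError("hidden layer sizes of W1/W2 disagree")
        self.mom1 = np.zeros_like(self.W1)
        self.mom2 = np.zeros_like(self.W2)

    @property
    def topology(self) -> tuple[int, int, int]:
        return (self.W1.shape[0] - 1, self.W1.shape[1], self.W2.shape[1])

    @property
    def n_inputs(self) -> int:
        return self.W1.shape[0] - 1

    @property
    def n_outputs(self) -> int:
        return self.W2.shape[1]

    @property
    def weight_count(self) -> int:
        """(inputs+1)·H + (H+1)·O, counting biases."""
        return self.W1.size + self.W2.size

    def copy(self) -> "LevelNet":
        net = LevelNet(self.W1.copy(), self.W2.copy())
        net.mom1 = self.mom1.copy()
        net.mom2 = self.mom2.copy()
        return net


def init_net(
    inputs: int,
    hidden: int,
    outputs: int,
    weight_range: tuple[float, float] = (-0.1, 0.1),
    seed: int = 0,
) -> LevelNet:
    """Uniformly initialized net; same seed gives bitwise-identical weights."""
    if inputs <= 0 or hidden <= 0 or outputs <= 0:
        raise ValueError("net dimensions must be positive")
    lo, hi = weight_range
    rng = np.random.default_rng(seed)
    W1 = rng.uniform(lo, hi, size=(inputs + 1, hidden))
    W2 = rng.uniform(lo, hi, size=(hidden + 1, outputs))
    return LevelNet(W1, W2)


def hidden_size(fraction: float, inputs: int) -> int:
    """Hidden-layer width as a fraction of the input width.

    A fraction of 0.6 with 100 inputs gives 60 neurons; the result is
    rounded half-up with a floor of one neuron.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if inputs < 1:
        raise ValueError("inputs must be >= 1")
    return max(1, int(np.floor(fraction * inputs + 0.5)))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def forward(net: LevelNet, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hidden and output activations for one instance (logistic φ)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (net.n_inputs,):
        raise ValueError(f"expected input of length {net.n_inputs}, got {x.shape}")
    h = _sigmoid(x @ net.W1[:-1] + net.W1[-1])
    o = _sigmoid(h @ net.W2[:-1] + net.W2[-1])
    return h, o


def forward_batch(net: LevelNet, X: np.ndarray) -> np.ndarray:
    """Output activations for a batch (vectorized prediction path)."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != net.n_inputs:
        raise ValueError(f"expected {net.n_inputs} input columns, got {X.shape[1]}")
    H = _sigmoid(X @ net.W1[:-1] + net.W1[-1])
    return _sigmoid(H @ net.W2[:-1] + net.W2[-1])


def backprop_gradients(
    net: LevelNet, x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of the half squared error E = ½Σ(o−y)² for one instance."""
    h, o = forward(net, x)
    delta_o = (o - y) * o * (1.0 - o)
    delta_h = (delta_o @ net.W2[:-1].T) * h * (1.0 - h)
    g2 = np.empty_like(net.W2)
    g2[:-1] = np.outer(h, delta_o)
    g2[-1] = delta_o
    g1 = np.empty_like(net.W1)
    g1[:-1] = np.outer(x, delta_h)
    g1[-1] = delta_h
    return g1, g2


def train_epoch(
    net: LevelNet,
    X: np.ndarray,
    Y: np.ndarray,
    hyper: TrainHyper,
    epoch_seed: int | None = None,
    shuffle: bool = True,
) -> float:
    """One pass of per-instance backpropagation updates; returns the MSE.

    Updates are Δw(t) = −lr·∂E/∂w + momentum·Δw(t−1) with the layer's own
    rate and momentum; the visiting order is a seeded shuffle.  The returned
    value is the post-epoch mean over instances of ½Σ_j (o_j − y_j)².
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y row counts differ")
    if Y.shape[1] != net.n_outputs:
        raise ValueError("Y width differs from net outputs")
    if not np.all(np.isfinite(X)):
        raise FloatingPointError("non-finite values in training inputs")

    order = np.arange(X.shape[0])
    if shuffle:
        np.random.default_rng(epoch_seed).shuffle(order)

    W1, W2, m1, m2 = net.W1, net.W2, net.mom1, net.mom2
    for i in order:
        x, y = X[i], Y[i]
        h = _sigmoid(x @ W1[:-1] + W1[-1])
        o = _sigmoid(h @ W2[:-1] + W2[-1])
        delta_o = (o - y) * o * (1.0 - o)
        delta_h = (delta_o @ W2[:-1].T) * h * (1.0 - h)
        m2[:-1] *= hyper.mom_output
        m2[:-1] -= hyper.lr_output * np.outer(h, delta_o)
        m2[-1] = hyper.mom_output * m2[-1] - hyper.lr_output * delta_o
        W2 += m2
        m1[:-1] *= hyper.mom_hidden
        m1[:-1] -= hyper.lr_hidden * np.outer(x, delta_h)
        m1[-1] = hyper.mom_hidden * m1[-1] - hyper.lr_hidden * delta_h
        W1 += m1

    O = forward_batch(net, X)
    return float(np.mean(0.5 * np.sum((O - Y) ** 2, axis=1)))


# ---------------------------------------------------------------------------
# Serialization (portable JSON checkpoints)
# ---------------------------------------------------------------------------

def save_net(net: LevelNet, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "topology": list(net.topology),
        "W1": net.W1.tolist(),
        "W2": net.W2.tolist(),
        "mom1": net.mom1.tolist(),
        "mom2": net.mom2.tolist(),
    }
    path.write_text(json.dumps(payload))
    return path


def load_net(path: str | Path) -> LevelNet:
    payload = json.loads(Path(path).read_text())
    net = LevelNet(np.array(payload["W1"]), np.array(payload["W2"]))
    net.mom1 = np.array(payload["mom1"])
    net.mom2 = np.array(payload["mom2"])
    return net
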