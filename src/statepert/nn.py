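"""Minimal fully-connected networks with hand-written backprop.

Both models in the perturbation engine — the class-label classifier and
the adversarial perturbation generator — are small dense networks trained
full-batch on CPU.  The generator's training signal must flow *through*
the frozen classifier back to the generator's parameters, so the forward
pass of each net returns the caches needed to propagate a gradient to its
input as well as to its weights.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam", "softmax", "softmax_cross_entropy"]


class MLP:
    """Dense network: ReLU hidden layers, linear output.

    Parameters
    ----------
    sizes
        Layer widths, e.g. ``(2000, 512, 128, 6)``.
    rng
        Seeded generator used for He-scaled weight initialisation.
    """

    def __init__(self, sizes: tuple[int, ...], rng: np.random.Generator):
        self.sizes = tuple(int(s) for s in sizes)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for n_in, n_out in zip(self.sizes[:-1], self.sizes[1:]):
            self.weights.append(rng.normal(0.0, np.sqrt(2.0 / n_in),
                                           size=(n_in, n_out)))
            self.biases.append(np.zeros(n_out))

    @property
    def params(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def forward(self, x: np.ndarray):
        """Return (output, caches); x is (batch, n_in)."""
        caches = []
        h = x
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ w + b
            if i < last:
                a = np.maximum(z, 0.0)
            else:
                a = z
            caches.append((h, z))
            h = a
        return h, caches

    def backward(self, d_out: np.ndarray, caches):
        """Backprop ``d_out`` (gradient w.r.t. the linear output).

        Returns (d_input, grads) with grads ordered like ``params``.
        """
        grad_w = [np.empty(0)] * len(self.weights)
        grad_b = [np.empty(0)] * len(self.biases)
        last = len(self.weights) - 1
        d = d_out
        for i in range(last, -1, -1):
            h_in, z = caches[i]
            if i < last:
                d = d * (z > 0.0)
            grad_w[i] = h_in.T @ d
            grad_b[i] = d.sum(axis=0)
            d = d @ self.weights[i].T
        return d, grad_w + grad_b

    def state_dict(self) -> dict:
        state = {"sizes": np.asarray(self.sizes)}
        for i, w in enumerate(self.weights):
            state[f"w{i}"] = w
        for i, b in enumerate(self.biases):
            state[f"b{i}"] = b
        return state

    @classmethod
    def from_state(cls, state: dict) -> "MLP":
        sizes = tuple(int(s) for s in state["sizes"])
        net = cls.__new__(cls)
        net.sizes = sizes
        n_layers = len(sizes) - 1
        net.weights = [np.asarray(state[f"w{i}"], dtype=float)
                       for i in range(n_layers)]
        net.biases = [np.asarray(state[f"b{i}"], dtype=float)
                      for i in range(n_layers)]
        return net


class Adam:
    """Adam optimiser over a list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray], lr_scale: float = 1.0) -> None:
        self.t += 1
        lr = self.lr * lr_scale
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            if self.weight_decay:
                p *= 1.0 - lr * self.weight_decay  # decoupled decay
            p -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y_idx: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(p[np.arange(n), y_idx] + 1e-300).mean()
    d = p.copy()
    d[np.arange(n), y_idx] -= 1.0
    return loss, d / n
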