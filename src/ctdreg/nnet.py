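"""Minimal feed-forward network with hand-written backpropagation.

The impulse-response function of the deconvolutional model is a small
multilayer perceptron trained against a custom exGaussian likelihood, so we
carry our own forward/backward passes and an Adam optimizer rather than
depending on a deep-learning framework.  Networks here are tiny (tens of
units), dense NumPy is ample.

Conventions:
  * tanh hidden activations;
  * the output layer is zero-initialized, so a freshly built network
    contributes exactly nothing to every distributional parameter (the
    model starts at its baseline and learns deviations);
  * parameters are a flat list of arrays, shared with the Adam state.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam"]


class MLP:
    """Fully-connected tanh network: in_dim -> hidden... -> out_dim.

    With no hidden layers this degenerates to a plain linear map, which is
    what the closed-form linear-IRF configuration uses.
    """

    def __init__(self, in_dim, hidden, out_dim, rng, out_bias=False):
        """``out_bias=False`` freezes the output-layer intercept at zero:
        the map then contributes nothing for zero input, so a stimulus
        event can only act through its feature values, never through its
        mere presence (no implicit event-rate channel)."""
        sizes = [int(in_dim)] + [int(h) for h in hidden] + [int(out_dim)]
        self.sizes = sizes
        self.out_bias = bool(out_bias)
        self.params = []
        for i in range(len(sizes) - 1):
            fan_in, fan_out = sizes[i], sizes[i + 1]
            if i == len(sizes) - 2:
                w = np.zeros((fan_in, fan_out))
            else:
                w = rng.normal(0.0, np.sqrt(1.0 / fan_in), size=(fan_in, fan_out))
            b = np.zeros(fan_out)
            self.params += [w, b]
        self._cache = None

    @property
    def n_layers(self):
        return len(self.sizes) - 1

    def forward(self, x, cache=True):
        """x: (n, in_dim) -> (n, out_dim); caches activations for backward."""
        acts = [x]
        h = x
        for i in range(self.n_layers):
            w, b = self.params[2 * i], self.params[2 * i + 1]
            h = h @ w + b
            if i < self.n_layers - 1:
                h = np.tanh(h)
            if cache:
                acts.append(h)
        if cache:
            self._cache = acts
        return h

    def backward(self, d_out):
        """Backprop d_out (n, out_dim) through the cached forward pass.

        Returns (grads, d_x): grads aligned with ``self.params``.
        """
        acts = self._cache
        if acts is None:
            raise RuntimeError("forward(cache=True) must precede backward")
        grads = [None] * len(self.params)
        delta = d_out
        for i in range(self.n_layers - 1, -1, -1):
            w = self.params[2 * i]
            a_in = acts[i]
            grads[2 * i] = a_in.T @ delta
            if i < self.n_layers - 1 or self.out_bias:
                grads[2 * i + 1] = delta.sum(axis=0)
            delta = delta @ w.T
            if i > 0:
                # acts[i] stores tanh output of layer i-1
                delta = delta * (1.0 - acts[i] ** 2)
        return grads, delta


class Adam:
    """Adam over a flat list of parameter arrays (updates in place)."""

    def __init__(self, params, lr=0.05, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            if g is None:
                continue
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
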