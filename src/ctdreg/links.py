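"""Link functions for positivity-constrained distributional parameters.

sigma and tau of the exGaussian must stay strictly positive, so the model
(and, conjugately, the synthetic generator) parameterizes them on an
unconstrained pre-link scale and maps through softplus.  Since
softplus(x) ~= x for x >> 0 and reading-time baselines sit far above zero,
pre-link effect sizes are effectively in milliseconds.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "softplus",
    "softplus_inv",
    "softplus_deriv",
    "PARAM_FLOOR",
    "positive_link",
    "positive_link_inv",
]

#: floor (ms) added under the softplus for sigma and tau: keeps the
#: likelihood and its gradients bounded when stacked negative effects
#: drive a parameter toward zero (sub-millisecond dispersion/skewness is
#: physically meaningless for reading times anyway)
PARAM_FLOOR = 1.0


def softplus(x):
    """log(1 + exp(x)), overflow-safe."""
    return np.logaddexp(0.0, np.asarray(x, float))


def softplus_deriv(x):
    """d softplus / dx = sigmoid(x)."""
    x = np.asarray(x, float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softplus_inv(y):
    """Inverse of softplus; y must be > 0. Stable for large y."""
    y = np.asarray(y, float)
    if np.any(y <= 0):
        raise ValueError("softplus_inv requires positive input")
    # log(exp(y) - 1) = y + log(1 - exp(-y))
    return y + np.log1p(-np.exp(-y))


def positive_link(eta):
    """Positivity link for sigma and tau: PARAM_FLOOR + softplus(eta)."""
    return PARAM_FLOOR + softplus(eta)


def positive_link_inv(y):
    """Pre-link value giving positive_link(eta) = y; y must exceed the floor."""
    y = np.asarray(y, float)
    if np.any(y <= PARAM_FLOOR):
        raise ValueError(f"value must exceed the link floor ({PARAM_FLOOR} ms)")
    return softplus_inv(y - PARAM_FLOOR)
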