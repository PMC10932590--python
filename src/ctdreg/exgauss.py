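"""Exponentially-modified Gaussian (exGaussian) distribution utilities.

The exGaussian is the convolution of a Normal(mu, sigma) with an Exponential
of mean tau.  It is the standard descriptive model for reaction-time
distributions: mu and sigma govern the location and dispersion of the
Gaussian component, tau governs the heavy right tail (skewness), and the
distribution mean is mu + tau.

Everything here is vectorized over numpy arrays.  The log-density is
evaluated through :func:`scipy.special.log_ndtr`, which keeps the
``exp(sigma^2 / 2 tau^2)`` factor and the Gaussian tail probability in log
space, so the density is finite and accurate even when tau << sigma (where
naive formulas overflow).  Analytic gradients with respect to (mu, sigma,
tau) are provided for maximum-likelihood fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr

__all__ = [
    "ExGaussParams",
    "exgauss_logpdf",
    "exgauss_logpdf_grads",
    "exgauss_rvs",
    "exgauss_mean",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class ExGaussParams:
    """Parameters of an exGaussian distribution, all in milliseconds.

    mu: location of the Gaussian component.
    sigma: dispersion of the Gaussian component (> 0).
    tau: mean of the exponential component; right-tail skewness (> 0).
    """

    mu: float
    sigma: float
    tau: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not (self.tau > 0):
            raise ValueError(f"tau must be > 0, got {self.tau}")

    @property
    def mean(self) -> float:
        return self.mu + self.tau


def _validate(sigma, tau) -> None:
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be strictly positive")
    if np.any(np.asarray(tau) <= 0):
        raise ValueError("tau must be strictly positive")


def exgauss_logpdf(x, mu, sigma, tau):
    """Log-density of the exGaussian at ``x``.

    Uses the identity
        log f(x) = -log tau + sigma^2/(2 tau^2) - (x - mu)/tau
                   + log Phi((x - mu)/sigma - sigma/tau),
    with the Gaussian log-CDF computed by ``log_ndtr`` so that the huge
    positive exponent and the tiny tail probability cancel in log space.
    """
    _validate(sigma, tau)
    x, mu, sigma, tau = np.broadcast_arrays(
        np.asarray(x, float), np.asarray(mu, float),
        np.asarray(sigma, float), np.asarray(tau, float),
    )
    z = (x - mu) / sigma - sigma / tau
    out = -np.log(tau) + (sigma / tau) ** 2 / 2.0 - (x - mu) / tau + log_ndtr(z)
    return out


def _phi_over_ndtr(z):
    """phi(z) / Phi(z), computed in log space (stable for very negative z)."""
    log_phi = -0.5 * z * z - _LOG_SQRT_2PI
    return np.exp(log_phi - log_ndtr(z))


def exgauss_logpdf_grads(x, mu, sigma, tau):
    """Gradients of the exGaussian log-density wrt (mu, sigma, tau).

    Returns (d_mu, d_sigma, d_tau), each broadcast to the common shape.
    """
    _validate(sigma, tau)
    x, mu, sigma, tau = np.broadcast_arrays(
        np.asarray(x, float), np.asarray(mu, float),
        np.asarray(sigma, float), np.asarray(tau, float),
    )
    z = (x - mu) / sigma - sigma / tau
    r = _phi_over_ndtr(z)
    d_mu = 1.0 / tau - r / sigma
    d_sigma = sigma / tau**2 + r * (-(x - mu) / sigma**2 - 1.0 / tau)
    d_tau = -1.0 / tau - sigma**2 / tau**3 + (x - mu) / tau**2 + r * sigma / tau**2
    return d_mu, d_sigma, d_tau


def exgauss_rvs(mu, sigma, tau, size=None, rng=None):
    """Draw exGaussian samples: Normal(mu, sigma) + Exponential(tau)."""
    _validate(sigma, tau)
    if rng is None:
        rng = np.random.default_rng()
    return rng.normal(mu, sigma, size=size) + rng.exponential(tau, size=size)


def exgauss_mean(mu, sigma, tau):
    """Mean of the exGaussian: mu + tau (linear in the skewness parameter)."""
    _validate(sigma, tau)
    return np.asarray(mu, float) + np.asarray(tau, float)
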