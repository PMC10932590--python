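"""Effect curves extracted from fitted ensembles.

These are the model's interpretable summaries: how the predicted response
(the exGaussian mean, or one of its parameters) deviates from a reference
prediction as a function of one predictor at zero delay; how that effect is
modulated by another predictor held at its mean and +/-1 SD; and how a
+1 SD increment decays over 0-2 s of delay.

Reference ("average case") convention, recorded in every curve: all
predictors at their training-set means (standardized 0), zero random
effects, and a single conditioning event at the probed delay.  Uncertainty
bands are pointwise percentiles of the curve across ensemble members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .links import positive_link
from .model import Ensemble, PARAM_NAMES

__all__ = [
    "EffectCurve",
    "TimecourseCurve",
    "instantaneous_effect",
    "interaction_overlay",
    "timecourse",
    "uncertainty_bands",
]

REFERENCE_CONVENTION = (
    "predictors at training means; zero random effects; "
    "single conditioning event at the probed delay"
)


@dataclass
class EffectCurve:
    predictor: str
    grid: np.ndarray  # standardized predictor values (SD units)
    scale: str  # mean | mu | sigma | tau, response in ms
    estimate: np.ndarray  # deviation from the reference prediction
    lo: np.ndarray | None = None
    hi: np.ndarray | None = None
    conditioning: dict = field(default_factory=dict)
    delay: float = 0.0
    ablated: bool = False
    degenerate_bands: bool = False
    reference: str = REFERENCE_CONVENTION

    def range(self):
        return float(self.estimate.max() - self.estimate.min())


@dataclass
class TimecourseCurve:
    predictor: str
    delays: np.ndarray  # seconds, within [0, 2]
    scale: str
    estimate: np.ndarray  # expected response change for a +1 SD step
    lo: np.ndarray | None = None
    hi: np.ndarray | None = None
    ablated: bool = False
    reference: str = REFERENCE_CONVENTION


def _scale_value(eta, scale):
    mu, sigma, tau = eta[:, 0], positive_link(eta[:, 1]), positive_link(eta[:, 2])
    return {"mean": mu + tau, "mu": mu, "sigma": sigma, "tau": tau}[scale]


def _member_curve(member, predictor, grid, conditioning, delay, scale):
    n = len(grid)
    x = {predictor: np.asarray(grid, float)}
    for k, v in conditioning.items():
        x[k] = np.full(n, float(v))
    eta = member.prelink_single_event(x, np.full(n, delay))
    xr = {k: np.full(1, float(v)) for k, v in conditioning.items()}
    xr[predictor] = np.zeros(1)
    eta_ref = member.prelink_single_event(xr, np.array([delay]))
    return _scale_value(eta, scale) - _scale_value(eta_ref, scale)[0]


def _in_model(ensemble, predictor):
    return predictor in ensemble.members[0].config.predictors


def default_grid(n=101, half_width=2.0):
    return np.linspace(-half_width, half_width, n)


def instantaneous_effect(
    ensemble: Ensemble,
    predictor: str,
    grid=None,
    conditioning=None,
    scale="mean",
) -> EffectCurve:
    """Deviation of the predicted response from its reference value as a
    function of one predictor at zero delay (the instantaneous effect).

    The grid is in standardized (SD) units, +/-2 SD by default.  For a
    predictor absent from the model a flat zero curve is returned with the
    ablated flag set.
    """
    grid = default_grid() if grid is None else np.asarray(grid, float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    conditioning = dict(conditioning or {})
    if not _in_model(ensemble, predictor):
        warnings.warn(f"predictor {predictor!r} is ablated from the model; flat curve")
        z = np.zeros(len(grid))
        return EffectCurve(predictor, grid, scale, z, z, z, conditioning, ablated=True)
    curves = np.stack(
        [
            _member_curve(m, predictor, grid, conditioning, 0.0, scale)
            for m in ensemble.members
        ]
    )
    est = curves.mean(axis=0)
    curve = EffectCurve(predictor, grid, scale, est, conditioning=conditioning)
    if len(ensemble) >= 2:
        uncertainty_bands(ensemble, curve, _member_curves=curves)
    return curve


def interaction_overlay(
    ensemble: Ensemble, predictor: str, other: str, grid=None, scale="mean"
):
    """Three instantaneous-effect curves for ``predictor``, conditioning
    ``other`` at its mean and +/-1 SD, plus an additivity score.

    Under additive effects the three curves are parallel; the score is the
    maximal spread between level curves over the grid (after removing each
    curve's own reference offset, parallel curves coincide).  Returns
    (curves, additivity_score).
    """
    if predictor == other:
        raise ValueError("predictor and conditioning predictor must differ")
    curves = [
        instantaneous_effect(ensemble, predictor, grid, {other: lev}, scale)
        for lev in (-1.0, 0.0, 1.0)
    ]
    stack = np.stack([c.estimate for c in curves])
    additivity_score = float((stack.max(axis=0) - stack.min(axis=0)).max())
    return curves, additivity_score


def timecourse(ensemble: Ensemble, predictor: str, delays=None, scale="mean") -> TimecourseCurve:
    """Expected response change from a +1 SD increment of one predictor on
    an event observed ``delay`` seconds before the response (the
    continuous-time spillover profile), over delays in [0, 2] s."""
    delays = np.linspace(0.0, 2.0, 41) if delays is None else np.asarray(delays, float)
    if np.any(delays < 0):
        raise ValueError("delays must be >= 0")
    if np.any(delays > 2.0):
        raise ValueError("timecourse delays are probed within [0, 2] s")
    if not _in_model(ensemble, predictor):
        warnings.warn(f"predictor {predictor!r} is ablated from the model; flat curve")
        z = np.zeros(len(delays))
        return TimecourseCurve(predictor, delays, scale, z, z, z, ablated=True)
    per_member = []
    for m in ensemble.members:
        eta1 = m.prelink_single_event({predictor: np.ones(len(delays))}, delays)
        eta0 = m.prelink_single_event({predictor: np.zeros(len(delays))}, delays)
        per_member.append(_scale_value(eta1, scale) - _scale_value(eta0, scale))
    stack = np.stack(per_member)
    est = stack.mean(axis=0)
    lo = hi = None
    if len(ensemble) >= 2:
        lo = np.percentile(stack, 2.5, axis=0, method="lower")
        hi = np.percentile(stack, 97.5, axis=0, method="higher")
    return TimecourseCurve(predictor, delays, scale, est, lo, hi)


def uncertainty_bands(ensemble: Ensemble, curve, level=0.95, _member_curves=None):
    """Pointwise percentile bands across ensemble members (in place).

    A documented substitute for variational credible intervals: the spread
    of independently seeded fits.  Zero-width bands (identical members) are
    flagged.  Requires >= 2 members.
    """
    if len(ensemble) < 2:
        raise ValueError("uncertainty bands require at least 2 ensemble members")
    if _member_curves is None:
        _member_curves = np.stack(
            [
                _member_curve(
                    m, curve.predictor, curve.grid, curve.conditioning,
                    curve.delay, curve.scale,
                )
                for m in ensemble.members
            ]
        )
    alpha = 100.0 * (1.0 - level) / 2.0
    # round outward to order statistics: conservative for small ensembles and
    # exactly monotone under adding members
    curve.lo = np.percentile(_member_curves, alpha, axis=0, method="lower")
    curve.hi = np.percentile(_member_curves, 100.0 - alpha, axis=0, method="higher")
    curve.degenerate_bands = bool(np.allclose(curve.lo, curve.hi))
    return curve.lo, curve.hi
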