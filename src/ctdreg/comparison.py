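"""Null-model construction and paired permutation tests.

Hypotheses about individual predictors, their interaction, and their
distributional targets are tested by out-of-sample model comparison: a
null and an alternative configuration are fitted to the training data and
their per-datapoint test-set log-likelihoods are compared with a paired
permutation test (random sign-swapping of the paired differences).

Null constructions:
  * drop_predictor - the predictor is removed from every network;
  * interaction_null - two distinct networks, one convolving the first
    critical predictor plus all controls and the other the second critical
    predictor plus all controls, so the critical pair may interact with
    controls but not with each other; the matched alternative has two
    redundant networks each convolving all predictors;
  * distributional_drop - three distinct networks, one per distributional
    parameter; the null removes one predictor from exactly one of them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model import ModelConfig, PARAM_NAMES

__all__ = [
    "AblationSpec",
    "ComparisonResult",
    "build_null_config",
    "paired_permutation_test",
    "aggregate_test",
]


@dataclass(frozen=True)
class AblationSpec:
    """What to ablate to form a null model.

    kind: drop_predictor | interaction_null | distributional_drop
    targets: predictor name(s); a pair for interaction_null.
    dist_param: for distributional_drop, the one parameter (mu | sigma |
    tau) whose network loses the predictor.
    """

    kind: str
    targets: tuple
    dist_param: str | None = None

    def __post_init__(self):
        if self.kind not in ("drop_predictor", "interaction_null", "distributional_drop"):
            raise ValueError(f"unknown ablation kind {self.kind!r}")
        if self.kind == "interaction_null" and len(self.targets) != 2:
            raise ValueError("interaction_null needs exactly two critical predictors")
        if self.kind == "distributional_drop":
            if self.dist_param not in PARAM_NAMES:
                raise ValueError("distributional_drop must name one of mu/sigma/tau")
            if len(self.targets) != 1:
                raise ValueError("distributional_drop ablates exactly one predictor")


def _check_targets(full: ModelConfig, targets):
    for t in targets:
        if t not in full.predictors:
            raise ValueError(f"ablation target {t!r} not in the full configuration")


def build_null_config(full: ModelConfig, spec: AblationSpec):
    """Derive the null configuration (and, where the test needs a matched
    architecture, the paired alternative).

    Returns the null ModelConfig for drop_predictor, and a (null,
    alternative) pair for interaction_null and distributional_drop, whose
    parameter counts differ only by the ablated inputs.
    """
    _check_targets(full, spec.targets)
    base_net = full.networks[0]

    if spec.kind == "drop_predictor":
        nets = []
        for net in full.networks:
            kept = tuple(p for p in net.predictors if p not in spec.targets)
            if len(kept) == 0:
                raise ValueError(
                    f"ablating {spec.targets} empties a network; add controls"
                )
            nets.append(replace(net, predictors=kept))
        return replace(full, networks=tuple(nets))

    if spec.kind == "interaction_null":
        a, b = spec.targets
        controls = tuple(p for p in full.predictors if p not in (a, b))
        null_nets = (
            replace(base_net, predictors=(a,) + controls),
            replace(base_net, predictors=(b,) + controls),
        )
        alt_nets = (
            replace(base_net, predictors=full.predictors),
            replace(base_net, predictors=full.predictors),
        )
        return (
            replace(full, networks=null_nets),
            replace(full, networks=alt_nets),
        )

    # distributional_drop: three per-parameter networks
    (pred,) = spec.targets
    alt_nets = tuple(
        replace(base_net, predictors=full.predictors, targets=(param,))
        for param in PARAM_NAMES
    )
    null_nets = tuple(
        replace(
            net,
            predictors=(
                tuple(p for p in net.predictors if p != pred)
                if net.targets == (spec.dist_param,)
                else net.predictors
            ),
        )
        for net in alt_nets
    )
    return replace(full, networks=null_nets), replace(full, networks=alt_nets)


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a paired permutation comparison of two ensembles."""

    ll_a: np.ndarray
    ll_b: np.ndarray
    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    per_dataset: tuple = ()

    @property
    def n(self):
        return len(self.ll_a)


def _permutation_p(diff, n_permutations, seed, chunk=256):
    """Two-sided p for the statistic sum(diff) under per-datapoint A/B
    swaps (sign flips), with the +1 small-sample correction."""
    stat = float(diff.sum())
    rng = np.random.default_rng(seed)
    n = len(diff)
    count = 0
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        flips = rng.random((m, n)) < 0.5
        stats = stat - 2.0 * (flips @ diff)
        count += int(np.sum(np.abs(stats) >= abs(stat) - 1e-12))
        done += m
    p = (1.0 + count) / (n_permutations + 1.0)
    return stat, p


def paired_permutation_test(ll_a, ll_b, n_permutations=10000, seed=0) -> ComparisonResult:
    """Paired permutation test of out-of-sample conditional likelihood.

    ll_a and ll_b are aligned per-datapoint test log-likelihood vectors of
    two ensembles.  The observed statistic is sum(ll_b - ll_a); the null is
    generated by independently swapping A/B per datapoint with probability
    1/2; p is two-sided with the +1 correction, so p >= 1/(n_permutations+1).
    """
    ll_a = np.asarray(ll_a, float)
    ll_b = np.asarray(ll_b, float)
    if ll_a.shape != ll_b.shape or ll_a.ndim != 1:
        raise ValueError("log-likelihood vectors must be aligned 1-D arrays")
    if len(ll_a) < 2:
        raise ValueError("need at least two datapoints")
    stat, p = _permutation_p(ll_b - ll_a, n_permutations, seed)
    return ComparisonResult(ll_a, ll_b, stat, p, n_permutations, seed)


def aggregate_test(per_dataset_pairs, n_permutations=10000, seed=0) -> ComparisonResult:
    """Pooled permutation test across datasets.

    Concatenates the per-datapoint difference vectors of every dataset and
    applies the same sign-swapping scheme; per-dataset contributions to the
    statistic are reported alongside.
    """
    pairs = list(per_dataset_pairs)
    if len(pairs) == 0:
        raise ValueError("need at least one dataset pair")
    diffs, contrib = [], []
    for ll_a, ll_b in pairs:
        ll_a = np.asarray(ll_a, float)
        ll_b = np.asarray(ll_b, float)
        if ll_a.shape != ll_b.shape or ll_a.ndim != 1:
            raise ValueError("log-likelihood vectors must be aligned 1-D arrays")
        d = ll_b - ll_a
        diffs.append(d)
        contrib.append(float(d.sum()))
    ll_a_all = np.concatenate([np.asarray(a, float) for a, _ in pairs])
    ll_b_all = np.concatenate([np.asarray(b, float) for _, b in pairs])
    stat, p = _permutation_p(np.concatenate(diffs), n_permutations, seed)
    return ComparisonResult(
        ll_a_all, ll_b_all, stat, p, n_permutations, seed, per_dataset=tuple(contrib)
    )
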