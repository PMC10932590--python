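"""Continuous-time deconvolutional exGaussian regression.

The model relates an asynchronous stream of word events to reading-time
responses: a neural impulse-response function (IRF) maps each past event's
predictor values and its continuous delay to additive contributions to the
pre-link location, dispersion, and skewness parameters of an exGaussian
predictive distribution.  Per response,

    eta = baseline + random offsets + sum over in-window past events
          of IRF(predictors, delay)
    mu = eta_mu;  sigma = 1 + softplus(eta_sigma);  tau = 1 + softplus(eta_tau)

and the response likelihood is exGaussian(mu, sigma, tau).  Training
maximizes the summed log-likelihood on the training partition by Adam with
early stopping on validation likelihood; statistical tests aggregate over
ensembles of 10 independently seeded fits.

Mixed effects: by-participant offsets on the baseline parameters,
by-participant multiplicative gains on each network's output (a compact
realization of random IRF parameters), and by-token-position intercepts on
the pre-link location, all shrunk toward zero by an L2 penalty.

Configurations may use several distinct networks over predictor subsets
(the basis of the interaction and distributional-parameter null models),
and a "linear IRF" configuration (no hidden layers, fixed decay kernel)
whose predictions have a closed form, used for oracle tests and fast
calibration studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd

from .exgauss import ExGaussParams, exgauss_logpdf, exgauss_logpdf_grads
from .histories import build_history_pairs
from .links import positive_link, positive_link_inv, softplus_deriv
from .nnet import MLP, Adam

__all__ = [
    "NetworkSpec",
    "ModelConfig",
    "Dataset",
    "FittedModel",
    "Ensemble",
    "fit",
    "fit_ensemble",
    "test_loglik",
    "convolve",
    "linear_irf_config",
]

PARAM_NAMES = ("mu", "sigma", "tau")


@dataclass(frozen=True)
class NetworkSpec:
    """One IRF network: which predictors it convolves, which distributional
    parameters it feeds, and its shape.

    fixed_kernel, when set, replaces the learned dependence on delay with a
    closed-form decay: the network sees only the predictor features and its
    output is multiplied by kernel(delay).  ("exponential", rate) or
    ("gamma", shape, rate).

    interactions=True appends all pairwise products of the network's
    predictors to its input features; with hidden=() this is how a linear
    configuration is allowed to express within-network interactions.
    """

    predictors: tuple
    targets: tuple = PARAM_NAMES
    hidden: tuple = (64, 64)
    interactions: bool = False
    fixed_kernel: tuple | None = None
    output_scale: float = 10.0

    def __post_init__(self):
        if len(self.predictors) == 0:
            raise ValueError("network needs at least one predictor")
        for t in self.targets:
            if t not in PARAM_NAMES:
                raise ValueError(f"unknown target parameter {t!r}")

    @property
    def in_dim(self):
        d = len(self.predictors)
        if self.interactions:
            d += len(self.predictors) * (len(self.predictors) - 1) // 2
        if self.fixed_kernel is None:
            d += 2  # delay in seconds and log(1 + delay)
        return d

    def kernel_value(self, delay):
        delay = np.asarray(delay, float)
        kind = self.fixed_kernel[0]
        if kind == "exponential":
            rate = self.fixed_kernel[1]
            g = np.exp(-rate * delay)
        elif kind == "gamma":
            shape, rate = self.fixed_kernel[1], self.fixed_kernel[2]
            mode = (shape - 1.0) / rate
            with np.errstate(divide="ignore", invalid="ignore"):
                g = np.where(
                    delay > 0,
                    np.exp((shape - 1.0) * (np.log(delay) - np.log(mode)) - rate * (delay - mode)),
                    0.0,
                )
        else:
            raise ValueError(f"unknown kernel {kind!r}")
        return np.where(delay >= 0, g, 0.0)


@dataclass(frozen=True)
class ModelConfig:
    networks: tuple
    history_max_events: int = 32
    history_max_seconds: float = 20.0
    ranef_participant_baseline: bool = True
    ranef_participant_gain: bool = True
    ranef_token_position: bool = True
    ranef_l2: float = 1e-4
    weight_l2: float = 1e-3  # shrinkage on IRF network weights (per-datapoint scale)
    lr: float = 0.01
    batch_size: int = 1024
    max_steps: int = 2000
    eval_every: int = 25
    patience: int = 10
    intercept_only: bool = False

    def __post_init__(self):
        if self.history_max_events <= 0 or self.history_max_seconds <= 0:
            raise ValueError("history window must be positive")
        if not self.intercept_only and len(self.networks) == 0:
            raise ValueError("at least one network required")

    @property
    def predictors(self):
        seen = []
        for net in self.networks:
            for p in net.predictors:
                if p not in seen:
                    seen.append(p)
        return tuple(seen)

    @classmethod
    def single_network(cls, predictors, hidden=(64, 64), **kwargs):
        net_kw = {
            k: kwargs.pop(k)
            for k in ("interactions", "fixed_kernel", "output_scale", "targets")
            if k in kwargs
        }
        net = NetworkSpec(tuple(predictors), hidden=tuple(hidden), **net_kw)
        return cls(networks=(net,), **kwargs)


def linear_irf_config(
    predictors,
    kernel=("exponential", 4.0),
    interactions=False,
    targets=PARAM_NAMES,
    **kwargs,
):
    """Closed-form configuration: linear in predictors, fixed decay kernel.

    Used for oracle tests and for fast calibration/power simulations where
    thousands of fits are needed.
    """
    net = NetworkSpec(
        tuple(predictors),
        targets=tuple(targets),
        hidden=(),
        interactions=interactions,
        fixed_kernel=tuple(kernel),
    )
    return ModelConfig(networks=(net,), **kwargs)


@dataclass
class Dataset:
    """An event table plus the responses to be modeled against it."""

    events: pd.DataFrame
    responses: pd.DataFrame

    def __post_init__(self):
        if "duration_ms" not in self.responses.columns:
            raise ValueError("responses must carry a duration_ms column")


# ---------------------------------------------------------------------------
# fitted model


def _moment_init(y):
    """Method-of-moments exGaussian start values (clamped to validity)."""
    m = float(np.mean(y))
    s = float(np.std(y))
    skew = float(np.mean(((y - m) / s) ** 3)) if s > 0 else 0.0
    tau = s * (max(skew, 0.05) / 2.0) ** (1.0 / 3.0)
    tau = min(max(tau, 2.0), 0.95 * s) if s > 2.0 else 2.0
    sigma = max(np.sqrt(max(s**2 - tau**2, 0.0)), 2.0)
    mu = m - tau
    return np.array([mu, positive_link_inv(sigma), positive_link_inv(tau)])


class FittedModel:
    """A trained deconvolutional regression model.

    Holds the learned networks, baseline, random-effect tables, the
    standardization statistics of its training events, and the training
    log (step, train NLL, validation log-likelihood).
    """

    def __init__(self, config, seed, standardization, participant_index, n_token_pos):
        self.config = config
        self.seed = seed
        self.standardization = standardization  # name -> (mean, sd)
        self.participant_index = participant_index  # id -> row
        self.n_token_pos = n_token_pos
        rng = np.random.default_rng(seed)
        self.networks = [
            MLP(net.in_dim, net.hidden, len(net.targets), rng)
            for net in config.networks
        ]
        self.baseline = np.zeros(3)
        n_part = len(participant_index)
        self.part_base = np.zeros((n_part, 3))
        self.part_gain = np.zeros((n_part, len(config.networks)))
        self.tokpos_mu = np.zeros(n_token_pos)
        self.training_log = []
        self.val_loglik_best = None

    # -- feature construction -------------------------------------------------

    def _standardize(self, events):
        out = {}
        for name in self.config.predictors:
            if name not in events.columns:
                raise KeyError(f"predictor {name!r} missing from event table")
            m, s = self.standardization[name]
            out[name] = (events[name].to_numpy(float) - m) / s
        return out

    def _net_features(self, net, xstd, rows, delay):
        cols = [xstd[p][rows] for p in net.predictors]
        if net.interactions:
            base = list(cols)
            for i, j in combinations(range(len(net.predictors)), 2):
                cols.append(base[i] * base[j])
        if net.fixed_kernel is None:
            cols.append(delay)
            cols.append(np.log1p(delay))
        return np.stack(cols, axis=1) if cols else np.empty((len(rows), 0))

    # -- forward passes -------------------------------------------------------

    def _participant_rows(self, participant_ids):
        idx = np.array(
            [self.participant_index.get(p, -1) for p in participant_ids], dtype=np.int64
        )
        return idx

    def _prelink(self, xstd, pairs, resp_part_rows, resp_tokpos, cache=False):
        """Pre-link eta (n_resp, 3) for full response vectors."""
        n = pairs.n_responses
        eta = np.tile(self.baseline, (n, 1))
        known = resp_part_rows >= 0
        if self.config.ranef_participant_baseline and known.any():
            eta[known] += self.part_base[resp_part_rows[known]]
        if self.config.ranef_token_position and self.n_token_pos > 0:
            ok = (resp_tokpos >= 0) & (resp_tokpos < self.n_token_pos)
            eta[ok, 0] += self.tokpos_mu[resp_tokpos[ok]]
        pair_part = resp_part_rows[pairs.pair_resp]
        for k, (net, mlp) in enumerate(zip(self.config.networks, self.networks)):
            feats = self._net_features(net, xstd, pairs.pair_event, pairs.delay)
            out = mlp.forward(feats, cache=cache) * net.output_scale
            if net.fixed_kernel is not None:
                out = out * net.kernel_value(pairs.delay)[:, None]
            if self.config.ranef_participant_gain:
                gain = np.where(
                    pair_part >= 0, 1.0 + self.part_gain[pair_part, k], 1.0
                )
                out = out * gain[:, None]
            for c, t in enumerate(net.targets):
                eta[:, PARAM_NAMES.index(t)] += np.bincount(
                    pairs.pair_resp, weights=out[:, c], minlength=n
                )
        return eta

    @staticmethod
    def _link(eta):
        return eta[:, 0], positive_link(eta[:, 1]), positive_link(eta[:, 2])

    def predict_params(self, events, responses):
        """(mu, sigma, tau) arrays for each response, given its event history.

        Responses for participants unseen in training fall back to the
        population-level (zero-offset) effects.
        """
        xstd = self._standardize(events)
        pairs = build_history_pairs(
            events["participant_id"].to_numpy(),
            events["time_s"].to_numpy(),
            responses["participant_id"].to_numpy(),
            responses["time_s"].to_numpy(),
            self.config.history_max_events,
            self.config.history_max_seconds,
        )
        part_rows = self._participant_rows(responses["participant_id"].to_numpy())
        tokpos = (
            responses["token_position"].to_numpy()
            if "token_position" in responses.columns
            else np.full(len(responses), -1)
        )
        eta = self._prelink(xstd, pairs, part_rows, tokpos)
        return self._link(eta)

    def loglik(self, events, responses):
        """Per-datapoint exGaussian log-likelihood of the responses."""
        mu, sigma, tau = self.predict_params(events, responses)
        return exgauss_logpdf(responses["duration_ms"].to_numpy(float), mu, sigma, tau)

    def irf_forward(self, x, delay, *, standardized=False):
        """Population-level IRF contribution of a single event.

        x maps predictor name -> value; returns the pre-link contribution
        vector (d_mu, d_sigma~, d_tau~) at the given delay (s).  Future
        events never influence a response, so negative delays are errors.
        """
        if delay < 0:
            raise ValueError("delay must be >= 0 (no acausal influence)")
        if standardized:
            xstd = {k: np.asarray([float(v)]) for k, v in x.items()}
        else:
            xstd = {}
            for k, v in x.items():
                m, s = self.standardization[k]
                xstd[k] = np.asarray([(float(v) - m) / s])
        out = np.zeros(3)
        d = np.asarray([float(delay)])
        for net, mlp in zip(self.config.networks, self.networks):
            if any(p not in xstd for p in net.predictors):
                raise KeyError("irf_forward requires values for all network predictors")
            feats = self._net_features(net, xstd, np.array([0]), d)
            o = mlp.forward(feats, cache=False)[0] * net.output_scale
            if net.fixed_kernel is not None:
                o = o * float(net.kernel_value(d)[0])
            for c, t in enumerate(net.targets):
                out[PARAM_NAMES.index(t)] += o[c]
        return out

    def prelink_single_event(self, x_std: dict, delays):
        """Vectorized eta for one conditioning event per row at the given
        delays, predictors standardized, zero random effects.  Used by the
        effect-curve module."""
        delays = np.asarray(delays, float)
        n = len(delays)
        xstd = {}
        for k, v in x_std.items():
            v = np.asarray(v, float)
            xstd[k] = np.broadcast_to(v, (n,)).copy()
        for name in self.config.predictors:
            if name not in xstd:
                xstd[name] = np.zeros(n)
        eta = np.tile(self.baseline, (n, 1))
        rows = np.arange(n)
        for net, mlp in zip(self.config.networks, self.networks):
            feats = self._net_features(net, xstd, rows, delays)
            out = mlp.forward(feats, cache=False) * net.output_scale
            if net.fixed_kernel is not None:
                out = out * net.kernel_value(delays)[:, None]
            for c, t in enumerate(net.targets):
                eta[:, PARAM_NAMES.index(t)] += out[:, c]
        return eta

    # -- parameter plumbing ---------------------------------------------------

    def _param_list(self):
        params = []
        for mlp in self.networks:
            params.extend(mlp.params)
        params.append(self.baseline)
        params.append(self.part_base)
        params.append(self.part_gain)
        params.append(self.tokpos_mu)
        return params

    def _snapshot(self):
        return [p.copy() for p in self._param_list()]

    def _restore(self, snap):
        for p, s in zip(self._param_list(), snap):
            p[...] = s


class Ensemble:
    """A set of independently seeded fits of one configuration, treated as a
    single predictive model (a uniform mixture of its members)."""

    def __init__(self, members):
        members = list(members)
        if len(members) == 0:
            raise ValueError("ensemble needs at least one member")
        self.members = members

    def __len__(self):
        return len(self.members)

    @property
    def seeds(self):
        return [m.seed for m in self.members]


# ---------------------------------------------------------------------------
# fitting


def fit(config: ModelConfig, train: Dataset, validation: Dataset, seed: int) -> FittedModel:
    """Maximum-likelihood fit with Adam, early-stopped on validation
    log-likelihood; returns the best-validation checkpoint.  Identical
    (config, data, seed) inputs give identical fits."""
    rng = np.random.default_rng(seed)
    ev = train.events
    stats = {}
    for name in config.predictors:
        col = ev[name].to_numpy(float)
        m, s = float(col.mean()), float(col.std())
        if s == 0:
            raise ValueError(f"predictor {name!r} is constant on the training events")
        stats[name] = (m, s)
    part_ids = pd.unique(
        np.concatenate(
            [
                train.events["participant_id"].to_numpy(),
                train.responses["participant_id"].to_numpy(),
            ]
        )
    )
    participant_index = {p: i for i, p in enumerate(part_ids)}
    if "token_position" in train.responses.columns:
        n_tokpos = int(train.responses["token_position"].max()) + 1
    else:
        n_tokpos = 0

    model = FittedModel(config, seed, stats, participant_index, n_tokpos)
    y_tr = train.responses["duration_ms"].to_numpy(float)
    model.baseline = _moment_init(y_tr)

    if config.intercept_only:
        xstd_tr = {}
    else:
        xstd_tr = model._standardize(train.events)
    pairs_tr = build_history_pairs(
        train.events["participant_id"].to_numpy(),
        train.events["time_s"].to_numpy(),
        train.responses["participant_id"].to_numpy(),
        train.responses["time_s"].to_numpy(),
        config.history_max_events,
        config.history_max_seconds,
    )
    part_tr = model._participant_rows(train.responses["participant_id"].to_numpy())
    tok_tr = (
        train.responses["token_position"].to_numpy()
        if n_tokpos
        else np.full(len(train.responses), -1)
    )

    # precompute per-network pair features once
    feats_tr = [
        model._net_features(net, xstd_tr, pairs_tr.pair_event, pairs_tr.delay)
        for net in config.networks
    ]
    kernels_tr = [
        net.kernel_value(pairs_tr.delay) if net.fixed_kernel is not None else None
        for net in config.networks
    ]
    pair_part_tr = part_tr[pairs_tr.pair_resp]

    n_train = len(y_tr)
    batch = min(config.batch_size, n_train)
    params = model._param_list()
    opt = Adam(params, lr=config.lr)
    n_nets = len(config.networks)
    lam = config.ranef_l2

    def batch_step(resp_idx):
        rows, local = pairs_tr.gather(resp_idx)
        bsz = len(resp_idx)
        eta = np.tile(model.baseline, (bsz, 1))
        bpart = part_tr[resp_idx]
        known = bpart >= 0
        if config.ranef_participant_baseline:
            eta[known] += model.part_base[bpart[known]]
        btok = tok_tr[resp_idx]
        if config.ranef_token_position and n_tokpos:
            eta[:, 0] += model.tokpos_mu[btok]
        outs, gains, raw_outs = [], [], []
        ppart = pair_part_tr[rows]
        for k, (net, mlp) in enumerate(zip(config.networks, model.networks)):
            f = feats_tr[k][rows]
            out = mlp.forward(f, cache=True) * net.output_scale
            if kernels_tr[k] is not None:
                out = out * kernels_tr[k][rows][:, None]
            raw_outs.append(out)
            if config.ranef_participant_gain:
                gain = np.where(ppart >= 0, 1.0 + model.part_gain[ppart, k], 1.0)
            else:
                gain = np.ones(len(rows))
            gains.append(gain)
            outg = out * gain[:, None]
            outs.append(outg)
            for c, t in enumerate(net.targets):
                eta[:, PARAM_NAMES.index(t)] += np.bincount(
                    local, weights=outg[:, c], minlength=bsz
                )
        mu, sigma, tau = model._link(eta)
        yb = y_tr[resp_idx]
        ll = exgauss_logpdf(yb, mu, sigma, tau)
        loss = -ll.mean()
        if not np.isfinite(loss):
            bad = resp_idx[~np.isfinite(ll)][:5]
            raise RuntimeError(
                f"non-finite training loss; offending response rows {bad.tolist()}"
            )
        d_mu, d_sig, d_tau = exgauss_logpdf_grads(yb, mu, sigma, tau)
        # clip per-datapoint score contributions: extreme sigma/tau
        # excursions early in training otherwise produce infinite gradients
        d_mu = np.clip(d_mu, -1e3, 1e3)
        d_sig = np.clip(d_sig, -1e3, 1e3)
        d_tau = np.clip(d_tau, -1e3, 1e3)
        d_eta = np.stack(
            [
                d_mu,
                d_sig * softplus_deriv(eta[:, 1]),
                d_tau * softplus_deriv(eta[:, 2]),
            ],
            axis=1,
        ) * (-1.0 / bsz)

        grads = []
        for k, (net, mlp) in enumerate(zip(config.networks, model.networks)):
            tcols = [PARAM_NAMES.index(t) for t in net.targets]
            d_outg = d_eta[local][:, tcols]
            d_out = d_outg * gains[k][:, None]
            if kernels_tr[k] is not None:
                d_out = d_out * kernels_tr[k][rows][:, None]
            g_net, _ = mlp.backward(d_out * net.output_scale)
            if config.weight_l2:
                g_net = [
                    g if g is None
                    else g + 2.0 * config.weight_l2 * p * bsz / max(n_train, 1)
                    for g, p in zip(g_net, mlp.params)
                ]
            grads.extend(g_net)
        g_base = d_eta.sum(axis=0)
        grads.append(g_base)
        n_part = len(model.part_base)
        g_pb = np.zeros_like(model.part_base)
        if config.ranef_participant_baseline:
            for c in range(3):
                g_pb[:, c] = np.bincount(
                    bpart[known], weights=d_eta[known, c], minlength=n_part
                )
            g_pb += 2.0 * lam * model.part_base / max(n_train, 1) * bsz
        grads.append(g_pb)
        g_pg = np.zeros_like(model.part_gain)
        if config.ranef_participant_gain and n_nets:
            okp = ppart >= 0
            for k, net in enumerate(config.networks):
                tcols = [PARAM_NAMES.index(t) for t in net.targets]
                d_gain = (d_eta[local][:, tcols] * raw_outs[k]).sum(axis=1)
                g_pg[:, k] = np.bincount(
                    ppart[okp], weights=d_gain[okp], minlength=n_part
                )
            g_pg += 2.0 * lam * model.part_gain / max(n_train, 1) * bsz
        grads.append(g_pg)
        g_tk = np.zeros_like(model.tokpos_mu)
        if config.ranef_token_position and n_tokpos:
            g_tk += np.bincount(btok, weights=d_eta[:, 0], minlength=n_tokpos)
            g_tk += 2.0 * lam * model.tokpos_mu / max(n_train, 1) * bsz
        grads.append(g_tk)
        return loss, grads

    # cached validation-side structures (pairing and features are fixed;
    # only the parameters change between evaluations)
    xstd_va = {} if config.intercept_only else model._standardize(validation.events)
    pairs_va = build_history_pairs(
        validation.events["participant_id"].to_numpy(),
        validation.events["time_s"].to_numpy(),
        validation.responses["participant_id"].to_numpy(),
        validation.responses["time_s"].to_numpy(),
        config.history_max_events,
        config.history_max_seconds,
    )
    part_va = model._participant_rows(
        validation.responses["participant_id"].to_numpy()
    )
    tok_va = (
        validation.responses["token_position"].to_numpy()
        if "token_position" in validation.responses.columns
        else np.full(len(validation.responses), -1)
    )
    feats_va = [
        model._net_features(net, xstd_va, pairs_va.pair_event, pairs_va.delay)
        for net in config.networks
    ]
    kernels_va = [
        net.kernel_value(pairs_va.delay) if net.fixed_kernel is not None else None
        for net in config.networks
    ]
    pair_part_va = part_va[pairs_va.pair_resp]
    y_va = validation.responses["duration_ms"].to_numpy(float)

    def val_loglik():
        n = pairs_va.n_responses
        eta = np.tile(model.baseline, (n, 1))
        known_v = part_va >= 0
        if config.ranef_participant_baseline:
            eta[known_v] += model.part_base[part_va[known_v]]
        if config.ranef_token_position and n_tokpos:
            ok = (tok_va >= 0) & (tok_va < n_tokpos)
            eta[ok, 0] += model.tokpos_mu[tok_va[ok]]
        for k, (net, mlp) in enumerate(zip(config.networks, model.networks)):
            out = mlp.forward(feats_va[k], cache=False) * net.output_scale
            if kernels_va[k] is not None:
                out = out * kernels_va[k][:, None]
            if config.ranef_participant_gain:
                gain = np.where(
                    pair_part_va >= 0, 1.0 + model.part_gain[pair_part_va, k], 1.0
                )
                out = out * gain[:, None]
            for col, t in enumerate(net.targets):
                eta[:, PARAM_NAMES.index(t)] += np.bincount(
                    pairs_va.pair_resp, weights=out[:, col], minlength=n
                )
        mu, sigma, tau = model._link(eta)
        return float(exgauss_logpdf(y_va, mu, sigma, tau).mean())

    best = model._snapshot()
    best_val = val_loglik()
    model.training_log.append((0, np.nan, best_val))
    stale = 0
    for step in range(1, config.max_steps + 1):
        if batch < n_train:
            idx = rng.choice(n_train, size=batch, replace=False)
        else:
            idx = np.arange(n_train)
        loss, grads = batch_step(idx)
        grads = [None if g is None else np.clip(g, -100.0, 100.0) for g in grads]
        opt.step(grads)
        if step % config.eval_every == 0 or step == config.max_steps:
            v = val_loglik()
            model.training_log.append((step, float(loss), v))
            if v > best_val:
                best_val = v
                best = model._snapshot()
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
    model._restore(best)
    model.val_loglik_best = best_val
    return model


def fit_ensemble(
    config: ModelConfig,
    train: Dataset,
    validation: Dataset,
    n_members: int = 10,
    base_seed: int = 0,
) -> Ensemble:
    """Fit n_members independent models with seeds base_seed..base_seed+n-1.

    A member that fails is retried once with a shifted seed; more than two
    unrecoverable failures abort the ensemble.
    """
    if n_members < 2:
        raise ValueError("an ensemble needs at least 2 members")
    members, failures = [], 0
    for j in range(n_members):
        seed = base_seed + j
        try:
            members.append(fit(config, train, validation, seed))
        except Exception as first:
            failures += 1
            if failures > 2:
                raise RuntimeError("too many ensemble member failures") from first
            warnings.warn(f"member seed {seed} failed ({first}); retrying")
            members.append(fit(config, train, validation, seed + 100003))
    return Ensemble(members)


def test_loglik(ensemble: Ensemble, test: Dataset) -> np.ndarray:
    """Per-datapoint out-of-sample log-likelihood of the ensemble.

    The ensemble is treated as a uniform mixture over members: the value is
    the log of the arithmetic mean of member densities, which makes the
    paired permutation comparison between two ensembles well defined.
    """
    lls = np.stack(
        [m.loglik(test.events, test.responses) for m in ensemble.members]
    )
    mx = lls.max(axis=0)
    return mx + np.log(np.mean(np.exp(lls - mx), axis=0))


def convolve(events: pd.DataFrame, response, model: FittedModel) -> ExGaussParams:
    """Predictive exGaussian parameters for one response given the event
    stream: baseline + random offsets + summed IRF contributions of all
    in-window past events.  With no in-window events the baseline-only
    parameters are returned."""
    if isinstance(response, pd.DataFrame):
        resp = response.iloc[[0]]
    else:
        resp = pd.DataFrame([response])
    mu, sigma, tau = model.predict_params(events, resp)
    return ExGaussParams(float(mu[0]), float(sigma[0]), float(tau[0]))
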