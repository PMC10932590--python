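"""The deconvolutional core: convolution, fitting, ensembles."""

import numpy as np
import pandas as pd
import pytest

import ctdreg as c
from ctdreg.links import positive_link
from ctdreg.model import Dataset, NetworkSpec, ModelConfig, PARAM_NAMES
from ctdreg.nnet import MLP
from ctdreg import studies


def _tiny_events(times, participant=0, x=None, cfg_preds=("a", "b")):
    n = len(times)
    df = pd.DataFrame(
        {
            "participant_id": participant,
            "text_id": 0,
            "sentence_index": 0,
            "token_position": np.arange(n),
            "time_s": times,
        }
    )
    rng = np.random.default_rng(0)
    for i, p in enumerate(cfg_preds):
        df[p] = x[:, i] if x is not None else rng.normal(size=n)
    return df


def _tiny_responses(times, durs, participant=0):
    return pd.DataFrame(
        {
            "participant_id": participant,
            "text_id": 0,
            "sentence_index": 0,
            "token_position": np.arange(len(times)),
            "time_s": times,
            "duration_ms": durs,
        }
    )


def _fitted_tiny(seed=0, hidden=(8,), steps=30, ranef=False):
    """A small trained model on a toy dataset (nonzero weights)."""
    rng = np.random.default_rng(seed)
    times = np.sort(rng.uniform(0, 20, 60))
    ev = _tiny_events(times)
    rs = _tiny_responses(times, rng.uniform(300, 600, 60))
    cfg = ModelConfig.single_network(
        ("a", "b"), hidden=hidden, max_steps=steps, eval_every=10, patience=50,
        ranef_participant_baseline=ranef, ranef_participant_gain=ranef,
        ranef_token_position=ranef,
    )
    return c.fit(cfg, Dataset(ev, rs), Dataset(ev, rs), seed=seed), ev


# ---------------------------------------------------------------------------
# irf_forward


def test_zero_initialized_network_contributes_nothing():
    m, _ = _fitted_tiny(steps=0)
    out = m.irf_forward({"a": 1.7, "b": -0.3}, 0.5)
    assert np.allclose(out, 0.0)


def test_irf_forward_deterministic_and_causal():
    m, _ = _fitted_tiny()
    x = {"a": 1.0, "b": 2.0}
    assert np.array_equal(m.irf_forward(x, 0.25), m.irf_forward(x, 0.25))
    with pytest.raises(ValueError):
        m.irf_forward(x, -0.1)


def test_linear_irf_has_closed_form():
    """With no hidden layers and a fixed kernel, the contribution is
    (W x + b) * scale * exp(-rate * delay), computable by hand."""
    rng = np.random.default_rng(1)
    times = np.sort(rng.uniform(0, 20, 80))
    ev = _tiny_events(times)
    rs = _tiny_responses(times, rng.uniform(300, 600, 80))
    cfg = c.linear_irf_config(
        ("a", "b"), kernel=("exponential", 4.0), max_steps=40, eval_every=10,
        patience=50, ranef_participant_baseline=False,
        ranef_participant_gain=False, ranef_token_position=False,
    )
    m = c.fit(cfg, Dataset(ev, rs), Dataset(ev, rs), seed=1)
    W, b = m.networks[0].params
    net = m.config.networks[0]
    xraw = {"a": 0.8, "b": -1.2}
    xstd = np.array(
        [(xraw[p] - m.standardization[p][0]) / m.standardization[p][1] for p in ("a", "b")]
    )
    delay = 0.37
    want = (xstd @ W + b) * net.output_scale * np.exp(-4.0 * delay)
    got = m.irf_forward(xraw, delay)
    assert np.allclose(got, want, atol=1e-12)


# ---------------------------------------------------------------------------
# convolve


def test_convolve_empty_history_returns_baseline():
    m, ev = _fitted_tiny()
    resp = _tiny_responses([0.0], [400.0], participant=99)
    resp["time_s"] = -50.0  # before every event
    params = c.convolve(ev, resp, m)
    assert params.mu == pytest.approx(m.baseline[0])
    assert params.sigma == pytest.approx(float(positive_link(m.baseline[1])))
    assert params.tau == pytest.approx(float(positive_link(m.baseline[2])))


def test_duplicated_event_doubles_prelink_contribution():
    m, _ = _fitted_tiny(ranef=False)
    x = np.array([[1.2, -0.5]])
    ev1 = _tiny_events([1.0], x=x)
    ev2 = pd.concat([ev1, ev1], ignore_index=True)
    resp = _tiny_responses([1.5], [400.0])
    base = m.baseline
    p1 = c.convolve(ev1, resp, m)
    p2 = c.convolve(ev2, resp, m)
    one = np.array([p1.mu - base[0]])
    two = np.array([p2.mu - base[0]])
    assert two == pytest.approx(2 * one, abs=1e-10)


def _convolve_oracle(model, events, responses):
    """Naive double loop: baseline + irf_forward per in-window event."""
    cfg = model.config
    out = []
    for _, r in responses.iterrows():
        eta = model.baseline.copy()
        hist = events[
            (events["participant_id"] == r["participant_id"])
            & (events["time_s"] <= r["time_s"])
        ].sort_values("time_s")
        hist = hist[r["time_s"] - hist["time_s"] <= cfg.history_max_seconds]
        hist = hist.tail(cfg.history_max_events)
        for _, e in hist.iterrows():
            x = {p: e[p] for p in cfg.predictors}
            eta = eta + model.irf_forward(x, float(r["time_s"] - e["time_s"]))
        out.append(
            [eta[0], float(positive_link(eta[1])), float(positive_link(eta[2]))]
        )
    return np.array(out)


@pytest.mark.parametrize("kind", ["nn", "linear"])
def test_convolve_matches_bruteforce_oracle(kind):
    rng = np.random.default_rng(5)
    for trial in range(10):
        n_ev = rng.integers(1, 11)
        times = np.sort(rng.uniform(0, 6, n_ev))
        ev = _tiny_events(times, x=rng.normal(size=(n_ev, 2)))
        if kind == "nn":
            m, _ = _fitted_tiny(seed=trial, steps=25)
        else:
            cfg = c.linear_irf_config(
                ("a", "b"), max_steps=25, eval_every=10, patience=50,
                ranef_participant_baseline=False, ranef_participant_gain=False,
                ranef_token_position=False,
            )
            tr_ev = _tiny_events(np.sort(rng.uniform(0, 20, 50)))
            tr_rs = _tiny_responses(
                tr_ev["time_s"].to_numpy(), rng.uniform(300, 600, 50)
            )
            m = c.fit(cfg, Dataset(tr_ev, tr_rs), Dataset(tr_ev, tr_rs), seed=trial)
        resp_times = np.sort(rng.uniform(times[0], times[-1] + 2, 2))
        rs = _tiny_responses(resp_times, [400.0, 420.0], participant=1234)
        mu, sigma, tau = m.predict_params(ev, rs)
        got = np.stack([mu, sigma, tau], axis=1)
        want = _convolve_oracle(m, ev, rs)
        assert np.max(np.abs(got - want)) < 1e-10


def test_temporal_causality():
    """Events after a response never change its predicted parameters."""
    m, _ = _fitted_tiny()
    ev = _tiny_events([0.5, 1.0], x=np.array([[0.3, -0.2], [1.0, 0.4]]))
    rs = _tiny_responses([1.2], [400.0])
    before = m.predict_params(ev, rs)
    future = _tiny_events([5.0], x=np.array([[40.0, -30.0]]))
    ev2 = pd.concat([ev, future], ignore_index=True)
    after = m.predict_params(ev2, rs)
    for a, b in zip(before, after):
        assert np.array_equal(a, b)


# ---------------------------------------------------------------------------
# fitting


def test_intercept_only_recovers_baseline_parameters():
    """On 5,000 i.i.d. exGaussian responses the intercept-only fit recovers
    the generator parameters, and agrees with scipy's independent
    maximum-likelihood estimator."""
    from scipy.stats import exponnorm

    cfg = c.GeneratorConfig(
        n_participants=2, n_texts=2, n_words_per_text=1250,
        participant_sd={"mu": 0.0, "sigma": 0.0, "tau": 0.0},
    ).with_effects(freq_surprisal={}, ctx_surprisal={}, word_length={})
    ev, rs, truth = c.simulate(cfg, 170)
    mcfg = ModelConfig(
        networks=(), intercept_only=True, max_steps=2500, eval_every=100,
        patience=10, batch_size=10**9, lr=0.05,
    )
    ds = Dataset(ev, rs)
    m = c.fit(mcfg, ds, ds, seed=0)
    mu, sigma, tau = m.baseline[0], float(positive_link(m.baseline[1])), float(
        positive_link(m.baseline[2])
    )
    b = cfg.baseline
    assert mu == pytest.approx(b.mu, rel=0.05)
    assert sigma == pytest.approx(b.sigma, rel=0.05)
    assert tau == pytest.approx(b.tau, rel=0.05)
    # dual route: agree with scipy's MLE of the same draw
    K, loc, scale = exponnorm.fit(rs["duration_ms"])
    assert mu == pytest.approx(loc, rel=0.01)
    assert sigma == pytest.approx(scale, rel=0.02)
    assert tau == pytest.approx(K * scale, rel=0.02)


def test_fit_is_seed_deterministic(small_sim, linear_fit):
    sp = small_sim["splits"]
    cfg = linear_fit.config
    again = c.fit(cfg, sp["train"], sp["validation"], seed=3)
    assert again.val_loglik_best == linear_fit.val_loglik_best
    for p1, p2 in zip(linear_fit._param_list(), again._param_list()):
        assert np.array_equal(p1, p2)


def test_early_stopping_returns_best_checkpoint(linear_fit):
    vals = [v for _, _, v in linear_fit.training_log]
    assert linear_fit.val_loglik_best == pytest.approx(max(vals))
    assert linear_fit.val_loglik_best >= vals[-1]


def test_full_model_beats_intercept_only_held_out(small_sim, linear_fit):
    sp = small_sim["splits"]
    icfg = ModelConfig(
        networks=(), intercept_only=True, max_steps=400, eval_every=25,
        patience=4, batch_size=10**9, lr=0.05,
    )
    m0 = c.fit(icfg, sp["train"], sp["validation"], seed=3)
    ll_full = linear_fit.loglik(sp["test"].events, sp["test"].responses).mean()
    ll_null = m0.loglik(sp["test"].events, sp["test"].responses).mean()
    assert ll_full >= ll_null


def test_constant_predictor_rejected(small_sim):
    sp = small_sim["splits"]
    ev = sp["train"].events.copy()
    ev["const"] = 1.0
    cfg = c.linear_irf_config(("const",), max_steps=10, eval_every=5, patience=2)
    with pytest.raises(ValueError, match="constant"):
        c.fit(cfg, Dataset(ev, sp["train"].responses), sp["validation"], seed=0)


# ---------------------------------------------------------------------------
# ensembles


def test_ensemble_seeds_and_member_count(small_sim):
    sp = small_sim["splits"]
    cfg = c.linear_irf_config(
        studies.PREDICTORS, max_steps=60, eval_every=20, patience=2,
        batch_size=10**9, lr=0.05,
    )
    ens = c.fit_ensemble(cfg, sp["train"], sp["validation"], n_members=3, base_seed=40)
    assert len(ens) == 3
    assert ens.seeds == [40, 41, 42]


def test_single_member_ensemble_rejected(small_sim):
    sp = small_sim["splits"]
    cfg = c.linear_irf_config(studies.PREDICTORS, max_steps=10)
    with pytest.raises(ValueError):
        c.fit_ensemble(cfg, sp["train"], sp["validation"], n_members=1)


def test_test_loglik_reduces_to_member_loglik(small_sim, linear_fit):
    sp = small_sim["splits"]
    single = c.test_loglik(c.Ensemble([linear_fit]), sp["test"])
    direct = linear_fit.loglik(sp["test"].events, sp["test"].responses)
    assert np.allclose(single, direct)
    # identical members: the mixture equals the common density
    twin = c.test_loglik(c.Ensemble([linear_fit, linear_fit]), sp["test"])
    assert np.allclose(twin, direct)


def test_ensemble_order_invariance(small_sim):
    sp = small_sim["splits"]
    cfg = c.linear_irf_config(
        studies.PREDICTORS, max_steps=60, eval_every=20, patience=2,
        batch_size=10**9, lr=0.05,
    )
    ens = c.fit_ensemble(cfg, sp["train"], sp["validation"], n_members=3, base_seed=40)
    fwd = c.test_loglik(ens, sp["test"])
    rev = c.test_loglik(c.Ensemble(ens.members[::-1]), sp["test"])
    assert np.allclose(fwd, rev)


def test_mlp_backward_matches_finite_differences():
    rng = np.random.default_rng(2)
    net = MLP(3, (5,), 2, rng, out_bias=True)
    # give the zero output layer nonzero values so gradients flow everywhere
    net.params[-2][...] = rng.normal(size=net.params[-2].shape)
    x = rng.normal(size=(4, 3))
    out = net.forward(x)
    d_out = rng.normal(size=out.shape)
    grads, _ = net.backward(d_out)
    h = 1e-6
    for pi in range(len(net.params)):
        flat = net.params[pi].ravel()
        for j in [0, flat.size - 1]:
            orig = flat[j]
            flat[j] = orig + h
            up = (net.forward(x, cache=False) * d_out).sum()
            flat[j] = orig - h
            dn = (net.forward(x, cache=False) * d_out).sum()
            flat[j] = orig
            assert grads[pi].ravel()[j] == pytest.approx((up - dn) / (2 * h), rel=1e-4, abs=1e-7)
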