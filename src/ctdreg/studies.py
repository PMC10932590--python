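"""Canned simulation studies: parameter recovery, test calibration, power.

These are the package's end-to-end validation experiments on synthetic data
with known ground truth:

  * recovery - fit a 10-member neural-IRF ensemble to the default synthetic
    dataset (20,000 responses, effects on the skewness parameter tau) and
    compare the recovered instantaneous effect curves, distributional
    attribution, interaction overlay, and timecourse against the generative
    truth;
  * frequency-ablation calibration - type-I error of the paired permutation
    test when the frequency predictor truly has no effect (small replicates,
    closed-form linear-IRF fits);
  * frequency-ablation power - rejection rate at the default frequency
    effect size on full-size (20,000-response) datasets;
  * interaction calibration/power - the matched two-network comparison with
    the generator's interaction switched off or set large.

Replicate sizes and fit configurations are fixed here so that test-suite
checks, the acceptance script, and the examples all run the same studies.
"""

from __future__ import annotations

import numpy as np

from .comparison import AblationSpec, build_null_config, paired_permutation_test
from .curves import instantaneous_effect, interaction_overlay, timecourse
from .measures import split_dataset
from .model import Ensemble, ModelConfig, NetworkSpec, fit, fit_ensemble, test_loglik
from .synthetic import GeneratorConfig, simulate

__all__ = [
    "PREDICTORS",
    "recovery_model_config",
    "recovery_study",
    "ablation_calibration_study",
    "ablation_power_study",
    "interaction_null_study",
    "interaction_power_study",
]

PREDICTORS = ("freq_surprisal", "ctx_surprisal", "word_length")
CRITICAL_PAIR = ("freq_surprisal", "ctx_surprisal")

# reduced-size neural IRF used for desk-scale recovery runs
_NN_KW = dict(
    hidden=(16,),
    history_max_events=8,
    history_max_seconds=4.0,
    batch_size=1024,
    lr=0.01,
    max_steps=2000,
    eval_every=50,
    patience=8,
)

# closed-form linear-IRF fits for the replicated simulation studies
_LIN_SMALL_KW = dict(max_steps=500, eval_every=25, patience=4, batch_size=10**9, lr=0.05)
_LIN_BIG_KW = dict(max_steps=700, eval_every=50, patience=5, batch_size=2048, lr=0.05)
_INT_SMALL_KW = dict(max_steps=600, eval_every=50, patience=5, batch_size=1024, lr=0.05)
_INT_BIG_KW = dict(max_steps=1000, eval_every=50, patience=6, batch_size=2048, lr=0.05)


def recovery_model_config(predictors=PREDICTORS):
    """Reduced-size neural-IRF configuration for recovery runs."""
    return ModelConfig.single_network(tuple(predictors), **_NN_KW)


def _linear_config(predictors=PREDICTORS, targets=("mu", "sigma", "tau"),
                   interactions=False, **kwargs):
    net = NetworkSpec(
        tuple(predictors),
        targets=tuple(targets),
        hidden=(),
        fixed_kernel=("exponential", 4.0),
        interactions=interactions,
    )
    return ModelConfig(networks=(net,), **kwargs)


def recovery_study(seed, n_members=10, fit_ablated=True):
    """Fit the full (and optionally frequency-ablated) neural ensembles to
    the default synthetic dataset and score recovery against ground truth.

    Returns a dict with the ensembles, the generative truth, the fitted and
    true curves, and summary metrics (truth correlations, distributional
    attribution ratios, additivity score, timecourse decay).
    """
    config = GeneratorConfig()
    events, responses, truth = simulate(config, seed)
    splits = split_dataset(events, responses)
    model_cfg = recovery_model_config()
    ensemble = fit_ensemble(
        model_cfg, splits["train"], splits["validation"],
        n_members=n_members, base_seed=seed + 10,
    )
    out = {
        "truth": truth,
        "splits": splits,
        "ensemble": ensemble,
        "model_config": model_cfg,
    }

    corrs, curves = {}, {}
    for pred in CRITICAL_PAIR:
        cur = instantaneous_effect(ensemble, pred)
        true_curve = truth.instantaneous_curve(pred, cur.grid)
        corrs[pred] = float(np.corrcoef(cur.estimate, true_curve)[0, 1])
        curves[pred] = (cur, true_curve)
    out["curves"] = curves
    out["truth_correlations"] = corrs

    param_ranges = {}
    for scale in ("mu", "sigma", "tau"):
        param_ranges[scale] = instantaneous_effect(
            ensemble, "freq_surprisal", scale=scale
        ).range()
    out["param_ranges"] = param_ranges

    overlay, additivity = interaction_overlay(
        ensemble, "freq_surprisal", "ctx_surprisal"
    )
    main_range = overlay[1].range()
    out["overlay"] = overlay
    out["additivity_score"] = additivity
    out["additivity_pct_of_main"] = 100.0 * additivity / main_range

    tc = timecourse(ensemble, "freq_surprisal")
    out["timecourse"] = tc
    at0 = tc.estimate[0]
    at1s = tc.estimate[np.searchsorted(tc.delays, 1.0)]
    out["timecourse_pct_at_1s"] = 100.0 * at1s / at0 if at0 != 0 else np.nan

    if fit_ablated:
        null_cfg = build_null_config(
            model_cfg, AblationSpec("drop_predictor", ("freq_surprisal",))
        )
        null_ensemble = fit_ensemble(
            null_cfg, splits["train"], splits["validation"],
            n_members=n_members, base_seed=seed + 60,
        )
        out["null_ensemble"] = null_ensemble
        res = paired_permutation_test(
            test_loglik(null_ensemble, splits["test"]),
            test_loglik(ensemble, splits["test"]),
            n_permutations=10000,
            seed=seed,
        )
        out["freq_ablation_result"] = res
    return out


def _one_ablation_comparison(seed, gen_config, model_kw, n_perm=1000):
    """Fit full vs frequency-ablated linear models; return the p-value."""
    events, responses, _ = simulate(gen_config, seed)
    splits = split_dataset(events, responses)
    full_cfg = _linear_config(**model_kw)
    null_cfg = build_null_config(
        full_cfg, AblationSpec("drop_predictor", ("freq_surprisal",))
    )
    mf = fit(full_cfg, splits["train"], splits["validation"], seed=seed * 2 + 1)
    mn = fit(null_cfg, splits["train"], splits["validation"], seed=seed * 2 + 2)
    res = paired_permutation_test(
        test_loglik(Ensemble([mn]), splits["test"]),
        test_loglik(Ensemble([mf]), splits["test"]),
        n_permutations=n_perm,
        seed=seed,
    )
    return res.p_value


def ablation_calibration_study(seed, n_reps=200):
    """Type-I error of the frequency-ablation permutation test.

    The generator's frequency effect is set to zero (H0 true); each
    replicate simulates a small dataset (4 participants x 2 texts x 100
    words = 800 responses), fits full and ablated linear-IRF models, and
    tests at alpha = 0.05.  Returns the array of p-values.
    """
    gen = GeneratorConfig(
        n_participants=4, n_texts=2, n_words_per_text=100
    ).with_effects(freq_surprisal={"tau": 0.0})
    return np.array(
        [
            _one_ablation_comparison(seed + i, gen, _LIN_SMALL_KW)
            for i in range(n_reps)
        ]
    )


def ablation_power_study(seed, n_reps=15):
    """Power of the frequency-ablation test at the default effect size on
    full-size datasets (20,000 responses).  Returns the p-values."""
    gen = GeneratorConfig()
    return np.array(
        [
            _one_ablation_comparison(seed + i, gen, _LIN_BIG_KW)
            for i in range(n_reps)
        ]
    )


def _one_interaction_comparison(seed, gen_config, model_kw, n_perm=1000):
    """Matched two-network interaction comparison; returns the p-value."""
    events, responses, _ = simulate(gen_config, seed)
    splits = split_dataset(events, responses)
    full_cfg = _linear_config(targets=("tau",), interactions=True, **model_kw)
    null_cfg, alt_cfg = build_null_config(
        full_cfg, AblationSpec("interaction_null", CRITICAL_PAIR)
    )
    mn = fit(null_cfg, splits["train"], splits["validation"], seed=seed * 2 + 1)
    ma = fit(alt_cfg, splits["train"], splits["validation"], seed=seed * 2 + 2)
    res = paired_permutation_test(
        test_loglik(Ensemble([mn]), splits["test"]),
        test_loglik(Ensemble([ma]), splits["test"]),
        n_permutations=n_perm,
        seed=seed,
    )
    return res.p_value


def interaction_null_study(seed, n_reps=50):
    """Rejection rate of the interaction test under additive truth
    (interaction_coef = 0), replicates of 3,200 responses."""
    gen = GeneratorConfig(
        n_participants=4, n_texts=4, n_words_per_text=200, interaction_coef=0.0
    )
    return np.array(
        [
            _one_interaction_comparison(seed + i, gen, _INT_SMALL_KW)
            for i in range(n_reps)
        ]
    )


def interaction_power_study(seed, n_reps=10, coef=30.0):
    """Rejection rate of the interaction test with a large injected
    frequency x predictability interaction, full-size datasets."""
    gen = GeneratorConfig(interaction_coef=coef)
    return np.array(
        [
            _one_interaction_comparison(seed + i, gen, _INT_BIG_KW)
            for i in range(n_reps)
        ]
    )
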