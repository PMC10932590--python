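import warnings

import numpy as np
import pytest

import ctdreg as c
from ctdreg import studies

# the heavy fitting studies emit benign convergence warnings; keep test
# output readable
warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def small_sim():
    """A small synthetic dataset with its splits and generative truth."""
    cfg = c.GeneratorConfig(n_participants=4, n_texts=2, n_words_per_text=100)
    events, responses, truth = c.simulate(cfg, 7)
    return {
        "config": cfg,
        "events": events,
        "responses": responses,
        "truth": truth,
        "splits": c.split_dataset(events, responses),
    }


@pytest.fixture(scope="session")
def linear_fit(small_sim):
    """One quick linear-IRF fit on the small dataset."""
    cfg = c.linear_irf_config(
        studies.PREDICTORS, max_steps=500, eval_every=25, patience=4,
        batch_size=10**9, lr=0.05,
    )
    sp = small_sim["splits"]
    return c.fit(cfg, sp["train"], sp["validation"], seed=3)


@pytest.fixture(scope="session")
def recovery():
    """The full parameter-recovery study: 10-member neural ensembles (full
    and frequency-ablated) fitted to the default 20,000-response dataset."""
    return studies.recovery_study(seed=11)
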