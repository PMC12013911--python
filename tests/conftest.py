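import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import multilab as ml


@pytest.fixture(scope="session")
def published_effects():
    return ml.load_published_effects()

@pytest.fixture(scope="session")
def published_overall():
    return ml.load_published_overall()


def two_group_table(control, treated, outcome_id="o", lab_id="L"):
    """Minimal single-lab gaussian observation table from two value lists."""
    vals = list(control) + list(treated)
    return pd.DataFrame({
        "lab_id": lab_id, "outcome_id": outcome_id,
        "unit_id": [f"u{i}" for i in range(len(vals))],
        "treatment": ["control"] * len(control) + ["treated"] * len(treated),
        "timepoint": 0, "response": vals, "scorable": True,
    })


def binary_cluster_data(n_units, n_obs, sigma, beta=0.8, alpha=0.2, trials=1, seed=3):
    """Simulated random-intercept binomial rows for GLMM/oracle comparisons."""
    from scipy.special import expit
    rng = np.random.default_rng(seed)
    x = np.repeat([0, 1], n_units // 2)
    u = rng.normal(0, sigma, n_units)
    p = expit(np.repeat(alpha + beta * x + u, n_obs))
    m = np.full(n_units * n_obs, trials, dtype=float)
    s = rng.binomial(trials, p).astype(float)
    X = np.column_stack([np.ones(n_units * n_obs), np.repeat(x, n_obs)])
    groups = np.repeat(np.arange(n_units), n_obs)
    return X, s, m, groups
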