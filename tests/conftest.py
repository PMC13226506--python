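import numpy as np
import pandas as pd
import pytest

from targetmr import CausalScenario, harmonize, retained, simulate_exposure_stats, simulate_outcome_stats


def make_pairs(bx, sx, by, sy, snp_ids=None):
    """Assemble a minimal harmonized-pair table from arrays."""
    n = len(bx)
    return pd.DataFrame(
        {
            "SNP": snp_ids if snp_ids is not None else [f"rs{i}" for i in range(n)],
            "beta_exp": np.asarray(bx, float),
            "se_exp": np.asarray(sx, float),
            "beta_out": np.asarray(by, float),
            "se_out": np.asarray(sy, float),
            "action": ["none"] * n,
        }
    )


def random_pairs(rng, n=13, theta=-0.306, pleiotropy=0.0):
    """Draw a synthetic harmonized-pair instance with known causal slope."""
    bx_true = rng.normal(0.1, 0.02, n)
    sx = rng.uniform(0.005, 0.02, n)
    sy = rng.uniform(0.02, 0.06, n)
    bx = bx_true + rng.normal(0, sx)
    by = theta * bx_true + pleiotropy + rng.normal(0, sy)
    return make_pairs(bx, sx, by, sy)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def default_scenario():
    return CausalScenario(seed=11)


@pytest.fixture
def harmonized_default(default_scenario):
    exp, truth = simulate_exposure_stats(default_scenario)
    out = simulate_outcome_stats(default_scenario, truth)
    pairs, _ = harmonize(exp, out)
    return retained(pairs)
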