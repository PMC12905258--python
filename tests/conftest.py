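import numpy as np
import pandas as pd
import pytest

from methylink.synthetic import (SimulationConfig, simulate_cohorts,
                                 simulate_genetic_layer)


@pytest.fixture(scope="session")
def small_config():
    """A compact three-cohort design used by several integration tests."""
    return SimulationConfig(
        n_per_cohort=(150, 150, 220), n_cpgs=250, n_causal_forward=25,
        n_causal_reverse=6, effect_sd=0.012, seed=42)


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_cohorts(small_config)


@pytest.fixture(scope="session")
def small_layer(small_config, small_sim):
    _, truth = small_sim
    return simulate_genetic_layer(truth, small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_summary(snps, beta, se, eaf=None, ea="A", oa="G", n=10_000):
    """Hand-build a SummaryStats frame."""
    k = len(snps)
    eaf = np.full(k, 0.3) if eaf is None else np.asarray(eaf, float)
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    ea = [ea] * k if isinstance(ea, str) else list(ea)
    oa = [oa] * k if isinstance(oa, str) else list(oa)
    from scipy.special import ndtr
    p = np.maximum(2 * ndtr(-np.abs(beta / se)), 1e-300)
    return pd.DataFrame({
        "snp_id": snps, "effect_allele": ea, "other_allele": oa,
        "eaf": eaf, "beta": beta, "se": se, "p": p, "n": n})
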