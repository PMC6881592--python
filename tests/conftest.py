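from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import epimetab as em

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced-scale cohort with planted effects, shared across tests."""
    cfg = em.SimConfig(n_genes=300, n_tumor=60, n_normal=20,
                       n_driver_targets=5, n_mutation_responsive=5, seed=123)
    return em.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_null_cohort():
    cfg = em.SimConfig(n_genes=300, n_tumor=60, n_normal=20,
                       n_driver_targets=5, n_mutation_responsive=5, seed=321)
    return em.simulate_null(cfg)


@pytest.fixture(scope="session")
def published_calls():
    """Published pan-cancer integrated probe-gene calls (fixture TSV)."""
    return pd.read_csv(DATA_DIR / "published_integrated_calls.tsv", sep="\t")


@pytest.fixture
def rng():
    return np.random.default_rng(7)
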