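import numpy as np
import pandas as pd
import pytest

from hatchboost import (BetaConfig, SimConfig, GenotypeMatrix,
                        simulate_population)


@pytest.fixture(scope="session")
def null_beta():
    return BetaConfig(year_sd=0.0, origin_nor=0.0, body_length=0.0,
                      return_day=0.0)


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully linked population used by several test modules."""
    cfg = SimConfig(n_years=10, founders_per_year=120, n_loci=60, seed=11)
    individuals, gm, truth = simulate_population(cfg)
    return cfg, individuals, gm, truth


@pytest.fixture(scope="session")
def clean_parentage_sim(null_beta):
    """Error-free, fully sampled sim with enough loci for parentage."""
    cfg = SimConfig(n_years=8, founders_per_year=80, n_loci=150, seed=5,
                    sampling_rate=1.0, missing_rate=0.0, per_allele_error=0.0,
                    beta=null_beta)
    individuals, gm, truth = simulate_population(cfg)
    return cfg, individuals, gm, truth


def toy_matrix(calls, n_ind=None, prefix="ind"):
    calls = np.asarray(calls, dtype=float)
    ids = [f"{prefix}{i}" for i in range(calls.shape[0])]
    loci = [f"L{j}" for j in range(calls.shape[1])]
    return GenotypeMatrix(np.array(ids, dtype=object),
                          np.array(loci, dtype=object), calls)


@pytest.fixture
def make_matrix():
    return toy_matrix
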