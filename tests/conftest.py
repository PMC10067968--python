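import numpy as np
import pandas as pd
import pytest

from pinnclock import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """~76-sample, 3-species cohort with 200 CpGs (20 age-related)."""
    cfg = SimConfig(
        n_cpgs=200,
        n_age_cpgs=20,
        animals_per_species=15,
        tissue_scheme=0.7,
        slope_scale=0.06,
        seed=42,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_dataset(small_sim):
    return small_sim[0]


@pytest.fixture(scope="session")
def small_truth(small_sim):
    return small_sim[1]


@pytest.fixture()
def tiny_sheet():
    """Hand-written 6-sample sheet: 2 species, mixed tissues, one paired animal."""
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4", "s5", "s6"],
            "animal_id": ["a1", "a1", "a2", "a3", "a4", "a5"],
            "species": ["seal", "seal", "seal", "walrus", "walrus", "walrus"],
            "tissue": ["blood", "skin", "blood", "blood", "skin", "blood"],
            "age_years": [1.0, 1.0, 5.0, 10.0, 20.0, 30.0],
            "origin": ["wild"] * 6,
        }
    )


@pytest.fixture()
def tiny_beta(tiny_sheet):
    rng = np.random.default_rng(0)
    cpgs = [f"cg{i:03d}" for i in range(5)]
    vals = rng.uniform(0.05, 0.95, (5, 6))
    return pd.DataFrame(vals, index=cpgs, columns=tiny_sheet["sample_id"].tolist())
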