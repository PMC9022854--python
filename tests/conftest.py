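import numpy as np
import pandas as pd
import pytest

import qcindex as qc
from qcindex.ratios import RATIO_COLUMNS
from qcindex.tables import AGE_STANDARDIZED, MEASURES


def make_measure_table(strata, measures=None):
    """Build a long-format age-standardized measure table from a dict of
    {(location, year, sex): {measure: value}}."""
    rows = []
    for (loc, year, sex), vals in strata.items():
        for m, v in vals.items():
            rows.append(
                {
                    "location": loc,
                    "year": year,
                    "sex": sex,
                    "age_group": AGE_STANDARDIZED,
                    "measure": m,
                    "value": v,
                }
            )
    return pd.DataFrame(rows)


def full_stratum(incidence=20.0, deaths=10.0, prevalence=200.0, yll=150.0, yld=30.0):
    return {
        "incidence": incidence,
        "deaths": deaths,
        "prevalence": prevalence,
        "yll": yll,
        "yld": yld,
        "daly": yll + yld,
    }


def random_ratio_table(rng, n=50, with_keys=True):
    """Positive, correlated 4-ratio table for PCA tests."""
    q = rng.uniform(0.05, 0.95, size=n)
    noise = lambda: np.exp(rng.normal(0, 0.15, size=n))
    df = pd.DataFrame(
        {
            "mir": (0.1 + 0.8 * (1 - q)) * noise(),
            "prev_inc": (1 + 9 * q) * noise(),
            "daly_prev": (0.2 + 2 * (1 - q)) * noise(),
            "yll_yld": (1 + 20 * (1 - q)) * noise(),
        }
    )
    if with_keys:
        df.insert(0, "location", [f"L{i:03d}" for i in range(n)])
        df.insert(1, "year", 2019)
        df.insert(2, "sex", "both")
        df.insert(3, "age_group", AGE_STANDARDIZED)
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_table():
    strata = {
        ("A", 2019, "both"): full_stratum(26.7, 13.7, 308.5, 250.0, 45.5),
        ("B", 2019, "both"): full_stratum(30.0, 8.0, 400.0, 160.0, 60.0),
        ("C", 2019, "both"): full_stratum(10.0, 7.0, 60.0, 140.0, 12.0),
        ("D", 2019, "both"): full_stratum(15.0, 3.0, 230.0, 60.0, 35.0),
    }
    return make_measure_table(strata)


@pytest.fixture(scope="session")
def default_run():
    """One default synthetic run shared across tests: config, latent truth,
    measures, and the full pipeline result."""
    cfg = qc.SyntheticConfig()
    latent = qc.simulate_latent(cfg)
    measures = qc.simulate_measures(latent, cfg)
    result = qc.run_pipeline(measures)
    return cfg, latent, measures, result


@pytest.fixture(scope="session")
def noise_free_run():
    cfg = qc.SyntheticConfig(noise_sd=0.0, sdi_noise_sd=0.0)
    latent = qc.simulate_latent(cfg)
    measures = qc.simulate_measures(latent, cfg)
    result = qc.run_pipeline(measures)
    return cfg, latent, measures, result
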