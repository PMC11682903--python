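import numpy as np
import pandas as pd
import pytest

from d2tpsa.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """One default-configuration cohort, shared across read-only tests."""
    return generate_cohort(CohortConfig(seed=20240))


@pytest.fixture(scope="session")
def clean_cohort() -> pd.DataFrame:
    """A cohort without missingness, for complete-case and model tests."""
    cfg = CohortConfig(n_patients=400, missingness={}, seed=7)
    return generate_cohort(cfg)


def make_count_data(
    n: int,
    seed: int,
    coefficients: dict[str, float],
    prevalences: dict[str, float],
    base_rate: float = 0.01,
    t_low: float = 12.0,
    t_high: float = 240.0,
) -> pd.DataFrame:
    """Minimal Poisson-offset test bed: binary covariates, exposure T, counts
    drawn from rate = T * base_rate * exp(x'beta); ``y`` is the count and
    ``exposure`` the offset carrier."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"patient_id": np.arange(n)})
    eta = np.zeros(n)
    for name, p in prevalences.items():
        df[name] = (rng.random(n) < p).astype(float)
        eta += coefficients.get(name, 0.0) * df[name].to_numpy()
    T = rng.uniform(t_low, t_high, size=n)
    df["exposure"] = T
    df["y"] = rng.poisson(T * base_rate * np.exp(eta))
    return df
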