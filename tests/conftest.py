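import numpy as np
import pandas as pd
import pytest

from histoarea import SyntheticCohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-patient cohort with moderate censoring, shared across tests."""
    cfg = SyntheticCohortConfig(
        n_patients=20, map_rows=40, map_cols=40, censor_rate=0.25, seed=42
    )
    return generate_cohort(cfg)


@pytest.fixture
def uncensored_frame():
    """Deterministic fully-uncensored survival table with distinct times."""

    def make(n: int, seed: int = 0) -> pd.DataFrame:
        r = np.random.default_rng(seed)
        times = np.sort(r.exponential(1.0, size=n)) + 0.01
        return pd.DataFrame(
            {
                "patient_id": [f"P{i:03d}" for i in range(n)],
                "time": times,
                "event": 1,
            }
        )

    return make
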