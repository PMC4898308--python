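import numpy as np
import pandas as pd
import pytest

from renalrisk.synthetic_cohort import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """A mid-sized cohort at the default study conditions, shared across tests."""
    return generate_cohort(SimulationConfig(n_patients=3000, seed=11))


@pytest.fixture(scope="session")
def complete_cohort() -> pd.DataFrame:
    """Cohort without any masking, for tests that need complete covariates."""
    return generate_cohort(SimulationConfig(n_patients=2000, seed=13, missing_fracs={}))


def uncensored_instance(rng: np.random.Generator, n: int, case_frac: float = 0.3):
    """Random (risks, times, events) with every subject observed at the horizon.

    Cases get an ESRD event before t=1, controls survive past it; usable as a
    censoring-free fixture where IPCW weights must all equal 1.
    """
    risks = rng.uniform(size=n)
    is_case = rng.uniform(size=n) < case_frac
    times = np.where(is_case, rng.uniform(0.05, 0.95, size=n), rng.uniform(1.05, 3.0, size=n))
    events = np.where(is_case, 1, 0)
    return risks, times, events
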