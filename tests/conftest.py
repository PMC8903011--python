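import numpy as np
import pandas as pd
import pytest

from fetalsplice.simulate import CohortConfig, simulate_cohort, simulate_study


@pytest.fixture(scope="session")
def table1():
    from fetalsplice.events import load_dm1_cortex_events

    return load_dm1_cortex_events()


@pytest.fixture(scope="session")
def small_study():
    """Paired developmental/DM1/adult cohorts sharing 300 events (36 regulated)."""
    cfg = CohortConfig(n_events=300, frac_true_fetal_shift=0.12, seed=2)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The default study conditions: 2000 events, 10% regulated, 20/20, depth 50."""
    return simulate_cohort(CohortConfig(seed=1), "development")


@pytest.fixture(scope="session")
def quiet_config():
    """Noise-free configuration for deterministic construction checks."""
    return CohortConfig(
        n_events=50,
        regulator_noise_sd=0.0,
        psi_logit_noise_sd=0.0,
        depth=2000.0,
        concentration=np.inf,
        seed=5,
    )
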