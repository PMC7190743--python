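import pandas as pd
import pytest

from variomics.registry import default_assays
from variomics.roster import default_roster, roster_truth_frame
from variomics.simulate import SimulationConfig, simulate_replicates


@pytest.fixture(scope="session")
def roster():
    return default_roster()


@pytest.fixture(scope="session")
def assays():
    return default_assays()


@pytest.fixture(scope="session")
def truth(roster) -> pd.DataFrame:
    return roster_truth_frame(roster).set_index("variant_id")


@pytest.fixture(scope="session")
def noise_free_replicates(roster, assays) -> pd.DataFrame:
    cfg = SimulationConfig(n_batches=2, reps_per_batch=3, sigma_batch=0.0, sigma_resid=0.0, seed=11)
    return simulate_replicates(roster, cfg, assays)


@pytest.fixture(scope="session")
def noisy_replicates(roster, assays) -> pd.DataFrame:
    cfg = SimulationConfig(n_batches=4, reps_per_batch=4, sigma_batch=0.05, sigma_resid=0.15, seed=23)
    return simulate_replicates(roster, cfg, assays)
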