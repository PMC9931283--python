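import numpy as np
import pytest

from walkmort.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """A moderate cohort under the default study conditions (fast ENMO path)."""
    return simulate_cohort(SimConfig(n_participants=1500, seed=101))


@pytest.fixture(scope="session")
def model_table(default_cohort):
    """Included participants with demographics, sensor aggregate and outcome."""
    p = default_cohort.participants
    cols = ["id", "age", "sex", "race", "site", "ENMOtrunc", "ENMOabs", "time", "event"]
    return p.loc[p["included"], cols].reset_index(drop=True)
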