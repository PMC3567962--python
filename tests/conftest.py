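import numpy as np
import pytest

from htncea import reference_config, run_psa


@pytest.fixture(scope="session")
def medium_config():
    return reference_config("medium")


@pytest.fixture(scope="session")
def configs():
    return {s: reference_config(s) for s in ("low", "medium", "high")}


@pytest.fixture(scope="session")
def psa_by_stratum(configs):
    """1000-iteration PSA per stratum, the study's Monte Carlo size."""
    seeds = np.random.SeedSequence(20130123).spawn(3)
    return {
        s: run_psa(configs[s], n_iter=1000, seed=int(child.generate_state(1)[0] % 2**31))
        for s, child in zip(("low", "medium", "high"), seeds)
    }
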