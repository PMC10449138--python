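import numpy as np
import pandas as pd
import pytest

import serotrace as st


@pytest.fixture(scope="session")
def quickstart_inputs():
    return st.quickstart_inputs(rng_seed=1)


@pytest.fixture(scope="session")
def quickstart_run():
    """One full quickstart simulation, shared across read-only tests."""
    return st.run_quickstart(rng_seed=1)


@pytest.fixture(scope="session")
def quickstart_model_pars(quickstart_inputs):
    return quickstart_inputs["model_pars"]


@pytest.fixture(scope="session")
def simple_map():
    """Infection + vaccination boosting the same single biomarker."""
    return st.BiomarkerMap(pd.DataFrame({
        "exposure_id": [1, 2], "biomarker_id": [1, 1]}))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
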