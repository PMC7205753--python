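import numpy as np
import pytest

import seamtrial as st

# linkage parameters of the reference fixture (posterior means of the
# worked example): log(T) = a + b*X + N(0, sigma^2)
LINKAGE = (0.16, -1.37, 1.53)

SCENARIO1 = [0.10, 0.15, 0.25, 0.30]
SCENARIO2 = [0.10, 0.15, 0.30, 0.30]
NULL10 = [0.10, 0.10, 0.10, 0.10]


@pytest.fixture(scope="session")
def linkage():
    return LINKAGE


@pytest.fixture
def scenario1_design():
    return st.DesignConfig.from_event_rates(SCENARIO1, threshold_delta=0.3)


@pytest.fixture
def null_design():
    return st.DesignConfig.from_event_rates(NULL10, threshold_delta=0.3)


@pytest.fixture(scope="session")
def scenario1_run():
    """One moderately sized scenario-1 OC run shared across tests."""
    design = st.DesignConfig.from_event_rates(SCENARIO1, threshold_delta=0.3)
    oc = st.OCConfig(n_replicates=400, master_seed=11, compute_counterfactual=True)
    return design, oc, st.run_oc(design, oc)
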