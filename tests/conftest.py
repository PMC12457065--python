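import numpy as np
import pytest

import trajnet as tn
from trajnet.simulate import DEFAULT_TRANSITIONS


@pytest.fixture(scope="session")
def growth_panel():
    """Two-class growth panel at the default stated-world parameters."""
    return tn.generate_growth_panel(tn.default_growth_spec(n_subjects=400, seed=11))


@pytest.fixture(scope="session")
def var_panel():
    """Stationary VAR panel with the high-risk transition pattern."""
    spec = tn.CrossLagSpec(
        n_subjects=600, transition=DEFAULT_TRANSITIONS["high_risk"], seed=21
    )
    return tn.generate_var_panel(spec)


@pytest.fixture(scope="session")
def fitted_two_class(growth_panel):
    return tn.fit_gmm(growth_panel, 2, n_starts=4, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
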