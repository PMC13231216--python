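import numpy as np
import pytest

from tddmri.fitting import FitConfig, _ForwardCache
from tddmri.scheme import default_scheme


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def forward_cache(scheme):
    """Shared spline cache so fitting tests do not rebuild the spectral sums."""
    return _ForwardCache(scheme, FitConfig())


@pytest.fixture(scope="session")
def table1_training():
    """The 2x2 training-set TSR table as a long-format cohort frame."""
    import pandas as pd

    return pd.DataFrame(
        {
            "response": [1] * 106 + [0] * 48,
            "tsr": [">=50%"] * 41 + ["<50%"] * 65 + [">=50%"] * 28 + ["<50%"] * 20,
        }
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
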