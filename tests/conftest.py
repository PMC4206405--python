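import numpy as np
import pandas as pd
import pytest

from mwmar import AbundancePanel, CovariatePanel, MaskSpec, MARParams
from mwmar.simulate import simulate_mar


@pytest.fixture
def stable_params_2():
    """Well-conditioned 2-taxon generating model."""
    return MARParams(
        a=np.array([0.2, -0.1]),
        b=np.array([[0.5, 0.2], [0.1, 0.6]]),
        sigma2=np.array([0.1, 0.1]),
    )


@pytest.fixture
def small_panel(stable_params_2):
    return simulate_mar(stable_params_2, T=120, seed=7, taxon_names=["x", "y"])


def monthly_series(values, start="1980-01", name=None):
    idx = pd.period_range(start, periods=len(values), freq="M")
    return pd.Series(np.asarray(values, dtype=float), index=idx, name=name)
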