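import numpy as np
import pytest

from cellmech import SLSParams, simulate_creep, simulate_indentation


@pytest.fixture
def ref_params():
    """Reference SLS triplet used in hand-computed examples."""
    return SLSParams(k1=200.0, k2=100.0, mu=300.0)


@pytest.fixture
def noiseless_record(ref_params):
    return simulate_creep(ref_params, delta_p=500.0, rp=3.5e-6, n_points=200)


@pytest.fixture
def noiseless_curve():
    return simulate_indentation(1721.0)
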