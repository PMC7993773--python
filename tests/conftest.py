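import numpy as np
import pytest

from stpfit.kernels import Kernel
from stpfit.srp import SRPParameters


@pytest.fixture
def mono_exp_params():
    """Facilitating mono-exponential SRP synapse with a variance kernel."""
    return SRPParameters(
        mu_kernel=Kernel.exponential([0.1], [0.2], baseline=-1.5),
        sigma_kernel=Kernel.exponential([0.1], [0.15], baseline=-1.5),
        sigma_scale=1.5)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
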