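import numpy as np
import pytest

from chlorofret.synthetic import psi_supercomplex


@pytest.fixture(scope="session")
def psi():
    """PSI–ACPI supercomplex stand-in; built once, treated as read-only."""
    return psi_supercomplex(seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
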