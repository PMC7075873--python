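import math

import numpy as np
import pytest

from mrebtwist.core_model import FilamentParams


@pytest.fixture(scope="session")
def wt() -> FilamentParams:
    """Wild-type flat-membrane parameter set."""
    return FilamentParams.wild_type()


@pytest.fixture(scope="session")
def wt_cyl() -> FilamentParams:
    """Wild-type parameters on an E. coli-sized cylinder (r = 400 nm)."""
    return FilamentParams.wild_type(r=400.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
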