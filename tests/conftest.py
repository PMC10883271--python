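import numpy as np
import pytest

from telofibre import FibreParams, WLCParams


@pytest.fixture
def wlc_inext() -> WLCParams:
    """Inextensible WLC (S = inf) with the default constants."""
    return WLCParams(stretch_modulus=float("inf"))


@pytest.fixture
def fibre_defaults() -> FibreParams:
    """The default 20-nucleosome, 157 bp repeat array on 3242 bp DNA."""
    return FibreParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
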