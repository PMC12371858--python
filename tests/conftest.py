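import numpy as np
import pytest

from tvfmap import MESEProtocol, SHORT_TE


@pytest.fixture(scope="session")
def short_te_170() -> MESEProtocol:
    """Short-TE-range CPMG protocol with the imperfect 170° refocusing pulse."""
    return MESEProtocol(
        tr_ms=500.0, te_first_ms=6.4, delta_te_ms=6.4, n_echoes=13,
        refocusing_flip_deg=170.0,
    )


@pytest.fixture(scope="session")
def short_te() -> MESEProtocol:
    return SHORT_TE


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
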