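import numpy as np
import pytest

from nearzero import RetentostatParams


@pytest.fixture
def retentostat_params() -> RetentostatParams:
    """The anaerobic glucose-limited retentostat operating point:
    D = 0.025 h-1, 50 g/L glucose feed, ms = 0.50 mmol g-1 h-1,
    Ysx_max = 0.097 g g-1, Cx0 from the chemostat balance."""
    return RetentostatParams(D=0.025, Cs_in=50.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
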