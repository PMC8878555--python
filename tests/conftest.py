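import numpy as np
import pytest

from ehgpred.synthetic import GeneratorParams, TERM_PARAMS, PRETERM_PARAMS

# Short records (8 min instead of 30) keep the unit suite fast while still
# leaving 2 full 1-min windows after the 180 s trims.
SHORT = dict(duration=480.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def short_term_params():
    return GeneratorParams(**SHORT)


@pytest.fixture(scope="session")
def short_preterm_params():
    return GeneratorParams(
        **SHORT,
        burst_rate=PRETERM_PARAMS.burst_rate,
        burst_amp=PRETERM_PARAMS.burst_amp,
        burst_freq_low=PRETERM_PARAMS.burst_freq_low,
        burst_freq_high=PRETERM_PARAMS.burst_freq_high,
    )
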