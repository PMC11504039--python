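import numpy as np
import pytest

from valvekit import synthetic as syn


@pytest.fixture
def noiseless_waveform_params():
    return syn.WaveformParams(noise_sd_pressure=0.0, noise_sd_flow=0.0, seed=0)


@pytest.fixture
def noiseless_waveform(noiseless_waveform_params):
    return syn.gen_pulse_waveform(noiseless_waveform_params)


@pytest.fixture
def default_indentation():
    return syn.gen_indentation_record(syn.IndentationParams(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
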