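import numpy as np
import pytest

import graftflow as gf


@pytest.fixture(scope="session")
def table3():
    return gf.table3_branches()


@pytest.fixture(scope="session")
def systemic():
    return gf.SystemicState()


@pytest.fixture(scope="session")
def default_schedule():
    return gf.PulseSchedule()


@pytest.fixture(scope="session")
def inlet_program(default_schedule):
    og = gf.og_flow_waveform(default_schedule, mean_flow=6.7e-5)
    native = gf.native_hf_waveform(5.33e-5)
    return gf.InletProgram(og=og, native=native)


@pytest.fixture(scope="session")
def aorta():
    return gf.default_aorta()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
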