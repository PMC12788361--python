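import dataclasses

import pytest

from slidegait import synthetic as syn


@pytest.fixture(scope="session")
def default_cfg():
    return syn.default_config()


@pytest.fixture(scope="session")
def noiseless_cfg(default_cfg):
    return dataclasses.replace(default_cfg, angle_noise_sd=0.0, pressure_noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_left(noiseless_cfg):
    return syn.generate_cycle(noiseless_cfg, "left")


@pytest.fixture(scope="session")
def noiseless_right(noiseless_cfg):
    return syn.generate_cycle(noiseless_cfg, "right")
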