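import numpy as np
import pytest

from ednasex import SimulationConfig, WellCount


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture
def sim_cfg():
    return SimulationConfig()


def make_well(k, n, target="male", sample_id="s1", well_id="w1",
              template_volume_ul=4.0, dilution_factor=1.0):
    return WellCount(
        well_id=well_id, sample_id=sample_id, target=target,
        positives=k, accepted=n,
        template_volume_ul=template_volume_ul,
        dilution_factor=dilution_factor,
    )


@pytest.fixture
def well_factory():
    return make_well
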