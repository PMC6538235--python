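import matplotlib

matplotlib.use("Agg")

import pytest

from srsphys.synthetic import SyntheticBeamParams, make_beam_dataset


@pytest.fixture(scope="session")
def params():
    return SyntheticBeamParams()


@pytest.fixture(scope="session")
def beam_data(params):
    return make_beam_dataset(params)
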