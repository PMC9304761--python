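import numpy as np
import pytest

from cpus.landscape import Landscape, LigandState


@pytest.fixture
def zero_landscape():
    """U identically zero everywhere."""
    return Landscape(
        well_depth=0.0, rep_amplitude=0.0, lj_epsilon=0.0,
        vdw_tail_amplitude=0.0, elec_amplitude=0.0,
    )


@pytest.fixture
def default_landscape():
    return Landscape()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_state(point):
    return LigandState.single_bead(point)
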