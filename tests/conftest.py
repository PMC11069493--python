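import numpy as np
import pytest

from esiopt.classify import PreprocConfig, preprocess
from esiopt.headmodel import ShellModel, build_montage, build_source_space, forward_gain
from esiopt.simulate import (
    MiConfig,
    RoiSpec,
    SimConfig,
    default_hand_knob_markers,
    select_roi,
    simulate_epochs,
    simulate_mi_dataset,
)


@pytest.fixture(scope="session")
def montage72():
    return build_montage("10-10")


@pytest.fixture(scope="session")
def src200():
    """Reduced bilateral source space: 100 sources per hemisphere."""
    return build_source_space(100, seed=0)


@pytest.fixture(scope="session")
def lf72(montage72, src200):
    return forward_gain(ShellModel(), montage72, src200)


@pytest.fixture(scope="session")
def roi40(src200):
    roi = select_roi(src200, RoiSpec(default_hand_knob_markers(), k=20))
    assert roi.size == 40
    return roi


@pytest.fixture(scope="session")
def epochs80(lf72, roi40):
    """80 noiseless epochs with the two 10%-amplitude background sources."""
    epochs, truths = simulate_epochs(lf72, roi40, SimConfig(), seed=11)
    return epochs, truths


@pytest.fixture(scope="session")
def single_source_epochs(lf72, roi40):
    epochs, truths = simulate_epochs(lf72, roi40, SimConfig(), seed=11, background=False)
    return epochs, truths


@pytest.fixture(scope="session")
def src600():
    """Denser test-scale source space for the motor-imagery fixtures."""
    return build_source_space(300, seed=0)


@pytest.fixture(scope="session")
def lf600(montage72, src600):
    return forward_gain(ShellModel(), montage72, src600)


@pytest.fixture(scope="session")
def mi_roi(src600):
    roi = select_roi(src600, RoiSpec(default_hand_knob_markers(), k=20))
    assert roi.size == 40
    return roi


@pytest.fixture(scope="session")
def mi_epochs(lf600, mi_roi, src600):
    left = mi_roi[mi_roi < len(src600) // 2]
    right = mi_roi[mi_roi >= len(src600) // 2]
    return simulate_mi_dataset(lf600, left, right, MiConfig(), seed=5)


@pytest.fixture(scope="session")
def mi_prepared(mi_epochs):
    return preprocess(mi_epochs, PreprocConfig())
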