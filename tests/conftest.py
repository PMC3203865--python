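import numpy as np
import pytest
from hypothesis import settings

from vibracal.mechanics import GridSpec
from vibracal.synthetic import (
    AcquisitionModel,
    ImageSpec,
    SubstrateFieldModel,
    default_cell_phantom,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def field_model():
    return SubstrateFieldModel()


@pytest.fixture(scope="session")
def grid():
    # 2 µm nodes covering the 192 x 192 µm default scene
    return GridSpec(origin=(0.0, 0.0), shape=(97, 97), spacing=2.0)


@pytest.fixture(scope="session")
def cell_scene():
    """Default disk phantom plus its probe position and noiseless acquisition."""
    cell = default_cell_phantom(ImageSpec())
    return cell, cell.probe_position(), AcquisitionModel(shot_noise=0.0)


@pytest.fixture(scope="session")
def noisy_acquisition():
    return AcquisitionModel()


def make_rect_stack(
    value_donor=100.0,
    value_acceptor=200.0,
    shape=(5, 40, 40),
    pixel_size=1.0,
    stimulus_frame=3,
):
    """Uniform two-channel stack for arithmetic-level tests."""
    from vibracal.imaging import ChannelStack

    donor = np.full(shape, value_donor)
    acceptor = np.full(shape, value_acceptor)
    return ChannelStack(
        donor=donor,
        acceptor=acceptor,
        pixel_size=pixel_size,
        frame_interval=1.0,
        stimulus_frame=stimulus_frame,
    )
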