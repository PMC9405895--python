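import numpy as np
import pytest

from rtpcflow.io import AcquisitionMeta, PCSeries
from rtpcflow.segmentation import SeedBox
from rtpcflow.simulate import FlowSimParams, PhantomParams, gen_pc_phantom


@pytest.fixture(scope="session")
def default_meta():
    return AcquisitionMeta(
        venc=70.0,
        pixel_spacing=(0.7, 0.7),
        slice_thickness=8.6,
        frame_interval=0.0585,
        start_time=1_000_000.0,
        vessel_label="IJV",
        breathing_mode="F",
    )


@pytest.fixture(scope="session")
def quiet_phantom():
    """Noiseless pulsatile phantom with its ground truth (shared, read-only)."""
    p = PhantomParams(flow=FlowSimParams(noise_sd=0.0, seed=7))
    return p, *gen_pc_phantom(p)


@pytest.fixture
def center_box():
    return SeedBox(box=(38, 54, 58, 74), seed=(48, 64))


@pytest.fixture
def small_series(default_meta):
    """Tiny 3-frame series with a bright 3x3 block for fast segmentation tests."""
    mag = np.full((3, 12, 12), 10.0)
    mag[:, 4:7, 4:7] = 100.0
    phase = np.zeros((3, 12, 12))
    phase[:, 4:7, 4:7] = -0.5
    phase[1, 4:7, 4:7] = -1.2  # frame 1 carries the highest flow
    return PCSeries(magnitude=mag, phase=phase, meta=default_meta)
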