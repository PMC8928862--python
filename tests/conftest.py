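from dataclasses import replace

import numpy as np
import pytest

from facmri import AcquisitionSpec, FatModelSpec
from facmri.synth import PhantomSpec


@pytest.fixture(scope="session")
def model_spec() -> FatModelSpec:
    return FatModelSpec()


@pytest.fixture(scope="session")
def acq() -> AcquisitionSpec:
    return AcquisitionSpec()


@pytest.fixture(scope="session")
def small_phantom_spec() -> PhantomSpec:
    """Down-scaled slice phantom (32 x 48) used across segmentation and
    round-trip tests; same tissue truth as the full-size default."""
    return replace(
        PhantomSpec(),
        shape=(32, 48),
        body_semiaxes=(13.0, 19.0),
        sat_thickness=5.0,
        fascia_offset=2.5,
        visceral_radius=5.0,
        visceral_offset=(-1.0, 0.0),
        spine_halfwidth=3.0,
        spine_height=4.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
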