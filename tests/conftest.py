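import numpy as np
import pytest

from csfpulse import AcquisitionParams, PhantomSpec


@pytest.fixture
def params() -> AcquisitionParams:
    """The documented spinal-canal protocol (VENC 10, 40 phases, 453 ms)."""
    return AcquisitionParams()


@pytest.fixture
def small_params() -> AcquisitionParams:
    """A fast 8-phase acquisition for unit tests."""
    return AcquisitionParams(n_phases=8)


@pytest.fixture
def small_phantom_spec() -> PhantomSpec:
    """A 32 x 32 plug-flow phantom with a single pure harmonic."""
    return PhantomSpec(
        grid_nx=32,
        grid_ny=32,
        canal_radius_mm=1.8,
        waveform_harmonics=((2.0, 1.0, 0.0),),
        velocity_profile="plug",
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
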