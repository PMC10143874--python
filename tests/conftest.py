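import numpy as np
import pytest

from hp13c import AcquisitionProtocol, GammaInput, PKParams


@pytest.fixture(scope="session")
def params():
    """Simulation parameter set: kPL = 0.05 1/s, T1 = 20 s / 30 s."""
    return PKParams(kpl=0.05, t1_pyr=20.0, t1_lac=30.0)


@pytest.fixture(scope="session")
def input_fn():
    """Gamma bolus, FWHM 8 s, unit amplitude, arriving at t = 0."""
    return GammaInput(fwhm=8.0, arrival_time=0.0, amplitude=1.0)


@pytest.fixture(scope="session")
def epi_protocol():
    """18-timepoint dynamic EPI protocol at 3 s temporal resolution."""
    return AcquisitionProtocol(
        encoding="epi_singleshot", metabolite_order=("pyruvate", "lactate"),
        flips={"pyruvate": 10.0, "lactate": 30.0},
        temporal_resolution=3.0, n_timepoints=18,
        matrix=(16, 16), fov=(32.0, 32.0))


@pytest.fixture(scope="session")
def csi_protocol():
    """Single-frame 8x8 CSI protocol, 10 deg flip, centric, 4.25 s frame."""
    return AcquisitionProtocol(
        encoding="csi", metabolite_order=("pyruvate", "lactate"),
        flips={"pyruvate": 10.0, "lactate": 10.0},
        temporal_resolution=4.25, n_timepoints=1,
        matrix=(8, 8), fov=(32.0, 32.0), ordering="centric")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
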