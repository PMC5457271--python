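import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from phantomflim.decay import AcquisitionSettings, DecayModel


@pytest.fixture(scope="session")
def settings_50mhz() -> AcquisitionSettings:
    """Standard acquisition: 50 MHz (20 ns period), 256 bins, 1e4 counts."""
    return AcquisitionSettings(rep_rate=50.0, n_bins=256, counts_target=1e4)


@pytest.fixture(scope="session")
def mono_392() -> DecayModel:
    """Free-dye solution ground truth: single 3.92 ns component."""
    return DecayModel(amplitudes=(1.0,), lifetimes=(3.92,))


@pytest.fixture(scope="session")
def biexp_peg() -> DecayModel:
    """PEG-5kDa conjugate ground truth: 81.16% at 1.15 ns + 3.92 ns."""
    return DecayModel(
        amplitudes=(0.8116, 0.1884),
        lifetimes=(1.15, 3.92),
        fixed_mask=(False, True),
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
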