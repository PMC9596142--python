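import numpy as np
import pytest

from vibroraman import fixtures
from vibroraman.spectra import SpectrumSettings


@pytest.fixture
def one_mode_model():
    return fixtures.displaced_one_mode(s_hr=0.5)


@pytest.fixture
def three_mode_model():
    return fixtures.three_mode_single_state()


@pytest.fixture
def conical_model():
    return fixtures.conical_two_state()


@pytest.fixture
def cs_model():
    return fixtures.cs_bright_dark()


@pytest.fixture
def interference_model():
    return fixtures.interference_two_state()


@pytest.fixture
def fast_settings():
    """Coarse but converged settings used by most spectrum tests."""
    return SpectrumSettings(gamma=0.12, tmax=150.0, n_tot=8, omega_step=0.02)


def random_rotation(seed: int) -> np.ndarray:
    """Proper random 3D rotation (QR of a Gaussian matrix, det forced +1)."""
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
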