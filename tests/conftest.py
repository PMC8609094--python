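import warnings

import numpy as np
import pytest

from rishharm import fibonacci_directions
from rishharm.gradients import GradientScheme


@pytest.fixture(scope="session")
def dirs60():
    return fibonacci_directions(60)


@pytest.fixture(scope="session")
def dirs45():
    return fibonacci_directions(45)


def make_scheme(n_dirs: int, bvalue: float, n_b0: int = 1) -> GradientScheme:
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, bvalue)])
    bvecs = np.vstack([np.zeros((n_b0, 3)), fibonacci_directions(n_dirs)])
    return GradientScheme(bvals, bvecs)


def tensor_attenuation(dirs: np.ndarray, bval: float, evals, evecs=None) -> np.ndarray:
    """Noise-free monoexponential attenuation for a single tensor."""
    evals = np.asarray(evals, dtype=float)
    R = np.eye(3) if evecs is None else np.asarray(evecs)
    D = R @ np.diag(evals) @ R.T
    return np.exp(-bval * np.einsum("ni,ij,nj->n", dirs, D, dirs))


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Silence the advisory warnings (small training groups etc.) in tests."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*training subjects.*")
        warnings.filterwarnings("ignore", message=".*training controls.*")
        yield
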