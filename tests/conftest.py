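import numpy as np
import pytest
from scipy.signal import chirp

import tvsc


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def default_params():
    """Moderate linear grid used by most pipeline-level tests."""
    grid = tvsc.make_frequency_grid(0.02, 0.4, 40, "linear")
    return tvsc.MorletParams(1.0, grid)


@pytest.fixture(scope="session")
def dense_params():
    """Finer grid covering 0.02-0.3 cycles/sample for reconstruction tests."""
    grid = tvsc.make_frequency_grid(0.02, 0.3, 200, "linear")
    return tvsc.MorletParams(1.0, grid)


def two_chirp_signal(n: int = 2048) -> np.ndarray:
    """Band-limited test signal: superposition of up- and down-going chirps
    sweeping 0.05-0.2 cycles/sample."""
    t = np.arange(n)
    return chirp(t, f0=0.05, f1=0.2, t1=n) + 0.7 * chirp(t, f0=0.2, f1=0.05, t1=n)


def interior_slice(tfd: tvsc.TFDecomposition) -> slice:
    """Time samples clear of the lowest-frequency cone of influence."""
    k = int(np.ceil(tfd.coi_halfwidth.max() * tfd.sampling_rate))
    return slice(k, tfd.times.size - k)


def power_iteration_lambda_max(mat: np.ndarray, n_iter: int = 500, tol: float = 1e-14) -> float:
    """Independent largest-eigenvalue oracle for a Hermitian matrix."""
    rng = np.random.default_rng(7)
    v = rng.standard_normal(mat.shape[0]) + 1j * rng.standard_normal(mat.shape[0])
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(n_iter):
        w = mat @ v
        lam_new = float(np.real(np.vdot(v, w)))
        nw = np.linalg.norm(w)
        if nw == 0:
            return 0.0
        v = w / nw
        if abs(lam_new - lam) < tol * max(1.0, abs(lam_new)):
            lam = lam_new
            break
        lam = lam_new
    return lam
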