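"""Pairwise wavelet coherence and the time-varying spatial coherence (TVSC).

For M channels with wavelet transforms W_i(t, f), the smoothed complex
coherence is

    C_ij(t, f) = <W_i W_j*> / (|<W_i W_i*>| |<W_j W_j*>|)^(1/2),

where <.> smooths in time (scale-adaptive kernel of width proportional to
sigma_t(f)) and over adjacent frequency rows.  The Hermitian, unit-diagonal
matrix Sigma(t, f) of all pairwise coherences summarises the spatial
correlation structure at each time-frequency point, and the TVSC is

    Psi(t, f) = (lambda_max(Sigma(t, f)) - 1) / (M - 1),

with lambda_max the largest eigenvalue.  Psi is 1 when all channels are
locally pairwise coherent (Sigma all-ones, lambda_max = M) and 0 when they
are uncorrelated (Sigma = I, lambda_max = 1).  For M = 2 the closed form
lambda_max = 1 + |C_12| makes Psi the classic wavelet-coherence modulus, so
Psi^2 reduces to the usual squared wavelet coherence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from .wavelet import MorletParams, TFDecomposition

__all__ = [
    "SmoothingSpec",
    "CoherenceField",
    "cross_spectrum",
    "smooth",
    "coherence_matrix",
    "tvsc",
]

#: smoothed auto-power below this multiple of the channel median is treated
#: as silent (coherence undefined); affected entries are zeroed and flagged
LOW_POWER_REL_EPS = 1e-12

#: Psi outside [0, 1] by more than this raises; within it, values are clipped
PSI_BOUND_TOL = 1e-6


@dataclass(frozen=True)
class SmoothingSpec:
    """Time/frequency smoothing behind the coherence estimator.

    time_halfwidth_factor scales the temporal kernel width as a multiple of
    the local sigma_t(f) (so smoothing adapts to scale); freq_bins is the odd
    number of adjacent frequency rows averaged with a boxcar.
    """

    time_kernel: str = "gaussian"
    time_halfwidth_factor: float = 1.0
    freq_bins: int = 5

    def __post_init__(self) -> None:
        if self.time_kernel not in ("gaussian", "boxcar"):
            raise ValueError("time_kernel must be 'gaussian' or 'boxcar'")
        if self.time_halfwidth_factor <= 0:
            raise ValueError("time_halfwidth_factor must be > 0")
        if self.freq_bins < 1 or self.freq_bins % 2 == 0:
            raise ValueError("freq_bins must be an odd count >= 1")


@dataclass
class CoherenceField:
    """Pairwise coherence matrices over the TF plane and the derived Psi map.

    sigma has shape (M, M, n_freqs, n_times), is Hermitian in its first two
    axes with unit diagonal; psi is filled by :func:`tvsc`.  low_power flags
    TF points where at least one channel had (numerically) no power in band
    and the corresponding coherences were set to 0.
    """

    sigma: np.ndarray
    frequencies: np.ndarray
    times: np.ndarray
    psi: np.ndarray | None = None
    low_power: np.ndarray | None = None

    @property
    def n_channels(self) -> int:
        return self.sigma.shape[0]


def cross_spectrum(tfd_i: TFDecomposition, tfd_j: TFDecomposition) -> np.ndarray:
    """Wavelet cross-spectrum W_i(t,f) W_j*(t,f) on a common grid."""
    if (
        tfd_i.coefficients.shape != tfd_j.coefficients.shape
        or not np.array_equal(tfd_i.frequencies, tfd_j.frequencies)
        or not np.array_equal(tfd_i.times, tfd_j.times)
    ):
        raise ValueError("decompositions are not on a common time-frequency grid")
    return tfd_i.coefficients * np.conj(tfd_j.coefficients)


def _time_sigmas(spec: SmoothingSpec, params: MorletParams) -> np.ndarray:
    """Temporal kernel half-width per frequency row, in samples."""
    return spec.time_halfwidth_factor * params.sigma_t() * params.sampling_rate


def _smooth_rows_real(field: np.ndarray, sigmas: np.ndarray, kernel: str) -> np.ndarray:
    out = np.empty_like(field)
    for j, sig in enumerate(sigmas):
        if kernel == "gaussian":
            if sig < 1e-3:
                out[j] = field[j]
            else:
                out[j] = gaussian_filter1d(field[j], sigma=sig, mode="reflect")
        else:
            size = 2 * int(round(sig)) + 1
            out[j] = uniform_filter1d(field[j], size=size, mode="reflect") if size > 1 else field[j]
    return out


def smooth(field: np.ndarray, spec: SmoothingSpec, params: MorletParams) -> np.ndarray:
    """Apply the <.> operator: scale-adaptive time kernel, then a frequency boxcar.

    Real and imaginary parts are smoothed identically; kernels are
    mass-normalised, so a constant field is unchanged.
    """
    field = np.asarray(field)
    if field.ndim != 2 or field.shape[0] != params.frequencies.size:
        raise ValueError("field does not match the analysis grid")
    if spec.freq_bins > field.shape[0]:
        raise ValueError("freq_bins exceeds the number of frequency rows")
    sigmas = _time_sigmas(spec, params)
    if np.iscomplexobj(field):
        out = _smooth_rows_real(field.real, sigmas, spec.time_kernel) + 1j * _smooth_rows_real(
            field.imag, sigmas, spec.time_kernel
        )
    else:
        out = _smooth_rows_real(field, sigmas, spec.time_kernel)
    if spec.freq_bins > 1:
        if np.iscomplexobj(out):
            out = uniform_filter1d(out.real, spec.freq_bins, axis=0, mode="reflect") + 1j * uniform_filter1d(
                out.imag, spec.freq_bins, axis=0, mode="reflect"
            )
        else:
            out = uniform_filter1d(out, spec.freq_bins, axis=0, mode="reflect")
    return out


def coherence_matrix(
    tfds: list[TFDecomposition], spec: SmoothingSpec | None = None
) -> CoherenceField:
    """Assemble the M x M complex coherence matrix Sigma(t, f).

    Off-diagonal entries are smoothed cross-spectra normalised by the
    smoothed auto-spectra; the diagonal is exactly 1.  TF points where a
    smoothed auto-spectrum vanishes (relative to the channel's median power)
    get zeroed coherences and are flagged in ``low_power``.
    """
    if len(tfds) < 2:
        raise ValueError("need at least 2 channels")
    spec = spec or SmoothingSpec()
    ref = tfds[0]
    params = ref.params
    for t in tfds[1:]:
        if not np.array_equal(t.frequencies, ref.frequencies) or not np.array_equal(
            t.times, ref.times
        ):
            raise ValueError("all channels must share the analysis grid")
    M = len(tfds)
    nf, nt = ref.coefficients.shape
    autos = np.empty((M, nf, nt))
    for m, t in enumerate(tfds):
        autos[m] = smooth(np.abs(t.coefficients) ** 2, spec, params)
    eps = LOW_POWER_REL_EPS * np.median(autos.reshape(M, -1), axis=1)
    silent = autos < eps[:, None, None]
    root = np.sqrt(np.where(silent, 1.0, autos))

    sigma = np.zeros((M, M, nf, nt), dtype=complex)
    sigma[np.arange(M), np.arange(M)] = 1.0
    for i in range(M):
        for j in range(i + 1, M):
            cij = smooth(
                tfds[i].coefficients * np.conj(tfds[j].coefficients), spec, params
            ) / (root[i] * root[j])
            bad = silent[i] | silent[j]
            if bad.any():
                cij = np.where(bad, 0.0, cij)
            sigma[i, j] = cij
            sigma[j, i] = np.conj(cij)
    return CoherenceField(
        sigma=sigma,
        frequencies=ref.frequencies.copy(),
        times=ref.times.copy(),
        low_power=silent.any(axis=0),
    )


def tvsc(field: CoherenceField, hermitian_tol: float = 1e-8) -> np.ndarray:
    """Largest-eigenvalue spatial coherence Psi(t, f) = (lambda_max - 1)/(M - 1).

    For M = 2 the closed form lambda_max = 1 + |C_12| is used; otherwise a
    batched Hermitian eigensolver runs per TF point.  The computed map is
    stored on ``field.psi`` and returned.
    """
    sigma = field.sigma
    M = sigma.shape[0]
    herm_dev = np.max(np.abs(sigma - np.conj(np.swapaxes(sigma, 0, 1))))
    if herm_dev > hermitian_tol:
        raise ValueError(f"coherence matrix not Hermitian (max deviation {herm_dev:g})")
    diag_dev = np.max(np.abs(sigma[np.arange(M), np.arange(M)] - 1.0))
    if diag_dev > hermitian_tol:
        raise ValueError("coherence matrix diagonal is not unity")
    if M == 2:
        lam = 1.0 + np.abs(sigma[0, 1])
    else:
        mats = np.ascontiguousarray(np.moveaxis(sigma, (0, 1), (-2, -1)))
        lam = np.linalg.eigvalsh(mats)[..., -1]
    psi = (lam - 1.0) / (M - 1.0)
    low, high = psi.min(), psi.max()
    if low < -PSI_BOUND_TOL or high > 1.0 + PSI_BOUND_TOL:
        raise ValueError(
            f"Psi out of [0, 1] beyond tolerance (range [{low:g}, {high:g}])"
        )
    psi = np.clip(psi, 0.0, 1.0)
    field.psi = psi
    return psi
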