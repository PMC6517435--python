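"""Surrogate time series for coherence significance testing.

Two algorithms:

* :func:`wavelet_surrogate` — non-stationary surrogates by phase
  randomisation in the continuous-wavelet domain.  The surrogate keeps the
  original's time-frequency modulus |W_x(t,f)| but replaces its phase with
  the wavelet phase of a fresh Gaussian white-noise series; the recombined
  field is inverted back to a time series and rank-rescaled to the amplitude
  distribution of the wavelet-filtered original.  The procedure may be
  iterated (phase of the current surrogate re-extracted and recombined) to
  tighten the match of the time-frequency structure.

* :func:`iaaft_surrogate` — the stationary iterative amplitude-adjusted
  Fourier transform baseline: exact amplitude distribution, Fourier
  amplitude spectrum converged toward the original's.

:func:`ensemble` draws K independent multichannel realisations, each channel
randomised with its own noise phase so that all cross-channel dependence is
destroyed while every channel's TF modulus is preserved — the null of M
uncorrelated processes with the observed time-varying spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .wavelet import MorletParams, cwt_forward, inverse_from_coefficients, _cwt_forward_multi

__all__ = [
    "SurrogateConfig",
    "SurrogateEnsemble",
    "wavelet_surrogate",
    "iaaft_surrogate",
    "ensemble",
    "wavelet_filtered",
]


@dataclass(frozen=True)
class SurrogateConfig:
    """Ensemble settings: size K, refinement iterations, seed, analysis band."""

    n_surrogates: int = 100
    n_iterations: int = 0
    rng_seed: int = 0
    frequency_band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_surrogates < 1:
            raise ValueError("need K >= 1 surrogates")
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")
        if self.frequency_band is not None:
            lo, hi = self.frequency_band
            if not (0 < lo < hi):
                raise ValueError("frequency_band must satisfy 0 < f_min < f_max")


@dataclass
class SurrogateEnsemble:
    """K x M x n array of surrogate realisations plus provenance."""

    realisations: np.ndarray
    algorithm: str
    rng_seed: int
    n_iterations: int = 0

    @property
    def n_surrogates(self) -> int:
        return self.realisations.shape[0]


def _band_params(params: MorletParams, band: tuple[float, float] | None) -> MorletParams:
    if band is None:
        return params
    lo, hi = band
    keep = (params.frequencies >= lo) & (params.frequencies <= hi)
    if not keep.any():
        raise ValueError("frequency_band does not intersect the analysis grid")
    return MorletParams(params.sampling_rate, params.frequencies[keep], params.m)


def wavelet_filtered(x: np.ndarray, params: MorletParams) -> np.ndarray:
    """Forward-then-inverse transform of x over the analysis band."""
    return inverse_from_coefficients(cwt_forward(x, params).coefficients, params)


def _check_non_constant(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("constant input: rank rescaling is undefined")
    return x


def _wavelet_surrogate_core(
    modulus: np.ndarray,
    target_sorted: np.ndarray,
    params: MorletParams,
    rng: np.random.Generator,
    n_iterations: int,
) -> np.ndarray:
    n = modulus.shape[1]
    noise = rng.standard_normal(n)
    phase = np.angle(cwt_forward(noise, params).coefficients)
    xhat = np.empty(n)
    for it in range(n_iterations + 1):
        xhat = inverse_from_coefficients(modulus * np.exp(1j * phase), params)
        if it < n_iterations:
            phase = np.angle(cwt_forward(xhat, params).coefficients)
    # rank rescaling: permutation of the filtered original ordered like xhat
    out = np.empty(n)
    out[np.argsort(xhat, kind="stable")] = target_sorted
    return out


def wavelet_surrogate(
    x: np.ndarray,
    params: MorletParams,
    rng: np.random.Generator | int | None = None,
    n_iterations: int = 0,
) -> np.ndarray:
    """One non-stationary surrogate of ``x`` (wavelet phase randomisation).

    The returned series is a permutation of the wavelet-filtered original,
    ordered by the ranks of the inverse transform of
    |W_x(t,f)| exp(i phi_noise(t,f)).
    """
    x = _check_non_constant(x)
    rng = np.random.default_rng(rng)
    tfd = cwt_forward(x, params)
    target = np.sort(wavelet_filtered(x, params))
    return _wavelet_surrogate_core(np.abs(tfd.coefficients), target, params, rng, n_iterations)


def iaaft_surrogate(
    x: np.ndarray,
    max_iter: int = 100,
    rng: np.random.Generator | int | None = None,
    return_spectral_errors: bool = False,
):
    """Stationary iAAFT surrogate of ``x``.

    Alternates imposing the original Fourier amplitude spectrum and the
    original amplitude distribution (by rank remapping); stops when the rank
    permutation stabilises or after ``max_iter`` sweeps.  With
    ``return_spectral_errors`` the per-iteration relative discrepancy of the
    amplitude spectrum is also returned.
    """
    x = _check_non_constant(x)
    rng = np.random.default_rng(rng)
    n = x.size
    amp = np.abs(np.fft.rfft(x))
    amp_norm = np.linalg.norm(amp)
    sorted_x = np.sort(x)
    s = rng.permutation(x)
    prev_order: np.ndarray | None = None
    errors = []
    for _ in range(max_iter):
        spec = np.fft.rfft(s)
        s = np.fft.irfft(amp * np.exp(1j * np.angle(spec)), n)
        errors.append(float(np.linalg.norm(np.abs(np.fft.rfft(s)) - amp) / amp_norm))
        order = np.argsort(s, kind="stable")
        s = np.empty(n)
        s[order] = sorted_x
        if prev_order is not None and np.array_equal(order, prev_order):
            break
        prev_order = order
    if return_spectral_errors:
        return s, np.asarray(errors)
    return s


def ensemble(
    X: np.ndarray,
    params: MorletParams,
    config: SurrogateConfig,
    algorithm: str = "wavelet",
) -> SurrogateEnsemble:
    """K multichannel surrogate realisations of an (M, n) record.

    Every channel of every realisation consumes an independent substream of
    a single seeded generator, so the ensemble is reproducible bit-for-bit
    from ``config.rng_seed`` and channels are mutually independent.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be an (M, n) matrix with M >= 2")
    if algorithm not in ("wavelet", "iaaft"):
        raise ValueError("algorithm must be 'wavelet' or 'iaaft'")
    M, n = X.shape
    K = config.n_surrogates
    streams = np.random.SeedSequence(config.rng_seed).spawn(K * M)
    out = np.empty((K, M, n))
    if algorithm == "wavelet":
        p = _band_params(params, config.frequency_band)
        W = _cwt_forward_multi(X, p)
        moduli = np.abs(W)
        targets = [
            np.sort(inverse_from_coefficients(W[m], p)) for m in range(M)
        ]
        for k in range(K):
            for m in range(M):
                rng = np.random.default_rng(streams[k * M + m])
                out[k, m] = _wavelet_surrogate_core(
                    moduli[m], targets[m], p, rng, config.n_iterations
                )
    else:
        for k in range(K):
            for m in range(M):
                rng = np.random.default_rng(streams[k * M + m])
                out[k, m] = iaaft_surrogate(X[m], rng=rng)
    return SurrogateEnsemble(
        realisations=out,
        algorithm=algorithm,
        rng_seed=config.rng_seed,
        n_iterations=config.n_iterations if algorithm == "wavelet" else 0,
    )
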