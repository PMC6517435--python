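"""Surrogate-based significance of the spatial coherence map.

The null hypothesis is M mutually uncorrelated processes that individually
retain the observed time-varying spectra.  Its Psi(t, f) distribution is
estimated by Monte Carlo over K surrogate ensembles (each channel phase
randomised independently in the wavelet domain).  Observed values are
compared by a one-sided z-test per TF point, and the resulting p-value map
is thresholded with Benjamini-Hochberg FDR control restricted to the
cone-of-influence interior.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .coherence import SmoothingSpec, coherence_matrix, tvsc
from .surrogates import SurrogateConfig, ensemble
from .wavelet import MorletParams, _cwt_forward_multi, _wrap_decomposition, coi_interior_mask, cone_of_influence

__all__ = [
    "SignificanceMap",
    "DetectionResult",
    "z_test",
    "fdr_mask",
    "run_detection",
]

logger = logging.getLogger(__name__)


@dataclass
class SignificanceMap:
    """z, p and FDR-thresholded significance over the TF plane.

    ``coi_mask`` is True at TF points clear of edge contamination; ``mask``
    (the detections) is always False outside it.  ``degenerate`` flags points
    whose surrogate spread was zero (p forced to 1).
    """

    z: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    q_level: float
    coi_mask: np.ndarray
    degenerate: np.ndarray | None = None

    def significant_fraction(self) -> float:
        """Fraction of COI-interior points declared significant."""
        n_int = int(self.coi_mask.sum())
        if n_int == 0:
            raise ValueError("cone of influence leaves no interior points")
        return float(self.mask[self.coi_mask].mean())


@dataclass
class DetectionResult:
    """End-to-end output: observed Psi map plus its significance assessment."""

    psi: np.ndarray
    frequencies: np.ndarray
    times: np.ndarray
    significance: SignificanceMap
    null_mean: np.ndarray
    null_sd: np.ndarray


def z_test(psi_obs: np.ndarray, psi_null: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-point z score of the observed map against K null maps.

    z = (Psi_obs - mean_null) / sd_null with the unbiased (K-1) denominator;
    p is the one-sided upper-tail normal probability.  Points with zero
    surrogate spread cannot exceed their degenerate null: p is set to 1.
    """
    psi_obs = np.asarray(psi_obs, dtype=float)
    psi_null = np.asarray(psi_null, dtype=float)
    if psi_null.ndim != psi_obs.ndim + 1 or psi_null.shape[1:] != psi_obs.shape:
        raise ValueError("psi_null must stack K maps with the shape of psi_obs")
    if psi_null.shape[0] < 2:
        raise ValueError("need at least K = 2 null maps")
    mu = psi_null.mean(axis=0)
    sd = psi_null.std(axis=0, ddof=1)
    # numerically-zero spread (identical surrogate values up to rounding)
    degenerate = sd <= 1e-12 * np.maximum(1.0, np.abs(mu))
    z = np.where(degenerate, 0.0, (psi_obs - mu) / np.where(degenerate, 1.0, sd))
    p = norm.sf(z)
    p[degenerate] = 1.0
    return z, p


def fdr_mask(p: np.ndarray, q: float, coi_mask: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg threshold over COI-interior p-values only.

    Edge-contaminated points neither enter the testing pool nor can be
    declared significant; the returned boolean map is False outside the COI
    interior.
    """
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    p = np.asarray(p, dtype=float)
    coi_mask = np.asarray(coi_mask, dtype=bool)
    if p.shape != coi_mask.shape:
        raise ValueError("p map and COI mask shapes differ")
    if not coi_mask.any():
        raise ValueError("cone of influence leaves no interior points to test")
    mask = np.zeros_like(coi_mask)
    mask[coi_mask] = multipletests(p[coi_mask], alpha=q, method="fdr_bh")[0]
    return mask


def _psi_of_matrix(X: np.ndarray, params: MorletParams, spec: SmoothingSpec) -> np.ndarray:
    n = X.shape[1]
    W = _cwt_forward_multi(X, params)
    tfds = [_wrap_decomposition(W[m], n, params) for m in range(X.shape[0])]
    return tvsc(coherence_matrix(tfds, spec))


def run_detection(
    X: np.ndarray,
    params: MorletParams,
    smoothing: SmoothingSpec | None = None,
    config: SurrogateConfig | None = None,
    q: float = 0.05,
) -> DetectionResult:
    """Full detection pipeline on an (M, n) multichannel record.

    Channels are standardised to zero mean and unit variance, transformed,
    and combined into the observed Psi map; K wavelet-surrogate ensembles
    provide the null distribution for the z-test; BH-FDR at level ``q``
    (COI interior only) yields the significance mask.  Deterministic given
    ``config.rng_seed``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be an (M, n) matrix with M >= 2")
    sd = X.std(axis=1, ddof=0)
    if np.any(sd == 0):
        raise ValueError("constant channel cannot be standardised")
    X = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    smoothing = smoothing or SmoothingSpec()
    config = config or SurrogateConfig()

    t0 = time.perf_counter()
    psi_obs = _psi_of_matrix(X, params, smoothing)
    logger.info("observed Psi map computed in %.2f s", time.perf_counter() - t0)

    t0 = time.perf_counter()
    ens = ensemble(X, params, config, algorithm="wavelet")
    psi_null = np.empty((config.n_surrogates,) + psi_obs.shape)
    for k in range(config.n_surrogates):
        psi_null[k] = _psi_of_matrix(ens.realisations[k], params, smoothing)
    logger.info(
        "K=%d null Psi maps computed in %.2f s", config.n_surrogates, time.perf_counter() - t0
    )

    z, p = z_test(psi_obs, psi_null)
    n = X.shape[1]
    times = np.arange(n) / params.sampling_rate
    coi = coi_interior_mask(times, cone_of_influence(params, n))
    mask = fdr_mask(p, q, coi)
    sig = SignificanceMap(
        z=z,
        p=p,
        mask=mask,
        q_level=q,
        coi_mask=coi,
        degenerate=(p >= 1.0) & (z == 0.0),
    )
    return DetectionResult(
        psi=psi_obs,
        frequencies=params.frequencies.copy(),
        times=times,
        significance=sig,
        null_mean=psi_null.mean(axis=0),
        null_sd=psi_null.std(axis=0, ddof=1),
    )
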