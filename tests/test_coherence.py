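"""Cross-spectra, smoothing and the eigenvalue-based spatial coherence."""

import numpy as np
import pytest

import tvsc
from tvsc.coherence import CoherenceField

from conftest import power_iteration_lambda_max


def _random_unit_diag_hermitian(m, rng):
    """Normalised Gram matrix: Hermitian, PSD, unit diagonal, |off-diag| <= 1."""
    a = rng.standard_normal((m, 2 * m)) + 1j * rng.standard_normal((m, 2 * m))
    s = a @ a.conj().T
    d = 1.0 / np.sqrt(np.real(np.diag(s)))
    return d[:, None] * s * d[None, :]


def _field_from_matrices(mats):
    """Wrap a (n_pts, M, M) stack as a CoherenceField on a dummy 1 x n_pts grid."""
    mats = np.asarray(mats)
    sigma = np.moveaxis(mats, 0, -1)[:, :, None, :]  # (M, M, 1, n_pts)
    return CoherenceField(
        sigma=sigma,
        frequencies=np.array([0.1]),
        times=np.arange(mats.shape[0], dtype=float),
    )


class TestCrossSpectrum:
    def test_self_cross_spectrum_is_power(self, default_params, rng):
        tfd = tvsc.cwt_forward(rng.standard_normal(512), default_params)
        w = tvsc.cross_spectrum(tfd, tfd)
        assert np.allclose(w.imag, 0.0)
        assert np.all(w.real >= 0)
        assert np.allclose(w.real, np.abs(tfd.coefficients) ** 2)

    def test_hermitian_symmetry(self, default_params, rng):
        ti = tvsc.cwt_forward(rng.standard_normal(512), default_params)
        tj = tvsc.cwt_forward(rng.standard_normal(512), default_params)
        assert np.allclose(tvsc.cross_spectrum(ti, tj), np.conj(tvsc.cross_spectrum(tj, ti)))

    def test_phase_lag_recovered(self, default_params):
        f0 = default_params.frequencies[17]
        phi = 0.9
        t = np.arange(2048)
        ti = tvsc.cwt_forward(np.cos(2 * np.pi * f0 * t), default_params)
        tj = tvsc.cwt_forward(np.cos(2 * np.pi * f0 * t - phi), default_params)
        w = tvsc.cross_spectrum(ti, tj)
        assert np.allclose(np.angle(w[17, 500:-500]), phi, atol=1e-6)

    def test_grid_mismatch_rejected(self, default_params, dense_params, rng):
        x = rng.standard_normal(512)
        with pytest.raises(ValueError):
            tvsc.cross_spectrum(
                tvsc.cwt_forward(x, default_params), tvsc.cwt_forward(x, dense_params)
            )


class TestSmoothing:
    def test_tiny_kernel_single_bin_is_identity(self, default_params, rng):
        field = rng.standard_normal((40, 300)) + 1j * rng.standard_normal((40, 300))
        spec = tvsc.SmoothingSpec(time_halfwidth_factor=1e-6, freq_bins=1)
        assert np.allclose(tvsc.smooth(field, spec, default_params), field)

    def test_constant_field_unchanged(self, default_params):
        field = np.full((40, 300), 2.5 + 0.5j)
        out = tvsc.smooth(field, tvsc.SmoothingSpec(), default_params)
        assert np.allclose(out, field)

    @pytest.mark.parametrize("kernel", ["gaussian", "boxcar"])
    def test_noise_variance_reduced(self, default_params, rng, kernel):
        field = rng.standard_normal((40, 2000))
        spec = tvsc.SmoothingSpec(time_kernel=kernel, time_halfwidth_factor=2.0, freq_bins=5)
        out = tvsc.smooth(field, spec, default_params)
        assert out.var() < 0.5 * field.var()

    def test_excessive_freq_bins_rejected(self, default_params, rng):
        field = rng.standard_normal((40, 100))
        with pytest.raises(ValueError):
            tvsc.smooth(field, tvsc.SmoothingSpec(freq_bins=41), default_params)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            tvsc.SmoothingSpec(freq_bins=4)
        with pytest.raises(ValueError):
            tvsc.SmoothingSpec(time_halfwidth_factor=0.0)


class TestCoherenceMatrix:
    def test_identical_channels_give_all_ones(self, default_params, rng):
        x = rng.standard_normal(1024)
        tfds = [tvsc.cwt_forward(x, default_params) for _ in range(4)]
        field = tvsc.coherence_matrix(tfds)
        interior = tfds[0].interior_mask() & ~field.low_power
        for i in range(4):
            for j in range(4):
                assert np.allclose(field.sigma[i, j][interior], 1.0)

    def test_independent_noise_coherence_low_under_heavy_smoothing(self, default_params, rng):
        spec = tvsc.SmoothingSpec(time_halfwidth_factor=4.0, freq_bins=9)
        tfds = [tvsc.cwt_forward(rng.standard_normal(8192), default_params) for _ in range(3)]
        field = tvsc.coherence_matrix(tfds, spec)
        interior = tfds[0].interior_mask()
        offdiag = np.abs(field.sigma[0, 1][interior])
        assert np.median(offdiag) < 0.5

    def test_bivariate_offdiagonal_is_classic_coherence(self, default_params, rng):
        x = rng.standard_normal(1024)
        y = 0.6 * x + rng.standard_normal(1024)
        spec = tvsc.SmoothingSpec()
        ti, tj = tvsc.cwt_forward(x, default_params), tvsc.cwt_forward(y, default_params)
        field = tvsc.coherence_matrix([ti, tj], spec)
        # classic definition: smoothed cross / sqrt of smoothed autos
        num = tvsc.smooth(tvsc.cross_spectrum(ti, tj), spec, default_params)
        den = np.sqrt(
            tvsc.smooth(np.abs(ti.coefficients) ** 2, spec, default_params)
            * tvsc.smooth(np.abs(tj.coefficients) ** 2, spec, default_params)
        )
        assert np.allclose(field.sigma[0, 1], num / den)
        assert np.max(np.abs(field.sigma[0, 1])) <= 1.0 + 1e-9

    def test_single_channel_rejected(self, default_params, rng):
        with pytest.raises(ValueError):
            tvsc.coherence_matrix([tvsc.cwt_forward(rng.standard_normal(512), default_params)])


class TestTVSC:
    def test_all_ones_matrix_gives_psi_one(self):
        m = 6
        field = _field_from_matrices([np.ones((m, m), dtype=complex)])
        assert np.allclose(tvsc.tvsc(field), 1.0, atol=1e-12)

    def test_identity_matrix_gives_psi_zero(self):
        field = _field_from_matrices([np.eye(5, dtype=complex)])
        assert np.allclose(tvsc.tvsc(field), 0.0, atol=1e-12)

    def test_bivariate_closed_form(self, rng):
        mats = []
        cs = rng.uniform(0, 1, 50) * np.exp(1j * rng.uniform(0, 2 * np.pi, 50))
        for c in cs:
            mats.append(np.array([[1.0, c], [np.conj(c), 1.0]]))
        psi = tvsc.tvsc(_field_from_matrices(mats))
        assert np.allclose(psi.ravel(), np.abs(cs), atol=1e-12)

    def test_eigen_path_matches_power_iteration_oracle(self, rng):
        mats = [_random_unit_diag_hermitian(m, rng) for m in (3, 4, 6) for _ in range(20)]
        for mat in mats:
            psi = tvsc.tvsc(_field_from_matrices([mat]))[0, 0]
            lam = power_iteration_lambda_max(mat)
            assert abs(psi - (lam - 1.0) / (mat.shape[0] - 1.0)) < 1e-8

    def test_psi_bounds_hold_on_random_coherence_fields(self, rng):
        mats = [_random_unit_diag_hermitian(5, rng) for _ in range(200)]
        psi = tvsc.tvsc(_field_from_matrices(mats))
        assert psi.min() >= 0.0 and psi.max() <= 1.0

    def test_permutation_invariance(self, default_params, rng):
        X = rng.standard_normal((4, 1024))
        X[1] += 0.5 * X[0]
        tfds = [tvsc.cwt_forward(x, default_params) for x in X]
        psi = tvsc.tvsc(tvsc.coherence_matrix(tfds))
        perm = [2, 0, 3, 1]
        psi_p = tvsc.tvsc(tvsc.coherence_matrix([tfds[i] for i in perm]))
        assert np.allclose(psi, psi_p, atol=1e-10)

    def test_bivariate_equivalence_on_signals(self, default_params, rng):
        x = rng.standard_normal(1024)
        y = 0.7 * x + rng.standard_normal(1024)
        tfds = [tvsc.cwt_forward(x, default_params), tvsc.cwt_forward(y, default_params)]
        field = tvsc.coherence_matrix(tfds)
        psi = tvsc.tvsc(field)
        assert np.allclose(psi, np.abs(field.sigma[0, 1]), atol=1e-12)

    def test_monotone_response_to_common_coupling(self, default_params, rng):
        f0 = default_params.frequencies[17]
        n = 2048
        t = np.arange(n)
        common = np.cos(2 * np.pi * f0 * t)
        noise = rng.standard_normal((4, n))
        medians = []
        for alpha in [0.0, 0.3, 0.6, 0.9]:
            X = alpha * common[None, :] + (1 - alpha) * noise
            tfds = [tvsc.cwt_forward(x, default_params) for x in X]
            psi = tvsc.tvsc(tvsc.coherence_matrix(tfds))
            interior = tfds[0].interior_mask()
            medians.append(np.median(psi[17][interior[17]]))
        assert all(b >= a for a, b in zip(medians, medians[1:]))

    def test_non_hermitian_input_rejected(self):
        mat = np.array([[1.0, 0.5], [0.2, 1.0]], dtype=complex)
        with pytest.raises(ValueError):
            tvsc.tvsc(_field_from_matrices([mat]))
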