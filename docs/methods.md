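# Methods

## Wavelet analysis

Channels are analysed with the complex Morlet wavelet
`w(t; f) = A exp(−t²/2σ_t²) exp(i2πft)`, indexed directly by analysis
frequency `f` rather than scale, with temporal width `σ_t = m/(2πf)`,
spectral width `σ_f = f/m` and unit-energy normalisation
`A = (σ_t√π)^{−1/2}`. The width parameter defaults to `m = 5`, at which the
wavelet is approximately analytic (spectral leakage to `ν ≤ 0` is
`exp(−m²/2) ≈ 4·10⁻⁶` of the peak). Coefficients are computed by
frequency-domain multiplication after zero-padding to the next power of two
above twice the record length; the implicit zero-padding edge effects are
flagged by the cone of influence, taken as the e-folding time of the Morlet
*power* envelope, `√2·σ_t(f)` (the amplitude-vs-power convention is not
universal; we fix the power-envelope one). Analysis frequencies within
`~4σ_f` of the Nyquist frequency are discretised imperfectly (the atom's
Gaussian spectrum is truncated); grids should keep a margin below Nyquist.

### Inverse transform

The signal is reconstructed as a weighted sum of the real parts of the
coefficient rows. Because the atoms are unit-energy, equal row weights do
not give a flat frequency response; base weights `√σ_t(f)·Δf` (local grid
step) remove the leading frequency dependence, and a fixed-point refinement
(divide each weight by the closed-form response of the weighted sum at that
row's frequency, iterated to convergence) flattens the response to a few
parts in 10³ across the covered band while keeping all weights positive.
A final scalar gain is calibrated once per grid by least squares against a
fixed-seed white-noise probe, band-limited to the grid's covered band so
partial-response edge regions cannot bias the fit; the calibrated gain is ≈2,
the factor lost when taking real parts of an analytic decomposition. The
resulting operator is linear and fixed per grid, so it applies identically
to surrogate modulus/phase recombinations. Round-trip error on band-limited
signals whose band is covered with margin is ~0.005, within the 0.01
criterion used throughout.

## The TVSC statistic

Pairwise smoothed complex coherences `C_ij` are assembled into the Hermitian
unit-diagonal matrix `Σ(t,f)` and summarised by
`Ψ = (λ_max − 1)/(M − 1)`. Because the smoothing kernels have positive
weights, `Σ` is positive semi-definite with trace `M`, hence `λ_max ∈ [1, M]`
and `Ψ ∈ [0, 1]` up to eigensolver rounding; values outside by more than
10⁻⁶ raise instead of being clipped silently. For `M = 2` the closed form
`λ_max = 1 + |C_12|` is used (and doubles as an independent oracle for the
eigen path, alongside a power-iteration oracle in the tests).

### Smoothing

The smoothing operator is a per-row Gaussian in time with width
`time_halfwidth_factor · σ_t(f)` (scale-adaptive, so each frequency row is
averaged over a comparable number of oscillation cycles) followed by a
boxcar over `freq_bins` adjacent rows. Defaults: factor 1, `freq_bins = 5`
on the 40-row default grid. These were chosen so that the bivariate
coherence of independent white noise sits near 0.6 (well below 1, leaving
dynamic range for detection) while the detector retains power on the
coupled-AR benchmark; both heavier and lighter smoothing were examined (see
Limitations). TF points where a smoothed auto-spectrum falls below 10⁻¹²
of the channel's median power get zeroed coherences and a `low_power` flag
rather than NaNs, keeping `Σ` eigendecomposable while recording
unreliability.

## Surrogate data and significance

Wavelet surrogates keep `|W_x(t,f)|` and impose the wavelet phase of a fresh
standard-Gaussian white-noise series of the same length; the recombined
field is inverted and rank-rescaled (stable sort) to the values of the
wavelet-filtered original, so the amplitude distribution is preserved
exactly and the time-frequency energy distribution approximately. The
recombination can be iterated (`n_iterations`), re-extracting the phase of
the current surrogate; the default is a single pass, with rescaling applied
after the final pass. Each channel of each of the `K` realisations consumes
an independent substream of one seeded generator: ensembles are bit-for-bit
reproducible and channels are independent, which is exactly the null of `M`
uncorrelated processes with the observed time-varying spectra. `K` defaults
to 100; the acceptance-scale experiments use `K = 50`. The stationary iAAFT
baseline (exact amplitude distribution, Fourier amplitude spectrum converged
by alternating projections with a rank-stabilisation stopping rule) is
provided for comparison.

Observed `Ψ` is compared per TF point by `z = (Ψ_obs − μ_K)/s_K` with the
unbiased `K − 1` denominator, one-sided upper-tail normal `p` (the method
seeks high coherence, not anti-coherence), and Benjamini–Hochberg FDR at
`q = 0.05` restricted to COI-interior points (edge-contaminated points are
neither tested nor selectable; BH rather than BY because smoothing induces
positive dependence). Degenerate TF points with numerically zero surrogate
spread get `p = 1`.

## Synthetic benchmarks

*Coupled AR system* — five linear difference equations driven by unit
Gaussian innovations; the driver `x1` is an AR(2) with poles at angle `π/4`
(spectral peak at 0.125 cycles/sample). Couplings `k2·x1(t−1)` into `x2` and
`k1·x1(t−2)` into `x4` switch from (0.15, 0) to (0.4, −0.5) at `t = 1000`
(post-burn-in indexing; 100 burn-in samples from zero initial conditions are
discarded). The printed system also carries constant couplings
(`0.4·x1(t−1)` into `x3`; the rotational `x4↔x5` block), so weak genuine
coherence exists at all times; the strong-coupling epoch `[1000, 2000)` is
the ground truth. The `x3` equation's cross term `−0.5·x2(t−2)` is
implemented as printed; a flag substitutes `x3(t−2)` should the user prefer
the self-lag reading.

*Rössler network* — ten non-identical chaotic Rössler oscillators
(`a = 0.165, b = 0.2, c = 10`), natural frequencies uniform on
`[0.98, 1.1]`, diffusively coupled on `x` through a connected Erdős–Rényi
graph with mean degree 4 (`G(n, nk_m/2)`, resampled until connected), driven
by white noise of intensity `D = 0.01` on the `x` equations, integrated by
Euler–Maruyama. Integration step 0.01, one recorded sample per time unit
after a 200-unit transient, 1300 samples by default — chosen so that the
rotation frequency `ω/2π ≈ 0.16–0.18` cycles/sample falls inside the default
analysis band and integration error is negligible at the attractor's scales.
Coupling `λ(t) = 0.5` for recorded time `500 < t < 900` and `0.001`
elsewhere; the window `(500, 900)` is the ground truth.

## Problem sizes

Pipeline-level experiments use a 40-frequency linear grid on
0.02–0.4 cycles/sample, `K = 50` surrogates, and records of 1024–2000
samples; the reconstruction experiments use a 200-frequency grid. These
sizes make the statistics stable while keeping a full pipeline run on a
single CPU in the tens of seconds.

## What the synthetic generators do and do not emulate

The generators reproduce the benchmarks' defining features: a known
switch-on of cross-channel coupling, non-stationary band-limited dynamics,
chaotic phase dynamics and observational-scale noise. They do not emulate
measurement artifacts, trends, missing data (exercised separately through
the imputation path), volume-conduction-style instantaneous mixing, or
heavy-tailed noise; passing benchmarks therefore demonstrates correct
detection of genuine dynamical coupling under these idealised conditions,
not robustness to every artifact of field recordings.

## Known limitations

* **Near-degenerate oscillator networks.** When channels are narrowband
  oscillators whose pairwise detunings are small (beat periods much longer
  than the scale-adaptive smoothing window, e.g. the Rössler network's
  `Δω ≈ 0.01–0.1` at a ±10-sample window), their phase differences are
  locally constant even without coupling, so `Ψ` is genuinely high and the
  surrogate test — whose null destroys all phase continuity between
  channels — correctly rejects independence outside the coupled window.
  Detections then concentrate at the oscillators' common band at *all*
  times, and the contrast between the coupled window and the rest is
  structurally limited (measured ~2–4.6× across smoothing settings, versus
  >13× on the AR benchmark). Heavier time smoothing does not cure this:
  the null spread shrinks faster than the out-of-window coherence decays.
  Interpreting significance on such systems requires care: the test
  answers "are these processes dependent at this TF point?", not "is the
  generating coupling switched on?".
* **Sensitivity at small coverage.** A single coherent pair among many
  channels raises `λ_max` only marginally above the independence null's
  bias, and BH over the full TF plane is strict when the signal occupies a
  small fraction of it; moderate couplings confined to one row can go
  undetected at `K = 50`.
* The z-test treats the surrogate `Ψ` distribution as Gaussian; it is
  mildly skewed, which is part of why the realised false-positive fraction
  on white noise sits well below the nominal `q`.
* Frequencies within `~4σ_f` of Nyquist and below `~1/(COI half-width)`
  of the record length are unreliable; the COI handles the latter, grid
  choice must handle the former.
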