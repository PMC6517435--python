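# tvsc — time-varying spatial coherence for non-stationary multivariate time series

`tvsc` detects **transient spatial coherence** — episodes in which many
channels of a multivariate record oscillate together — in signals whose
spectral content changes over time (epileptic EEG, epidemiological case
counts, coupled-oscillator networks, …). Classical coherence significance
tests assume stationarity; `tvsc` instead combines:

1. a **continuous Morlet wavelet transform** per channel, giving complex
   coefficients `W_i(t, f)`;
2. the **time-varying spatial coherence** statistic. With smoothed pairwise
   complex coherences

   `C_ij(t,f) = ⟨W_i W_j*⟩ / (‖⟨W_i W_i*⟩‖ ‖⟨W_j W_j*⟩‖)^½`

   collected into the Hermitian, unit-diagonal matrix `Σ(t,f)`, the statistic
   is the normalised largest eigenvalue

   `Ψ(t,f) = (λ_max(Σ(t,f)) − 1) / (M − 1) ∈ [0, 1]`,

   equal to 1 when all `M` channels are locally pairwise coherent and 0 when
   they are uncorrelated. For `M = 2`, `Ψ = |C_12|`, the classic wavelet
   coherence modulus;
3. **non-stationary surrogate data**: each channel's wavelet *modulus* is kept
   and its wavelet *phase* is replaced by the phase of fresh white noise; the
   recombined field is inverted and rank-rescaled to the filtered original's
   amplitude distribution. Surrogates therefore preserve each channel's
   time-varying spectrum while destroying all cross-channel dependence — the
   null hypothesis of `M` uncorrelated processes;
4. a one-sided **z-test** of the observed `Ψ` against `K` surrogate maps with
   **Benjamini–Hochberg FDR** control (default `q = 0.05`) restricted to the
   cone-of-influence interior of the time-frequency plane.

The package also ships the two standard synthetic benchmarks used to validate
such detectors — a five-channel coupled autoregressive system whose coupling
strengths switch at a known time, and a random network of ten noisy
non-identical Rössler oscillators whose diffusive coupling is switched on
inside a known window — plus the stationary iAAFT surrogate baseline.

## Worked example

```python
import numpy as np
import tvsc

# five-channel AR benchmark: couplings strengthen at t = 1000
ds = tvsc.simulate_ar(tvsc.ARSpec(rng_seed=3))

grid = tvsc.make_frequency_grid(0.02, 0.4, 40, "linear")
params = tvsc.MorletParams(sampling_rate=1.0, frequencies=grid)
res = tvsc.run_detection(
    ds.data, params, config=tvsc.SurrogateConfig(n_surrogates=50, rng_seed=3)
)
sig = res.significance
lo, hi = ds.ground_truth_window
inside = (res.times >= lo) & (res.times < hi)
d_in = sig.mask[sig.coi_mask & inside[None, :]].mean()
d_out = sig.mask[sig.coi_mask & ~inside[None, :]].mean()
print(f"significant density inside window:  {d_in:.4f}")
print(f"significant density outside window: {d_out:.4f}")
```

prints

```
significant density inside window:  0.0949
significant density outside window: 0.0061
```

i.e. ~9.5% of reliable time-frequency points are flagged inside the
strong-coupling epoch versus ~0.6% outside it — the detector concentrates its
detections in the epoch where the generating couplings are strong (the small
outside rate reflects the system's weaker, always-on couplings).

The same pipeline is available from the shell:

```sh
tvsc simulate --model ar --seed 3 --out ar.csv --truth-out truth.json
tvsc analyze ar.csv --k 50 --seed 3 --outdir results/ --plot
tvsc surrogate ar.csv --algorithm wavelet --k 10 --seed 1 --out-prefix sur/ar
```

`analyze` writes the `Ψ`, `z` and `p` maps, the boolean significance mask and
the cone-of-influence mask as TSV time-frequency maps plus a `run.json`
provenance record.

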