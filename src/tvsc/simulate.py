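"""Synthetic benchmarks with known ground-truth synchrony windows.

Two spatial systems exercise the detection pipeline:

* :func:`simulate_ar` — five coupled linear autoregressive processes.  The
  driver x1 is an AR(2) with a spectral peak near 0.125 cycles/sample; x2
  and x4 receive couplings k2*x1(t-1) and k1*x1(t-2) whose strengths switch
  at a known time (defaults: k1 0 -> -0.5, k2 0.15 -> 0.4 at t = 1000), so
  the strong-coupling epoch [switch, n) is the ground truth.

* :func:`simulate_rossler` — a random network of non-identical chaotic
  Rossler oscillators with diffusive coupling on x, driven by weak white
  noise, integrated by Euler-Maruyama.  The coupling strength lambda(t) is
  piecewise constant (0.5 inside a window, 0.001 elsewhere), making the
  window the ground-truth synchronised regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "ARSpec",
    "RosslerSpec",
    "SimulatedDataset",
    "simulate_ar",
    "simulate_rossler",
    "random_mean_degree_graph",
]

_SQ2 = np.sqrt(2.0)


@dataclass(frozen=True)
class ARSpec:
    """Five-channel AR benchmark settings.

    Couplings (k1 into x4, k2 into x2) take their ``*_pre`` values for
    samples before ``switch_time`` and ``*_post`` from then on; time is
    indexed after a discarded burn-in.  ``x3_self_lag`` replaces the printed
    cross term -0.5*x2(t-2) in the x3 equation with -0.5*x3(t-2) (possible
    typo in the source system); default keeps the term as printed.
    """

    n_samples: int = 2000
    switch_time: int = 1000
    k1_pre: float = 0.0
    k1_post: float = -0.5
    k2_pre: float = 0.15
    k2_post: float = 0.4
    noise_sd: float = 1.0
    rng_seed: int = 0
    burn_in: int = 100
    x3_self_lag: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.switch_time < self.n_samples):
            raise ValueError("switch_time must lie inside (0, n_samples)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.burn_in < 2:
            raise ValueError("burn_in must be >= 2 (two lags are needed)")


@dataclass(frozen=True)
class RosslerSpec:
    """Noisy Rossler-network benchmark settings.

    ``coupling_high`` applies for recorded times strictly inside
    ``coupling_window`` (units of recorded samples); ``coupling_low``
    elsewhere.  Natural frequencies are drawn uniformly from
    ``omega_range``; the coupling graph is a connected random graph with
    mean degree ``mean_degree``.  Integration uses Euler-Maruyama with step
    ``dt_integration``, recording x every ``sample_interval`` after
    discarding ``transient`` time units.
    """

    n_oscillators: int = 10
    n_samples: int = 1300
    omega_range: tuple[float, float] = (0.98, 1.1)
    coupling_window: tuple[float, float] = (500.0, 900.0)
    coupling_high: float = 0.5
    coupling_low: float = 0.001
    mean_degree: float = 4.0
    noise_intensity: float = 0.01
    dt_integration: float = 0.01
    sample_interval: float = 1.0
    transient: float = 200.0
    a: float = 0.165
    b: float = 0.2
    c: float = 10.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_oscillators < 2:
            raise ValueError("need at least 2 oscillators")
        if self.dt_integration <= 0 or self.dt_integration > self.sample_interval / 10:
            raise ValueError("dt_integration must be positive and << sample_interval")
        if self.noise_intensity < 0:
            raise ValueError("noise intensity D must be >= 0")
        if self.mean_degree >= self.n_oscillators:
            raise ValueError("mean degree must be below the number of oscillators")


@dataclass
class SimulatedDataset:
    """Channels x samples matrix plus the ground-truth synchrony window."""

    data: np.ndarray
    ground_truth_window: tuple[int, int]
    spec: object = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("simulated data contain non-finite values")
        lo, hi = self.ground_truth_window
        # lo == hi encodes an empty window (system never synchronised)
        if not (0 <= lo <= hi <= self.data.shape[1]):
            raise ValueError("ground-truth window outside the recorded range")


def simulate_ar(spec: ARSpec | None = None) -> SimulatedDataset:
    """Iterate the five coupled difference equations of the AR benchmark.

    Innovations are independent Gaussians (sd ``noise_sd``); initial
    conditions are zero and ``burn_in`` leading samples are discarded so the
    printed switch time refers to post-burn-in sample indices.
    """
    spec = spec or ARSpec()
    rng = np.random.default_rng(spec.rng_seed)
    total = spec.burn_in + spec.n_samples
    x = np.zeros((5, total + 2))  # two leading zero columns hold the lags
    eps = rng.normal(0.0, spec.noise_sd, size=(5, total))
    for t in range(total):
        i = t + 2
        post = (t - spec.burn_in) >= spec.switch_time
        k1 = spec.k1_post if post else spec.k1_pre
        k2 = spec.k2_post if post else spec.k2_pre
        x1_1, x1_2 = x[0, i - 1], x[0, i - 2]
        x3_cross = x[2, i - 2] if spec.x3_self_lag else x[1, i - 2]
        x[0, i] = 0.95 * _SQ2 * x1_1 - 0.9025 * x1_2 + eps[0, t]
        x[1, i] = 0.6 * x[1, i - 1] - 0.3 * x[1, i - 2] + k2 * x1_1 + eps[1, t]
        x[2, i] = 0.8 * x[2, i - 1] - 0.5 * x3_cross + 0.4 * x1_1 + eps[2, t]
        x[3, i] = k1 * x1_2 + 0.25 * _SQ2 * x[3, i - 1] + 0.25 * _SQ2 * x[4, i - 1] + eps[3, t]
        x[4, i] = -0.25 * _SQ2 * x[3, i - 1] + 0.25 * _SQ2 * x[4, i - 1] + eps[4, t]
        if np.max(np.abs(x[:, i])) > 1e8:
            raise RuntimeError(f"AR trajectory diverged at step {t} (seed {spec.rng_seed})")
    data = x[:, 2 + spec.burn_in :].copy()
    return SimulatedDataset(
        data=data,
        ground_truth_window=(spec.switch_time, spec.n_samples),
        spec=spec,
    )


def random_mean_degree_graph(
    n: int, km: float, rng: np.random.Generator | int | None = None, max_tries: int = 1000
) -> np.ndarray:
    """Connected Erdos-Renyi G(n, m) adjacency with mean degree ``km``.

    The edge count m = n*km/2 must be an integer; sampling repeats until a
    connected graph is drawn.
    """
    if km >= n:
        raise ValueError("mean degree must be below n")
    m_edges = n * km / 2.0
    if abs(m_edges - round(m_edges)) > 1e-9:
        raise ValueError("n * km must be even so the edge count is integral")
    m_edges = int(round(m_edges))
    rng = np.random.default_rng(rng)
    for _ in range(max_tries):
        g = nx.gnm_random_graph(n, m_edges, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            adj = nx.to_numpy_array(g, dtype=float)
            return adj
    raise RuntimeError("failed to sample a connected graph; increase km or max_tries")


def _rossler_coupling(t_rec: float, spec: RosslerSpec) -> float:
    lo, hi = spec.coupling_window
    return spec.coupling_high if lo < t_rec < hi else spec.coupling_low


def simulate_rossler(spec: RosslerSpec | None = None) -> SimulatedDataset:
    """Integrate the noisy Rossler network and record the x coordinates.

    dx_i = -w_i y_i - z_i + lambda(t) sum_j xi_ij (x_j - x_i) + noise
    dy_i =  w_i x_i + a y_i
    dz_i =  b + z_i (x_i - c)

    White noise of intensity D enters the x equations only (Euler-Maruyama
    increments of sd sqrt(2 D dt)).  lambda(t) follows the recorded-sample
    clock: t = 0 at the end of the transient.
    """
    spec = spec or RosslerSpec()
    rng = np.random.default_rng(spec.rng_seed)
    M = spec.n_oscillators
    adj = random_mean_degree_graph(M, spec.mean_degree, rng)
    deg = adj.sum(axis=1)
    omega = rng.uniform(*spec.omega_range, size=M)

    xs = rng.uniform(-5.0, 5.0, size=M)
    ys = rng.uniform(-5.0, 5.0, size=M)
    zs = rng.uniform(0.0, 1.0, size=M)

    dt = spec.dt_integration
    noise_sd = np.sqrt(2.0 * spec.noise_intensity * dt)
    steps_per_sample = int(round(spec.sample_interval / dt))
    n_transient = int(round(spec.transient / dt))
    data = np.empty((M, spec.n_samples))

    def step(lam: float) -> None:
        nonlocal xs, ys, zs
        coupling = lam * (adj @ xs - deg * xs)
        dx = -omega * ys - zs + coupling
        dy = omega * xs + spec.a * ys
        dz = spec.b + zs * (xs - spec.c)
        xs = xs + dt * dx + noise_sd * rng.standard_normal(M)
        ys = ys + dt * dy
        zs = zs + dt * dz
        if np.max(np.abs(xs)) > 1e3 or np.max(np.abs(zs)) > 1e6:
            raise RuntimeError(
                f"Rossler trajectory escaped (seed {spec.rng_seed}); "
                "reduce dt_integration or noise_intensity"
            )

    for _ in range(n_transient):
        step(spec.coupling_low)
    for s in range(spec.n_samples):
        data[:, s] = xs
        lam = _rossler_coupling(s * spec.sample_interval, spec)
        for _ in range(steps_per_sample):
            step(lam)

    lo = int(np.ceil(spec.coupling_window[0] / spec.sample_interval))
    hi = int(min(np.floor(spec.coupling_window[1] / spec.sample_interval), spec.n_samples))
    return SimulatedDataset(data=data, ground_truth_window=(lo, hi), spec=spec)
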