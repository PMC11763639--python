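"""Synthetic task-related EEG with known microstate structure.

Six designed neural sources — background noise, two crossing chirps, and
three Gaussian-pulse-modulated sines — are mixed through a random square
matrix (instantaneous linear model ``X = M S``) and averaged over trials,
emulating an evoked-response recording whose true state sequence S1–S5 is
known per sample.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimulationConfig",
    "SimulatedEEG",
    "make_sources",
    "make_mixing_matrix",
    "make_dataset",
    "ground_truth_labels",
    "easy_config",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the six-source simulated EEG.

    Defaults reproduce the reference simulation: a 1000 ms record at
    1000 Hz, six channels, 50 averaged trials; chirps sweeping between
    10 and 30 Hz with ±5 Hz endpoint fluctuation; pulse-modulated sines
    at 30/20/10 Hz (±5 Hz) under 300 ms Gaussian envelopes centered at
    800/500/200 ms (±50 ms), peak 1, sine amplitude 0.5.
    """

    n_channels: int = 6
    duration_ms: int = 1000
    srate_hz: int = 1000
    n_trials: int = 50
    chirp_f_low: float = 10.0
    chirp_f_high: float = 30.0
    freq_jitter_hz: float = 5.0
    pulse_centers_ms: tuple[float, ...] = (800.0, 500.0, 200.0)
    pulse_center_jitter_ms: float = 50.0
    pulse_duration_ms: float = 300.0
    pulse_peak_amp: float = 1.0
    sine_amp: float = 0.5
    sine_freqs_hz: tuple[float, ...] = (30.0, 20.0, 10.0)
    random_phase: bool = True
    mixing_seed: int = 0
    trial_seed: int = 1

    def __post_init__(self) -> None:
        if self.n_channels != 1 + 2 + len(self.pulse_centers_ms):
            raise ValueError("n_channels must equal the number of sources (square mixing)")
        if len(self.sine_freqs_hz) != len(self.pulse_centers_ms):
            raise ValueError("one sine frequency per pulse center required")
        for name in ("duration_ms", "srate_hz", "n_trials", "chirp_f_low",
                     "chirp_f_high", "pulse_duration_ms", "pulse_peak_amp",
                     "sine_amp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.freq_jitter_hz < 0 or self.pulse_center_jitter_ms < 0:
            raise ValueError("jitters must be nonnegative")
        if self.freq_jitter_hz >= min(self.chirp_f_low, *self.sine_freqs_hz):
            raise ValueError("frequency jitter must be smaller than the nominal frequencies")
        if self.pulse_center_jitter_ms >= self.pulse_duration_ms:
            raise ValueError("pulse center jitter must be smaller than the pulse duration")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_ms * self.srate_hz / 1000.0))

    @property
    def n_states(self) -> int:
        return len(self.pulse_centers_ms) + 2

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SimulatedEEG:
    """A simulated recording with its generating quantities attached."""

    data: np.ndarray           # (n_channels, n_samples) trial-averaged mixed signal
    sources: np.ndarray        # (n_trials, n_sources, n_samples) per-trial sources
    mixing: np.ndarray         # (n, n) mixing matrix M
    truth: np.ndarray          # (n_samples,) state labels in {1..5}
    config: SimulationConfig = field(repr=False)


def easy_config(**overrides) -> SimulationConfig:
    """A fully coherent, jitter-free configuration.

    All frequency/center fluctuations are zero and sine phases are fixed,
    so every trial is identical up to the noise source and trial averaging
    suppresses only the noise. Useful as an easy recovery regime.
    """
    base = dict(freq_jitter_hz=0.0, pulse_center_jitter_ms=0.0, random_phase=False)
    base.update(overrides)
    return SimulationConfig(**base)


def make_sources(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Generate one trial's source matrix (n_sources × n_samples).

    Source 1 is unit-variance Gaussian white noise. Sources 2–3 are
    constant-amplitude linear chirps sweeping (low±j)→(high±j) Hz and the
    reverse; endpoint fluctuations are drawn once per trial. Sources 4–6
    are sines (amplitude ``sine_amp``, per-trial ±j Hz fluctuation, random
    initial phase when ``random_phase``) under Gaussian envelopes of the
    configured duration (σ = duration/6, peak ``pulse_peak_amp``).
    """
    T = config.n_samples
    t = np.arange(T) / config.srate_hz  # seconds
    dur = T / config.srate_hz
    jf = config.freq_jitter_hz
    S = np.empty((config.n_channels, T))

    S[0] = rng.standard_normal(T)

    for row, (f0n, f1n) in zip(
        (1, 2),
        ((config.chirp_f_low, config.chirp_f_high),
         (config.chirp_f_high, config.chirp_f_low)),
    ):
        f0 = f0n + rng.uniform(-jf, jf)
        f1 = f1n + rng.uniform(-jf, jf)
        phi = rng.uniform(0.0, 2.0 * np.pi) if config.random_phase else 0.0
        # linear chirp: phase(t) = 2π (f0 t + (f1-f0) t² / (2 dur)) + phi
        phase = 2.0 * np.pi * (f0 * t + (f1 - f0) * t * t / (2.0 * dur)) + phi
        S[row] = np.cos(phase)

    sigma_s = (config.pulse_duration_ms / 1000.0) / 6.0  # ≈99.7% mass in the nominal duration
    jc = config.pulse_center_jitter_ms / 1000.0
    for k, (center_ms, f_nom) in enumerate(zip(config.pulse_centers_ms, config.sine_freqs_hz)):
        f = f_nom + rng.uniform(-jf, jf)
        center = center_ms / 1000.0 + rng.uniform(-jc, jc)
        phi = rng.uniform(0.0, 2.0 * np.pi) if config.random_phase else 0.5 * np.pi
        env = config.pulse_peak_amp * np.exp(-0.5 * ((t - center) / sigma_s) ** 2)
        S[3 + k] = env * config.sine_amp * np.sin(2.0 * np.pi * f * t + phi)
    return S


def make_mixing_matrix(config: SimulationConfig, max_cond: float = 1e3,
                       max_redraws: int = 100) -> np.ndarray:
    """Draw an i.i.d. standard-normal mixing matrix with a conditioning guard."""
    rng = np.random.default_rng(config.mixing_seed)
    n = config.n_channels
    for _ in range(max_redraws):
        M = rng.standard_normal((n, n))
        if np.linalg.cond(M) < max_cond:
            return M
    raise RuntimeError(
        f"could not draw a mixing matrix with condition number < {max_cond:g} "
        f"in {max_redraws} attempts"
    )


def ground_truth_labels(config: SimulationConfig) -> np.ndarray:
    """Per-sample state labels in {1..5} (0-based samples, half-open runs).

    Boundaries sit at the nominal (unjittered) pulse centers ± half the
    pulse duration: with centers 200/500/800 ms and 300 ms pulses the runs
    are S1=[0,50), S2=[50,350), S3=[350,650), S4=[650,950), S5=[950,1000) ms.
    """
    T = config.n_samples
    sr = config.srate_hz / 1000.0  # samples per ms
    centers = sorted(config.pulse_centers_ms)
    half = config.pulse_duration_ms / 2.0
    bounds_ms = [centers[0] - half] + [c + half for c in centers]
    bounds = [int(round(b * sr)) for b in bounds_ms]
    labels = np.empty(T, dtype=np.int64)
    edges = [0] + bounds + [T]
    for state, (lo, hi) in enumerate(zip(edges[:-1], edges[1:]), start=1):
        labels[lo:hi] = state
    return labels


def make_dataset(config: SimulationConfig, mixing: np.ndarray | None = None) -> SimulatedEEG:
    """Generate a trial-averaged simulated EEG recording.

    One mixing matrix (from ``mixing_seed``, unless given explicitly) is
    applied to every trial; the recording is the mean over ``n_trials`` of
    ``M @ S_trial``. Ground-truth labels depend only on the configuration.
    """
    if mixing is None:
        M = make_mixing_matrix(config)
    else:
        M = np.asarray(mixing, dtype=float)
        if M.shape != (config.n_channels, config.n_channels):
            raise ValueError("mixing matrix shape must match n_channels")
    rng = np.random.default_rng(config.trial_seed)
    sources = np.empty((config.n_trials, config.n_channels, config.n_samples))
    for i in range(config.n_trials):
        sources[i] = make_sources(config, rng)
    data = np.einsum("ij,tjs->is", M, sources) / config.n_trials
    return SimulatedEEG(data=data, sources=sources, mixing=M,
                        truth=ground_truth_labels(config), config=config)
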