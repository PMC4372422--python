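"""Synthetic pulse-wave sessions with controllable spectral coupling.

The generator emulates what the downstream pipeline actually sees in a
finger-PPG record: a quasi-periodic pulse train (a fundamental plus a few
decaying harmonics, with slow random phase drift that broadens the spectral
lines), a degree-6 polynomial baseline drift standing in for sensor
settling, and additive white noise. It makes no attempt at physiological
pulse morphology — only the spectral envelope matters to the LPC models and
every distortion measure built on them.

A session consists of four signals. The care-giver's generator parameters
(fundamental pulse frequency and harmonic decay) are drawn from a prior;
the participant's during-session parameters are a convex interpolation
between an independent draw and the care-giver's, with weight kappa in
[0, 1]: kappa = 1 means identical generators (independent noise and
jitter), kappa = 0 fully independent generators. The before and after
signals always use independent draws from the same prior, playing the role
of control recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .signal_io import SESSION_LABELS, Signal

__all__ = ["SynthConfig", "PulseParams", "generate_ppg", "generate_session"]


@dataclass(frozen=True)
class SynthConfig:
    """Study-scale generator settings.

    n : samples per record (default 1800 — a 3-minute recording at an
        abstract ~10 samples/s, matching the downsampled rate at which a
        pulse wave's harmonics occupy the full spectral band the way vowel
        formants do in speech; the sampling rate itself is never used).
    pulse_rate : mean fundamental, in cycles per 100 samples (default 12,
        i.e. ~72 beats/min at 10 samples/s). Per-signal fundamentals are
        drawn uniformly from pulse_rate * [0.75, 1.33] / 100 cycles/sample.
    harmonics : number of partials, amplitudes decaying geometrically with a
        per-signal decay factor drawn from U(0.4, 0.7).
    drift : peak scale of the degree-6 polynomial baseline drift.
    noise_sd : standard deviation of the additive white Gaussian noise.
    fm_depth : relative depth of the slow frequency modulation emulating
        beat-to-beat pulse-rate variability; the instantaneous fundamental
        is f0 (1 + fm_depth z_t) with z a unit-variance slow process. This
        broadens every harmonic line to a width ~ fm_depth * f0, so that
        realization noise stays well inside a line while distinct
        fundamentals stay well separated.
    fm_tau : correlation time of the modulation process, in samples
        (default ~2 pulse periods, beat-to-beat variability).
    am_depth : relative depth of the slow amplitude modulation emulating
        beat-to-beat pulse-amplitude variability (respiration, vasomotion).
    background : level of the broadband physiological background (vasomotor
        and motion activity), as a fraction of the pulse-train RMS. Rendered
        as low-pass-filtered noise, it puts the harmonic peaks ~20 dB above
        a smooth continuum — the usual look of a finger-pulse spectrum — and
        keeps the all-pole fit well conditioned even with no sensor noise.
    coupling : kappa in [0, 1], spectral similarity of the care-giver and
        during-session generators.
    seed : RNG seed; every sample is reproducible from it.
    """

    n: int = 1800
    pulse_rate: float = 12.0
    harmonics: int = 3
    drift: float = 0.5
    noise_sd: float = 0.1
    fm_depth: float = 0.02
    fm_tau: float = 15.0
    am_depth: float = 0.2
    background: float = 0.25
    coupling: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        if self.n < 26:  # 2 * (p + 1) for the default order p = 12
            raise ValueError("n too small for downstream LPC")
        if self.harmonics < 1:
            raise ValueError("need at least one harmonic")


@dataclass(frozen=True)
class PulseParams:
    """The spectral identity of one pulse generator.

    A person's pulse differs from another's in rate (f0), overall harmonic
    roll-off (decay) and the fine balance of the individual harmonics
    (shape, one log-amplitude tweak per harmonic) — the same features an
    all-pole envelope resolves.
    """

    f0: float  # fundamental, cycles per sample
    decay: float  # geometric harmonic amplitude decay
    shape: tuple[float, ...] = ()  # per-harmonic log-amplitude tweaks

    def amplitude(self, harmonic: int) -> float:
        """Amplitude of the 1-based ``harmonic``."""
        tweak = self.shape[harmonic - 1] if harmonic - 1 < len(self.shape) else 0.0
        return self.decay ** (harmonic - 1) * float(np.exp(tweak))

    def interpolate(self, other: "PulseParams", weight: float) -> "PulseParams":
        """Convex combination: weight 1 returns ``other`` exactly."""
        n = max(len(self.shape), len(other.shape))
        mine = np.zeros(n)
        mine[: len(self.shape)] = self.shape
        theirs = np.zeros(n)
        theirs[: len(other.shape)] = other.shape
        return PulseParams(
            f0=(1.0 - weight) * self.f0 + weight * other.f0,
            decay=(1.0 - weight) * self.decay + weight * other.decay,
            shape=tuple((1.0 - weight) * mine + weight * theirs),
        )


def _draw_params(rng: np.random.Generator, config: SynthConfig) -> PulseParams:
    base = config.pulse_rate / 100.0
    return PulseParams(
        f0=rng.uniform(0.75 * base, 4.0 / 3.0 * base),
        decay=rng.uniform(0.35, 0.75),
        shape=tuple(rng.normal(0.0, 0.4, config.harmonics)),
    )


def _slow_modulation(rng: np.random.Generator, n: int, tau: float) -> np.ndarray:
    """Stationary unit-variance AR(1) process with correlation time tau."""
    from scipy.signal import lfilter

    rho = np.exp(-1.0 / tau)
    e = rng.normal(0.0, np.sqrt(1.0 - rho * rho), n)
    e[0] = rng.normal()  # start in the stationary distribution
    return lfilter([1.0], [1.0, -rho], e)


def _render(params: PulseParams, config: SynthConfig,
            rng: np.random.Generator, label: str) -> Signal:
    t = np.arange(config.n, dtype=float)
    x = np.zeros(config.n)
    # instantaneous fundamental wanders around f0 (pulse-rate variability);
    # the harmonic phases stay mutually coherent, as in a real pulse train
    z = _slow_modulation(rng, config.n, config.fm_tau)
    phase = 2.0 * np.pi * np.cumsum(params.f0 * (1.0 + config.fm_depth * z))
    # one shared amplitude modulator: the whole pulse swells and shrinks
    w = _slow_modulation(rng, config.n, config.fm_tau)
    envelope = 1.0 + config.am_depth * w
    for harmonic in range(1, config.harmonics + 1):
        amp = params.amplitude(harmonic)
        offset = rng.uniform(0.0, 2.0 * np.pi)
        x += amp * envelope * np.sin(harmonic * phase + offset)
    if config.background:
        from scipy.signal import lfilter

        pulse_rms = float(np.sqrt(np.mean(x * x)))
        raw = rng.normal(0.0, 1.0, config.n)
        colored = lfilter([1.0], [1.0, -0.9], raw)  # low-frequency vasomotor part
        colored *= 1.0 / np.sqrt(np.mean(colored * colored))
        flat = rng.normal(0.0, 1.0, config.n)  # broadband measurement-chain part
        mix = np.sqrt(0.2) * colored + np.sqrt(0.8) * flat
        x += config.background * pulse_rms * mix
    if config.drift:
        coeffs = rng.normal(0.0, 1.0, 7)  # degree-6 drift polynomial
        u = 2.0 * t / (config.n - 1) - 1.0
        drift = np.polynomial.polynomial.polyval(u, coeffs)
        peak = np.max(np.abs(drift))
        if peak > 0:
            x += config.drift * drift / peak * np.max(np.abs(x))
    if config.noise_sd:
        x += rng.normal(0.0, config.noise_sd, config.n)
    return Signal(x, label=label)


def generate_ppg(config: SynthConfig, params: PulseParams | None = None,
                 label: str = "synthetic") -> Signal:
    """One synthetic pulse-wave record, deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    if params is None:
        params = _draw_params(rng, config)
    return _render(params, config, rng, label)


def generate_session(coupling: float | None = None, seed: int | None = None,
                     config: SynthConfig | None = None,
                     ) -> tuple[Signal, Signal, Signal, Signal]:
    """Four session signals (caregiver, before, during, after).

    The during-session generator interpolates between an independent draw
    and the care-giver's with weight ``coupling``; before and after are
    always independent draws from the same prior.
    """
    config = config or SynthConfig()
    if coupling is not None:
        config = replace(config, coupling=coupling)
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    caregiver_params = _draw_params(rng, config)
    during_own = _draw_params(rng, config)
    before_params = _draw_params(rng, config)
    after_params = _draw_params(rng, config)
    during_params = during_own.interpolate(caregiver_params, config.coupling)
    labels = SESSION_LABELS
    caregiver = _render(caregiver_params, config, rng, labels[0])
    before = _render(before_params, config, rng, labels[1])
    during = _render(during_params, config, rng, labels[2])
    after = _render(after_params, config, rng, labels[3])
    return caregiver, before, during, after
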