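"""Seeded generator of labeled synthetic nanomotion recordings.

The study's raw cantilever recordings are not deposited, so this module
produces surrogate signals with the statistical structure the analysis
assumes: stationary colored noise (white + 1/f^alpha + an optional resonance
peak), intermittent spikes from cell-scale events, and — for positive-label
recordings only — a band-limited change in spectral power that relaxes
exponentially toward its plateau after drug onset.  The generator makes no
attempt to model cell biophysics; its only contract is that the two classes
are distinguishable through band-limited spectral statistics, in either
direction (power_ratio below or above 1).

All randomness flows from a single integer seed, at every granularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import fft as sfft
from scipy import signal as sps

from .signals import DeflectionRecording, Label, Phase, PhaseSpan, RecordingMeta
from .viability import DoseResponseData, four_pl


class ConfigError(ValueError):
    """A simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class NoiseConfig:
    white_sigma: float = 1.0
    pink_amplitude: float = 0.5
    pink_exponent: float = 1.0


@dataclass(frozen=True)
class ResonanceConfig:
    """Second-order resonator emulating the cantilever's mechanical resonance.

    Disabled by default (amplitude 0) because the desk-scale 4 kHz profile
    cannot represent the ~8.5 kHz peak; the 18 kHz ovarian profile enables it.
    """

    freq_hz: float = 8500.0
    q_factor: float = 30.0
    amplitude: float = 0.0


@dataclass(frozen=True)
class SpikeConfig:
    rate_hz: float = 0.05
    amp_scale: float = 5.0
    width_s: float = 0.02


@dataclass(frozen=True)
class EffectConfig:
    """Class effect: multiplicative band-power change with exponential onset.

    For a positive-label recording the power in [band_lo_hz, band_hi_hz)
    relaxes from its baseline toward baseline x power_ratio with time
    constant tau_min after drug onset; the spike rate is scaled likewise by
    spike_rate_ratio.  Negative labels and non-drug phases are untouched.
    """

    band_lo_hz: float = 0.5
    band_hi_hz: float = 10.0
    power_ratio: float = 0.25
    spike_rate_ratio: float = 1.0
    tau_min: float = 30.0


@dataclass(frozen=True)
class SimulationConfig:
    sampling_rate: float = 4000.0
    blank_min: float = 5.0
    medium_min: float = 120.0
    drug_min: float = 120.0
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    resonance: ResonanceConfig = field(default_factory=ResonanceConfig)
    spikes: SpikeConfig = field(default_factory=SpikeConfig)
    effect: EffectConfig = field(default_factory=EffectConfig)
    label: Label = Label.NEGATIVE
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", Label(self.label))
        nyquist = self.sampling_rate / 2.0
        for name in ("sampling_rate", "blank_min", "medium_min", "drug_min"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.effect.power_ratio <= 0 or self.effect.spike_rate_ratio <= 0:
            raise ConfigError("effect ratios must be positive")
        if self.effect.band_hi_hz > nyquist:
            raise ConfigError(
                f"effect band upper edge {self.effect.band_hi_hz} Hz exceeds "
                f"Nyquist {nyquist} Hz"
            )
        if not self.effect.band_lo_hz < self.effect.band_hi_hz:
            raise ConfigError("effect band must have band_lo_hz < band_hi_hz")
        if self.resonance.amplitude > 0 and self.resonance.freq_hz >= nyquist:
            raise ConfigError("resonance frequency must be below Nyquist")

    @property
    def total_s(self) -> float:
        return 60.0 * (self.blank_min + self.medium_min + self.drug_min)


def ovarian_profile(**overrides) -> SimulationConfig:
    """18 kHz profile with an 8.5 kHz resonance and a 7-8 kHz effect band."""
    base = dict(
        sampling_rate=18000.0,
        drug_min=360.0,
        resonance=ResonanceConfig(freq_hz=8500.0, q_factor=30.0, amplitude=0.5),
        effect=EffectConfig(band_lo_hz=7000.0, band_hi_hz=8000.0, power_ratio=0.25),
    )
    base.update(overrides)
    return SimulationConfig(**base)


def onset_gain(t_since_onset_s: np.ndarray, ratio: float, tau_min: float) -> np.ndarray:
    """Multiplicative power gain profile: 1 -> ratio with time constant tau."""
    t = np.maximum(np.asarray(t_since_onset_s, dtype=float), 0.0)
    return 1.0 + (ratio - 1.0) * (1.0 - np.exp(-t / (tau_min * 60.0)))


def _pink_noise(rng: np.random.Generator, n: int, fs: float, exponent: float) -> np.ndarray:
    """Unit-variance 1/f^alpha noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = sfft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    out = sfft.irfft(spec * shape, n=n)
    sd = out.std()
    return out / sd if sd > 0 else out


def _resonance_noise(
    rng: np.random.Generator, n: int, fs: float, cfg: ResonanceConfig
) -> np.ndarray:
    b, a = sps.iirpeak(cfg.freq_hz, cfg.q_factor, fs=fs)
    out = sps.lfilter(b, a, rng.standard_normal(n))
    sd = out.std()
    return out / sd if sd > 0 else out


def _band_split(x: np.ndarray, fs: float, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
    """Zero-phase FFT split of x into in-band [lo, hi) and out-of-band parts."""
    spec = sfft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    mask = (freqs >= lo) & (freqs < hi)
    band = sfft.irfft(np.where(mask, spec, 0.0), n=x.size)
    return band, x - band


def _spike_train(
    rng: np.random.Generator,
    n: int,
    fs: float,
    spikes: SpikeConfig,
    rate_profile: np.ndarray,
) -> np.ndarray:
    """Poisson spikes with exponential amplitudes and a half-cosine pulse.

    ``rate_profile`` gives the instantaneous rate (Hz) per 1-s chunk; an
    inhomogeneous process is realized chunk-by-chunk.
    """
    out = np.zeros(n)
    width = max(int(round(spikes.width_s * fs)), 2)
    pulse = np.sin(np.pi * np.arange(width) / (width - 1))
    chunk = int(fs)
    n_chunks = len(rate_profile)
    counts = rng.poisson(rate_profile)  # rate x 1 s
    for ci in np.nonzero(counts)[0]:
        for _ in range(counts[ci]):
            pos = ci * chunk + int(rng.integers(0, chunk))
            if pos >= n:
                continue
            amp = rng.exponential(spikes.amp_scale) * rng.choice([-1.0, 1.0])
            end = min(pos + width, n)
            out[pos:end] += amp * pulse[: end - pos]
    return out


def simulate_recording(cfg: SimulationConfig) -> DeflectionRecording:
    """Generate one recording; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sampling_rate
    n = int(round(cfg.total_s * fs))
    noise = cfg.noise.white_sigma * rng.standard_normal(n)
    if cfg.noise.pink_amplitude > 0:
        noise += cfg.noise.pink_amplitude * _pink_noise(
            rng, n, fs, cfg.noise.pink_exponent
        )
    if cfg.resonance.amplitude > 0:
        noise += cfg.resonance.amplitude * _resonance_noise(rng, n, fs, cfg.resonance)

    drug_start_s = 60.0 * (cfg.blank_min + cfg.medium_min)
    positive = cfg.label == Label.POSITIVE

    if positive and cfg.effect.power_ratio != 1.0:
        band, rest = _band_split(noise, fs, cfg.effect.band_lo_hz, cfg.effect.band_hi_hz)
        t = np.arange(n) / fs - drug_start_s
        gain = onset_gain(t, cfg.effect.power_ratio, cfg.effect.tau_min)
        gain[t < 0] = 1.0
        noise = rest + np.sqrt(gain) * band

    if cfg.spikes.rate_hz > 0:
        chunk_t = np.arange(int(np.ceil(cfg.total_s))) + 0.5 - drug_start_s
        rates = np.full(chunk_t.size, cfg.spikes.rate_hz)
        if positive and cfg.effect.spike_rate_ratio != 1.0:
            mod = onset_gain(chunk_t, cfg.effect.spike_rate_ratio, cfg.effect.tau_min)
            mod[chunk_t < 0] = 1.0
            rates *= mod
        noise += _spike_train(rng, n, fs, cfg.spikes, rates)

    blank_end = 60.0 * cfg.blank_min
    medium_end = blank_end + 60.0 * cfg.medium_min
    phases = [
        PhaseSpan(Phase.BLANK, 0.0, blank_end),
        PhaseSpan(Phase.MEDIUM, blank_end, medium_end),
        PhaseSpan(Phase.DRUG, medium_end, cfg.total_s),
    ]
    meta = RecordingMeta(
        experiment_id=f"sim-{cfg.seed}",
        cell_line="synthetic",
        drug="synthetic",
        concentration_uM=0.0,
        label=cfg.label,
    )
    return DeflectionRecording(noise, fs, phases, meta)


@dataclass
class Cohort:
    recordings: list[DeflectionRecording]
    labels: list[Label]
    concentrations: list[float]

    def __post_init__(self) -> None:
        if not len(self.recordings) == len(self.labels) == len(self.concentrations):
            raise ValueError("cohort fields must have equal lengths")


def member_configs(
    n_pos: int,
    n_neg: int,
    cfg_template: SimulationConfig,
    seed: int,
) -> list[SimulationConfig]:
    """Per-recording configs with labels and deterministically derived seeds.

    Exposed separately from :func:`simulate_cohort` so pipelines can stream
    recordings one at a time instead of holding a whole cohort in memory.
    """
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_pos + n_neg)
    labels = [Label.POSITIVE] * n_pos + [Label.NEGATIVE] * n_neg
    return [
        replace(cfg_template, label=lab, seed=int(s))
        for lab, s in zip(labels, child_seeds)
    ]


def simulate_cohort(
    n_pos: int,
    n_neg: int,
    cfg_template: SimulationConfig,
    seed: int,
    concentrations: list[float] | None = None,
) -> Cohort:
    configs = member_configs(n_pos, n_neg, cfg_template, seed)
    if concentrations is None:
        concentrations = [0.0] * len(configs)
    recs = []
    for i, (cfg, conc) in enumerate(zip(configs, concentrations)):
        rec = simulate_recording(cfg)
        rec.meta = replace(
            rec.meta, experiment_id=f"sim-{seed}-{i:03d}", concentration_uM=conc
        )
        recs.append(rec)
    return Cohort(recs, [c.label for c in configs], list(concentrations))


def simulate_dose_response(
    ic50_uM: float,
    hill: float,
    top: float,
    bottom: float,
    concentrations: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DoseResponseData:
    """Viability drawn from a 4PL curve plus Gaussian noise (noise_sd in %)."""
    if ic50_uM <= 0:
        raise ConfigError("ic50_uM must be positive")
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise ConfigError("concentrations must be nonnegative")
    rng = np.random.default_rng(seed)
    viability = four_pl(conc, bottom, top, ic50_uM, hill)
    if noise_sd > 0:
        viability = viability + rng.normal(0.0, noise_sd, size=conc.size)
    return DoseResponseData(concentration_uM=conc, viability_pct=viability)
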