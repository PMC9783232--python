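"""Seeded synthetic acoustic scenes: rope-jump sessions and breathing clips.

The generators encode exactly the statistical structure the analysis
pipeline exploits — periodic high-energy footfall bursts over ambient
noise, and breathing noise whose low-band energy and spectral spread
grow with exercise intensity — without claiming acoustic realism.
Every source of randomness flows from one seed through named
substreams, so onsets, burst textures and ambient noise can be varied
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfilt

from .audio_io import AudioSignal, PipelineConfig, write_wav

__all__ = [
    "DomainLabel",
    "JumpSceneSpec",
    "JumpSceneTruth",
    "BreathClipSpec",
    "synth_jump_scene",
    "synth_breath_clip",
    "make_intensity_dataset",
    "heart_rate_for_intensity",
]

_FACTOR_LEVELS = 2  # two choices per factor: user, floor, footwear


@dataclass(frozen=True)
class DomainLabel:
    """A recording condition: (user, floor, footwear), each binary.

    ``domain_id`` encodes the factor triple uniquely:
    ``id = user*4 + floor*2 + footwear``.
    """

    domain_id: int

    def __post_init__(self) -> None:
        if not 0 <= self.domain_id < _FACTOR_LEVELS**3:
            raise ValueError(f"domain_id must be in [0, 8), got {self.domain_id}")

    @property
    def factors(self) -> tuple[int, int, int]:
        d = self.domain_id
        return (d >> 2) & 1, (d >> 1) & 1, d & 1

    @classmethod
    def from_factors(cls, user: int, floor: int, footwear: int) -> "DomainLabel":
        return cls(domain_id=user * 4 + floor * 2 + footwear)

    @property
    def gain(self) -> float:
        """Per-domain amplitude gain in [0.5, 1.5], deterministic in the id."""
        return 0.5 + self.domain_id / (_FACTOR_LEVELS**3 - 1)

    @property
    def tilt(self) -> float:
        """First-order spectral tilt coefficient in [-0.3, 0.3]."""
        user, floor, footwear = self.factors
        return 0.3 * (user + floor - footwear - 1) / 2 + 0.05 * self.domain_id / 7

    @property
    def resonance_hz(self) -> float:
        """Per-domain timbre signature: a resonance peak frequency.

        Each (user, floor, footwear) combination colours the sound with
        its own resonance, so domains stay identifiable even after
        per-clip normalization — the cue the domain-adversarial
        regressor must learn to ignore.
        """
        return 450.0 + 350.0 * ((self.domain_id * 3) % 8)


def _apply_domain(x: np.ndarray, domain: DomainLabel, sample_rate: int) -> np.ndarray:
    """Gain, one-tap tilt y[n] = x[n] + tilt*x[n-1], and a resonance boost."""
    from scipy.signal import iirpeak, tf2sos

    y = x + domain.tilt * np.concatenate(([0.0], x[:-1]))
    w0 = min(domain.resonance_hz, 0.4 * sample_rate) / (sample_rate / 2)
    b, a = iirpeak(w0, Q=4.0)
    y = y + 1.3 * sosfilt(tf2sos(b, a), y)
    return domain.gain * y


@dataclass(frozen=True)
class JumpSceneSpec:
    duration: float
    n_jumps: int
    base_period: float = 0.5
    period_jitter: float = 0.02
    impulse_decay: float = 0.05
    snr_db: float = 20.0
    amp_jitter: float = 0.1
    domain: DomainLabel = field(default_factory=lambda: DomainLabel(0))
    sample_rate: int = 16_000
    start_offset: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_jumps < 0 or self.duration <= 0:
            raise ValueError("n_jumps >= 0 and duration > 0 required")
        if self.n_jumps * self.base_period > self.duration:
            raise ValueError(
                f"{self.n_jumps} jumps at period {self.base_period}s do not fit "
                f"in {self.duration}s"
            )
        if not 0 <= self.period_jitter <= 0.2:
            raise ValueError("period_jitter must lie in [0, 0.2]")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")


@dataclass(frozen=True)
class JumpSceneTruth:
    onset_times: np.ndarray  # seconds, strictly increasing
    true_count: int
    true_period: float

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onset_times, dtype=np.float64)
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if self.true_count != onsets.size:
            raise ValueError("true_count must equal len(onset_times)")
        object.__setattr__(self, "onset_times", onsets)


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named child stream so each component is independently reproducible."""
    root = np.random.SeedSequence(seed)
    names = ("onsets", "bursts", "ambient", "breath", "dataset")
    return np.random.Generator(np.random.PCG64(root.spawn(len(names))[names.index(name)]))


def _periodic_carrier(
    rng: np.random.Generator, n: int, period_samples: int, sr: int
) -> np.ndarray:
    """Unit-RMS band-limited (1-4 kHz) noise, periodic with the jump period.

    Successive footfalls are cut from this shared carrier, so the sounds
    of consecutive jumps are strongly correlated at the true period --
    the premise the squared-difference period search relies on. Timing
    jitter shifts only the burst envelopes, not the carrier phase.
    """
    one = rng.standard_normal(period_samples)
    sos = butter(
        2, [1000.0 / (sr / 2), min(4000.0 / (sr / 2), 0.95)], "bandpass", output="sos"
    )
    one = sosfilt(sos, np.tile(one, 3))[period_samples : 2 * period_samples]
    one /= max(np.sqrt(np.mean(one**2)), 1e-12)
    reps = n // period_samples + 2
    return np.tile(one, reps)[:n]


def synth_jump_scene(spec: JumpSceneSpec) -> tuple[AudioSignal, JumpSceneTruth]:
    """Generate a rope-jump session and its ground truth.

    Onsets are ``start_offset + k * base_period`` with per-interval
    multiplicative jitter; each onset receives a unit-RMS footfall burst
    scaled by the domain gain and per-jump amplitude jitter; ambient
    white noise is scaled so the burst-to-noise RMS ratio equals
    ``snr_db``.
    """
    sr = spec.sample_rate
    n = int(round(spec.duration * sr))
    rng_on = _substream(spec.seed, "onsets")
    rng_b = _substream(spec.seed, "bursts")
    rng_a = _substream(spec.seed, "ambient")

    # stationary phase jitter around the rhythm grid: each onset deviates
    # independently from k * base_period, so interval deviations stay
    # bounded by +/- 2 * period_jitter * base_period instead of drifting
    # as a random walk (jumpers keep a beat; the square-wave model of the
    # detector assumes exactly this kind of stable period)
    eta = spec.base_period * spec.period_jitter * rng_on.uniform(
        -0.5, 0.5, size=spec.n_jumps
    )
    if spec.n_jumps:
        eta[0] = 0.0
    onsets = spec.start_offset + spec.base_period * np.arange(spec.n_jumps) + eta
    if spec.n_jumps == 0:
        onsets = np.empty(0)

    clean = np.zeros(n)
    burst_amp = 0.3
    period_samples = max(int(round(spec.base_period * sr)), 8)
    carrier = _periodic_carrier(rng_b, n + period_samples, period_samples, sr)
    nb = max(int(round(4 * spec.impulse_decay * sr)), 8)
    env = np.exp(-np.arange(nb) / (spec.impulse_decay * sr))
    # amplitude jitter follows an AR(1) walk: neighbouring jumps sound
    # more alike than distant ones, as human pacing does
    amps = np.ones(max(spec.n_jumps, 1))
    z = 0.0
    for k in range(spec.n_jumps):
        z = 0.7 * z + np.sqrt(1 - 0.7**2) * rng_b.standard_normal()
        amps[k] = 1.0 + spec.amp_jitter * z
    for k, onset in enumerate(onsets):
        i0 = int(round(onset * sr))
        i1 = min(i0 + nb, n)
        if i0 >= n:
            continue
        b = _apply_domain(
            burst_amp * amps[k] * env[: i1 - i0] * carrier[i0:i1], spec.domain, sr
        )
        clean[i0:i1] += b

    # actual burst RMS over its own duration (unit-RMS carrier times the
    # decay envelope), so snr_db is a true burst-to-noise RMS ratio
    burst_rms = burst_amp * spec.domain.gain * float(np.sqrt(np.mean(env**2)))
    noise_rms = burst_rms / 10 ** (spec.snr_db / 20)
    noise = noise_rms * rng_a.standard_normal(n)
    audio = np.clip(clean + noise, -1.0, 1.0)

    truth = JumpSceneTruth(
        onset_times=onsets, true_count=spec.n_jumps, true_period=spec.base_period
    )
    return AudioSignal(samples=audio, sample_rate=sr), truth


@dataclass(frozen=True)
class BreathClipSpec:
    intensity_r: float
    duration: float = 30.0
    heart_rate_h: float | None = None
    domain: DomainLabel = field(default_factory=lambda: DomainLabel(0))
    snr_db: float = 20.0
    sample_rate: int = 16_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.intensity_r <= 100:
            raise ValueError(f"intensity_r must lie in [0, 100], got {self.intensity_r}")
        if self.heart_rate_h is None:
            object.__setattr__(
                self, "heart_rate_h", heart_rate_for_intensity(self.intensity_r)
            )


def heart_rate_for_intensity(r: float) -> float:
    """Heart rate consistent with intensity r under the 120-180 bpm mapping."""
    return float(round(120.0 + 60.0 * r / 100.0))


def synth_breath_clip(spec: BreathClipSpec) -> AudioSignal:
    """Generate a post-exercise breathing clip.

    Breathing is modelled as band-limited noise (inside 100-3500 Hz)
    amplitude-modulated at the breath rate. Intensity raises the breath
    rate (~0.25 -> ~0.8 Hz), the overall level, and the upper edge of
    the noise band, so both band energy and spectral spread increase
    monotonically with ``intensity_r``.
    """
    sr = spec.sample_rate
    r = spec.intensity_r / 100.0
    n = int(round(spec.duration * sr))
    rng = _substream(spec.seed, "breath")

    f_lo = 150.0
    f_hi = 400.0 + 2200.0 * r  # spectral spread grows with intensity
    f_hi = min(f_hi, 0.45 * sr)
    sos = butter(2, [f_lo / (sr / 2), f_hi / (sr / 2)], "bandpass", output="sos")
    carrier = sosfilt(sos, rng.standard_normal(n))
    carrier /= max(np.sqrt(np.mean(carrier**2)), 1e-12)

    rate_hz = 0.25 + 0.55 * r
    t = np.arange(n) / sr
    phase = rng.uniform(0, 2 * np.pi)
    # partial modulation depth: energy present in any sub-window
    envelope = 0.55 + 0.45 * np.sin(2 * np.pi * rate_hz * t + phase) ** 2
    level = 0.02 * (1.0 + 3.0 * r)
    breath = _apply_domain(level * envelope * carrier, spec.domain, sr)

    breath_rms = np.sqrt(np.mean(breath**2))
    noise = (breath_rms / 10 ** (spec.snr_db / 20)) * rng.standard_normal(n)
    return AudioSignal(samples=np.clip(breath + noise, -1.0, 1.0), sample_rate=sr)


def _split_counts(n: int, test_fraction: float = 0.25) -> int:
    return int(np.floor(n * test_fraction))


def make_intensity_dataset(
    n_per_domain: int,
    domains: list[DomainLabel],
    seed: int,
    *,
    config: PipelineConfig | None = None,
    clip_duration: float = 30.0,
    snr_db: float = 20.0,
) -> tuple[list, pd.DataFrame]:
    """Build a labelled intensity dataset with a stratified 3:1 split.

    For every domain, ``n_per_domain`` clips are drawn with intensity
    uniform on [0, 100]; heart rate follows ``120 + 60 r / 100``; jump
    speed increases mildly with intensity. The manifest assigns
    train/test per domain so the global split is exactly 3:1 whenever
    the total is divisible by 4 (largest-remainder apportionment).
    """
    from .breath_profile import mel_spectrogram
    from .intensity_net import IntensitySample

    if not domains:
        raise ValueError("at least one domain is required")
    if len(domains) < 2:
        raise ValueError("at least two domains are required for a domain split")
    cfg = config or PipelineConfig()
    rng = _substream(seed, "dataset")

    # apportion test quota per domain: floor everywhere, remainder to low ids
    total = n_per_domain * len(domains)
    total_test = total // 4
    base = total_test // len(domains)
    extra = total_test - base * len(domains)

    samples: list[IntensitySample] = []
    rows = []
    for d_idx, domain in enumerate(domains):
        n_test = base + (1 if d_idx < extra else 0)
        test_positions = set(rng.choice(n_per_domain, size=n_test, replace=False).tolist())
        for k in range(n_per_domain):
            r = float(rng.uniform(0, 100))
            h = heart_rate_for_intensity(r)
            speed = float(np.clip(1.0 + 1.5 * r / 100.0 + rng.normal(0, 0.1), 0.5, 3.5))
            clip_seed = int(rng.integers(0, 2**31 - 1))
            clip = synth_breath_clip(
                BreathClipSpec(
                    intensity_r=r,
                    duration=clip_duration,
                    domain=domain,
                    snr_db=snr_db,
                    sample_rate=cfg.sample_rate,
                    seed=clip_seed,
                )
            )
            spec = mel_spectrogram(clip, config=cfg)
            samples.append(
                IntensitySample(
                    spectrogram=spec, speed=speed, intensity_r=r, heart_rate=h, domain=domain
                )
            )
            rows.append(
                {
                    "index": len(samples) - 1,
                    "domain_id": domain.domain_id,
                    "r": r,
                    "h": h,
                    "speed": speed,
                    "clip_seed": clip_seed,
                    "split": "test" if k in test_positions else "train",
                }
            )
    manifest = pd.DataFrame(rows)
    return samples, manifest


def write_scene(
    out_dir: str | Path, name: str, signal: AudioSignal, truth: JumpSceneTruth | None = None
) -> Path:
    """Persist a clip (PCM16 WAV) plus a CSV row of its ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    wav_path = out_dir / f"{name}.wav"
    write_wav(wav_path, signal)
    if truth is not None:
        pd.DataFrame(
            {
                "path": [str(wav_path)],
                "count": [truth.true_count],
                "period": [truth.true_period],
                "onsets": [";".join(f"{t:.6f}" for t in truth.onset_times)],
            }
        ).to_csv(out_dir / f"{name}.truth.csv", index=False)
    return wav_path
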