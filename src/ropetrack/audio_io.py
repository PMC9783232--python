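"""Audio I/O, band-pass preprocessing, framing, and pipeline configuration.

All indices stored by this package are 0-based with half-open intervals;
the classic 1-based signal-processing formulas are translated at the
boundary when frames are cut.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.io import wavfile
from scipy.signal import butter, sosfiltfilt

logger = logging.getLogger("ropetrack")

__all__ = [
    "AudioSignal",
    "FrameSeq",
    "PipelineConfig",
    "read_wav",
    "write_wav",
    "bandpass",
    "frame_signal",
    "load_config",
]


@dataclass(frozen=True)
class AudioSignal:
    """A mono audio signal: float samples plus a sampling rate in Hz."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("AudioSignal must be mono (1-D sample array)")
        if not np.all(np.isfinite(samples)):
            raise ValueError("AudioSignal samples must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.samples.size / self.sample_rate


@dataclass(frozen=True)
class FrameSeq:
    """A framed view of a signal: ``frames[i] = x[i*shift : i*shift + length]``."""

    frames: np.ndarray  # (fn, L)
    frame_length: int
    frame_shift: int

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float64)
        if frames.ndim != 2 or frames.shape[1] != self.frame_length:
            raise ValueError("frames must be a (fn, frame_length) matrix")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_bounds(self, i: int) -> tuple[int, int]:
        """Half-open sample interval covered by frame ``i``."""
        start = i * self.frame_shift
        return start, start + self.frame_length


@dataclass
class PipelineConfig:
    """All tunable parameters of the monitoring pipeline.

    The jump band's upper cutoff is clipped to ``0.45 * sample_rate``
    before filtering so the nominal 8 kHz edge stays realizable at the
    default 16 kHz rate.
    """

    sample_rate: int = 16_000
    frame_length: int = 800
    frame_shift: int = 800
    jump_band: tuple[float, float] = (500.0, 8000.0)
    breath_band: tuple[float, float] = (100.0, 3500.0)
    omega: float = 6.0
    t_min_frames: int = 6
    t_max_frames: int = 25
    seed: int = 0
    # mel spectrogram
    n_fft: int = 512
    hop: int = 160
    n_mels: int = 64
    image_size: int = 64
    # GAN
    gan_base_channels: int = 8
    gan_crop_size: int = 16
    gan_n_crops: int = 4
    gan_lr: float = 1e-4
    gan_steps: int = 200
    gan_attention: bool = True
    gan_local_discriminator: bool = True
    # DANN
    dann_alpha: float = 0.1
    dann_lr: float = 1e-3
    dann_epochs: int = 10
    dann_batch_size: int = 32
    dann_feature_dim: int = 32
    dann_domain_adaptation: bool = True

    def __post_init__(self) -> None:
        for low, high in (self.jump_band, self.breath_band):
            if not (0 < low < high):
                raise ValueError(f"invalid band ({low}, {high})")
            if low >= self.sample_rate / 2:
                raise ValueError(f"band ({low}, {high}) exceeds Nyquist")
        if self.t_min_frames >= self.t_max_frames:
            raise ValueError("t_min_frames must be < t_max_frames")

    def effective_jump_band(self) -> tuple[float, float]:
        low, high = self.jump_band
        return low, min(high, 0.45 * self.sample_rate)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        return cls(**_load_mapping(path))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_mapping(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a key-value mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("jump_band", "breath_band"):
        if key in data:
            data[key] = tuple(data[key])
    return data


def load_config(path: str | Path | None, **overrides) -> PipelineConfig:
    """Load a config file (YAML key-value) and apply explicit overrides."""
    base = _load_mapping(path) if path is not None else {}
    base.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**base)


def read_wav(path: str | Path) -> AudioSignal:
    """Read a PCM or float WAV file as a mono AudioSignal in [-1, 1].

    Multi-channel input is averaged down to mono. Integer PCM is scaled
    by the full-scale value of its dtype.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"audio file not found: {path}")
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # pragma: no cover - scipy error text varies
        raise ValueError(f"unreadable WAV file: {path}") from exc
    if data.size == 0:
        raise ValueError(f"empty WAV file: {path}")
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        if info.min == 0:  # unsigned PCM is offset-binary
            samples = 2.0 * data.astype(np.float64) / info.max - 1.0
        else:
            samples = data.astype(np.float64) / info.max
    else:
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return AudioSignal(samples=samples, sample_rate=int(rate))


def write_wav(path: str | Path, signal: AudioSignal, subtype: str = "pcm16") -> None:
    """Write a mono signal as PCM16 (default) or float32 WAV."""
    x = np.clip(signal.samples, -1.0, 1.0)
    if subtype == "pcm16":
        wavfile.write(path, signal.sample_rate, (x * 32767.0).astype(np.int16))
    elif subtype == "float32":
        wavfile.write(path, signal.sample_rate, x.astype(np.float32))
    else:
        raise ValueError(f"unsupported WAV subtype: {subtype}")


def bandpass(signal: AudioSignal, low: float, high: float, order: int = 4) -> AudioSignal:
    """Zero-phase Butterworth band-pass filter.

    Forward-backward filtering preserves the timing of impulsive events,
    which downstream endpoint detection depends on.
    """
    nyq = signal.sample_rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"invalid band ({low}, {high}) for sample rate {signal.sample_rate}"
        )
    sos = butter(order, [low / nyq, high / nyq], btype="bandpass", output="sos")
    filtered = sosfiltfilt(sos, signal.samples)
    return AudioSignal(samples=filtered, sample_rate=signal.sample_rate)


def frame_signal(signal: AudioSignal, frame_length: int, frame_shift: int) -> FrameSeq:
    """Cut a signal into frames of ``frame_length`` samples every ``frame_shift``.

    The trailing partial frame is discarded, so the frame count is
    ``floor((N - L) / inc) + 1``.
    """
    if frame_length < 1 or frame_shift < 1:
        raise ValueError("frame_length and frame_shift must be >= 1")
    n = len(signal)
    if n < frame_length:
        raise ValueError(
            f"signal of {n} samples is shorter than one frame ({frame_length})"
        )
    fn = (n - frame_length) // frame_shift + 1
    idx = np.arange(frame_length)[None, :] + frame_shift * np.arange(fn)[:, None]
    return FrameSeq(
        frames=signal.samples[idx], frame_length=frame_length, frame_shift=frame_shift
    )
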