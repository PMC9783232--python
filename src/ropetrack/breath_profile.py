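"""Breathing-sound mel spectrograms.

Band-pass (100-3500 Hz) -> magnitude STFT -> triangular mel filter bank
-> log(1 + x) compression -> per-clip min-max normalization to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import stft as _stft

from .audio_io import AudioSignal, PipelineConfig, bandpass

__all__ = ["MelSpectrogram", "hz_to_mel", "mel_to_hz", "mel_filterbank", "mel_spectrogram", "to_image"]


def hz_to_mel(f):
    """m = 2595 * log10(1 + f / 700)."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    out = 2595.0 * np.log10(1.0 + f / 700.0)
    return float(out) if out.ndim == 0 else out


def mel_to_hz(m):
    m = np.asarray(m, dtype=np.float64)
    out = 700.0 * (10.0 ** (m / 2595.0) - 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class MelSpectrogram:
    """values: normalized [0,1] mel-bin x time matrix; log_mel: pre-normalization."""

    values: np.ndarray
    log_mel: np.ndarray
    n_fft: int
    hop: int
    n_mels: int
    f_lo: float
    f_hi: float
    sample_rate: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(v)):
            raise ValueError("spectrogram values must be finite")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("normalized values must lie in [0, 1]")
        if self.n_mels < 1:
            raise ValueError("n_mels must be >= 1")


def mel_filterbank(
    n_mels: int, n_fft: int, sample_rate: int, f_lo: float, f_hi: float
) -> np.ndarray:
    """Triangular filters with edges equally spaced on the mel scale.

    Returns an (n_mels, n_fft // 2 + 1) non-negative weight matrix; every
    STFT bin strictly inside (f_lo, f_hi) receives positive total weight.
    """
    edges_mel = np.linspace(hz_to_mel(f_lo), hz_to_mel(f_hi), n_mels + 2)
    edges_hz = mel_to_hz(edges_mel)
    fft_freqs = np.arange(n_fft // 2 + 1) * sample_rate / n_fft
    fb = np.zeros((n_mels, fft_freqs.size))
    for m in range(n_mels):
        lo, ctr, hi = edges_hz[m], edges_hz[m + 1], edges_hz[m + 2]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-12)
        fb[m] = np.maximum(0.0, np.minimum(up, down))
    return fb


def mel_spectrogram(
    clip: AudioSignal, config: PipelineConfig | None = None
) -> MelSpectrogram:
    """Compute the breathing-band mel spectrogram of a clip."""
    cfg = config or PipelineConfig(sample_rate=clip.sample_rate)
    if len(clip) < cfg.n_fft:
        raise ValueError(
            f"clip of {len(clip)} samples shorter than one STFT window ({cfg.n_fft})"
        )
    f_lo, f_hi = cfg.breath_band
    f_hi = min(f_hi, 0.45 * clip.sample_rate)
    filtered = bandpass(clip, f_lo, f_hi)
    _, _, spec = _stft(
        filtered.samples,
        fs=clip.sample_rate,
        window="hann",
        nperseg=cfg.n_fft,
        noverlap=cfg.n_fft - cfg.hop,
        boundary="zeros",
        padded=True,
    )
    mag = np.abs(spec)
    fb = mel_filterbank(cfg.n_mels, cfg.n_fft, clip.sample_rate, f_lo, f_hi)
    log_mel = np.log1p(fb @ mag)
    span = np.ptp(log_mel)
    if span > 0:
        values = (log_mel - log_mel.min()) / span
    else:  # flat input (e.g. silence): zero guard instead of 0/0
        values = np.zeros_like(log_mel)
    return MelSpectrogram(
        values=values,
        log_mel=log_mel,
        n_fft=cfg.n_fft,
        hop=cfg.hop,
        n_mels=cfg.n_mels,
        f_lo=f_lo,
        f_hi=f_hi,
        sample_rate=clip.sample_rate,
    )


def save_spectrogram(path, spec: MelSpectrogram) -> None:
    """Persist a spectrogram (values + parameters) as an .npz array file."""
    np.savez(
        path,
        values=spec.values,
        log_mel=spec.log_mel,
        params=np.array([spec.n_fft, spec.hop, spec.n_mels,
                         spec.f_lo, spec.f_hi, spec.sample_rate]),
    )


def load_spectrogram(path) -> MelSpectrogram:
    with np.load(path) as data:
        n_fft, hop, n_mels, f_lo, f_hi, sr = data["params"]
        return MelSpectrogram(
            values=data["values"], log_mel=data["log_mel"],
            n_fft=int(n_fft), hop=int(hop), n_mels=int(n_mels),
            f_lo=float(f_lo), f_hi=float(f_hi), sample_rate=int(sr),
        )


def to_image(spec: MelSpectrogram, size: int = 64) -> np.ndarray:
    """Center-crop/pad the time axis (and crop mel bins) to a size x size image."""
    v = spec.values
    n_mels, n_t = v.shape
    if n_mels < size:
        v = np.pad(v, ((0, size - n_mels), (0, 0)))
    v = v[:size]
    if n_t < size:
        pad = size - n_t
        v = np.pad(v, ((0, 0), (pad // 2, pad - pad // 2)))
    elif n_t > size:
        start = (n_t - size) // 2
        v = v[:, start : start + size]
    return v.astype(np.float64)
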