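"""End-to-end sessions: count jumps in a recording, estimate intensity."""

from __future__ import annotations

import logging
import time

import numpy as np

from .audio_io import AudioSignal, PipelineConfig, frame_signal
from .breath_profile import mel_spectrogram, to_image
from .jump_counter import (
    JumpEvents,
    count_and_speed,
    default_thresholds,
    detect_endpoints,
    zero_crossing_rate,
)
from .jump_detector import separate_jump_sound, short_time_energy

logger = logging.getLogger("ropetrack")

__all__ = ["count_session", "breath_image"]


def count_session(
    signal: AudioSignal, config: PipelineConfig | None = None
) -> tuple[JumpEvents, dict]:
    """Full counting chain on one recording.

    Detect/separate the jump sound, run dual-threshold endpoint
    detection on the separated signal, then count and compute speed with
    the two-period stop rule. Returns the events plus the detection
    details dict (threshold, period models, ...).
    """
    cfg = config or PipelineConfig(sample_rate=signal.sample_rate)
    t0 = time.perf_counter()
    separated, details = separate_jump_sound(signal, cfg)
    logger.debug("separation took %.3fs", time.perf_counter() - t0)

    frames = frame_signal(separated, cfg.frame_length, cfg.frame_shift)
    energy = short_time_energy(frames)
    zcr = zero_crossing_rate(frames)

    noise_frames = ~details["masked"].frame_mask
    filt_frames = frame_signal(details["filtered"], cfg.frame_length, cfg.frame_shift)
    noise_zcr = zero_crossing_rate(filt_frames)[noise_frames]
    thresholds = default_thresholds(details["threshold"].h, noise_zcr)

    events = detect_endpoints(energy.values, zcr, thresholds)

    periods = [m.period for m in details["period_models"] if m is not None]
    period = int(np.median(periods)) if periods else cfg.frame_length * cfg.t_min_frames
    result = count_and_speed(
        events,
        session_duration=signal.duration,
        period_samples=period,
        frame_shift=cfg.frame_shift,
        sample_rate=signal.sample_rate,
    )
    details["endpoint_thresholds"] = thresholds
    details["session_period"] = period
    return result, details


def breath_image(
    clip: AudioSignal, config: PipelineConfig | None = None
) -> np.ndarray:
    """Mel-spectrogram image (size x size) of a breathing clip."""
    cfg = config or PipelineConfig(sample_rate=clip.sample_rate)
    return to_image(mel_spectrogram(clip, cfg), cfg.image_size)
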