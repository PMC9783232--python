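"""Rope-jump sound detection and separation.

Stages: per-frame short-time energy, histogram-based dynamic threshold,
frame masking, three-segment split, squared-difference period search,
and a duty-cycle square-wave fit whose mask isolates the jump sound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .audio_io import AudioSignal, FrameSeq, PipelineConfig, bandpass, frame_signal

logger = logging.getLogger("ropetrack")

__all__ = [
    "EnergySeries",
    "ThresholdResult",
    "MaskedSignal",
    "PeriodModel",
    "short_time_energy",
    "dynamic_threshold",
    "mask_below_threshold",
    "split_three_segments",
    "estimate_period",
    "fit_simulated_wave",
    "apply_jump_mask",
    "separate_jump_sound",
]

SQUARE_HIGH = 0.3  # level assigned to active samples of the square-wave mask


@dataclass(frozen=True)
class EnergySeries:
    """Per-frame short-time energy with the frame geometry that produced it."""

    values: np.ndarray
    frame_length: int
    frame_shift: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if np.any(values < 0):
            raise ValueError("energies must be non-negative")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class ThresholdResult:
    h: float
    h1: float
    h2: float
    omega: float
    bin_centers: np.ndarray
    smoothed_counts: np.ndarray


@dataclass(frozen=True)
class MaskedSignal:
    """Signal with below-threshold frames zeroed, plus the per-frame keep mask."""

    samples: np.ndarray
    frame_length: int
    frame_shift: int
    frame_mask: np.ndarray  # bool per frame, True = kept

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class PeriodModel:
    start_frame: int  # t: first active frame of the segment (local index)
    period: int  # T in samples
    duty_frames: int  # Tc
    correlation: float  # C of the best square-wave fit
    f_curve: np.ndarray
    j_min: int  # lag of f_curve[0]


def short_time_energy(frames: FrameSeq) -> EnergySeries:
    """E(i) = mean of squared amplitudes within frame i."""
    if frames.n_frames == 0:
        raise ValueError("empty frame sequence")
    return EnergySeries(
        values=np.mean(frames.frames**2, axis=1),
        frame_length=frames.frame_length,
        frame_shift=frames.frame_shift,
    )


def dynamic_threshold(
    energy: EnergySeries,
    omega: float = 6.0,
    n_bins: int = 64,
    smooth_width: int = 3,
) -> ThresholdResult:
    """Histogram-mode threshold h = (omega*H1 + H2) / (omega + 1).

    The energy histogram (``n_bins`` bins over [0, max E]) is smoothed
    with a centered moving average; H1 and H2 are the bin centers of the
    largest and second-largest local maxima (plateau starts and boundary
    bins included). If fewer than two local maxima exist, H2 falls back
    to max(E) so h always lies between the noise mode and the peak
    energies.
    """
    e = energy.values
    if e.size < 2:
        raise ValueError("need at least two frames to estimate a threshold")
    if np.ptp(e) == 0:
        raise ValueError("degenerate input: all frame energies identical")
    counts, edges = np.histogram(e, bins=n_bins, range=(0.0, float(e.max())))
    centers = 0.5 * (edges[:-1] + edges[1:])
    kernel = np.ones(smooth_width) / smooth_width
    smoothed = np.convolve(counts.astype(np.float64), kernel, mode="same")

    # local maximum = strict rise from the left, non-strict on the right
    # (plateau start), with virtual -inf outside the histogram: the noise
    # mode often occupies bin 0 and must still count as a mode
    ext = np.concatenate(([-np.inf], smoothed, [-np.inf]))
    is_max = (ext[1:-1] > ext[:-2]) & (ext[1:-1] >= ext[2:])
    peak_bins = np.nonzero(is_max)[0]
    # stable order: by descending smoothed count, ties -> lower bin
    order = peak_bins[np.lexsort((peak_bins, -smoothed[peak_bins]))]
    if order.size >= 2:
        h1, h2 = float(centers[order[0]]), float(centers[order[1]])
    elif order.size == 1:
        h1, h2 = float(centers[order[0]]), float(e.max())
    else:
        h1, h2 = float(centers[int(np.argmax(smoothed))]), float(e.max())
    h = (omega * h1 + h2) / (omega + 1.0)
    return ThresholdResult(
        h=h, h1=h1, h2=h2, omega=omega, bin_centers=centers, smoothed_counts=smoothed
    )


def mask_below_threshold(
    signal: AudioSignal, frames: FrameSeq, energy: EnergySeries, h: float
) -> MaskedSignal:
    """Zero every sample belonging to a frame with E(i) < h."""
    expected_fn = (len(signal) - frames.frame_length) // frames.frame_shift + 1
    if frames.n_frames != expected_fn or len(energy) != frames.n_frames:
        raise ValueError("frame/energy geometry does not match the signal")
    keep = energy.values >= h
    out = signal.samples.copy()
    for i in np.nonzero(~keep)[0]:
        start = i * frames.frame_shift
        out[start : start + frames.frame_length] = 0.0
    return MaskedSignal(
        samples=out,
        frame_length=frames.frame_length,
        frame_shift=frames.frame_shift,
        frame_mask=keep,
    )


def split_three_segments(
    masked: MaskedSignal,
) -> tuple[int, int, list[tuple[int, int]]]:
    """Split [0, N) into thirds, sliding each cut forward to a zero sample.

    Nominal cuts at N/3 and 2N/3 are advanced to the next sample where
    the masked signal is zero so no retained burst is bisected; if no
    zero exists at or after a nominal cut, the nominal cut is used.
    Returns ``(a1, a2, [(0, a1), (a1, a2), (a2, N)])``.
    """
    n = len(masked)
    if n < 3 * masked.frame_length:
        raise ValueError("masked signal shorter than three frames")

    def advance(cut: int, lo: int) -> int:
        cut = max(cut, lo)
        zeros = np.nonzero(masked.samples[cut:] == 0.0)[0]
        if zeros.size == 0:
            logger.warning("no zero sample at/after nominal cut %d; using nominal", cut)
            return cut
        return cut + int(zeros[0])

    a1 = advance(n // 3, 1)
    a2 = advance(2 * n // 3, a1 + 1)
    a1 = min(a1, n - 2)
    a2 = min(max(a2, a1 + 1), n - 1)
    return a1, a2, [(0, a1), (a1, a2), (a2, n)]


def _f_curve_direct(x: np.ndarray, m: int, j_lo: int, j_hi: int) -> np.ndarray:
    head = x[:m]
    return np.array(
        [float(np.sum((head - x[j : j + m]) ** 2)) for j in range(j_lo, j_hi + 1)]
    )


def _f_curve_fft(x: np.ndarray, m: int, j_lo: int, j_hi: int) -> np.ndarray:
    head = x[:m]
    s1 = float(np.sum(head**2))
    csq = np.concatenate(([0.0], np.cumsum(x**2)))
    lags = np.arange(j_lo, j_hi + 1)
    s2 = csq[lags + m] - csq[lags]
    # cross term: sum_i x[i] * x[i+j] for each lag j
    corr = fftconvolve(x, head[::-1], mode="valid")  # corr[j] = dot(head, x[j:j+m])
    return s1 + s2 - 2.0 * corr[lags]


def estimate_period(
    segment: np.ndarray,
    t_min_frames: int,
    t_max_frames: int,
    frame_length: int,
    method: str = "auto",
) -> tuple[int, np.ndarray]:
    """Lag minimizing f(j) = sum_i (x(i) - x(i+j))^2 over j in [L*Tmin, L*Tmax].

    The sum runs over i = 0 .. N - L*Tmax - 1 for every lag so that all
    f(j) values aggregate the same number of terms. Returns the period
    ``T`` in samples (smallest lag on ties) and the f-curve, whose first
    entry corresponds to lag ``L * t_min_frames``.

    ``method``: 'direct' (naive vectorized), 'fft' (cumulative-sum +
    FFT cross-correlation), or 'auto' (direct for small workloads).
    """
    x = np.asarray(segment, dtype=np.float64)
    n = x.size
    j_lo, j_hi = frame_length * t_min_frames, frame_length * t_max_frames
    m = n - j_hi
    if m < 1:
        raise ValueError(
            f"segment of {n} samples too short for max lag {j_hi} (need > {j_hi})"
        )
    if method == "auto":
        method = "direct" if m * (j_hi - j_lo + 1) <= 2_000_000 else "fft"
    if method == "direct":
        f = _f_curve_direct(x, m, j_lo, j_hi)
    elif method == "fft":
        f = _f_curve_fft(x, m, j_lo, j_hi)
    else:
        raise ValueError(f"unknown method {method!r}")
    t = j_lo + int(np.argmin(f))  # argmin takes the smallest index on ties
    return t, f


def refine_period_octave(
    period: int,
    f_curve: np.ndarray,
    j_min: int,
    search_halfwidth: int = 400,
    rel_tol: float = 1.5,
) -> int:
    """Correct the octave ambiguity of the squared-difference search.

    When the true period P and its multiples all fall inside the search
    range, f is near-minimal at each multiple and argmin may land on
    2P or 3P. If an integer divisor of the argmin also reaches within
    ``rel_tol`` of the minimum (checked in a small window around the
    divisor), the smallest such divisor is taken as the period.
    """
    f_best = f_curve[period - j_min]
    j_max = j_min + f_curve.size - 1
    for k in (4, 3, 2):
        cand = period // k
        if cand < j_min:
            continue
        lo = max(j_min, cand - search_halfwidth)
        hi = min(j_max, cand + search_halfwidth)
        window = f_curve[lo - j_min : hi - j_min + 1]
        if window.size and window.min() <= rel_tol * f_best:
            return lo + int(np.argmin(window))
    return period


def period_candidates(
    period: int, f_curve: np.ndarray, j_min: int, search_halfwidth: int = 400
) -> list[int]:
    """The f-argmin plus the local f-minima near its integer divisors.

    When P and its multiples all lie inside the search range, argmin f
    may land on 2P or 3P; the frame-quantized mask support can even make
    the multiple score better in f. The divisors are kept as candidates
    and the square-wave correlation arbitrates between them.
    """
    j_max = j_min + f_curve.size - 1
    cands = [period]
    for k in (2, 3, 4):
        cand = period // k
        if cand < j_min:
            continue
        lo = max(j_min, cand - search_halfwidth)
        hi = min(j_max, cand + search_halfwidth)
        window = f_curve[lo - j_min : hi - j_min + 1]
        if window.size:
            cands.append(lo + int(np.argmin(window)))
    return sorted(set(cands))


def square_wave_from_mask(masked_samples: np.ndarray) -> np.ndarray:
    """S_n = 0.3 where the masked signal is nonzero, else 0."""
    return np.where(np.asarray(masked_samples) != 0.0, SQUARE_HIGH, 0.0)


def _template(n: int, start_frame: int, period: int, duty_frames: int, frame_length: int) -> np.ndarray:
    """Periodic square wave: duty_frames*L active samples per period of T samples."""
    s = np.zeros(n)
    start = start_frame * frame_length
    width = duty_frames * frame_length
    pos = start
    while pos < n:
        s[pos : min(pos + width, n)] = SQUARE_HIGH
        pos += period
    return s


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    da, db = a - a.mean(), b - b.mean()
    denom = np.sqrt(np.sum(da**2) * np.sum(db**2))
    if denom == 0:
        raise ValueError("undefined correlation: constant sequence")
    return float(np.sum(da * db) / denom)


def fit_simulated_wave(
    masked_segment: np.ndarray,
    period: int,
    frame_length: int,
    start_frame: int | None = None,
) -> tuple[np.ndarray, int, float]:
    """Fit the simulated square wave to a masked segment.

    Builds the observed square wave S (active where the masked signal is
    nonzero) and, for each duty in 1..floor(T/L) frames, a periodic
    template starting at the first active frame; returns the template
    maximizing Pearson correlation with S (smaller duty on ties), the
    chosen duty, and the correlation.
    """
    x = np.asarray(masked_segment, dtype=np.float64)
    s_obs = square_wave_from_mask(x)
    if np.ptp(s_obs) == 0:
        raise ValueError("undefined correlation: observed square wave is constant")
    if start_frame is None:
        first_active = int(np.nonzero(s_obs)[0][0])
        start_frame = first_active // frame_length
    max_duty = max(period // frame_length, 1)
    best: tuple[float, int, np.ndarray] | None = None
    for duty in range(1, max_duty + 1):
        tmpl = _template(x.size, start_frame, period, duty, frame_length)
        if np.ptp(tmpl) == 0:
            continue
        c = _pearson(s_obs, tmpl)
        if best is None or c > best[0]:
            best = (c, duty, tmpl)
    if best is None:
        raise ValueError("no valid duty-cycle template for this segment")
    c, duty, tmpl = best
    return tmpl, duty, c


def apply_jump_mask(
    masked: MaskedSignal, square_wave: np.ndarray, sample_rate: int
) -> AudioSignal:
    """X''(n) = X'(n) where the stitched square wave is active, else 0."""
    wave = np.asarray(square_wave)
    if wave.size != len(masked):
        raise ValueError(
            f"square wave length {wave.size} != masked signal length {len(masked)}"
        )
    out = np.where(wave == SQUARE_HIGH, masked.samples, 0.0)
    return AudioSignal(samples=out, sample_rate=sample_rate)


def details_to_json(details: dict) -> dict:
    """JSON-serializable view of the detection artifacts for inspection."""
    thr: ThresholdResult = details["threshold"]
    out = {
        "threshold": {"h": thr.h, "h1": thr.h1, "h2": thr.h2, "omega": thr.omega},
        "energy": details["energy"].values.tolist(),
        "segment_cuts": [int(c) for c in details["segment_cuts"]],
        "segments": [[int(a), int(b)] for a, b in details["segments"]],
        "period_models": [
            None
            if m is None
            else {
                "start_frame": m.start_frame,
                "period": m.period,
                "duty_frames": m.duty_frames,
                "correlation": m.correlation,
                "j_min": m.j_min,
                "f_curve": m.f_curve.tolist(),
            }
            for m in details["period_models"]
        ],
    }
    return out


def separate_jump_sound(
    signal: AudioSignal,
    config: PipelineConfig | None = None,
    bandpass_input: bool = True,
) -> tuple[AudioSignal, dict]:
    """Full detection chain: band-pass -> STE threshold mask -> per-segment
    period + square-wave fit -> separated jump sound X''.

    Returns the separated signal and a details dict with the threshold,
    masked signal, segment boundaries and per-segment PeriodModels.
    Segments too short for the period search keep their masked samples
    unchanged (their square wave is the observed one). Set
    ``bandpass_input=False`` when the input is already band-limited
    (e.g. re-running detection on a separated signal).
    """
    cfg = config or PipelineConfig(sample_rate=signal.sample_rate)
    if bandpass_input:
        low, high = cfg.effective_jump_band()
        filtered = bandpass(signal, low, high)
    else:
        filtered = signal
    frames = frame_signal(filtered, cfg.frame_length, cfg.frame_shift)
    energy = short_time_energy(frames)
    thr = dynamic_threshold(energy, omega=cfg.omega)
    masked = mask_below_threshold(filtered, frames, energy, thr.h)
    a1, a2, intervals = split_three_segments(masked)

    stitched = np.zeros(len(masked))
    models: list[PeriodModel | None] = []
    min_len = cfg.frame_length * cfg.t_max_frames
    for start, end in intervals:
        seg = masked.samples[start:end]
        if not np.any(seg != 0.0):
            models.append(None)
            continue
        if seg.size <= min_len:
            stitched[start:end] = square_wave_from_mask(seg)
            models.append(None)
            continue
        period, f_curve = estimate_period(
            seg, cfg.t_min_frames, cfg.t_max_frames, cfg.frame_length
        )
        j_min = cfg.frame_length * cfg.t_min_frames
        tmpl = duty = corr = None
        for cand in period_candidates(period, f_curve, j_min):
            c_tmpl, c_duty, c_corr = fit_simulated_wave(seg, cand, cfg.frame_length)
            if corr is None or c_corr > corr:
                tmpl, duty, corr, period = c_tmpl, c_duty, c_corr, cand
        first_active = int(np.nonzero(seg)[0][0]) // cfg.frame_length
        stitched[start:end] = tmpl
        models.append(
            PeriodModel(
                start_frame=first_active,
                period=period,
                duty_frames=duty,
                correlation=corr,
                f_curve=f_curve,
                j_min=cfg.frame_length * cfg.t_min_frames,
            )
        )
    separated = apply_jump_mask(masked, stitched, signal.sample_rate)
    details = {
        "threshold": thr,
        "energy": energy,
        "masked": masked,
        "segments": intervals,
        "segment_cuts": (a1, a2),
        "period_models": models,
        "square_wave": stitched,
        "filtered": filtered,
    }
    return separated, details
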