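import numpy as np
import pytest

from ropetrack.audio_io import AudioSignal, FrameSeq, PipelineConfig, frame_signal
from ropetrack.jump_detector import (
    EnergySeries,
    MaskedSignal,
    apply_jump_mask,
    dynamic_threshold,
    estimate_period,
    fit_simulated_wave,
    mask_below_threshold,
    period_candidates,
    separate_jump_sound,
    short_time_energy,
    split_three_segments,
    square_wave_from_mask,
)
from ropetrack.synthetic_scenes import JumpSceneSpec, synth_jump_scene


def frames_of(values, L=4):
    return FrameSeq(frames=np.asarray(values, dtype=float), frame_length=L, frame_shift=L)


class TestShortTimeEnergy:
    def test_zero_frame(self):
        e = short_time_energy(frames_of([[0, 0, 0, 0]]))
        assert e.values[0] == 0.0

    def test_constant_half(self):
        e = short_time_energy(frames_of([[0.5] * 4]))
        assert e.values[0] == pytest.approx(0.25)

    def test_alternating_hand_sum(self):
        e = short_time_energy(frames_of([[1, -1, 1, -1]]))
        assert e.values[0] == pytest.approx(1.0)

    def test_nonnegative(self, rng):
        frames = frames_of(rng.standard_normal((10, 4)))
        assert np.all(short_time_energy(frames).values >= 0)


def _oracle_threshold(energies, omega, n_bins=64, smooth_width=3):
    """Independent mode-scan: histogram, moving average, explicit loop."""
    counts, edges = np.histogram(energies, bins=n_bins, range=(0.0, energies.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    smoothed = np.convolve(counts.astype(float), np.ones(smooth_width) / smooth_width, "same")
    peaks = []
    for b in range(n_bins):
        left = smoothed[b - 1] if b > 0 else -np.inf
        right = smoothed[b + 1] if b < n_bins - 1 else -np.inf
        if smoothed[b] > left and smoothed[b] >= right:
            peaks.append(b)
    peaks.sort(key=lambda b: (-smoothed[b], b))
    if len(peaks) >= 2:
        h1, h2 = centers[peaks[0]], centers[peaks[1]]
    elif len(peaks) == 1:
        h1, h2 = centers[peaks[0]], energies.max()
    else:
        h1, h2 = centers[int(np.argmax(smoothed))], energies.max()
    return (omega * h1 + h2) / (omega + 1.0)


class TestDynamicThreshold:
    def _series(self, values):
        return EnergySeries(values=np.asarray(values, float), frame_length=4, frame_shift=4)

    def test_bimodal_construction(self, rng):
        e = np.concatenate([
            0.1 + 0.002 * rng.standard_normal(300),
            0.4 + 0.002 * rng.standard_normal(60),
        ])
        e = np.clip(e, 0, 0.41)
        thr = dynamic_threshold(self._series(e), omega=6.0)
        assert thr.h1 == pytest.approx(0.1, abs=0.02)
        assert thr.h2 == pytest.approx(0.4, abs=0.02)
        assert thr.h == pytest.approx((6 * thr.h1 + thr.h2) / 7.0)
        assert thr.h == pytest.approx((6 * 0.1 + 0.4) / 7.0, abs=0.01)

    def test_large_omega_limit(self, rng):
        e = np.concatenate([
            0.1 + 0.002 * rng.standard_normal(300),
            0.4 + 0.002 * rng.standard_normal(60),
        ])
        thr = dynamic_threshold(self._series(e), omega=1e9)
        assert thr.h == pytest.approx(thr.h1, rel=1e-6)

    def test_matches_bruteforce_oracle_on_random_series(self, rng):
        for _ in range(100):
            e = np.abs(rng.standard_normal(rng.integers(20, 200)))
            thr = dynamic_threshold(self._series(e), omega=6.0)
            assert thr.h == pytest.approx(_oracle_threshold(e, 6.0), rel=1e-12)

    def test_threshold_bracketed_by_modes(self, rng):
        for _ in range(50):
            e = np.abs(rng.standard_normal(100))
            thr = dynamic_threshold(self._series(e), omega=6.0)
            assert min(thr.h1, thr.h2) <= thr.h <= max(thr.h1, thr.h2)

    def test_noise_mode_in_first_bin_is_detected(self):
        # sparse high-energy frames stretch the histogram range so far
        # that the entire noise mode falls into bin 0; it must still be
        # recognized as H1 (regression: the threshold used to latch onto
        # a tiny burst bin and mask nearly everything)
        rng = np.random.default_rng(3)
        e = np.concatenate([
            1e-4 + 1e-6 * rng.standard_normal(300),
            rng.uniform(3e-3, 9e-3, 25),
        ])
        thr = dynamic_threshold(self._series(np.abs(e)), omega=6.0)
        assert thr.h1 < 3e-4
        assert thr.h < 2e-3

    def test_identical_energies_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            dynamic_threshold(self._series(np.full(10, 0.3)))

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            dynamic_threshold(self._series(np.array([0.1])))


class TestMasking:
    def _setup(self, rng, n=4000, L=800):
        sig = AudioSignal(samples=rng.standard_normal(n) * 0.1, sample_rate=16_000)
        frames = frame_signal(sig, L, L)
        energy = short_time_energy(frames)
        return sig, frames, energy

    def test_h_zero_keeps_everything(self, rng):
        sig, frames, energy = self._setup(rng)
        masked = mask_below_threshold(sig, frames, energy, 0.0)
        assert np.array_equal(masked.samples, sig.samples)

    def test_h_above_max_zeroes_frames(self, rng):
        sig, frames, energy = self._setup(rng)
        masked = mask_below_threshold(sig, frames, energy, energy.values.max() * 2)
        assert np.all(masked.samples[: frames.n_frames * 800] == 0)

    def test_zeroed_runs_align_to_frames(self, rng):
        sig, frames, energy = self._setup(rng)
        h = np.median(energy.values)
        masked = mask_below_threshold(sig, frames, energy, h)
        for i in range(frames.n_frames):
            block = masked.samples[i * 800 : (i + 1) * 800]
            assert np.all(block == 0) or np.array_equal(
                block, sig.samples[i * 800 : (i + 1) * 800]
            )

    def test_geometry_mismatch_rejected(self, rng):
        sig, frames, energy = self._setup(rng)
        short_sig = AudioSignal(samples=sig.samples[:2000], sample_rate=16_000)
        with pytest.raises(ValueError, match="geometry"):
            mask_below_threshold(short_sig, frames, energy, 0.1)

    def test_burst_frames_retained_noise_zeroed(self):
        sig, truth = synth_jump_scene(
            JumpSceneSpec(duration=12.0, n_jumps=2, base_period=5.0,
                          snr_db=30.0, seed=4)
        )
        separated, det = separate_jump_sound(sig)
        masked = det["masked"]
        burst_frames = set()
        for onset in truth.onset_times:
            f0 = int(onset * 16_000) // 800
            burst_frames.update(range(f0, f0 + 3))
        noise_idx = [i for i in range(masked.frame_mask.size) if i not in burst_frames]
        assert np.mean(~masked.frame_mask[noise_idx]) >= 0.9
        for onset in truth.onset_times:
            i = int(onset * 16_000)
            assert np.any(masked.samples[i : i + 3200] != 0)


class TestSplitThreeSegments:
    def _masked(self, samples, L=800):
        x = np.asarray(samples, float)
        fn = x.size // L
        mask = np.array([np.any(x[i * L : (i + 1) * L] != 0) for i in range(fn)])
        return MaskedSignal(samples=x, frame_length=L, frame_shift=L, frame_mask=mask)

    def test_all_zero_nominal_cuts(self):
        masked = self._masked(np.zeros(9000))
        a1, a2, intervals = split_three_segments(masked)
        assert a1 == 3000 and a2 == 6000

    def test_partition_property(self, rng):
        x = rng.standard_normal(10_000)
        masked = self._masked(x)
        _, _, intervals = split_three_segments(masked)
        assert intervals[0][0] == 0 and intervals[-1][1] == 10_000
        for (a, b), (c, d) in zip(intervals, intervals[1:]):
            assert b == c
        assert all(b > a for a, b in intervals)

    def test_burst_straddling_cut_not_bisected(self):
        x = np.zeros(9000)
        x[2800:3400] = 0.5  # burst across the nominal cut at 3000
        masked = self._masked(x, L=100)
        a1, _, _ = split_three_segments(masked)
        assert a1 == 3400
        assert masked.samples[a1] == 0.0


class TestEstimatePeriod:
    def test_exact_square_wave(self):
        L, p = 10, 37
        x = np.zeros(1000)
        for start in range(0, 1000, p):
            x[start : start + 12] = 0.3
        t, f = estimate_period(x, 2, 5, L)  # lags 20..50
        assert t == p
        assert f[p - 20] == pytest.approx(0.0, abs=1e-12)

    def test_matches_naive_double_loop(self, rng):
        for _ in range(20):
            n = 600
            x = rng.standard_normal(n)
            x[rng.random(n) < 0.5] = 0.0  # masked-like
            t, f = estimate_period(x, 2, 5, 10)
            m = n - 50
            f_naive = []
            for j in range(20, 51):
                acc = 0.0
                for i in range(m):
                    acc += (x[i] - x[i + j]) ** 2
                f_naive.append(acc)
            f_naive = np.array(f_naive)
            assert t == 20 + int(np.argmin(f_naive))
            assert np.allclose(f, f_naive, rtol=1e-9)

    def test_fft_agrees_with_direct(self, rng):
        x = rng.standard_normal(4000)
        t_d, f_d = estimate_period(x, 2, 5, 100, method="direct")
        t_f, f_f = estimate_period(x, 2, 5, 100, method="fft")
        assert t_d == t_f
        assert np.allclose(f_d, f_f, rtol=1e-8)

    def test_scene_period_recovery(self):
        spec = JumpSceneSpec(duration=22.0, n_jumps=40, base_period=0.5,
                             period_jitter=0.02, snr_db=20.0, seed=2)
        sig, _ = synth_jump_scene(spec)
        _, det = separate_jump_sound(sig)
        periods = [m.period for m in det["period_models"] if m is not None]
        assert periods
        assert abs(np.median(periods) / 16_000 - 0.5) <= 0.05

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            estimate_period(np.zeros(100), 2, 5, 30)

    def test_ties_take_smallest_lag(self):
        x = np.zeros(500)  # f(j) = 0 for every lag
        t, f = estimate_period(x, 2, 5, 10)
        assert t == 20


class TestFitSimulatedWave:
    def test_self_match_perfect_square_wave(self):
        L, period, duty = 10, 60, 2
        x = np.zeros(600)
        for start in range(0, 600, period):
            x[start : start + duty * L] = 0.5
        tmpl, tc, c = fit_simulated_wave(x, period, L)
        assert tc == duty
        assert c == pytest.approx(1.0, abs=1e-12)

    def test_pearson_self_correlation(self, rng):
        from ropetrack.jump_detector import _pearson

        x = rng.standard_normal(100)
        assert _pearson(x, x) == pytest.approx(1.0)

    def test_constant_wave_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_simulated_wave(np.zeros(600), 60, 10)

    def test_square_wave_levels(self, rng):
        x = rng.standard_normal(100)
        x[:50] = 0.0
        s = square_wave_from_mask(x)
        assert set(np.unique(s)) <= {0.0, 0.3}


class TestApplyJumpMask:
    def _masked(self, x, L=10):
        fn = x.size // L
        mask = np.array([np.any(x[i * L : (i + 1) * L] != 0) for i in range(fn)])
        return MaskedSignal(samples=x, frame_length=L, frame_shift=L, frame_mask=mask)

    def test_all_active_returns_masked(self, rng):
        x = rng.standard_normal(100)
        out = apply_jump_mask(self._masked(x), np.full(100, 0.3), 16_000)
        assert np.array_equal(out.samples, x)

    def test_all_zero_wave_silences(self, rng):
        x = rng.standard_normal(100)
        out = apply_jump_mask(self._masked(x), np.zeros(100), 16_000)
        assert np.all(out.samples == 0)

    def test_length_mismatch_rejected(self, rng):
        x = rng.standard_normal(100)
        with pytest.raises(ValueError, match="length"):
            apply_jump_mask(self._masked(x), np.zeros(90), 16_000)

    def test_projection_idempotent(self, rng):
        x = rng.standard_normal(100)
        wave = np.where(rng.random(100) < 0.5, 0.3, 0.0)
        once = apply_jump_mask(self._masked(x), wave, 16_000)
        twice = apply_jump_mask(self._masked(once.samples), wave, 16_000)
        assert np.array_equal(once.samples, twice.samples)


class TestSeparateJumpSound:
    def test_bursts_survive_in_separated_signal(self, clean_scene):
        # every burst keeps >= 50% of its threshold-retained samples
        # after the square-wave mask is applied
        sig, truth = clean_scene
        separated, det = separate_jump_sound(sig)
        masked = det["masked"]
        survived = 0
        for onset in truth.onset_times:
            i = int(onset * 16_000)
            retained = np.sum(masked.samples[i : i + 3200] != 0)
            kept = np.sum(separated.samples[i : i + 3200] != 0)
            if retained and kept >= 0.5 * retained:
                survived += 1
        assert survived >= 0.9 * truth.true_count

    def test_rerun_support_never_grows(self, clean_scene):
        # masking is a projection: re-detection only removes samples
        sig, _ = clean_scene
        s1, _ = separate_jump_sound(sig)
        s2, _ = separate_jump_sound(s1, bandpass_input=False)
        assert np.all((s2.samples != 0) <= (s1.samples != 0))
        assert np.sum(s2.samples != 0) > 0

    def test_period_candidates_include_divisors(self):
        f = np.full(1500, 100.0)
        f[800] = 1.0  # argmin at lag 1300
        cands = period_candidates(1300, f, 500)
        assert 1300 in cands
        assert any(abs(c - 650) <= 400 for c in cands)

    def test_details_serialize_to_json(self, clean_scene):
        import json

        from ropetrack.jump_detector import details_to_json

        sig, _ = clean_scene
        _, det = separate_jump_sound(sig)
        payload = json.dumps(details_to_json(det))
        back = json.loads(payload)
        assert back["threshold"]["h"] == det["threshold"].h
        assert len(back["period_models"]) == 3

    def test_period_recovery_rate_over_seeds(self):
        hits = 0
        n = 12
        for seed in range(n):
            rng = np.random.default_rng(400 + seed)
            bp = float(rng.uniform(0.4, 0.8))
            jit = float(rng.uniform(0.0, 0.05))
            snr = float(rng.uniform(10.0, 30.0))
            sig, truth = synth_jump_scene(JumpSceneSpec(
                duration=30 * bp + 2, n_jumps=30, base_period=bp,
                period_jitter=jit, snr_db=snr, seed=seed))
            _, det = separate_jump_sound(sig)
            periods = [m.period for m in det["period_models"] if m is not None]
            if periods and abs(np.median(periods) / 16_000 - bp) <= 0.1 * bp:
                hits += 1
        assert hits >= 0.9 * n
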