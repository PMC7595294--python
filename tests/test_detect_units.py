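"""Unit tests for spectrogram, envelopes, segmentation, classification,
fusion and summary operations."""

import numpy as np
import pytest

from hivesignals import (
    BandConfig,
    DetectionParams,
    ESFRecording,
    EventAnnotation,
    EventSpec,
    band_envelope,
    compute_spectrogram,
    count_waggle_runs,
    evaluate_detector,
    fuse_channels,
    generate_recording,
    segment_events,
    summarize,
)
from hivesignals.detect import (
    BandEnvelope,
    _build_context,
    classify_event,
    mad_threshold,
)

FS = 4410.0


def _tone_recording(freq, duration=5.0, fs=FS, n_channels=1):
    t = np.arange(int(duration * fs)) / fs
    x = np.sin(2 * np.pi * freq * t)
    return ESFRecording(samples=np.tile(x, (n_channels, 1)), sample_rate=fs)


class TestSpectrogram:
    def test_pure_tone_peaks_at_its_frequency(self):
        spec = compute_spectrogram(_tone_recording(100.0), 0, window_length=0.2)
        profile = spec.magnitudes.mean(axis=1)
        peak = spec.freq_axis[np.argmax(profile)]
        df = spec.freq_axis[1] - spec.freq_axis[0]
        assert abs(peak - 100.0) <= df

    def test_zero_input_gives_zero_magnitudes(self):
        rec = ESFRecording(samples=np.zeros((1, 5000)), sample_rate=FS)
        spec = compute_spectrogram(rec, 0, window_length=0.05)
        assert not spec.magnitudes.any()

    def test_chirp_peak_frequency_is_monotone(self):
        from scipy.signal import chirp
        t = np.arange(int(10 * FS)) / FS
        x = chirp(t, f0=50.0, f1=400.0, t1=10.0, method="linear")
        rec = ESFRecording(samples=x[np.newaxis], sample_rate=FS)
        spec = compute_spectrogram(rec, 0, window_length=0.25)
        # skip edge frames where the window only partly covers the chirp
        peaks = spec.freq_axis[np.argmax(spec.magnitudes[:, 3:-3], axis=0)]
        assert np.all(np.diff(peaks) >= 0)
        # and the instantaneous-frequency oracle: f(t) = 50 + 35 t
        mid = spec.time_axis[3:-3]
        np.testing.assert_allclose(peaks, 50.0 + 35.0 * mid, atol=10.0)

    def test_energy_conservation_within_tolerance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=int(5 * FS))
        rec = ESFRecording(samples=x[np.newaxis], sample_rate=FS)
        spec = compute_spectrogram(rec, 0, window_length=0.05)  # hop = window/2
        assert spec.signal_energy() == pytest.approx(np.sum(x ** 2), rel=0.05)

    def test_channel_out_of_range(self):
        with pytest.raises(IndexError):
            compute_spectrogram(_tone_recording(100.0), 3, window_length=0.05)


class TestBandEnvelope:
    def test_fanning_band_dominates_during_fanning(self, cfg):
        spec_ev = EventSpec("fanning", t_start=1.0, duration=12.0, fundamental_freq=100.0,
                            amplitude=5.0)
        rec, _ = generate_recording([spec_ev], 14.0, 1, noise_sigma=1.0, seed=2, band_config=cfg)
        spec = compute_spectrogram(rec, 0, window_length=0.2)
        env_f = band_envelope(spec, cfg.fanning_band)
        in_event = (env_f.time_axis > 1.5) & (env_f.time_axis < 12.5)
        for other in (cfg.waggle_high_band, cfg.stop_band):
            env_o = band_envelope(spec, other)
            assert np.all(env_f.energy[in_event] > env_o.energy[in_event])

    def test_zero_signal_zero_envelope(self):
        rec = ESFRecording(samples=np.zeros((1, 5000)), sample_rate=FS)
        spec = compute_spectrogram(rec, 0, window_length=0.05)
        assert not band_envelope(spec, (90, 120)).energy.any()

    def test_additivity_for_disjoint_supports(self, cfg):
        """envelope(A+B) = envelope(A) + envelope(B) for disjoint supports."""
        from hivesignals.synth import synth_fanning
        seg_a = synth_fanning(EventSpec("fanning", duration=11.0, fundamental_freq=100.0), cfg)
        seg_b = synth_fanning(EventSpec("fanning", duration=11.0, fundamental_freq=110.0), cfg)
        n = int(26.0 * FS)

        def env_of(placements):
            x = np.zeros(n)
            for seg, t0 in placements:
                i0 = int(t0 * FS)
                x[i0:i0 + seg.size] += seg
            rec = ESFRecording(samples=x[np.newaxis], sample_rate=FS)
            spec = compute_spectrogram(rec, 0, window_length=0.2)
            return band_envelope(spec, cfg.fanning_band).energy

        both = env_of([(seg_a, 0.5), (seg_b, 14.0)])
        total = env_of([(seg_a, 0.5)]) + env_of([(seg_b, 14.0)])
        np.testing.assert_allclose(both, total, rtol=1e-6, atol=1e-6 * total.max())

    def test_empty_band_rejected(self):
        spec = compute_spectrogram(_tone_recording(100.0), 0, window_length=0.05)
        with pytest.raises(ValueError):
            band_envelope(spec, (101.0, 105.0))  # narrower than one 20 Hz bin
        with pytest.raises(ValueError):
            band_envelope(spec, (3000.0, 4000.0))  # beyond Nyquist


class TestSegmentation:
    def _env(self, energy, hop=0.02):
        t = np.arange(len(energy)) * hop + hop / 2
        return BandEnvelope(band=(90, 120), energy=np.asarray(energy, float),
                            time_axis=t, hop=hop)

    def test_flat_envelope_yields_nothing(self, params):
        assert segment_events(self._env(np.full(500, 3.3)), params) == []

    def test_single_burst_recovered_within_one_hop(self, params):
        energy = np.full(1000, 1.0)
        energy[400:450] = 400.0  # boxcar burst, 1 s at hop 0.02
        ivs = segment_events(self._env(energy), params)
        assert len(ivs) == 1
        t0, t1 = ivs[0]
        # smoothing may widen the crossing by about one hop on each side
        assert abs(t0 - 400 * 0.02) <= 3 * 0.02
        assert abs(t1 - 450 * 0.02) <= 3 * 0.02

    def test_sub_gap_bursts_merge(self, params):
        energy = np.full(1000, 1.0)
        energy[100:140] = 300.0
        energy[142:180] = 300.0  # 0.04 s gap < min_gap_merge 0.1 s
        ivs = segment_events(self._env(energy), params)
        assert len(ivs) == 1

    def test_threshold_is_scale_free(self):
        rng = np.random.default_rng(1)
        e = rng.gamma(2.0, size=5000)
        t1 = mad_threshold(e, 5.0)
        t2 = mad_threshold(37.0 * e, 5.0)
        assert t2 == pytest.approx(37.0 * t1, rel=1e-6)


class TestClassification:
    def _context(self, cfg, params, events, duration, noise=1.0, seed=4):
        rec, _ = generate_recording(events, duration, 1, noise_sigma=noise,
                                    seed=seed, band_config=cfg)
        return _build_context(rec, 0, cfg, params)

    def test_fanning_event_labeled_fanning(self, cfg, params):
        ev = EventSpec("fanning", t_start=2.0, duration=12.0, fundamental_freq=100.0,
                       amplitude=10.0)
        ctx = self._context(cfg, params, [ev], 16.0)
        assert classify_event((2.0, 14.0), ctx, cfg, params) == "fanning"

    def test_stop_pulse_labeled_stop(self, cfg, params):
        ev = EventSpec("stop_signal", t_start=2.0, duration=0.3, fundamental_freq=300.0,
                       n_harmonics=2, amplitude=10.0)
        ctx = self._context(cfg, params, [ev], 5.0)
        assert classify_event((2.0, 2.3), ctx, cfg, params) == "stop_signal"

    def test_waggle_run_labeled_waggle(self, cfg, params):
        ev = EventSpec("waggle_run", t_start=2.0, duration=1.0, fundamental_freq=210.0,
                       pulse_rate=15.0, amplitude=10.0)
        ctx = self._context(cfg, params, [ev], 5.0)
        assert classify_event((2.0, 3.0), ctx, cfg, params) == "waggle_run"

    def test_truncated_fanning_rejected_not_reassigned(self, cfg, params):
        """A stable 100 Hz tone shorter than the 10 s gate is rejected."""
        t = np.arange(int(9.0 * FS)) / FS
        x = np.zeros_like(t)
        i0, i1 = int(2.0 * FS), int(7.0 * FS)
        x[i0:i1] = 10.0 * np.sin(2 * np.pi * 100.0 * t[: i1 - i0])
        rng = np.random.default_rng(0)
        rec = ESFRecording(samples=(x + rng.normal(size=x.size))[np.newaxis], sample_rate=FS)
        ctx = _build_context(rec, 0, cfg, params)
        assert classify_event((2.0, 7.0), ctx, cfg, params) is None


class TestCountsAndSummary:
    def test_well_separated_runs_counted_individually(self, params):
        ivs = [(2.0 * k, 2.0 * k + 1.0) for k in range(5)]  # 1 s return phases
        assert count_waggle_runs(ivs, params) == 5

    def test_empty_is_zero(self, params):
        assert count_waggle_runs([], params) == 0

    def test_sub_split_gap_intervals_merge_into_one_run(self, params):
        assert count_waggle_runs([(0.0, 1.0), (1.1, 2.0)], params) == 1

    def test_rate_arithmetic(self, params):
        events = [EventAnnotation("waggle_run", 0, 2.0 * k, 2.0 * k + 1.0) for k in range(30)]
        s = summarize(events, 1800.0, params)
        assert s.waggle_runs_per_hour == pytest.approx(60.0)

    def test_fanning_fraction_uses_interval_union(self, params):
        events = [
            EventAnnotation("fanning", 0, 0.0, 10.0),
            EventAnnotation("fanning", 1, 5.0, 20.0),
        ]
        s = summarize(events, 100.0, params)
        assert s.fanning_fraction == pytest.approx(0.20)

    def test_no_events(self, params):
        s = summarize([], 600.0, params)
        assert s.waggle_runs_per_hour == 0
        assert s.stop_signals_per_hour == 0
        assert s.fanning_fraction == 0

    def test_invalid_duration_or_event_raises(self, params):
        with pytest.raises(ValueError):
            summarize([], 0.0, params)
        with pytest.raises(ValueError):
            summarize([EventAnnotation("fanning", 0, 700.0, 710.0)], 600.0, params)

    def test_rates_double_over_half_duration(self, params):
        events = [EventAnnotation("stop_signal", 0, 10.0 * k, 10.0 * k + 0.3) for k in range(10)]
        s1 = summarize(events, 200.0, params)
        s2 = summarize(events, 100.0, params)
        assert s2.stop_signals_per_hour == pytest.approx(2 * s1.stop_signals_per_hour)


class TestFusion:
    def test_identical_events_on_two_channels_fuse(self, params):
        events = [
            EventAnnotation("stop_signal", 0, 1.0, 1.3, energy=5.0),
            EventAnnotation("stop_signal", 1, 1.0, 1.3, energy=9.0),
        ]
        fused = fuse_channels(events, params)
        assert len(fused) == 1
        assert fused[0].channel == 1  # attributed to the stronger sensor

    def test_disjoint_events_stay_separate(self, params):
        events = [
            EventAnnotation("stop_signal", 0, 1.0, 1.3),
            EventAnnotation("stop_signal", 1, 5.0, 5.3),
        ]
        assert len(fuse_channels(events, params)) == 2

    def test_different_classes_never_fuse(self, params):
        events = [
            EventAnnotation("waggle_run", 0, 1.0, 2.0),
            EventAnnotation("fanning", 1, 1.0, 2.0, t_end=12.0) if False else
            EventAnnotation("stop_signal", 1, 1.0, 1.3),
        ]
        assert len(fuse_channels(events, params)) == 2

    def test_transitive_chain_matches_brute_force_components(self, params):
        """Union-find fusion equals BFS connected components on random instances."""
        rng = np.random.default_rng(3)
        for _ in range(25):
            events = [
                EventAnnotation("waggle_run", int(rng.integers(0, 4)),
                                t0 := float(rng.uniform(0, 20)),
                                t0 + float(rng.uniform(0.5, 2.0)))
                for _ in range(8)
            ]
            fused = fuse_channels(events, params)

            def iou(a, b):
                inter = min(a.t_end, b.t_end) - max(a.t_start, b.t_start)
                return max(inter, 0.0) / (max(a.t_end, b.t_end) - min(a.t_start, b.t_start))

            # oracle: BFS over the IoU graph
            adj = {i: [j for j in range(len(events)) if j != i
                       and iou(events[i], events[j]) >= params.fusion_overlap_min]
                   for i in range(len(events))}
            seen, n_components = set(), 0
            for i in range(len(events)):
                if i in seen:
                    continue
                n_components += 1
                stack = [i]
                while stack:
                    k = stack.pop()
                    if k in seen:
                        continue
                    seen.add(k)
                    stack.extend(adj[k])
            assert len(fused) == n_components


class TestEvaluation:
    def _truth(self):
        return [EventAnnotation("stop_signal", 0, float(k), float(k) + 0.3) for k in range(9)]

    def test_identity_scores_perfectly(self):
        truth = self._truth()
        scores = evaluate_detector(truth, truth)
        assert scores["stop_signal"]["precision"] == 1.0
        assert scores["stop_signal"]["recall"] == 1.0

    def test_missing_detections_zero_recall(self):
        scores = evaluate_detector(self._truth(), [])
        assert scores["stop_signal"]["recall"] == 0.0

    def test_one_spurious_detection(self):
        truth = self._truth()
        detected = truth + [EventAnnotation("stop_signal", 0, 50.0, 50.3)]
        scores = evaluate_detector(truth, detected)
        assert scores["stop_signal"]["precision"] == pytest.approx(0.9)
        assert scores["stop_signal"]["recall"] == 1.0
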