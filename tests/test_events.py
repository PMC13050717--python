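"""High-pass filtering, pooled thresholding, and peak detection vs oracles."""

import numpy as np
import pytest
from scipy import signal as sps

from xenphys.events import (
    CalciumEventDetector,
    FilteredTrace,
    ThresholdModel,
    derive_global_threshold,
    detect_events,
    highpass_filter,
    summarize_events,
)
from xenphys.imaging import Trace
from xenphys.simulate import COHORT_PRESETS, EventTrainConfig, GroundTruth, synthesize_trace

FS = 2.0


def _sine(freq, amp=1.0, duration=3600.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return Trace(amp * np.sin(2 * np.pi * freq * t), fs)


class TestHighpass:
    def test_dc_rejection(self):
        out = highpass_filter(Trace(np.full(7200, 5.0), FS))
        assert np.max(np.abs(out.values)) < 1e-6 * 5.0

    def test_deep_stopband_attenuation(self):
        # 0.1x cutoff; zero-phase 2nd-order Butterworth => 4th-order magnitude
        out = highpass_filter(_sine(0.0005, amp=1.0, duration=3 / 0.0005))
        core = out.values[2000:-2000]  # avoid edge transients
        assert np.max(np.abs(core)) < 0.1

    def test_passband_preservation(self):
        out = highpass_filter(_sine(0.05, amp=1.0))
        core = out.values[2000:-2000]
        assert np.max(np.abs(core)) == pytest.approx(1.0, rel=0.05)

    def test_closed_form_magnitude_response(self):
        # |H|^2 of butter(2) applied twice, evaluated by scipy freqz oracle
        sos = sps.butter(2, 0.005, btype="highpass", fs=FS, output="sos")
        for freq, lo, hi in [(0.0005, 0.0, 0.01), (0.05, 0.95, 1.0)]:
            w, h = sps.sosfreqz(sos, worN=[2 * np.pi * freq / FS])
            gain = np.abs(h[0]) ** 2  # forward-backward
            assert lo <= gain <= hi

    def test_short_trace_warns(self):
        with pytest.warns(UserWarning, match="warm-up"):
            highpass_filter(Trace(np.random.default_rng(0).normal(size=100), FS))

    def test_zero_phase_keeps_peak_position(self):
        t = np.arange(7200) / FS
        bump = 10 * np.exp(-((t - 1800) ** 2) / (2 * 10**2))
        out = highpass_filter(Trace(bump, FS))
        assert abs(np.argmax(out.values) - np.argmax(bump)) <= 1


class TestThreshold:
    def test_forced_alternating_trace(self):
        trace = FilteredTrace(np.tile([1.0, -1.0], 100), FS)
        model = derive_global_threshold([trace])
        assert model.pooled_sd == pytest.approx(1.0)
        assert model.threshold == pytest.approx(3.0)

    def test_pooled_gaussian_traces(self):
        rng = np.random.default_rng(5)
        traces = [FilteredTrace(rng.normal(0, 2.0, 3600), FS) for _ in range(12)]
        model = derive_global_threshold(traces)
        assert model.threshold == pytest.approx(6.0, abs=0.1)
        assert model.n_traces == 12 and model.n_samples == 12 * 3600

    def test_pooling_is_order_invariant(self, rng):
        a = FilteredTrace(rng.normal(size=500), FS)
        b = FilteredTrace(rng.normal(1.0, 2.0, size=700), FS)
        assert derive_global_threshold([a, b]).pooled_sd == pytest.approx(
            derive_global_threshold([b, a]).pooled_sd, rel=1e-14
        )

    def test_empty_and_degenerate_pools_rejected(self):
        with pytest.raises(ValueError):
            derive_global_threshold([])
        with pytest.raises(ValueError, match="zero-variance"):
            derive_global_threshold([FilteredTrace(np.zeros(100), FS)])


def oracle_detect(x, fs, threshold, min_width_s=5.0, min_distance_s=5.0):
    """Brute-force reference: scan all local maxima, measure width at half
    prominence explicitly, prune by distance (higher wins, ties earlier),
    then threshold."""
    n = len(x)
    maxima = []
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j + 1 < n and x[j + 1] < x[i]:
                maxima.append(i)  # first sample of a plateau
            i = j + 1
        else:
            i += 1
    survivors = []
    for p in maxima:
        # prominence: drop to the highest minimum separating p from higher terrain
        left = x[: p + 1]
        higher_left = np.nonzero(left > x[p])[0]
        lo = higher_left[-1] + 1 if len(higher_left) else 0
        left_min = left[lo : p + 1].min()
        right = x[p:]
        higher_right = np.nonzero(right > x[p])[0]
        hi = p + higher_right[0] if len(higher_right) else n
        right_min = x[p:hi].min()
        prom = x[p] - max(left_min, right_min)
        level = x[p] - prom / 2
        li = p
        while li > 0 and x[li - 1] >= level:
            li -= 1
        # sub-sample interpolation to the crossing, as scipy does
        if li > 0 and x[li - 1] < level:
            lpos = li - (x[li] - level) / (x[li] - x[li - 1])
        else:
            lpos = li
        ri = p
        while ri < n - 1 and x[ri + 1] >= level:
            ri += 1
        if ri < n - 1 and x[ri + 1] < level:
            rpos = ri + (x[ri] - level) / (x[ri] - x[ri + 1])
        else:
            rpos = ri
        width = (rpos - lpos) / fs
        if width >= min_width_s:
            survivors.append(p)
    survivors = np.array(survivors, dtype=int)
    order = sorted(range(len(survivors)), key=lambda k: (-x[survivors[k]], survivors[k]))
    keep = np.zeros(len(survivors), bool)
    suppressed = np.zeros(len(survivors), bool)
    for k in order:
        if suppressed[k]:
            continue
        keep[k] = True
        close = np.abs(survivors - survivors[k]) < min_distance_s * fs
        close[np.arange(len(survivors)) == k] = False
        suppressed |= close
    final = [p for p, kp in zip(survivors, keep) if kp and x[p] > threshold]
    return np.array(sorted(final))


class TestDetect:
    def _model(self, threshold=3.0):
        return ThresholdModel(pooled_sd=threshold / 3.0)

    def test_zero_trace_gives_no_events(self):
        ft = FilteredTrace(np.zeros(3600), FS)
        assert len(detect_events(ft, self._model())) == 0

    def test_two_gaussian_bumps(self):
        t = np.arange(int(600 * FS)) / FS
        x = 10 * np.exp(-((t - 100) ** 2) / (2 * 4**2)) + 10 * np.exp(
            -((t - 200) ** 2) / (2 * 4**2)
        )
        events = detect_events(FilteredTrace(x, FS, raw=x), self._model())
        assert len(events) == 2
        assert events.amplitudes == pytest.approx([10.0, 10.0], abs=0.01)
        assert events.peak_times_s == pytest.approx([100.0, 200.0], abs=0.5)

    def test_close_bumps_merged_by_distance(self):
        t = np.arange(int(600 * FS)) / FS
        x = 10 * np.exp(-((t - 100) ** 2) / (2 * 4**2)) + 9 * np.exp(
            -((t - 103) ** 2) / (2 * 4**2)
        )
        events = detect_events(FilteredTrace(x, FS, raw=x), self._model())
        assert len(events) == 1
        assert events.peak_times_s[0] == pytest.approx(100.0, abs=1.5)

    def test_matches_brute_force_oracle_on_random_traces(self, rng):
        # smooth random traces: white noise through a moving average
        n_traces, n = 1000, 400
        model = self._model(threshold=1.0)
        for _ in range(n_traces):
            x = np.convolve(rng.normal(size=n), np.ones(9) / 9, mode="same")
            got = detect_events(FilteredTrace(x, FS), model, min_width_s=3.0, min_distance_s=4.0)
            want = oracle_detect(x, FS, 1.0, min_width_s=3.0, min_distance_s=4.0)
            assert np.array_equal((got.peak_times_s * FS).astype(int), want)

    def test_raising_multiplier_never_increases_count(self, rng):
        x = np.convolve(rng.normal(size=2000), np.ones(15) / 15, mode="same") * 5
        ft = FilteredTrace(x, FS)
        counts = [
            len(detect_events(ft, ThresholdModel(pooled_sd=0.5, multiplier=m)))
            for m in (1.0, 2.0, 3.0, 4.0, 6.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_false_positive_rate_on_pure_noise(self, rng):
        # pooled-control conditions: pure Gaussian noise at pool SD, 3xSD cutoff
        model = ThresholdModel(pooled_sd=1.0)
        total = 0
        n_rec = 200
        for _ in range(n_rec):
            ft = FilteredTrace(rng.normal(0, 1.0, 3600), FS)
            total += len(detect_events(ft, model))
        assert total / n_rec < 0.5

    def test_planted_event_recovery_sensitivity(self):
        # events at >=2x threshold, kernel width >= 2x min width
        preset = COHORT_PRESETS["control"]
        model = ThresholdModel(pooled_sd=0.36)  # pooled control scale
        cfg = EventTrainConfig(rate=4.0, amplitude_mean=5.0, amplitude_sd=0.5,
                               rise_tau_s=2.0, decay_tau_s=12.0, min_separation_s=30.0)
        from xenphys.simulate import simulate_event_train

        detected, planted = 0, 0
        for seed in range(120):
            truth = simulate_event_train(cfg, seed)
            trace = synthesize_trace(truth, cfg, preset.noise, fs=FS, seed=seed + 10_000)
            ft = highpass_filter(trace)
            events = detect_events(ft, model)
            for t0 in truth.event_times_s:
                planted += 1
                if np.any(np.abs(events.peak_times_s - (t0 + 4.3)) < 10.0):
                    detected += 1
        assert planted > 200
        assert detected / planted >= 0.95

    def test_amplitude_source_filtered_vs_raw(self):
        t = np.arange(int(600 * FS)) / FS
        raw = 10 * np.exp(-((t - 300) ** 2) / (2 * 6**2)) + 2.0  # offset baseline
        filt = raw - 2.0
        events = detect_events(FilteredTrace(filt, FS, raw=raw), self._model())
        assert events.amplitudes[0] == pytest.approx(12.0, abs=0.05)
        events_f = detect_events(
            FilteredTrace(filt, FS, raw=raw), self._model(), amplitude_source="filtered"
        )
        assert events_f.amplitudes[0] == pytest.approx(10.0, abs=0.05)


class TestSummaryAndDetector:
    def test_empty_summary(self):
        events = detect_events(FilteredTrace(np.zeros(100), FS), ThresholdModel(1.0))
        count, amp = summarize_events(events, duration_s=50.0)
        assert count == 0 and np.isnan(amp)

    def test_single_event_summary(self):
        t = np.arange(int(300 * FS)) / FS
        x = 5 * np.exp(-((t - 150) ** 2) / (2 * 5**2))
        events = detect_events(FilteredTrace(x, FS, raw=x), ThresholdModel(1.0))
        count, amp = summarize_events(events)
        assert count == 1 and amp == pytest.approx(5.0, abs=0.01)

    def test_detector_threshold_fixed_after_fit(self, rng):
        controls = [Trace(rng.normal(0, 1.0, 3600), FS) for _ in range(3)]
        det = CalciumEventDetector().fit(controls)
        frozen = det.threshold_
        t = np.arange(3600) / FS
        big = Trace(50 * np.exp(-((t - 900) ** 2) / (2 * 8**2)), FS)
        det.predict(big)  # an extreme experimental trace must not move it
        assert det.threshold_ == frozen

    def test_detector_sklearn_params_roundtrip(self):
        det = CalciumEventDetector(multiplier=2.5)
        assert det.get_params()["multiplier"] == 2.5
        det.set_params(min_width_s=7.0)
        assert det.min_width_s == 7.0

    def test_unfitted_detector_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            CalciumEventDetector().predict(Trace(np.zeros(3600), FS))
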