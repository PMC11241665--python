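"""Mini detection sensitivity/precision, rise time, decay fits, IEI, averaging."""

import numpy as np
import pytest

from ipsckit.minis import (
    DetectionConfig,
    decay_segment,
    detect_minis,
    fit_biexp_decay,
    iei_cdf,
    mean_normalized_waveform,
    rise_time,
    summarize_cell,
)
from ipsckit.synthgen import EventKinetics, make_kernel, preset, simulate_minis
from ipsckit.traces import SweepTrace

KIN = EventKinetics(0.25, 0.8, 1.5, 6.0)


def _trace_with_events(times_ms, amp=40.0, dur_ms=2000.0, dt=0.1, noise=0.0,
                       seed=0, kin=KIN):
    rng = np.random.default_rng(seed)
    n = int(round(dur_ms / dt))
    s = rng.normal(0.0, noise, n) if noise > 0 else np.zeros(n)
    w = make_kernel(kin, dt)
    for t in times_ms:
        i = int(round(t / dt))
        stop = min(n, i + w.size)
        s[i:stop] -= amp * w[:stop - i]
    return SweepTrace(samples=s, dt=dt, protocol="minis")


class TestDetection:
    def test_noiseless_events_found_exactly(self):
        times = 100.0 + np.arange(10) * 150.0
        tr = _trace_with_events(times)
        events = detect_minis(tr, DetectionConfig(kinetics=KIN))
        assert len(events) == 10
        onsets = np.array([e.onset for e in events])
        np.testing.assert_allclose(onsets, times, atol=2 * tr.dt)

    def test_sensitivity_and_precision_on_noiseless_synthetic(self):
        rng = np.random.default_rng(3)
        times = np.sort(rng.uniform(50.0, 59_000.0, 300))
        times = times[np.concatenate([[True], np.diff(times) > 30.0])]
        tr = _trace_with_events(times, dur_ms=60_000.0)
        events = detect_minis(tr, DetectionConfig(kinetics=KIN))
        det = np.array([e.onset for e in events])
        matched = sum(np.min(np.abs(det - t)) < 3.0 for t in times)
        sensitivity = matched / times.size
        precision = sum(np.min(np.abs(times - d)) < 3.0 for d in det) / det.size
        assert sensitivity >= 0.99
        assert precision == 1.0

    def test_false_positive_rate_on_pure_noise(self):
        p = preset("sham").with_(mini_rate=0.0)
        fp_counts = []
        for seed in range(10):
            tr, _ = simulate_minis(p, 100.0, 0.1, seed=seed)
            fp_counts.append(len(detect_minis(tr,
                                              DetectionConfig(kinetics=KIN))))
        assert np.sum(fp_counts) / (10 * 100.0) < 0.2

    def test_short_recording_rejected(self):
        tr = SweepTrace(samples=np.zeros(5000), dt=0.1, protocol="minis")
        with pytest.raises(ValueError, match="1 s"):
            detect_minis(tr)

    def test_frequency_estimator_unbiased_across_rates(self):
        # detected frequency within 3% of the generative rate, averaged over
        # seeds, for amplitudes comfortably above the noise floor
        for rate in (5.0, 12.15, 20.25):
            p = preset("sham").with_(mini_rate=rate)
            freqs = []
            for seed in range(25):
                tr, _ = simulate_minis(p, 100.0, 0.1, seed=seed)
                cfg = DetectionConfig(kinetics=p.kernel)
                events = detect_minis(tr, cfg)
                freqs.append(sum(e.multiplicity for e in events) / 100.0)
            assert np.mean(freqs) == pytest.approx(rate, rel=0.03)


class TestRiseTime:
    def test_linear_ramp(self):
        t = np.arange(0, 1.0001, 0.001)
        assert rise_time(t, t) == pytest.approx(0.6, abs=1e-3)

    def test_exponential_rise_closed_form(self):
        tau = 0.5
        t = np.arange(0, 5, 0.001)
        y = 1.0 - np.exp(-t / tau)
        expected = tau * (np.log(1 / 0.2) - np.log(1 / 0.8))
        assert rise_time(t, y[: t.size]) == pytest.approx(expected, rel=1e-2)

    def test_instantaneous_step_bounded_by_dt(self):
        t = np.array([0.0, 0.1, 0.2, 0.3])
        y = np.array([0.0, 1.0, 1.0, 1.0])
        assert rise_time(t, y) <= 0.1


class TestBiexpFit:
    def test_single_exponential_degenerates_cleanly(self):
        t = np.arange(0, 25, 0.1)
        a1, tau1, a2, _tau2, _ = fit_biexp_decay(t, np.exp(-t / 2.0))
        assert tau1 == pytest.approx(2.0, rel=0.01)
        assert a2 == pytest.approx(0.0, abs=1e-6)

    def test_recovers_fast_component_of_study_kinetics(self):
        # a1=0.7, tau1=1.11, tau2=8: noiseless parameters back within 1%
        t = np.arange(0, 30, 0.05)
        y = 0.7 * np.exp(-t / 1.11) + 0.3 * np.exp(-t / 8.0)
        a1, tau1, a2, tau2, _ = fit_biexp_decay(t, y)
        assert tau1 == pytest.approx(1.11, rel=0.01)
        assert tau2 == pytest.approx(8.0, rel=0.01)
        assert a1 == pytest.approx(0.7, rel=0.01)

    def test_mean_of_noisy_events_recovers_tau1(self, rng):
        t = np.arange(0, 25, 0.1)
        clean = 0.6 * np.exp(-t / 1.5) + 0.4 * np.exp(-t / 7.0)
        noisy = clean + rng.normal(0, 0.05, (500, t.size))
        _a1, tau1, *_ = fit_biexp_decay(t, noisy.mean(axis=0))
        assert tau1 == pytest.approx(1.5, rel=0.05)

    def test_matches_dense_grid_search_oracle(self, rng):
        # independent brute-force oracle: dense tau grid + linear lstsq
        t = np.arange(0, 25, 0.1)
        for _ in range(20):
            tau1 = float(rng.uniform(0.5, 2.5))
            tau2 = tau1 * float(rng.uniform(3.0, 8.0))
            a1 = float(rng.uniform(0.3, 0.9))
            y = a1 * np.exp(-t / tau1) + (1 - a1) * np.exp(-t / tau2)

            grid = np.geomspace(0.2, 60.0, 120)
            best = (np.inf, None, None)
            for i, g1 in enumerate(grid):
                e1 = np.exp(-t / g1)
                for g2 in grid[i + 1:]:
                    basis = np.column_stack([e1, np.exp(-t / g2)])
                    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
                    rss = float(np.sum((basis @ coef - y) ** 2))
                    if rss < best[0]:
                        best = (rss, g1, g2)
            rss_grid, g1, g2 = best
            _a1f, t1f, _a2f, t2f, rss_fit = fit_biexp_decay(t, y)
            # the continuous optimum must be at least as good as the dense
            # grid, and must sit within one grid step of its optimum
            assert rss_fit <= rss_grid * 1.001 + 1e-12
            assert t1f == pytest.approx(g1, rel=0.06)
            assert t1f == pytest.approx(tau1, rel=0.01)
            assert t2f == pytest.approx(tau2, rel=0.02)

    def test_short_segment_rejected(self):
        t = np.arange(0, 3, 0.1)
        with pytest.raises(ValueError):
            fit_biexp_decay(t, np.exp(-t))


class TestIeiCdf:
    def test_small_example(self):
        ieis, frac = iei_cdf([0.0, 10.0, 20.0])
        np.testing.assert_array_equal(ieis, [10.0, 10.0])
        assert frac[-1] == 1.0

    def test_poisson_mean_iei_is_inverse_rate(self):
        p = preset("sham").with_(mini_rate=10.0, noise_sd=0.0)
        _, truth = simulate_minis(p, 200.0, 0.1, seed=5)
        ieis, _ = iei_cdf(truth.event_times)
        assert np.mean(ieis) == pytest.approx(100.0, rel=0.1)  # 1/10 Hz in ms

    def test_cdf_nondecreasing_and_bounded(self, rng):
        times = np.sort(rng.uniform(0, 1000, 50))
        _, frac = iei_cdf(times)
        assert np.all(np.diff(frac) >= 0)
        assert 0.0 < frac[0] and frac[-1] == 1.0

    def test_needs_two_events(self):
        with pytest.raises(ValueError):
            iei_cdf([5.0])


class TestMeanWaveform:
    def test_identical_events_average_to_single_event(self):
        times = 100.0 + np.arange(12) * 150.0
        tr = _trace_with_events(times)
        events = detect_minis(tr, DetectionConfig(kinetics=KIN))
        _t, w = mean_normalized_waveform(tr, events)
        assert w.min() == pytest.approx(-1.0)
        k = make_kernel(KIN, tr.dt)
        i_peak = int(np.argmin(w))
        n = min(w.size - i_peak, k.size - int(np.argmax(k)))
        np.testing.assert_allclose(w[i_peak:i_peak + n],
                                   -k[np.argmax(k):np.argmax(k) + n],
                                   atol=0.02)

    def test_amplitude_jitter_removed_by_normalization(self, rng):
        times = 100.0 + np.arange(40) * 120.0
        dt = 0.1
        n = int(round(5200 / dt))
        s = np.zeros(n)
        w = make_kernel(KIN, dt)
        for t in times:
            i = int(round(t / dt))
            amp = 40.0 * float(rng.lognormal(0, 0.3))
            s[i:i + w.size] -= amp * w[: n - i]
        tr = SweepTrace(samples=s, dt=dt, protocol="minis")
        events = detect_minis(tr, DetectionConfig(kinetics=KIN))
        _t, wave = mean_normalized_waveform(tr, events)
        dec_t, dec_y = decay_segment(wave, dt)
        _a1, tau1, *_ = fit_biexp_decay(dec_t, dec_y)
        assert tau1 == pytest.approx(KIN.tau1, rel=0.02)

    def test_too_few_clean_events_raises(self):
        tr = _trace_with_events(100.0 + np.arange(5) * 200.0)
        events = detect_minis(tr, DetectionConfig(kinetics=KIN))
        with pytest.raises(ValueError, match="clean events"):
            mean_normalized_waveform(tr, events)


class TestSummarizeCell:
    def test_frequency_is_count_over_duration(self):
        times = 100.0 + np.arange(20) * 90.0
        tr = _trace_with_events(times)
        events = detect_minis(tr, DetectionConfig(kinetics=KIN))
        s = summarize_cell(tr, events)
        assert s.frequency == pytest.approx(s.n_events / tr.duration_s)
        assert s.tau1 == pytest.approx(KIN.tau1, rel=0.02)
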