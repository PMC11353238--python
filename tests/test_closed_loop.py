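import numpy as np
import pytest

from tacsnet import (
    ConfigurationError,
    SyntheticSignalSpec,
    detect_dominant_frequency,
    estimate_phase_amplitude,
    generate_signal,
    matched_protocol,
    run_closed_loop,
    run_simulation,
    sliding_windows,
)
from tacsnet.config import ClosedLoopConfig
from tacsnet.stimulation import stimulus_value

FS = 200.0


def windows_of(signal, window_s=2.0, step_s=0.5):
    return sliding_windows(signal, FS, window_s, step_s)


def noisy_sine(freq, amp=1.0, phase=0.0, noise=0.1, seconds=10.0, seed=0):
    spec = SyntheticSignalSpec(
        components=((freq, amp, phase),), noise_sd=noise, fs=FS,
        duration_s=seconds, seed=seed,
    )
    return generate_signal(spec).values


class TestSlidingWindows:
    def test_window_count(self):
        w, c = windows_of(np.zeros(2000), 2.0, 1.0)  # 10 s, 2 s window, 1 s step
        assert len(w) == 9
        assert c[0] == 1000.0 and c[-1] == 9000.0

    def test_single_window_when_equal_length(self):
        w, _ = windows_of(np.zeros(400), 2.0, 1.0)
        assert len(w) == 1

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ConfigurationError):
            windows_of(np.zeros(100), 2.0, 1.0)

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ConfigurationError):
            windows_of(np.zeros(2000), 2.0, 0.0)

    def test_windows_are_demeaned(self):
        w, _ = windows_of(np.arange(2000, dtype=float))
        for seg in w:
            assert abs(seg.mean()) < 1e-9


class TestDetector:
    def test_detects_clean_oscillation(self):
        sig = noisy_sine(4.0, noise=0.1)
        w, c = windows_of(sig)
        det = detect_dominant_frequency(w, FS, ClosedLoopConfig(), c)
        assert det.passed
        assert 3.5 <= det.f_hat_hz <= 4.5

    def test_white_noise_fails_validation(self):
        rng = np.random.default_rng(1)
        w, c = windows_of(rng.normal(size=2000))
        det = detect_dominant_frequency(w, FS, ClosedLoopConfig(), c)
        assert not det.passed

    def test_diagnostics_reported_for_every_window(self):
        sig = noisy_sine(6.0)
        w, c = windows_of(sig)
        det = detect_dominant_frequency(w, FS, ClosedLoopConfig(), c)
        assert len(det.diagnostics) == len(w)
        assert all(np.isfinite(d.snr) for d in det.diagnostics)

    def test_frequency_within_search_band(self):
        for f in (3.5, 5.0, 9.5):
            w, c = windows_of(noisy_sine(f))
            det = detect_dominant_frequency(w, FS, ClosedLoopConfig(), c)
            assert det.passed
            assert abs(det.f_hat_hz - f) <= 0.25  # one 0.5 Hz bin


class TestParameterRecovery:
    @pytest.mark.parametrize("freq", [3.0, 5.0, 8.0, 10.0])
    @pytest.mark.parametrize("phase", [0.0, np.pi / 2, np.pi, 3 * np.pi / 2])
    def test_frequency_phase_amplitude_recovery(self, freq, phase):
        amp = 1.5
        sig = noisy_sine(freq, amp=amp, phase=phase, noise=0.1, seed=3)
        w, c = windows_of(sig)
        det = detect_dominant_frequency(w, FS, ClosedLoopConfig(), c)
        assert det.passed
        assert abs(det.f_hat_hz - freq) <= 0.25
        # phase/amplitude from one window, extrapolated to t=0:
        # A sin(2 pi f t + phi) = A cos(2 pi f t + phi - pi/2)
        est_phase, est_amp = estimate_phase_amplitude(w[0], FS, freq, 0.0, c[0])
        want = np.mod(phase - np.pi / 2, 2 * np.pi)
        err = np.angle(np.exp(1j * (est_phase - want)))
        assert abs(err) <= 0.3
        assert est_amp == pytest.approx(amp, rel=0.10)

    def test_amplitude_scales_linearly(self):
        amps = []
        for a in (0.5, 1.0, 2.0):
            sig = noisy_sine(4.0, amp=a, noise=0.0)
            w, c = windows_of(sig)
            _, est = estimate_phase_amplitude(w[0], FS, 4.0, c[0], c[0])
            amps.append(est)
        assert amps[1] / amps[0] == pytest.approx(2.0, rel=1e-3)
        assert amps[2] / amps[1] == pytest.approx(2.0, rel=1e-3)


class TestPhaseEstimation:
    def test_sine_phase_at_window_center(self):
        # integer number of 4 Hz periods in the 2 s window
        sig = noisy_sine(4.0, noise=0.0)
        w, c = windows_of(sig)
        phase, amp = estimate_phase_amplitude(w[0], FS, 4.0, c[0], c[0])
        assert phase == pytest.approx(np.mod(-np.pi / 2, 2 * np.pi), abs=0.05)
        assert amp == pytest.approx(1.0, rel=0.02)

    def test_extrapolation_is_periodic(self):
        sig = noisy_sine(4.0, noise=0.0)
        w, c = windows_of(sig)
        p0, _ = estimate_phase_amplitude(w[0], FS, 4.0, c[0], c[0])
        p1, _ = estimate_phase_amplitude(w[0], FS, 4.0, c[0] + 250.0, c[0])
        assert p1 == pytest.approx(p0, abs=1e-9)

    def test_frequency_outside_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            estimate_phase_amplitude(np.zeros(400), FS, 150.0, 0.0)


class TestMatchedProtocol:
    @pytest.mark.parametrize("phase_onset", [0.0, 1.0, np.pi, 5.5])
    def test_stimulus_cosine_phase_matches_signal_at_onset(self, phase_onset):
        proto = matched_protocol(4.0, phase_onset, 5.0, onset_ms=3210.0,
                                 offset_ms=9000.0)
        # the stimulus should equal A cos(phase_onset) at onset
        assert stimulus_value(proto, 3210.0) == pytest.approx(
            5.0 * np.cos(phase_onset), abs=1e-9
        )
        # and advance at frequency f: a quarter period later the cosine
        # phase has advanced by pi/2
        assert stimulus_value(proto, 3210.0 + 62.5) == pytest.approx(
            5.0 * np.cos(phase_onset + np.pi / 2), abs=1e-9
        )


class TestClosedLoopRun:
    def test_unsatisfiable_criteria_reduce_to_plain_run(self, toy_config):
        cfg = toy_config.model_copy(deep=True)
        cfg.closed_loop.snr_min = 1e12
        cfg.engine.duration_ms = 3500.0
        cfg.closed_loop.max_monitor_ms = cfg.engine.duration_ms
        out = run_closed_loop(cfg)
        assert not out.detection.passed
        assert out.protocol is None
        plain = run_simulation(cfg, protocol=None)
        assert np.array_equal(out.simulation.spike_times_ex, plain.spike_times_ex)
        assert np.array_equal(out.simulation.spike_ids_ex, plain.spike_ids_ex)

    def test_closed_loop_is_reproducible(self, toy_config):
        cfg = toy_config.model_copy(deep=True)
        cfg.closed_loop.max_monitor_ms = cfg.engine.duration_ms
        a = run_closed_loop(cfg)
        b = run_closed_loop(cfg)
        assert a.detection.passed == b.detection.passed
        assert np.array_equal(a.simulation.spike_times_ex, b.simulation.spike_times_ex)
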