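"""Detection of the network's dominant frequency, phase and amplitude, and
closed-loop delivery of matched tACS.

The detector segments the population-activity signal into overlapping
sliding windows, takes the FFT magnitude of each demeaned window inside a
search band (default 3-10 Hz), and validates the per-window peak by four
criteria: peak significance (magnitude above mean + k.SD of in-band
magnitudes), signal-to-noise ratio (peak power over median in-band power),
a subharmonic check (a stronger peak at half the candidate frequency
demotes the candidate), and consistency (candidates agreeing within a
tolerance across enough consecutive windows).  Phase and amplitude come
from the complex Fourier coefficient at the detected bin, with phase
expressed in the cosine-reference convention x(t) ~ A cos(2 pi f t + phi)
and extrapolated to any reference time.

The closed-loop runner monitors an unstimulated simulation, and on the
first validated detection starts a tACS protocol whose frequency equals the
detected frequency and whose sine is aligned with the extrapolated phase of
the ongoing oscillation at onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import ClosedLoopConfig, RunConfig, default_config
from .engine import Simulation, SimulationResult
from .errors import ConfigurationError
from .stimulation import KIND_TACS, StimulusProtocol

TWO_PI = 2.0 * np.pi


@dataclass
class WindowDiagnostics:
    """Per-window detector evidence, loggable as one CSV row."""

    t_center_ms: float
    f_candidate_hz: float
    significance_z: float
    snr: float
    harmonic_demoted: bool
    valid: bool


@dataclass
class DetectionResult:
    """Outcome of dominant-frequency detection over a set of windows."""

    passed: bool
    f_hat_hz: float = np.nan
    phase_hat: float = np.nan        # radians at t_ref, cosine convention
    amplitude_hat: float = np.nan    # signal units
    t_ref_ms: float = np.nan
    window_times_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    diagnostics: list[WindowDiagnostics] = field(default_factory=list)


@dataclass
class ClosedLoopResult:
    """Simulation result plus the detection log and delivered protocol."""

    simulation: SimulationResult
    detection: DetectionResult
    protocol: Optional[StimulusProtocol]
    onset_ms: Optional[float]


def sliding_windows(
    signal: np.ndarray,
    fs: float,
    window_s: float,
    step_s: float,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Overlapping demeaned segments and their centre times (ms).

    The first window starts at sample 0; subsequent windows advance by
    ``step_s``.  Raises when the window exceeds the signal or step <= 0.
    """
    if step_s <= 0:
        raise ConfigurationError("sliding-window step must be > 0")
    signal = np.asarray(signal, dtype=float)
    nwin = int(round(window_s * fs))
    step = int(round(step_s * fs))
    if nwin > len(signal):
        raise ConfigurationError("window longer than signal")
    starts = np.arange(0, len(signal) - nwin + 1, step)
    windows = [signal[s:s + nwin] - signal[s:s + nwin].mean() for s in starts]
    centers_ms = (starts + nwin / 2.0) / fs * 1000.0
    return windows, centers_ms


def _window_fft(window: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    mag = np.abs(np.fft.rfft(window))
    freqs = np.fft.rfftfreq(len(window), d=1.0 / fs)
    return freqs, mag


def detect_dominant_frequency(
    windows: Sequence[np.ndarray],
    fs: float,
    criteria: Optional[ClosedLoopConfig] = None,
    window_times_ms: Optional[np.ndarray] = None,
) -> DetectionResult:
    """Validated dominant-frequency estimate from sliding-window FFTs.

    ``passed`` is true only when at least ``min_consistent_windows``
    consecutive windows each pass the significance and SNR criteria with
    candidates agreeing within ``agreement_hz``; f_hat is the mean of the
    agreeing candidates of the first such run.  A failed detection returns
    passed=False with full diagnostics rather than raising.
    """
    crit = criteria or ClosedLoopConfig()
    lo, hi = crit.band_hz
    if window_times_ms is None:
        window_times_ms = np.arange(len(windows), dtype=float)
    diags: list[WindowDiagnostics] = []
    for w, tc in zip(windows, window_times_ms):
        freqs, mag = _window_fft(np.asarray(w, dtype=float), fs)
        band = (freqs >= lo) & (freqs <= hi)
        if band.sum() < 3:
            raise ConfigurationError("search band holds fewer than 3 FFT bins")
        bf, bm = freqs[band], mag[band]
        k = int(np.argmax(bm))
        demoted = False
        # subharmonic check: a stronger component at half the candidate
        # frequency indicates the candidate is its harmonic
        sub = bf[k] / 2.0
        if sub >= freqs[1]:
            ksub = int(np.argmin(np.abs(freqs - sub)))
            if mag[ksub] > bm[k] and lo <= freqs[ksub] <= hi:
                k = int(np.argmin(np.abs(bf - freqs[ksub])))
                demoted = True
        peak, f_cand = bm[k], bf[k]
        # noise statistics exclude the peak bin and its direct neighbours,
        # otherwise a strong line inflates the SD and caps the attainable z
        noise = np.delete(bm, slice(max(0, k - 1), k + 2))
        sd = noise.std()
        z = (peak - noise.mean()) / sd if sd > 0 else np.inf
        med = np.median(bm**2)
        snr = peak**2 / med if med > 0 else np.inf
        valid = (z > crit.significance_sd) and (snr >= crit.snr_min)
        diags.append(WindowDiagnostics(
            t_center_ms=float(tc), f_candidate_hz=float(f_cand),
            significance_z=float(z), snr=float(snr),
            harmonic_demoted=demoted, valid=bool(valid),
        ))

    need = crit.min_consistent_windows
    for start in range(0, len(diags) - need + 1):
        run = diags[start:start + need]
        if not all(d.valid for d in run):
            continue
        cands = np.array([d.f_candidate_hz for d in run])
        if np.ptp(cands) <= 2 * crit.agreement_hz:
            return DetectionResult(
                passed=True,
                f_hat_hz=float(cands.mean()),
                t_ref_ms=float(run[-1].t_center_ms),
                window_times_ms=np.asarray(window_times_ms),
                diagnostics=diags,
            )
    return DetectionResult(
        passed=False,
        window_times_ms=np.asarray(window_times_ms),
        diagnostics=diags,
    )


def estimate_phase_amplitude(
    window: np.ndarray,
    fs: float,
    f_hat: float,
    t_ref_ms: float,
    t_center_ms: Optional[float] = None,
) -> tuple[float, float]:
    """Phase (cosine convention, radians in [0, 2 pi)) and amplitude at f_hat.

    The complex rfft coefficient at the bin nearest ``f_hat`` gives the
    amplitude 2|X_k|/N and the phase at the window start; the phase is then
    extrapolated to ``t_ref_ms`` as phi(t_ref) = phi + 2 pi f (t_ref -
    t_start)/1000.  ``t_center_ms`` locates the window in absolute time
    (defaults to its own centre, i.e. a window-relative reference).
    """
    window = np.asarray(window, dtype=float)
    n = len(window)
    if not 0.0 < f_hat < fs / 2.0:
        raise ConfigurationError(f"f_hat={f_hat} Hz outside (0, Nyquist)")
    x = window - window.mean()
    k = int(round(f_hat * n / fs))
    k = min(max(k, 1), n // 2)
    coef = np.fft.rfft(x)[k]
    amplitude = 2.0 * np.abs(coef) / n
    window_ms = n / fs * 1000.0
    t_center_ms = window_ms / 2.0 if t_center_ms is None else t_center_ms
    t_start_ms = t_center_ms - window_ms / 2.0
    phase = np.angle(coef) + TWO_PI * f_hat * (t_ref_ms - t_start_ms) / 1000.0
    return float(np.mod(phase, TWO_PI)), float(amplitude)


def matched_protocol(
    f_hat: float,
    phase_at_onset: float,
    amplitude_pa: float,
    onset_ms: float,
    offset_ms: float,
) -> StimulusProtocol:
    """tACS protocol whose sine matches the signal's cosine phase at onset.

    The stimulus A sin(2 pi f (t)/1000 + phi_stim) equals
    A cos(2 pi f t/1000 + phi_stim - pi/2), so aligning its cosine phase at
    ``onset_ms`` with ``phase_at_onset`` requires
    phi_stim = phase_at_onset + pi/2 - 2 pi f onset/1000.
    """
    phi = phase_at_onset + np.pi / 2.0 - TWO_PI * f_hat * onset_ms / 1000.0
    return StimulusProtocol(
        kind=KIND_TACS, amplitude=amplitude_pa, frequency=f_hat,
        phase=float(np.mod(phi, TWO_PI)), onset_ms=onset_ms, offset_ms=offset_ms,
    )


def run_closed_loop(config: Optional[RunConfig] = None) -> ClosedLoopResult:
    """Monitor, detect, then stimulate with matched tACS.

    The unstimulated network is simulated while the excitatory activity
    signal is re-analysed every detection step; on the first validated
    detection a matched protocol starts at the next step boundary and runs
    for ``closed_loop.post_onset_ms``.  Without a detection within
    ``closed_loop.max_monitor_ms`` the unstimulated result is returned with
    a passed=False log.
    """
    config = config or default_config()
    cl = config.closed_loop
    sim = Simulation(config, protocol=None)
    bin_ms = config.engine.activity_bin_ms
    fs = 1000.0 / bin_ms
    check_ms = cl.step_s * 1000.0
    min_signal_ms = (cl.window_s + (cl.min_consistent_windows - 1) * cl.step_s) * 1000.0

    detection = DetectionResult(passed=False)
    signal = np.empty(0)
    t_check = max(check_ms, min_signal_ms)
    while t_check <= cl.max_monitor_ms:
        sim.run(t_check)
        res = sim.result()
        signal = res.activity("excitatory")
        windows, centers = sliding_windows(signal, fs, cl.window_s, cl.step_s)
        detection = detect_dominant_frequency(windows, fs, cl, centers)
        if detection.passed:
            break
        t_check += check_ms

    if not detection.passed:
        sim.run(cl.max_monitor_ms)  # finish the monitoring span even if no
        return ClosedLoopResult(     # window ever fit / validated
            simulation=sim.result(), detection=detection,
            protocol=None, onset_ms=None,
        )

    onset_ms = sim.t_ms
    # phase/amplitude from the last full window of the monitored signal
    nwin = int(round(cl.window_s * fs))
    tail = signal[-nwin:]
    t_center = (len(signal) - nwin / 2.0) * bin_ms
    phase_onset, amp_hat = estimate_phase_amplitude(
        tail, fs, detection.f_hat_hz, onset_ms, t_center
    )
    detection.phase_hat = phase_onset
    detection.amplitude_hat = amp_hat
    detection.t_ref_ms = onset_ms
    if cl.amplitude_policy == "proportional":
        amplitude = cl.amplitude_gain * amp_hat
    else:
        amplitude = cl.amplitude_pa
    protocol = matched_protocol(
        detection.f_hat_hz, phase_onset, amplitude,
        onset_ms, onset_ms + cl.post_onset_ms,
    )
    sim.set_protocol(protocol)
    sim.run(onset_ms + cl.post_onset_ms)
    return ClosedLoopResult(
        simulation=sim.result(), detection=detection,
        protocol=protocol, onset_ms=onset_ms,
    )
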