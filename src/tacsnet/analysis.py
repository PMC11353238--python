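"""Spectral and spatiotemporal analyses of population-activity signals.

Power spectra use the Welch averaged-periodogram estimate (Hann window,
1 s segments, 50% overlap by default) on the demeaned signal.  "Relative
power" at a target frequency f0 is the fraction of band power in
[f0 - half_band, f0 + half_band] over the power in the total band
(defaults 0.5 Hz half-band, 0.5-50 Hz total), a number in [0, 1]; the
"average relative power" of a condition is the mean of this fraction over
independent seeded runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.signal

from .config import RunConfig
from .engine import run_simulation
from .errors import ConfigurationError
from .stimulation import KIND_TACS, StimulusProtocol


@dataclass
class Spectrum:
    """One-sided Welch power spectral density."""

    freqs: np.ndarray      # Hz, ascending, <= fs/2
    power: np.ndarray      # PSD, >= 0
    fs: float              # sampling rate of the input signal (Hz)
    window_s: float
    overlap_frac: float

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def peak_frequency(self, fmin: float = 0.0, fmax: Optional[float] = None) -> float:
        """Frequency of the maximum PSD value within [fmin, fmax]."""
        fmax = self.freqs[-1] if fmax is None else fmax
        mask = (self.freqs >= fmin) & (self.freqs <= fmax)
        if not mask.any():
            raise ConfigurationError("empty frequency band")
        sel = np.flatnonzero(mask)
        return float(self.freqs[sel[np.argmax(self.power[sel])]])


@dataclass
class SweepResult:
    """Mean relative power over an amplitude x frequency stimulation grid."""

    amplitudes: np.ndarray
    frequencies: np.ndarray
    relative_power: np.ndarray   # shape (n_amplitudes, n_frequencies)
    seeds_per_cell: int
    per_seed: np.ndarray = field(default=None, repr=False)  # (A, F, seeds)


def welch_psd(
    signal: np.ndarray,
    fs: float,
    window_s: float = 1.0,
    overlap_frac: float = 0.5,
) -> Spectrum:
    """Welch PSD of a demeaned signal (Hann window).

    Raises ConfigurationError when the signal is shorter than one window.
    """
    signal = np.asarray(signal, dtype=float)
    nperseg = int(round(window_s * fs))
    if nperseg < 2:
        raise ConfigurationError("welch window must span at least 2 samples")
    if len(signal) < nperseg:
        raise ConfigurationError(
            f"signal of {len(signal)} samples is shorter than the {nperseg}-sample "
            "window; use a shorter window"
        )
    x = signal - signal.mean()
    freqs, power = scipy.signal.welch(
        x, fs=fs, window="hann", nperseg=nperseg,
        noverlap=int(round(overlap_frac * nperseg)),
        detrend="constant",
    )
    return Spectrum(freqs=freqs, power=power, fs=fs,
                    window_s=window_s, overlap_frac=overlap_frac)


def band_power(spec: Spectrum, fmin: float, fmax: float) -> float:
    """Rectangle-rule integral of the PSD over bins with centre in [fmin, fmax]."""
    mask = (spec.freqs >= fmin) & (spec.freqs <= fmax)
    if not mask.any():
        raise ConfigurationError(f"no spectral bins in band [{fmin}, {fmax}] Hz")
    return float(np.sum(spec.power[mask]) * spec.df)


def relative_power(
    spec: Spectrum,
    f0: float,
    half_band: float = 0.5,
    total_band: tuple[float, float] = (0.5, 50.0),
) -> float:
    """Fraction of total-band power concentrated within f0 +/- half_band."""
    lo, hi = total_band
    if not (lo <= f0 <= hi):
        raise ConfigurationError(f"f0={f0} Hz outside total band {total_band}")
    total = band_power(spec, lo, hi)
    if total == 0.0:
        return 0.0
    return band_power(spec, f0 - half_band, f0 + half_band) / total


def activity_map(
    spike_times: np.ndarray,
    spike_ids: np.ndarray,
    grid_shape: tuple[int, int],
    t_center: float,
    half_window: float,
) -> np.ndarray:
    """Per-grid-cell spike counts in [t_center - half_window, t_center + half_window]."""
    rows, cols = grid_shape
    out = np.zeros(rows * cols)
    sel = (spike_times >= t_center - half_window) & (spike_times <= t_center + half_window)
    if sel.any():
        out += np.bincount(np.asarray(spike_ids)[sel], minlength=rows * cols)
    return out.reshape(rows, cols)


def spectrogram(
    signal: np.ndarray,
    fs: float,
    window_s: float = 1.0,
    step_s: float = 0.25,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short-time FFT power over sliding Hann windows.

    Returns (times_s of window centres, freqs Hz, matrix freqs x times).
    """
    signal = np.asarray(signal, dtype=float)
    nperseg = int(round(window_s * fs))
    step = int(round(step_s * fs))
    if step <= 0:
        raise ConfigurationError("spectrogram step must be > 0")
    if len(signal) < nperseg:
        raise ConfigurationError("signal shorter than one spectrogram window")
    freqs, times, sxx = scipy.signal.spectrogram(
        signal, fs=fs, window="hann", nperseg=nperseg,
        noverlap=nperseg - step, detrend="constant", mode="psd",
    )
    return times, freqs, sxx


def run_relative_power(
    config: RunConfig,
    protocol: Optional[StimulusProtocol],
    f0: float,
    segment_ms: Optional[tuple[float, float]] = None,
) -> float:
    """Relative power at ``f0`` of the excitatory activity of one run."""
    res = run_simulation(config, protocol=protocol)
    sig = res.activity_ex
    if segment_ms is not None:
        lo = int(segment_ms[0] / res.activity_bin_ms)
        hi = int(segment_ms[1] / res.activity_bin_ms)
        sig = sig[lo:hi]
    ana = config.analysis
    spec = welch_psd(sig, res.activity_fs_hz, ana.welch_window_s, ana.welch_overlap)
    return relative_power(spec, f0, ana.half_band_hz, tuple(ana.total_band_hz))


def entrainment_sweep(
    amplitudes: Sequence[float],
    frequencies: Sequence[float],
    base_config: RunConfig,
    n_seeds: int = 5,
    endogenous_hz: float = 4.0,
) -> SweepResult:
    """Mean relative power at the stimulation frequency over an (A, f) grid.

    Frequency-0 cells are unstimulated baselines evaluated at the endogenous
    frequency; amplitude-0 cells likewise run without stimulation.  Each cell
    averages ``n_seeds`` independent runs with seeds derived from
    ``base_config.seed``.
    """
    amplitudes = np.asarray(list(amplitudes), dtype=float)
    frequencies = np.asarray(list(frequencies), dtype=float)
    per_seed = np.zeros((len(amplitudes), len(frequencies), n_seeds))
    for ia, amp in enumerate(amplitudes):
        for jf, freq in enumerate(frequencies):
            for k in range(n_seeds):
                cfg = base_config.model_copy(deep=True)
                cfg.seed = int(base_config.seed + 1000 * k + 17)
                if amp == 0.0 or freq == 0.0:
                    proto, f0 = None, endogenous_hz
                else:
                    proto = StimulusProtocol(
                        kind=KIND_TACS, amplitude=float(amp), frequency=float(freq)
                    )
                    f0 = float(freq)
                per_seed[ia, jf, k] = run_relative_power(cfg, proto, f0)
    return SweepResult(
        amplitudes=amplitudes,
        frequencies=frequencies,
        relative_power=per_seed.mean(axis=2),
        seeds_per_cell=n_seeds,
        per_seed=per_seed,
    )
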