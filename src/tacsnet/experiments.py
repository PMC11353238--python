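"""Canonical stimulation experiments, each a seed-swept, table-producing run.

These functions tie the simulator, stimulation waveforms and spectral
analysis into the standard comparisons: unstimulated baseline (endogenous
rhythm), tACS vs tDCS at matched amplitude, half-wave-rectified tACS
variants, mismatched-frequency tACS, the amplitude x frequency entrainment
sweep, and the closed-loop matched-stimulation run.  Every experiment
returns one tidy DataFrame with one row per (condition, seed).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .analysis import entrainment_sweep, relative_power, welch_psd
from .closed_loop import (
    estimate_phase_amplitude,
    matched_protocol,
    run_closed_loop,
)
from .config import RunConfig, default_config
from .engine import Simulation, SimulationResult, run_simulation
from .stimulation import (
    KIND_TACS,
    KIND_TDCS,
    MODE_FULL,
    StimulusProtocol,
)

ENDOGENOUS_HZ = 4.0


def derive_seeds(base_seed: int, n: int) -> list[int]:
    """Independent per-run seeds derived from one base seed (all < 2^31)."""
    return [int(s) for s in np.random.SeedSequence(base_seed).generate_state(n) % 2**31]


def _config(seed: int, duration_ms: float, template: Optional[RunConfig]) -> RunConfig:
    cfg = (template or default_config()).model_copy(deep=True)
    cfg.seed = int(seed)
    cfg.engine.duration_ms = float(duration_ms)
    return cfg


def _spectral_row(res: SimulationResult, f0: float,
                  segment_ms: Optional[tuple[float, float]] = None) -> dict:
    sig_ex, sig_in = res.activity_ex, res.activity_in
    if segment_ms is not None:
        lo = int(segment_ms[0] / res.activity_bin_ms)
        hi = int(segment_ms[1] / res.activity_bin_ms)
        sig_ex, sig_in = sig_ex[lo:hi], sig_in[lo:hi]
    ana = res.config.analysis
    spec = welch_psd(sig_ex, res.activity_fs_hz, ana.welch_window_s, ana.welch_overlap)
    return {
        "dominant_hz": spec.peak_frequency(ana.total_band_hz[0], 10.0),
        "relative_power": relative_power(
            spec, f0, ana.half_band_hz, tuple(ana.total_band_hz)
        ),
        "peak_activity_ex_pct": float(sig_ex.max()),
        "peak_activity_in_pct": float(sig_in.max()),
    }


def baseline_run(seed: int, duration_ms: float = 5000.0,
                 config: Optional[RunConfig] = None) -> dict:
    """Unstimulated run; dominant frequency and relative power at 4 Hz."""
    res = run_simulation(_config(seed, duration_ms, config), protocol=None)
    row = _spectral_row(res, ENDOGENOUS_HZ)
    row["seed"] = seed
    row["condition"] = "baseline"
    return row


def baseline_experiment(base_seed: int, n_seeds: int = 5,
                        duration_ms: float = 5000.0,
                        config: Optional[RunConfig] = None) -> pd.DataFrame:
    return pd.DataFrame([
        baseline_run(s, duration_ms, config) for s in derive_seeds(base_seed, n_seeds)
    ])


def run_aligned_tacs(
    seed: int,
    frequency: float = ENDOGENOUS_HZ,
    amplitude: float = 5.0,
    mode: str = MODE_FULL,
    monitor_ms: float = 3000.0,
    stim_ms: float = 5000.0,
    config: Optional[RunConfig] = None,
) -> tuple[SimulationResult, StimulusProtocol]:
    """tACS phase-aligned to the ongoing oscillation at a fixed frequency.

    The unstimulated network is monitored for ``monitor_ms``; the phase of
    the target frequency is read from the last detector window of the
    excitatory activity signal, and stimulation starts at ``monitor_ms``
    with its sine aligned to the extrapolated phase.
    """
    cfg = _config(seed, monitor_ms + stim_ms, config)
    sim = Simulation(cfg, protocol=None)
    sim.run(monitor_ms)
    res = sim.result()
    sig = res.activity_ex
    fs = res.activity_fs_hz
    nwin = int(round(cfg.closed_loop.window_s * fs))
    tail = sig[-nwin:]
    t_center = (len(sig) - nwin / 2.0) * res.activity_bin_ms
    phase_onset, _ = estimate_phase_amplitude(tail, fs, frequency, monitor_ms, t_center)
    proto = matched_protocol(
        frequency, phase_onset, amplitude, monitor_ms, monitor_ms + stim_ms
    )
    if mode != MODE_FULL:
        proto = StimulusProtocol(
            kind=KIND_TACS, amplitude=amplitude, frequency=frequency,
            phase=proto.phase, mode=mode,
            onset_ms=monitor_ms, offset_ms=monitor_ms + stim_ms,
        )
    sim.set_protocol(proto)
    sim.run(monitor_ms + stim_ms)
    return sim.result(), proto


def stimulation_run(
    seed: int,
    kind: str,
    mode: str = MODE_FULL,
    frequency: float = ENDOGENOUS_HZ,
    amplitude: float = 5.0,
    duration_ms: float = 5000.0,
    align_phase: bool = False,
    config: Optional[RunConfig] = None,
) -> dict:
    """One stimulated run; relative power is evaluated at the stimulation
    frequency (the endogenous 4 Hz for tDCS)."""
    f0 = frequency if kind == KIND_TACS else ENDOGENOUS_HZ
    if align_phase and kind == KIND_TACS:
        res, _ = run_aligned_tacs(
            seed, frequency=frequency, amplitude=amplitude, mode=mode,
            stim_ms=duration_ms, config=config,
        )
        row = _spectral_row(
            res, f0, segment_ms=(res.duration_ms - duration_ms, res.duration_ms)
        )
    else:
        proto = StimulusProtocol(
            kind=kind, amplitude=amplitude,
            frequency=frequency if kind == KIND_TACS else 0.0,
            mode=mode,
        )
        res = run_simulation(_config(seed, duration_ms, config), protocol=proto)
        row = _spectral_row(res, f0)
    row["seed"] = seed
    return row


def tacs_vs_tdcs_experiment(base_seed: int, n_seeds: int = 5,
                            amplitude: float = 5.0,
                            config: Optional[RunConfig] = None) -> pd.DataFrame:
    """Full-wave 4 Hz phase-aligned tACS vs constant tDCS, matched amplitude."""
    rows = []
    for seed in derive_seeds(base_seed, n_seeds):
        for cond, kind, align in (
            ("tacs", KIND_TACS, True), ("tdcs", KIND_TDCS, False),
        ):
            row = stimulation_run(
                seed, kind, amplitude=amplitude, align_phase=align, config=config
            )
            row["condition"] = cond
            rows.append(row)
    return pd.DataFrame(rows)


def halfwave_experiment(base_seed: int, n_seeds: int = 5,
                        amplitude: float = 5.0,
                        config: Optional[RunConfig] = None) -> pd.DataFrame:
    """Full vs depolarizing-only vs hyperpolarizing-only 4 Hz tACS."""
    rows = []
    for seed in derive_seeds(base_seed, n_seeds):
        for cond in ("full", "depolarizing_only", "hyperpolarizing_only"):
            row = stimulation_run(
                seed, KIND_TACS, mode=cond, amplitude=amplitude,
                align_phase=(cond == "full"), config=config,
            )
            row["condition"] = cond
            rows.append(row)
    return pd.DataFrame(rows)


def mismatch_experiment(base_seed: int, n_seeds: int = 5,
                        frequency: float = 7.0, amplitude: float = 5.0,
                        config: Optional[RunConfig] = None) -> pd.DataFrame:
    """tACS delivered off the endogenous frequency (default 7 Hz)."""
    rows = []
    for seed in derive_seeds(base_seed, n_seeds):
        row = stimulation_run(seed, KIND_TACS, frequency=frequency,
                              amplitude=amplitude, config=config)
        row["condition"] = f"tacs_{frequency:g}hz"
        rows.append(row)
    return pd.DataFrame(rows)


def sweep_experiment(base_seed: int,
                     amplitudes: Sequence[float] = (1.0, 5.0, 10.0, 15.0),
                     frequencies: Sequence[float] = tuple(range(0, 10)),
                     n_seeds: int = 3,
                     config: Optional[RunConfig] = None) -> pd.DataFrame:
    """Amplitude x frequency entrainment sweep in long format."""
    cfg = (config or default_config()).model_copy(deep=True)
    cfg.seed = int(base_seed)
    sweep = entrainment_sweep(amplitudes, frequencies, cfg, n_seeds=n_seeds)
    rows = []
    for ia, amp in enumerate(sweep.amplitudes):
        for jf, freq in enumerate(sweep.frequencies):
            for k in range(sweep.seeds_per_cell):
                rows.append({
                    "amplitude_pa": amp, "frequency_hz": freq, "seed_index": k,
                    "relative_power": sweep.per_seed[ia, jf, k],
                })
    return pd.DataFrame(rows)


def closed_loop_experiment(base_seed: int, n_seeds: int = 5,
                           config: Optional[RunConfig] = None) -> pd.DataFrame:
    """Closed-loop detection plus matched stimulation, one row per seed.

    Peak activities are measured after stimulation onset (whole run when no
    detection locks)."""
    rows = []
    for seed in derive_seeds(base_seed, n_seeds):
        cfg = (config or default_config()).model_copy(deep=True)
        cfg.seed = int(seed)
        out = run_closed_loop(cfg)
        res = out.simulation
        onset = out.onset_ms or 0.0
        row = _spectral_row(
            res, out.detection.f_hat_hz if out.detection.passed else ENDOGENOUS_HZ,
            segment_ms=(onset, res.duration_ms),
        )
        row.update({
            "seed": seed, "condition": "closed_loop",
            "passed": out.detection.passed,
            "detected_hz": out.detection.f_hat_hz,
            "onset_ms": onset if out.detection.passed else np.nan,
            "phase_hat_rad": out.detection.phase_hat,
            "amplitude_hat_pct": out.detection.amplitude_hat,
        })
        rows.append(row)
    return pd.DataFrame(rows)
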