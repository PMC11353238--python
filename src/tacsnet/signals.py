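"""Synthetic oscillatory test signals with known ground truth.

These generators make the detector and spectral analyses testable without
running the full network: a signal is a sum of sinusoids
A sin(2 pi f t + phi) plus seeded Gaussian noise, returned together with its
ground-truth component list.  Signals round-trip through two-column CSV
(time_ms, value) with a JSON sidecar carrying the ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError


@dataclass(frozen=True)
class SyntheticSignalSpec:
    """Recipe for a noisy multi-sinusoid signal."""

    components: tuple[tuple[float, float, float], ...]  # (freq Hz, amplitude, phase rad)
    noise_sd: float = 0.0
    fs: float = 200.0
    duration_s: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        for f, _, _ in self.components:
            if not 0 < f < self.fs / 2:
                raise ConfigurationError(
                    f"component frequency {f} Hz aliases at fs={self.fs} Hz"
                )


@dataclass
class GeneratedSignal:
    """Sampled series plus the ground truth that produced it."""

    t_ms: np.ndarray
    values: np.ndarray
    spec: SyntheticSignalSpec

    @property
    def fs(self) -> float:
        return self.spec.fs

    def ground_truth(self) -> dict:
        return {
            "components": [
                {"frequency_hz": f, "amplitude": a, "phase_rad": p}
                for f, a, p in self.spec.components
            ],
            "noise_sd": self.spec.noise_sd,
            "fs_hz": self.spec.fs,
            "duration_s": self.spec.duration_s,
            "seed": self.spec.seed,
        }


def generate_signal(spec: SyntheticSignalSpec) -> GeneratedSignal:
    """Sum of sinusoids plus seeded Gaussian noise."""
    n = int(round(spec.duration_s * spec.fs))
    t_s = np.arange(n) / spec.fs
    x = np.zeros(n)
    for f, a, p in spec.components:
        x += a * np.sin(2.0 * np.pi * f * t_s + p)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        x += rng.normal(0.0, spec.noise_sd, size=n)
    return GeneratedSignal(t_ms=t_s * 1000.0, values=x, spec=spec)


def write_signal_csv(sig: GeneratedSignal, path: str | Path) -> None:
    """Write (time_ms, value) CSV plus a JSON ground-truth sidecar."""
    path = Path(path)
    pd.DataFrame({"time_ms": sig.t_ms, "value": sig.values}).to_csv(path, index=False)
    path.with_suffix(".json").write_text(json.dumps(sig.ground_truth(), indent=1))


def read_signal_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, float]:
    """Read a (time_ms, value) CSV; returns (t_ms, values, fs_hz)."""
    df = pd.read_csv(path)
    if not {"time_ms", "value"} <= set(df.columns):
        raise ConfigurationError("signal CSV needs columns time_ms, value")
    t = df["time_ms"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ConfigurationError("signal CSV needs at least 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ConfigurationError("signal CSV must be uniformly sampled")
    return t, df["value"].to_numpy(dtype=float), 1000.0 / dt[0]
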