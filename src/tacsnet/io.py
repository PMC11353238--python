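"""Result and network serialization: HDF5 (primary) and CSV (interchange)."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .config import RunConfig
from .engine import SimulationResult
from .errors import ConfigurationError
from .topology import SynapticNetwork


def save_result_hdf5(result: SimulationResult, path: str | Path) -> None:
    """One self-describing HDF5 file: raster, traces, activity, stimulus,
    config echo and seed."""
    with h5py.File(path, "w") as f:
        f.attrs["config_json"] = json.dumps(result.config.model_dump(mode="json"))
        f.attrs["seed"] = result.seed
        f.attrs["dt_ms"] = result.dt_ms
        f.attrs["duration_ms"] = result.duration_ms
        f.attrs["n_ex"] = result.n_ex
        f.attrs["n_in"] = result.n_in
        f.attrs["activity_bin_ms"] = result.activity_bin_ms
        f.create_dataset("spike_times_ex", data=result.spike_times_ex)
        f.create_dataset("spike_ids_ex", data=result.spike_ids_ex)
        f.create_dataset("spike_times_in", data=result.spike_times_in)
        f.create_dataset("spike_ids_in", data=result.spike_ids_in)
        f.create_dataset("activity_ex", data=result.activity_ex)
        f.create_dataset("activity_in", data=result.activity_in)
        f.create_dataset("stimulus", data=result.stimulus_log)
        f.create_dataset("trace_ids_ex", data=result.trace_ids_ex)
        f.create_dataset("trace_ids_in", data=result.trace_ids_in)
        f.create_dataset("traces_ex", data=result.traces_ex)
        f.create_dataset("traces_in", data=result.traces_in)


def load_result_hdf5(path: str | Path) -> SimulationResult:
    with h5py.File(path, "r") as f:
        config = RunConfig(**json.loads(f.attrs["config_json"]))
        return SimulationResult(
            dt_ms=float(f.attrs["dt_ms"]),
            duration_ms=float(f.attrs["duration_ms"]),
            spike_times_ex=f["spike_times_ex"][:],
            spike_ids_ex=f["spike_ids_ex"][:].astype(int),
            spike_times_in=f["spike_times_in"][:],
            spike_ids_in=f["spike_ids_in"][:].astype(int),
            n_ex=int(f.attrs["n_ex"]),
            n_in=int(f.attrs["n_in"]),
            activity_bin_ms=float(f.attrs["activity_bin_ms"]),
            trace_ids_ex=f["trace_ids_ex"][:].astype(int),
            trace_ids_in=f["trace_ids_in"][:].astype(int),
            traces_ex=f["traces_ex"][:],
            traces_in=f["traces_in"][:],
            stimulus_log=f["stimulus"][:],
            seed=int(f.attrs["seed"]),
            config=config,
        )


def export_raster_csv(result: SimulationResult, path: str | Path) -> None:
    """Raster as (time_ms, population, neuron_id) rows."""
    df = pd.concat([
        pd.DataFrame({
            "time_ms": result.spike_times_ex,
            "population": "excitatory",
            "neuron_id": result.spike_ids_ex,
        }),
        pd.DataFrame({
            "time_ms": result.spike_times_in,
            "population": "inhibitory",
            "neuron_id": result.spike_ids_in,
        }),
    ]).sort_values(["time_ms", "population", "neuron_id"])
    df.to_csv(path, index=False)


def export_traces_csv(result: SimulationResult, path: str | Path) -> None:
    """Membrane traces as (time_ms, population, neuron_id, V_mV) rows."""
    frames = []
    for pop, ids, traces in (
        ("excitatory", result.trace_ids_ex, result.traces_ex),
        ("inhibitory", result.trace_ids_in, result.traces_in),
    ):
        if traces.size == 0:
            continue
        t = np.arange(traces.shape[0]) * result.dt_ms
        for col, nid in enumerate(ids):
            frames.append(pd.DataFrame({
                "time_ms": t, "population": pop,
                "neuron_id": nid, "V_mV": traces[:, col],
            }))
    pd.concat(frames).to_csv(path, index=False)


def export_activity_csv(result: SimulationResult, path: str | Path) -> None:
    t = np.arange(len(result.activity_ex)) * result.activity_bin_ms
    pd.DataFrame({
        "time_ms": t,
        "activity_ex_pct": result.activity_ex,
        "activity_in_pct": result.activity_in,
    }).to_csv(path, index=False)


def export_network_csv(net: SynapticNetwork, path: str | Path, seed: int | None = None) -> None:
    """Edge list (projection, pre_id, post_id) with a JSON header sidecar."""
    path = Path(path)
    rows = []
    for name, adj in (("py_py", net.py_py), ("py_in", net.py_in), ("in_py", net.in_py)):
        for pre, targets in enumerate(adj):
            rows.append(pd.DataFrame({
                "projection": name, "pre_id": pre, "post_id": targets,
            }))
    pd.concat(rows).to_csv(path, index=False)
    header = {
        "py_shape": list(net.py_shape), "in_shape": list(net.in_shape),
        "w_py_py": net.w_py_py, "w_py_in": net.w_py_in, "w_in_py": net.w_in_py,
        "seed": seed,
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=1))


def import_network_csv(path: str | Path) -> SynapticNetwork:
    path = Path(path)
    df = pd.read_csv(path)
    header = json.loads(path.with_suffix(".json").read_text())
    py_shape = tuple(header["py_shape"])
    in_shape = tuple(header["in_shape"])
    n_py = py_shape[0] * py_shape[1]
    n_in = in_shape[0] * in_shape[1]
    adj = {}
    for name, n_pre in (("py_py", n_py), ("py_in", n_py), ("in_py", n_in)):
        sub = df[df.projection == name]
        lists = [np.empty(0, dtype=int)] * n_pre
        for pre, grp in sub.groupby("pre_id"):
            lists[int(pre)] = np.sort(grp.post_id.to_numpy(dtype=int))
        adj[name] = lists
    if not adj:
        raise ConfigurationError("empty network CSV")
    return SynapticNetwork(
        py_shape=py_shape, in_shape=in_shape,
        py_py=adj["py_py"], py_in=adj["py_in"], in_py=adj["in_py"],
        w_py_py=header["w_py_py"], w_py_in=header["w_py_in"],
        w_in_py=header["w_in_py"],
    )
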