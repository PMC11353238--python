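import numpy as np
import pytest

from tacsnet import (
    StimulusProtocol,
    population_activity,
    run_simulation,
)
from tacsnet.engine import Simulation


def quiet(cfg, **noise):
    c = cfg.model_copy(deep=True)
    c.noise.max_ex = noise.get("max_ex", 0.0)
    c.noise.max_in = noise.get("max_in", 0.0)
    return c


class TestPopulationActivity:
    def test_all_neurons_in_one_bin_is_100(self):
        t = np.zeros(1600)
        ids = np.arange(1600)
        act = population_activity(t, ids, 1600, 5.0, 50.0)
        assert act[0] == 100.0
        assert np.all(act[1:] == 0.0)

    def test_half_population_is_50(self):
        act = population_activity(np.zeros(800), np.arange(800), 1600, 5.0, 10.0)
        assert act[0] == 50.0

    def test_repeated_spikes_count_once(self):
        act = population_activity(
            np.array([1.0, 2.0, 3.0]), np.array([7, 7, 7]), 100, 5.0, 10.0
        )
        assert act[0] == 1.0

    def test_empty_raster_gives_zeros(self):
        act = population_activity(np.empty(0), np.empty(0, int), 100, 5.0, 100.0)
        assert act.shape == (20,)
        assert np.all(act == 0.0)

    def test_percentages_bounded(self, toy_config):
        res = run_simulation(toy_config)
        assert np.all(res.activity_ex >= 0.0) and np.all(res.activity_ex <= 100.0)
        assert np.all(res.activity_in >= 0.0) and np.all(res.activity_in <= 100.0)


class TestRunSimulation:
    def test_no_drive_no_spikes(self, toy_config):
        cfg = quiet(toy_config)
        cfg.network.w_py_py = 0.0
        cfg.network.w_py_in = 0.0
        cfg.network.w_in_py = 0.0
        res = run_simulation(cfg)
        assert len(res.spike_times_ex) == 0
        assert len(res.spike_times_in) == 0
        assert np.all(res.activity_ex == 0.0)

    def test_identical_seed_identical_raster(self, toy_config):
        r1 = run_simulation(toy_config)
        r2 = run_simulation(toy_config)
        assert np.array_equal(r1.spike_times_ex, r2.spike_times_ex)
        assert np.array_equal(r1.spike_ids_ex, r2.spike_ids_ex)
        assert np.array_equal(r1.spike_times_in, r2.spike_times_in)

    def test_different_seed_different_raster(self, toy_config):
        other = toy_config.model_copy(deep=True)
        other.seed = toy_config.seed + 1
        r1 = run_simulation(toy_config)
        r2 = run_simulation(other)
        assert not (
            len(r1.spike_times_ex) == len(r2.spike_times_ex)
            and np.array_equal(r1.spike_times_ex, r2.spike_times_ex)
            and np.array_equal(r1.spike_ids_ex, r2.spike_ids_ex)
        )

    def test_spike_times_on_dt_grid_within_duration(self, toy_config):
        res = run_simulation(toy_config)
        t = res.spike_times_ex
        assert np.all(t >= 0.0) and np.all(t < res.duration_ms)
        assert np.allclose(np.round(t / res.dt_ms), t / res.dt_ms)

    def test_membrane_never_left_above_threshold(self, toy_config):
        res = run_simulation(toy_config)
        if res.traces_ex.size:
            assert res.traces_ex.max() < 30.0 + 1e-9

    def test_stimulus_log_matches_protocol(self, toy_config):
        proto = StimulusProtocol(kind="tdcs", amplitude=2.5, onset_ms=100.0,
                                 offset_ms=200.0)
        res = run_simulation(quiet(toy_config), protocol=proto)
        t = np.arange(len(res.stimulus_log)) * res.dt_ms
        inside = (t >= 100.0) & (t < 200.0)
        assert np.all(res.stimulus_log[inside] == 2.5)
        assert np.all(res.stimulus_log[~inside] == 0.0)

    def test_tonic_drive_gives_periodic_identical_isis(self, toy_config):
        """With noise and synapses silenced, constant tDCS makes each neuron a
        deterministic oscillator with constant inter-spike intervals."""
        cfg = quiet(toy_config)
        cfg.network.w_py_py = 0.0
        cfg.network.w_py_in = 0.0
        cfg.network.w_in_py = 0.0
        cfg.engine.duration_ms = 2000.0
        proto = StimulusProtocol(kind="tdcs", amplitude=10.0)
        res = run_simulation(cfg, protocol=proto)
        nid = res.spike_ids_ex[0]
        times = res.spike_times_ex[res.spike_ids_ex == nid]
        isis = np.diff(times)[2:]  # discard initial transient
        assert len(isis) >= 3
        assert np.ptp(isis) <= res.dt_ms + 1e-9

    def test_disabling_depression_increases_excitatory_spiking(self, toy_config):
        cfg = toy_config.model_copy(deep=True)
        cfg.synapses.r_dep = 1.0
        with_dep = run_simulation(toy_config)
        without = run_simulation(cfg)
        assert len(without.spike_times_ex) >= len(with_dep.spike_times_ex)


class TestIncrementalSimulation:
    def test_mid_run_protocol_change_equals_preset_protocol(self, toy_config):
        proto = StimulusProtocol(kind="tdcs", amplitude=4.0, onset_ms=250.0)
        full = run_simulation(toy_config, protocol=proto)
        sim = Simulation(toy_config, protocol=None)
        sim.run(250.0)
        sim.set_protocol(proto)
        sim.run(toy_config.engine.duration_ms)
        res = sim.result()
        assert np.array_equal(res.spike_times_ex, full.spike_times_ex)
        assert np.array_equal(res.spike_ids_ex, full.spike_ids_ex)

    def test_result_duration_tracks_steps(self, toy_config):
        sim = Simulation(toy_config)
        sim.run(123.0)
        assert sim.result().duration_ms == pytest.approx(123.0)


def test_result_hdf5_round_trip(tmp_path, toy_config):
    from tacsnet.io import load_result_hdf5, save_result_hdf5

    res = run_simulation(toy_config)
    path = tmp_path / "run.h5"
    save_result_hdf5(res, path)
    back = load_result_hdf5(path)
    assert np.array_equal(back.spike_times_ex, res.spike_times_ex)
    assert np.array_equal(back.spike_ids_in, res.spike_ids_in)
    assert np.array_equal(back.stimulus_log, res.stimulus_log)
    assert back.seed == res.seed
    assert back.config == res.config
    np.testing.assert_allclose(back.activity_ex, res.activity_ex)


def test_raster_and_activity_csv_exports(tmp_path, toy_config):
    import pandas as pd

    from tacsnet.io import export_activity_csv, export_raster_csv, export_traces_csv

    res = run_simulation(toy_config)
    export_raster_csv(res, tmp_path / "raster.csv")
    export_activity_csv(res, tmp_path / "act.csv")
    export_traces_csv(res, tmp_path / "traces.csv")
    raster = pd.read_csv(tmp_path / "raster.csv")
    assert len(raster) == len(res.spike_times_ex) + len(res.spike_times_in)
    act = pd.read_csv(tmp_path / "act.csv")
    assert {"time_ms", "activity_ex_pct", "activity_in_pct"} <= set(act.columns)
    traces = pd.read_csv(tmp_path / "traces.csv")
    assert set(traces.population.unique()) == {"excitatory", "inhibitory"}
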