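# Full run configuration with every default spelled out.
# Any subset may be given; omitted keys take these values. Unknown keys
# are rejected. `tacsnet simulate --config this.yaml --out run.h5`
seed: 0
network:
  py_shape: [40, 40]
  in_shape: [20, 20]
  degree_py_py: 121
  degree_py_in: 29
  degree_in_py: 49
  radius_py_py: 6        # null -> smallest radius covering the degree
  radius_py_in: 3
  w_py_py: 0.027         # per-synapse conductance increments (6:2:4 ratio)
  w_py_in: 0.009
  w_in_py: 0.018
noise:
  max_ex: 5.0            # pA, uniform kick amplitude bound (excitatory)
  max_in: 2.0
  interval_ms: 10.0      # per-neuron piecewise-constant interval
  event_prob: 0.15       # probability an interval carries a kick
stimulus:
  kind: none             # none | tdcs | tacs
  amplitude: 5.0         # pA
  frequency: 4.0         # Hz (tACS)
  phase: 0.0             # radians
  mode: full             # full | depolarizing_only | hyperpolarizing_only
  onset_ms: 0.0
  offset_ms: null        # null -> until end of run
  target: all            # all | excitatory_only
engine:
  dt_ms: 0.1
  duration_ms: 5000.0
  activity_bin_ms: 5.0
  spike_threshold_mv: 30.0
  n_trace_ex: 3
  n_trace_in: 3
synapses:
  tau_ex_ms: 2.0
  tau_in_ms: 3.0
  r_dep: 0.6
  tau_dep_ms: 300.0
analysis:
  welch_window_s: 1.0
  welch_overlap: 0.5
  half_band_hz: 0.5
  total_band_hz: [0.5, 50.0]
closed_loop:
  window_s: 2.0
  step_s: 0.5
  band_hz: [3.0, 10.0]
  significance_sd: 3.0
  snr_min: 5.0
  min_consistent_windows: 3
  agreement_hz: 0.5
  amplitude_policy: fixed   # fixed | proportional
  amplitude_pa: 5.0
  amplitude_gain: 0.25
  max_monitor_ms: 10000.0
  post_onset_ms: 5000.0
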