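# Methods

## Model

`tacsnet` simulates a two-population cortical sheet: 1600 pyramidal (PY)
neurons on a 40×40 grid and 400 fast-spiking inhibitory (IN) neurons on a
20×20 grid. Each neuron follows the two-variable quadratic
(Izhikevich-type) dynamics

    dV/dt = 0.04 V² + 5 V + 140 − u + I_noise + I_stim − G_EX (V − V_AMPA) − G_IN (V − V_GABA)
    du/dt = a (b V − u)

with a spike emitted when V ≥ 30 mV, followed by the reset V ← c,
u ← u + d. Both equations are advanced by a single forward-Euler step at
dt = 0.1 ms, evaluating both derivatives from the pre-step state. The
recovery equation is integrated in its continuous form scaled by dt; a
dt-free discrete map at this step size would make the recovery dynamics
depend on the integration grid rather than on time.

Parameter heterogeneity uses one uniform deviate ρ per neuron:

| population  | a                | b                | c (mV)             | d            |
|-------------|------------------|------------------|--------------------|--------------|
| excitatory  | 0.02             | 0.2              | −65 + 15 ρ² ∈ [−65, −50] | 8 − 6 ρ² ∈ [2, 8] |
| inhibitory  | 0.02 + 0.08 ρ    | 0.25 − 0.05 ρ    | −65                | 2            |

The squared deviate biases excitatory cells toward regular spiking;
inhibitory cells span the fast-spiking range. Initial conditions are
V = −65 mV, u = bV. Reversal potentials are V_AMPA = 0 mV and
V_GABA = −80 mV.

## Synapses

Summed conductances per postsynaptic neuron decay exponentially with
τ_EX = 2 ms and τ_IN = 3 ms. A presynaptic spike instantaneously increments
every target's conductance by the projection weight; PY→PY increments are
additionally scaled by the presynaptic short-term depression variable
d_dep ∈ (0, 1] (g = d·G). After each spike d_dep is multiplied by r = 0.6
and recovers exponentially toward 1 with time constant τ_d = 300 ms. Only
PY→PY efferents depress; PY→IN transmission is undepressed (the depressing
term is defined only for the excitatory–excitatory connection, and keeping
feed-forward inhibition undepressed is the conservative choice).

Connectivity is fixed out-degree: every PY neuron contacts exactly 121 PY
targets sampled without replacement from its Chebyshev radius-6
neighbourhood (pool 168 when interior; clipped at edges, no wraparound,
min(degree, pool) at the border) and 29 IN targets from the radius-3
neighbourhood of its mapped coarse-grid position (i//2, j//2); every IN
neuron contacts 49 PY neurons sampled uniformly from the whole sheet
(global inhibitory feedback). The radii are the smallest whose interior
pools cover the required degrees. There are no self-connections, no
duplicate edges within a projection, no conduction delays, and no IN→IN
coupling.

### Synaptic weight calibration

The reference parameter set gives the three projections in the ratio
PY→PY : PY→IN : IN→PY = 6 : 2 : 4 (printed as 0.0006/0.0002/0.0004), but
taken literally as conductance increments on the millivolt scale these
values cannot support the collective dynamics this model family is known
for: a fully synchronized volley of all 121 PY inputs produces a ~4.7 pA
transient decaying with τ = 2 ms, while recruiting a resting neuron
requires roughly 4 pA sustained for ~10 ms. In a direct test (a seeded
7×7 patch of spiking neurons in an otherwise quiet sheet) the excitation
wave dies within 5 ms at those magnitudes. We therefore keep the printed
ratio and scale all three weights by one common factor, chosen once as the
regime where (i) excitation waves propagate through fully resting tissue
and (ii) re-ignition after a wave is gated by depression recovery rather
than by single-cell firing rates. The shipped defaults are
w_PY→PY = 0.027, w_PY→IN = 0.009, w_IN→PY = 0.018 (factor 45). With them
the unstimulated network alternates quiescent DOWN states with brief
global UP bursts recurring at ~4 Hz — the slow rhythm the model is built
to exhibit.

## Background noise

Noise emulates afferent background input as brief per-neuron current
kicks: each neuron's noise is piecewise constant over its own 10 ms
intervals (interval boundaries staggered uniformly across neurons so there
is no population-wide refresh clock). At each boundary the neuron draws,
with probability 0.15, a current uniform on [0, 5] pA (PY) or [0, 2] pA
(IN), and is otherwise noise-free for that interval.

The temporal structure matters more than it may appear, and is the one
place where this implementation had to commit to a design the reference
description leaves open:

- noise redrawn every 0.1 ms step is filtered by the membrane to its mean
  (~2.5 pA), which is below the ~4 pA rheobase — the network stays silent
  forever;
- noise held continuously (any refresh interval, 100% duty) makes every
  neuron fire at the cell-intrinsic 8–11 Hz floor of this neuron model's
  f–I curve, which chronically depresses the synapses and entrains the
  network at 8–11 Hz instead of the slow rhythm;
- sparse kicks (the shipped default) keep DOWN states quiescent, let
  depression recover fully between UP states, and supply enough ignition
  events (~10³ per second across the sheet) that UP onset is gated by
  synaptic recovery. This reproduces the described mechanism: after a
  DOWN state, PY synapses rebound from depression and the next UP state
  ignites.

All four noise parameters (two maxima, interval, event probability) are
exposed in the `noise` config block; `event_prob = 1` recovers the
held-uniform variant.

## Stimulation

tDCS is a constant current; tACS is A·sin(2πft/1000 + φ) with t in ms.
Half-wave rectified variants zero one half-cycle: depolarizing-only keeps
max(0, ·), hyperpolarizing-only keeps min(0, ·); the two rectified
waveforms sum to the full sine exactly. Stimulation is added identically
to every targeted neuron (default: both populations; configurable to
excitatory-only), within [onset, offset). The delivered waveform is logged
at every step for audit.

## Simulation loop

Per step: (1) conductance decay; (2) total current assembly
(noise + stimulus + synaptic); (3) membrane update; (4) spike detection
and reset; (5) spike delivery (current step's spikes, no delay);
(6) depression recovery then per-spike depression; (7) recording.
Spike delivery is implemented as one sparse matrix–vector product per
projection (CSR, post×pre). A 5 s run of the default 2000-neuron network
takes on the order of 10 s on one CPU core.

Population activity is the percentage of *distinct* neurons of a
population spiking within a 5 ms bin (a neuron spiking twice in a bin
counts once), i.e. a rate signal sampled at 200 Hz. The bin width is a
package choice (exposed as `engine.activity_bin_ms`): 5 ms is fine enough
to resolve burst onsets yet coarse enough that single spikes register as
percentage steps of one neuron.

## Spectral analysis

PSDs use Welch's method on the demeaned signal: Hann window, 1 s segments,
50% overlap. Relative power at f₀ is the rectangle-rule integral of the
PSD over bins whose centres lie in [f₀ − 0.5, f₀ + 0.5] Hz divided by the
integral over 0.5–50 Hz; "average relative power" of a condition is the
mean of this fraction over independent seeded runs. Note two estimator
properties: (i) with 1 s segments the Hann main lobe spans three 1 Hz
bins, so even a pure line concentrates only ~⅔ of its power inside the
±0.5 Hz band; (ii) the activity signal of this network is a low-duty
pulse train whose power is spread over a harmonic comb up to ~40 Hz, which
bounds the achievable relative power near ~0.1–0.2 however perfectly the
rhythm is entrained. Comparisons between conditions remain meaningful;
absolute values are not comparable to analyses computed on smooth
(near-sinusoidal) signals. Phase-locking diagnostics are the more
sensitive entrainment measure here: under matched 4 Hz tACS the
inter-burst interval locks to 250 ± 1 ms (vs 245 ± 37 ms unstimulated).

The spectrogram is a short-time FFT (Hann) over sliding windows; the
amplitude×frequency entrainment sweep runs independent seeded simulations
per grid cell and reports mean relative power at the stimulation frequency
(unstimulated cells — amplitude 0 or frequency 0 — are evaluated at the
endogenous 4 Hz).

## Closed loop

The detector segments the excitatory activity signal into 2 s windows
stepped by 0.5 s, demeans each, and takes FFT magnitudes inside the 3–10 Hz
search band. A window's candidate (the in-band argmax) is validated by:
peak significance (magnitude > mean + 3 SD of in-band magnitudes,
excluding the peak bin and its direct neighbours from the noise estimate —
with only ~15 in-band bins, including the peak caps the attainable z-score
near 3.6 and makes the criterion vacuous); SNR (peak power ≥ 5× median
in-band power); a subharmonic check (a stronger component at half the
candidate frequency demotes the candidate); and consistency (three
consecutive valid windows agreeing within ±0.5 Hz). The detected frequency
is the mean of the agreeing candidates.

Phase and amplitude come from the complex rfft coefficient at the bin
nearest f̂: amplitude 2|X_k|/N, phase in the cosine convention
x(t) ≈ A cos(2πft + φ), extrapolated linearly in time to any reference
instant. On first validated detection the runner starts tACS at f̂ whose
sine matches the extrapolated signal phase at onset
(φ_stim = φ_signal(onset) + π/2 − 2πf̂·onset/1000), at a fixed 5 pA by
default (a policy proportional to the detected amplitude is available but
the mapping from activity units to pA has no principled reference value).
Stimulation then runs with fixed parameters — the loop does not re-tune
after lock. Monitoring lasts at most 10 s; without a validated detection
the run is returned unstimulated with the full diagnostics log.

## Synthetic signals

The fixture generator produces sums of sinusoids plus seeded Gaussian
noise with the ground truth attached, written as two-column CSV
(time_ms, value) with a JSON sidecar. Detector tests sweep
f ∈ {3…10} Hz × φ ∈ {0, π/2, π, 3π/2} and require recovery of f within one
FFT bin, φ within 0.3 rad, and A within 10%. These fixtures validate the
detector in isolation; they do not emulate real EEG (no 1/f background,
no nonstationarity), so passing them says nothing about detection
performance on human recordings.

## Problem sizes and reproducibility

The canonical experiments use the full 2000-neuron network for 5 s of
simulated time per run and 5 seeds per condition; the closed-loop runs
monitor up to 10 s and stimulate for 5 s. Per-run seeds are derived from
one base seed via `numpy.random.SeedSequence` (kept below 2³¹). Identical
config + seed reproduces rasters bit-for-bit; the closed-loop pipeline is
fully deterministic given the seed because detection thresholds are
deterministic functions of the signal.

## Known limitations

- The synaptic weight scale and the noise temporal structure are package
  calibrations (see above), fixed once to restore the documented dynamical
  regime; absolute relative-power values are bounded by the pulse-train
  character of the activity signal and sit well below values reported for
  smooth population signals.
- UP states are brief (~20–30 ms) global bursts; regimes with long
  reverberating UP states are not reachable with per-spike depression
  r = 0.6 and τ_EX = 2 ms at any weight scale we examined.
- No conduction delays, no NMDA/GABA_B kinetics, no long-term plasticity,
  no electric-field forward modelling — stimulation is an injected current,
  identical for every targeted neuron.
- The half-cycle comparisons and the frequency-mismatch comparison inherit
  the duty-cycle sensitivity of the band-fraction metric: tighter locking
  narrows bursts and can lower the metric even as entrainment improves.
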