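# Methods

## Overview

`spikecircuit` couples a conductance-based spiking-network simulator to the
spike-train and functional-connectivity statistics used for microelectrode
array (MEA) recordings of cultured neurons. The simulator emulates how cypin
overexpression reshapes circuit activity through three physiological levers
— AMPA receptor conductance, connection density, and presynaptic drive —
and its rasters run through exactly the same analysis path as recorded
data, so simulated and in vitro activity are directly comparable.

## The network model

500 leaky integrate-and-fire neurons (400 excitatory, 100 inhibitory) with
conductance-based synapses. The membrane potential obeys

    C_m dV/dt = -g_m (V - V_L) - I_syn + I_AHP + I_pre

integrated by forward Euler at dt = 0.1 ms. `I_syn` sums AMPA, NMDA and
GABA-A conductance currents; NMDA carries the standard magnesium-block
voltage dependence `B(V) = 1 / (1 + [Mg]/3.57 exp(-0.062 V/mV))`. `I_AHP`
is a spike-triggered adaptation current: each spike increments a
calcium-like variable that decays with `tau_ca` and gates a potassium-like
conductance (reversal −80 mV), producing slow fatigue. `I_pre` is external
drive with two components: a per-neuron constant bias drawn once per run
from a Gaussian (the seeded external input current) and a Gaussian noise
current (the presynaptic noise). Directed connectivity is sampled
independently per ordered pair with class probabilities E→E 0.1, E→I 0.05,
I→E 0.2, I→I 0.2, no self-connections.

All synapses carry Tsodyks–Markram short-term plasticity (utilization `u`
jumps by `U(1-u)` per presynaptic spike and decays back with `tau_facil`;
resources `x` deplete by the released fraction `u·x` and recover with
`tau_rec`). Excitatory–excitatory synapses additionally carry pair-based
STDP with exponential windows (trace implementation, weights clipped to
`[0, w_max]`).

### Parameter values

Membrane and receptor constants are in the style of the culture-bursting
model family this simulator follows; every number lives in
`NeuronParameters`, `SynapseParameters` and `SimulationConfig` (SI units)
so the full set is auditable in one place. Non-obvious choices:

* **Hyperpolarizing GABA-A (E_inh = −80 mV), τ_GABA = 10 ms, g_IE = 18 nS.**
  Inhibition must be able to pull the excitatory population below rest, not
  merely shunt it, for interneuron feedback to regulate the network when
  the drive to *every* neuron rises. This is what lets a uniform doubling
  of presynaptic noise raise network rate only ~2-fold while a selective
  doubling of 4 neurons' external current raises those neurons ~20-fold:
  population-level drive recruits interneurons (whose smaller capacitance
  makes them more noise-sensitive), a 1% subpopulation does not.
* **Quiet interneurons at rest** (`bias_inh_scale = 0.5`): the inhibitory
  class receives half the constant bias, so baseline inhibition is weak and
  the excitatory recurrence can generate population bursts, while the
  interneurons remain available as a reserve brake.
* **Per-class short-term plasticity**: inhibitory synapses depress less and
  recover faster (`U_inh = 0.2, tau_rec_inh = 0.1 s`) than excitatory ones
  (`U = 0.3, tau_rec = 0.4 s`); sustained inhibition would otherwise
  collapse exactly when it is needed.
* **Balanced STDP** (`A_plus = A_minus = 0.005`, 20-ms windows): weights are
  stable under the symmetric pairings inside population bursts; the only
  systematic drift is causal — neurons that reliably lead bursts (the
  stimulated inputs during training) potentiate their outgoing synapses.
* **Drive calibration**: the bias (0.27 ± 0.05 nA) and noise SD
  (9.7 pA·√s) were calibrated once so the control network shows population
  bursting (≥ 50 pooled spikes in 50 ms) over a quiet tonic background,
  then frozen. They are study conditions, not per-experiment knobs.

### Perturbation conditions

`apply_cypin_condition` maps named conditions to the three scalings
(AMPA, connection density, presynaptic current):

| condition    | AMPA | density | I_pre |
|--------------|------|---------|-------|
| `control`    | 1    | 1       | 1     |
| `cypin_oe_1` | 1    | 0.75    | 2     |
| `cypin_oe_2` | 2    | 2       | 2     |

AMPA scaling multiplies the AMPA maximal conductance only (NMDA and GABA
untouched); density scaling multiplies all four class probabilities,
clipped at 1 with a warning; `ipre_scale` multiplies the presynaptic
*noise* SD of every neuron. The constant bias is the separately seeded
external input current: it is touched only by the entrainment stimulus,
which multiplies both bias and noise of the stimulated neurons. This split
follows the two roles the drive plays — a seeded per-neuron input level
versus an ongoing stochastic presynaptic barrage.

### Numerical choices

* Forward Euler, dt = 0.1 ms; single-neuron trajectories match the
  closed-form membrane decay to first order in dt (tested).
* The noise current is band-limited: refreshed every 1 ms (10 steps) and
  held constant in between, with SD scaled by 1/√(update interval) so the
  variance delivered to the membrane matches the white-noise limit. The
  noise spectrum is flat to ~1 kHz, two orders of magnitude above the 8-Hz
  membrane cutoff, so membrane statistics are indistinguishable from true
  white noise at a tenth of the random-number cost.
* Plasticity is event-driven: per-neuron summed receptor conductances decay
  every step; per-synapse STP state advances analytically between
  presynaptic spikes; STDP uses per-neuron pre/post traces.
* A runaway guard aborts a run whose mean rate exceeds
  `max_mean_rate` (150 Hz/neuron) with the offending step index.
* Determinism: one master seed spawns independent streams for
  connectivity, bias and the integration noise, so a fixed config
  reproduces byte-identical rasters.

## The analysis stack

The processing chain mirrors standard extracellular practice and is applied
identically to recorded, simulated and synthetic rasters:

1. **Filtering** (raw traces): zero-phase 4th-order Butterworth band-pass
   20–2000 Hz plus a 60-Hz notch (Q = 30). Zero-phase application keeps
   spike peaks unshifted; reflect padding is extended to cover the ringing
   of the 20-Hz corner and the high-Q notch so edge transients cannot
   masquerade as spikes.
2. **Detection**: per channel, threshold = 4.5 × noise SD estimated as
   MAD/0.6745 within non-overlapping 10-s windows (robust to the spikes
   themselves); one spike per suprathreshold excursion of |v|, timestamped
   at the absolute maximum; spikes within 2 ms of the previous kept spike
   are discarded.
3. **Per-train statistics**: spike rate (count/duration), ISI mean and CV
   (sample SD; flagged NaN below 2/3 spikes), Fano factor (variance/mean of
   counts in non-overlapping bins, default 1 s, flagged NaN when the mean
   count is zero or the recording is shorter than 10 bins).
4. **Active sources**: rate ≥ the 75th percentile (linear interpolation) of
   the per-recording rate distribution; recording-level summaries average
   over active sources.
5. **Burst detection**: per-electrode burstlets (≥ 4 spikes with ISIs below
   min(100 ms, 1/(4·rate)), peripherally extended at min(200 ms,
   1/(3·rate)); the "times the firing rate" caps are read as fractions of
   the mean ISI, the only dimensionally consistent reading) and population
   network bursts (≥ 50 pooled spikes within 50 ms; qualifying windows
   merge only when they share spikes). Interburst interval = difference of
   successive burst onsets.
6. **Functional connectivity**: spike trains binned at 1 ms; edge weight =
   maximum normalized cross-correlation over integer-bin lags within
   ±20 ms. Normalization is the coefficient convention (raw lagged dot
   product over the product of vector norms), so a lag-shifted copy scores
   exactly 1; the matrix is symmetric with zero diagonal, and silent
   sources get zero edges with a logged warning. Mean subtraction before
   normalization is available behind a flag (default off, the spike-train
   convention).
7. **Graph measures**: weighted global efficiency (mean inverse shortest
   path, edge length 1/weight), the Wang-style weighted local efficiency
   (cube-root weighting on neighborhood subgraphs; the < 0.001 baseline
   exclusion is applied at normalization time, not inside the metric), and
   Louvain community detection (resolution 1, best-Q of 100 repeats with
   derived sub-seeds) with weighted modularity Q.

## The entrainment protocol

`run_entrainment` executes stabilize → control → training → testing. After
the control phase, 1% of excitatory neurons (4 of 400, uniform-random under
the run seed) have their external current doubled. Readouts: population-
pooled firing rates per phase; fold changes (testing vs control phase, same
population); signal fidelity = output-population rate / input-population
rate, before (control phase) and after (testing phase) training; and
pre/post functional networks with graph measures. Output neurons are the
396 non-stimulated excitatory neurons; inhibitory neurons belong to
neither population. The conditioning of the output population is carried
entirely by the network's own STP/STDP dynamics.

Mechanistically, the stimulated neurons fire tonically (~20–30 Hz) against
a quiet background, their causally-leading spikes potentiate their outgoing
E–E synapses, and their sustained drive multiplies the population burst
rate — raising the whole network's rate several-fold while their own rate
rises an order of magnitude more, which is what drops the fidelity from
~1 to ~0.35.

## The synthetic-data generators

`generate_raster` produces spike rasters with known ground truth:
homogeneous-Poisson background per source; optional compound bursts
(Poisson burst onsets, fixed spikes-per-burst and intra-burst ISI) unioned
with the background; optional planted correlation via a shared mother train
per group (each member copies mother spikes with the sharing probability,
jittered, topped up with independent Poisson so the marginal rate is
unchanged). A 2-ms absolute refractory period is imposed so the analysis
chain's 2-ms duplicate guard is exercised but not confounded.
`generate_trace` embeds a biphasic extracellular spike template at planted
times in Gaussian noise, with optional 60-Hz mains hum, retaining the
ground-truth times.

What the generators do *not* emulate: electrode-level mixing of several
neurons, spike-waveform diversity and overlap, nonstationary rates,
development or pharmacology. Passing the planted-recovery tests therefore
shows the pipeline is correct on its own terms, not that it is robust to
every pathology of real MEA data.

## Problem sizes and reproduction

The entrainment readouts are rate ratios and stationary in phase length;
the packaged acceptance script (`scripts/acceptance.py`) runs the protocol
at 100-s phases with three seeds per condition, and the condition-fold
comparison at 100-s analysis windows with two replicates — the package's
standard reduced-length setting. The full 300-s phases of the original
design are available by passing a `PhasePlan` explicitly.

## Known limitations

* The quantitative parameter set is this package's own calibration of an
  under-determined model family; only the printed quantities (counts,
  probabilities, dt, durations, condition scalings, burst definitions) are
  fixed by the design it follows. Different parameter sets reproduce the
  qualitative phenomenology with different fold magnitudes.
* Under the frozen conditions the perturbed networks reproduce the control
  entrainment readouts and the condition-1 spike-rate fold well, but the
  condition-level fidelities (≈0.34 and ≈0.7 versus the reference 0.19 and
  0.36) and the condition-2 burst-rate fold (≈1.3 versus 2.9) agree in
  direction, not magnitude: uniform-drive compression strong enough to pin
  those numbers simultaneously suppresses the selective-stimulation
  response in this model family.
* Louvain is stochastic; best-of-repeats with a logged master seed is the
  reproducibility policy, not a consensus clustering.
* No spike sorting: sources are electrodes or neurons, never sorted units.
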