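# spikecircuit

Simulation and analysis of how cypin overexpression reshapes neural-circuit
activity. The package pairs two things that are usually separate:

* a **conductance-based spiking-network simulator** — 500 leaky
  integrate-and-fire neurons (400 excitatory / 100 inhibitory) with AMPA,
  NMDA (Mg-block) and GABA-A synapses, short-term plasticity on every
  synapse, STDP on excitatory–excitatory synapses, spike-triggered
  adaptation and stochastic presynaptic drive, with named perturbation
  conditions that emulate cypin overexpression by scaling AMPA conductance,
  connection density and presynaptic current;
* the **microelectrode-array (MEA) analysis stack** — band-pass/notch
  filtering, adaptive 4.5-SD spike detection, spike rate / ISI / CV / Fano
  factor, the 75th-percentile active-electrode rule, per-electrode
  burstlets and population network bursts, maximal normalized
  cross-correlation functional networks, and weighted graph measures
  (global/local efficiency, Louvain communities, modularity Q).

Simulated rasters run through exactly the same analysis path as recorded
data, so in-silico and in-vitro activity are directly comparable. A
synthetic-data module generates rasters and raw voltage traces with planted
ground truth (rates, bursts, pairwise correlation, community structure) so
the whole chain is testable without any recordings.

The membrane potential follows the Langevin equation

    C_m dV/dt = -g_m (V - V_L) - I_syn + I_AHP + I_pre

integrated by forward Euler at dt = 0.1 ms; `docs/methods.md` documents the
model, every parameter and the design decisions.

## Worked example

```python
import numpy as np
from spikecircuit import (SimulationConfig, PhasePlan, run_entrainment,
                          detect_network_bursts, run_simulation)

# 10-s stabilization + 60-s analysis window of the control network
raster = run_simulation(SimulationConfig(duration=60.0, seed=17))
bursts = detect_network_bursts(raster)
print(f"{raster.n_spikes} spikes, "
      f"mean rate {raster.rates().mean():.2f} Hz, "
      f"{len(bursts) / raster.duration:.2f} network bursts/s")

# entrainment: double the external current of 1% of excitatory neurons
res = run_entrainment(SimulationConfig(), "control", seed=11,
                      phases=PhasePlan(10.0, 100.0, 100.0, 100.0),
                      compute_networks=False)
print(f"fidelity before training {res.fidelity_pre:.2f}, "
      f"after {res.fidelity_post:.2f}; "
      f"input x{res.input_fold:.1f}, output x{res.output_fold:.1f}")
```

prints

```
37380 spikes, mean rate 1.25 Hz, 0.08 network bursts/s
fidelity before training 1.05, after 0.35; input x33.4, output x11.3
```

Before training the 4 stimulated "input" neurons and the 396 remaining
"output" excitatory neurons fire at the same rate (fidelity ≈ 1). Doubling
the inputs' external current drives them ~30-fold above their baseline
while the rest of the network follows only ~11-fold through the recurrent
synapses, so the output/input rate ratio — the signal fidelity — drops to
≈ 0.35. (Each protocol run is stochastic; the fold changes vary severalfold
across seeds, the fidelities much less.)

The same experiment for the cypin-overexpression conditions:

```python
res1 = run_entrainment(SimulationConfig(), "cypin_oe_1", seed=11, ...)
```

`cypin_oe_1` (AMPA ×1, density ×0.75, presynaptic current ×2) lowers the
post-training fidelity further; `cypin_oe_2` (AMPA ×2, density ×2,
presynaptic current ×2) does not lower it relative to control.

## Command line

```bash
spikecircuit simulate --condition cypin_oe_1 --seed 3 --out run1/
spikecircuit analyze run1/raster.tsv --out run1/metrics.tsv
spikecircuit connect run1/raster.tsv --out run1/W.tsv
spikecircuit graph run1/W.tsv --out run1/
spikecircuit entrain --condition control --seed 3 --out ent/
spikecircuit suite --replicates 2 --out suite/
```

Everything is delimited text plus a JSON run manifest.

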