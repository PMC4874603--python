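# pfcsim — a data-driven prefrontal cortex spiking network simulator

`pfcsim` builds and simulates a rodent prefrontal-cortex (PFC)
microcircuit whose every parameter comes from slice electrophysiology and
anatomy: heterogeneous simplified adaptive exponential integrate-and-fire
(simpAdEx) neurons of five types across layers 2/3 and 5, wired by
cell-type-specific connection probabilities with clustering and
reciprocity, and coupled through conductance-based AMPA/GABA_A/NMDA
synapses with Tsodyks–Markram short-term plasticity, transmission delays
and release failures.  Driven only by constant background currents, the
network settles into the asynchronous-irregular, fluctuation-driven
regime observed in vivo: most pyramidal cells sit well below threshold
and spike rarely; all irregularity is generated inside the network.

The package is for computational neuroscientists who want a
physiologically constrained yet cheap PFC model: one 30 s, 1000-neuron
simulation takes about a minute on one CPU core.

## The model in brief

Each neuron follows the simpAdEx equations

    C dV/dt = -g_L (V - E_L) + g_L Δ_T e^{(V - V_th)/Δ_T} + I - w  =  w_V - w

with a piecewise adaptation rule: `dw/dt = 0` far from the V-nullcline
`w_V`, nullcline-tracking `dw/dt = Θ(V_th - V)(1 - τ_m/τ_w)(dw_V/dV)(dV/dt)`
inside the band `|w - w_V| ≤ (τ_m/τ_w) w_V`, and a projection onto
`(1 - τ_m/τ_w) w_V` at the upper band edge.  Spikes (V crossing V_up)
reset V to V_r and increment w by b.  Parameters are drawn per cell from
per-type distributions (Gaussian / Gamma / exponential marginals).

Synaptic currents follow
`I_X = g_max s(V) Σ_k a_k (e^{-(t-t_k-τ_D)/τ_off} - e^{-(t-t_k-τ_D)/τ_on}) (V - E_rev)`
with the NMDA magnesium-block gate `s(V) = 1.08/(1 + 0.19 e^{-0.064V})`
and release efficacies `a_k` from the corrected Tsodyks–Markram
recursion.  Integration is second-order Runge-Kutta with a 0.05 ms
maximum step and exactly timed spike and delivery events (see
`docs/methods.md` for the numerical details and all modeling choices).

## Worked example

```python
import numpy as np
from pfcsim import BackgroundCurrents, build_network
from pfcsim.simulate import run
from pfcsim.experiments import resting_state_summary

graph = build_network(1000, seed=1)          # default single-column PFC
rec = run(graph, BackgroundCurrents.uniform(250.0, 200.0),  # pA: PC, IN
          duration=30_000.0, seed=2, record_cfg={"v_ids": "pc"})
s = resting_state_summary(graph, rec)
print(f"spiking cells (>10 spikes/30 s): {s['fraction_spiking']:.1f}%")
print(f"rheobase  spiking {s['rheobase_spiking']:.1f} pA"
      f" / silent {s['rheobase_nonspiking']:.1f} pA")
print(f"membrane fluctuation SD {s['vm_sd']:.2f} mV; "
      f"mean V - V_up {s['v_minus_threshold']:.1f} mV")
print(f"CV {s['cv']:.2f}, mean ISI {s['mean_isi']:.0f} ms, "
      f"CC(0) {s['cc0']:.4f}")
```

Output of this exact snippet:

```
spiking cells (>10 spikes/30 s): 30.6%
rheobase  spiking 4.4 pA / silent 66.6 pA
membrane fluctuation SD 3.55 mV; mean V - V_up -18.0 mV
CV 1.19, mean ISI 367 ms, CC(0) 0.0260
```

Read it as: under a third of the cells count as spiking over 30 s; the
cells that do spike have rheobases at the very low end of the
distribution while the silent majority needs ~66 pA to fire at all; the
average pyramidal membrane potential floats ~18 mV below the firing
threshold with ~3.6 mV fluctuations — the variance-driven regime — and
the spike trains are Poisson-like (CV ≈ 1) with near-zero pairwise
correlations.

Stimulus experiments (`pfcsim.experiments`) add input volleys: a
250-spike/5 ms volley onto 10% of L2/3 pyramidal cells evokes a
population response peaking ≈9 ms later in L2/3 and ≈16–18 ms later in
L5.  The `background` module estimates how large a surrounding network
must be for its synaptic input to replace the constant background
currents, and the `analysis` module holds the spike-train, membrane and
LFP statistics plus the subsampled Kolmogorov–Smirnov comparison
harness.

## Command line

```bash
pfcsim run --n-neurons 1000 --duration 30000 --seed 7 --out out.h5
pfcsim analyze --spikes out.h5 --against surrogate --report report.json
pfcsim scan-size --columns 1:15:2 --density 10000:90000:20000 --out currents.csv
```

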