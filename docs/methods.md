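# Model and methods

`pfcsim` simulates a rodent prefrontal-cortex (PFC) microcircuit at the
level of individual spiking neurons and conductance-based synapses, and
ships the statistics used to compare the simulated activity against awake
in-vivo recordings.  This note documents the model equations, the
parameter conventions, the numerical scheme, and the design choices made
where the construction was genuinely open.

## Single-neuron model (simpAdEx)

Each cell is a two-variable simplified adaptive exponential
integrate-and-fire neuron with membrane potential `V` and adaptation
current `w`:

    C dV/dt = -g_L (V - E_L) + g_L Δ_T exp((V - V_th)/Δ_T) + I - w
            = w_V(V, I) - w

`w_V` is the V-nullcline.  Instead of a linear ODE for `w`, the phase
plane is split into regimes by the band of half-width `(τ_m/τ_w)·w_V`
around the nullcline (`τ_m = C/g_L`):

* outside the band (`|w - w_V| > (τ_m/τ_w) w_V`): `dw/dt = 0` — during
  the fast voltage transit the slow adaptation is frozen;
* inside the band: `w` crawls along a scaled copy of the nullcline,
  `dw/dt = Θ(V_th - V)(1 - τ_m/τ_w)(dw_V/dV)(dV/dt)`;
* on reaching the upper boundary `w = (1 + τ_m/τ_w) w_V` from above, the
  state is projected to the lower edge `w → (1 - τ_m/τ_w) w_V`,
  approximating the fast relaxation across the nullcline.

A spike is registered when `V` crosses the absolute threshold `V_up`;
then `V → V_r` and `w → w + b`.  The construction yields closed-form
f-I curves (which is how the underlying parameter tables were fitted to
slice recordings) while reproducing AdEx-like spike patterns: adapting
pyramidal trains, fast-spiking responses, and so on.

Two regularizations keep sampled populations well-behaved:

* the band ratio `τ_m/τ_w` is capped at 0.95 for the rare sampled cells
  with `τ_w ≤ τ_m` (the band construction assumes slow adaptation);
* a hyperpolarization floor at −200 mV projects `w` onto the band
  boundary if an extreme adaptation transient would otherwise drive a
  deep, physiologically meaningless sawtooth.

The rheobase is the saddle-node current of the V-equation at frozen
adaptation, `I_rh = g_L (V_th - E_L) - g_L Δ_T`.  Cells sampled with
negative rheobase fire without input ("generator neurons").

## Heterogeneous populations

Intrinsic parameters are drawn per cell from per-type marginal
distributions (Gaussian for `C, g_L, E_L, V_r, V_th, V_up`; Gamma,
moment-matched, for `Δ_T` and `τ_w`; exponential, matched on the mean,
for `b`).  The source data were fitted as a multivariate (Box-Cox
transformed Gaussian) distribution whose covariances are not published;
this package therefore samples the marginals **independently**.  That
substitution matters: the rheobase, a nonlinear combination of four
parameters, acquires a heavier low/negative tail than correlated
sampling would give.  Consequences are flagged under *Limitations*.

Hard invariants (positive `C, g_L, Δ_T, τ_w`; `V_r < V_up`;
`V_th < V_up`) are enforced by resampling only the offending parameter
(the threshold pair jointly), preserving the unconstrained marginal
moments exactly.  The pair constraints shift the threshold-parameter
means by a few percent — the unavoidable price of conditioning strongly
overlapping marginals.

Ten groups populate one column: pyramidal cells (PC) and four
interneuron classes per layer (L2/3 and L5) — local basket cells (IN-L,
fast-spiking model), cross-layer bitufted cells (IN-CL), cross-column
basket cells (IN-CC, pyramidal-like intrinsic parameters but GABAergic)
and far-reaching Martinotti cells (IN-F).  Composition follows the
shipped fraction table (47% PC L2/3, 38% PC L5, 15% interneurons);
counts use largest-remainder rounding.

## Synapses

Receptor currents are conductance-based with double-exponential kinetics
(τ_on/τ_off: AMPA 1.4/10 ms, GABA_A 3/40 ms, NMDA 4.3/75 ms; reversal 0
mV for AMPA/NMDA, −70 mV for GABA_A) and an NMDA magnesium-block gate
`s(V) = 1.08 / (1 + 0.19 exp(-0.064 V))`.  Kernels are scaled so their
maximum is one, making `g_max` literally the peak conductance.  Every
excitatory contact carries an NMDA component at 1.09 × the AMPA peak
conductance, sharing the AMPA delay and presynaptic state.  Each
presynaptic spike fails to release with probability 0.3, one draw per
contact (AMPA and NMDA see the same vesicle).

Short-term plasticity follows the corrected Tsodyks–Markram recursion
with per-synapse `(U, τ_rec, τ_fac)` drawn from six class tables
(facilitating E1/I1, depressing E2/I2, combined E3/I3).  Classes are
assigned per connection from a probability map keyed by pre/post cell
kind.  Two conventions are switchable in config and their defaults were
deliberate choices:

* `g_unit: psp_mv` — the shipped connection table quotes synaptic
  strength as unitary PSP amplitudes in mV (its source literature's
  convention, and the table's own column header).  Strengths are
  converted to peak conductances through each postsynaptic type's
  passive unit response (linearized membrane convolved with the kernel);
  EPSPs are referenced at the postsynaptic resting potential, IPSPs at a
  −55 mV holding potential (GABA_A reverses near rest, so a resting
  reference would be degenerate).  The literal nS reading remains
  available (`g_unit: nS`) but produces a runaway high-rate network
  state with depolarizing net synaptic current, nothing like the
  low-rate fluctuation-driven regime the model is meant to operate in.
* `stp_normalized: true` — release amplitudes enter as `u_k R_k / U`, so
  a naive synapse's first PSP equals its calibration target exactly
  (with the raw `u_k R_k` convention a calibrated synapse's first PSP
  would be `U·g_max`, i.e. 4× below its own calibration).

The shipped STP map (PC→PC uniform over E1/E2/E3; PC→basket-type
depressing E2; PC→bitufted and PC→Martinotti facilitating E1; IN→PC
half I1, half I3; IN→IN depressing I2) is a reconstruction: the
source figure's per-pair probabilities were not recoverable, so the map
was assembled from the paired-recording literature and, among the
literature-plausible candidates, the variant retained is the one that
produces the documented network regime (low-rate fluctuation-driven
pyramidal firing with ~20–30% spiking cells, inhibition-dominated net
synaptic current, membrane-potential SD ≈ 3.3 mV).  Every alternative
stays reachable through the config.

## Wiring

Connections are Bernoulli per ordered cell-type pair with tabulated
probabilities (e.g. PC L2/3 → PC L2/3 at 0.139, strong L2/3→L5
feedforward at 0.233, dense IN-F → PC at 0.71).  Same-layer PC–PC
blocks additionally get:

* a **common-neighbor pass**: pair probability
  `p (1 + β n_common/⟨n_common⟩) / (1 + β)` with β = 1, resampled once —
  degree variance grows at fixed mean density (the clustering
  signature);
* a **reciprocity adjustment** to 47% bidirectional among connected
  pairs, converting unidirectional and bidirectional pairs into one
  another while conserving the directed edge count.

Interneuron-to-interneuron wiring uses the lumped within-layer rows
(0.25 in L2/3, 0.60 in L5); IN-CC inherits the IN-L rows (both are
basket cells).  Weights are log-normal (moment-matched per row), delays
Gaussian truncated at 0.1 ms.  In multi-column mode, cross-column
probability and weight decay as `exp(-d·L_C/l)` (`L_C` = 300 µm;
`l` = 114 µm for excitatory, 95 µm for inhibitory axons) and delays
scale as `(1 + d)`.  An LSPS utility (`lsps_rescale`) reproduces the
photostimulation-map rescaling under which the shipped table was
originally calibrated.

## Integration

A compiled (numba) core advances all neurons with the midpoint
second-order Runge-Kutta scheme at a maximum step of 0.05 ms.  Synaptic
conductances are pairs of exponential accumulators per receptor per
neuron, propagated with their exact solution.  Delayed deliveries sit in
a binary min-heap; spike times are located by linear interpolation of
the crossing of `V_up`, the reset is applied at the crossing and the
post-reset remainder of the step is integrated (keeping the scheme
second-order through resets), and deliveries are scheduled at
`t_cross + τ_D`.  Two stepping modes:

* `event_split=True`: every delivery terminates a step exactly at its
  arrival time (fully event-exact; step count grows with event count);
* `event_split=False` (production default): deliveries inside a step are
  injected analytically-exactly into the linear conductance states at
  their arrival times; the membrane step itself does not split.  Since
  kernels start at zero amplitude, the coupling error is an O(h) lag
  confined to the first ≤0.05 ms of each kernel rise.  The two modes are
  cross-checked spike-for-spike on small networks in the test suite.

All neurons start at `V = E_L`, `w = 0` (a warm-start override exists).
All stochasticity — build randomness, release failures, stimulus draws —
derives from user seeds; equal seeds give bit-identical runs.  A
divergence guard aborts if any `|V|` exceeds 1000 mV.

One 30 s, 1000-neuron simulation takes on the order of a minute of CPU.

## Background currents and their estimation

All cells receive constant, noise-free DC: 250 pA to pyramidal cells and
200 pA to interneurons by default (per-layer values configurable).  All
irregularity is generated inside the network.

The `background` module estimates which currents a *larger* surround
network would deliver: the expected input count per cell class is the
radial integral `2πD p_con ∫ x exp(-x/l) dx` over a 1 mm-high cylinder,
split into a within-column term (up to `L_C`) and a cross-column term
weighted by the fraction of neurons whose class projects beyond a column
(only PC L2/3, IN-CC and IN-F do; both fractions derive from the
composition table).  The printed source formula has a growing
exponential in this integral, which diverges; the decaying sign is
implemented, consistent with the stated exponential decay of
connectivity.  A lumped-Poisson simulation then drives one
composition-averaged neuron with event trains at the implied total rate
(steady-state short-term-plasticity efficacy at the per-input rate;
failures as thinning) and reports the time-averaged net synaptic
current.  Per-input rates default to the simulated network's own
per-class mean rates — self-consistency applied once, not iterated.

## Stimuli

A stimulus is a brief volley (`n_spikes` in a window, default 250 in
5 ms) from a virtual input population onto a random 10% of a layer's
pyramidal cells.  Each volley spike is carried by its own virtual unit
through a naive synapse per target (PC L2/3→PC L2/3 parameters with
`g_max` overridden; first-release efficacy; independent failures and
delays), so the volley is not attenuated by short-term depression.  By
default every unit contacts every selected target; `distribute=True`
sends each spike to a single random target.  The stimulus conductance is
a model-internal parameter in nS (it is the swept quantity of the
ignition experiments), not a PSP-table entry.

## Analysis

* Per-train mean ISI and CV, restricted to trains with ≥10 spikes
  (at 30 s this equals the >0.33 Hz "spiking neuron" definition).
* ISI autocorrelation with optional moving-average local-mean
  subtraction (the stationarity correction; simulated data are
  stationary by construction, so the global mean is the default), and a
  pooled half-width-at-half-maximum summary in ms.
* Zero-lag cross-correlation CC(0) between ISI-interpolated signals on a
  200 ms grid over jointly valid segments (a binned-count variant is
  provided; the bin width is config).
* The KS harness: repeated (100×) two-sample Kolmogorov–Smirnov tests on
  subsamples of 30, reporting mean D and p per statistic and the
  worst-case summary; the admissible-overlap criterion is D_KS < 0.4.
* LFP proxy: the summed synaptic current over all neurons (excitatory
  and inhibitory currents partially cancel), sampled at 1 kHz; Welch
  spectrum with log-log slope fits on 1–60 Hz and 60–200 Hz.
* Membrane fluctuation SD after excising a window around each spike
  (−2 ms to +10 ms by default — the data constrain only that spikes are
  removed).
* A surrogate generator reproducing the published summary moments of the
  reference recordings (CV ~ N(1.04, 0.33) truncated positive, mean ISI
  log-normal 570 ± 610 ms, CC(0) ~ N(2.4·10⁻⁴, 0.025)); it exists so the
  comparison harness is testable — it is a synthetic stand-in, not data.
  The published CC(0) dispersion is garbled in the available text
  ("± 2.5", impossible for a correlation); 0.025 was chosen as
  consistent with the published histograms and with the Gaussian-weight
  network's CC(0) = 0.017 being described as much more synchronized.

The subthreshold-distance statistic (`v_minus_threshold`) uses `V_up`,
which the source model treats as *the* firing threshold.  The membrane
fluctuation statistic averages over firing pyramidal cells (the
comparison data are patch-clamp recordings from putative pyramidal
cells).

## What the defaults reproduce, and known limitations

At the default scale (N = 1000, 30 s, 250/200 pA) the model operates in
the documented regime: ~20–30% of cells spike more than 10 times in
30 s, the mean pyramidal membrane potential sits ≈17 mV below threshold
with fluctuation SD ≈ 3.3 mV, CV near one with near-zero pairwise
correlations, a 1/f-like low-frequency LFP spectrum with a steeper
high-frequency tail, and volley propagation latencies of ≈9 ms (L2/3)
and ≈16–18 ms (L5).

Known limitations, all consequences of information unavailable to this
build:

* **Independent marginals.**  The missing parameter covariances fatten
  the low-rheobase tail, so the *spiking* subpopulation's mean rheobase
  comes out near zero instead of ≈43 pA (the non-spiking mean
  reproduces), and a disinhibited network has no stable quiet state —
  generator neurons ignite it spontaneously.
* **Ignition experiments.**  With the distributed stimulus at
  conductance 2 nS and a seed-matched no-stimulus control subtraction,
  the reduced-inhibition evoked counts land at the published magnitude
  (L2/3 ≈ 470 vs 404 ± 116; L5 ≈ 170 vs 118 ± 33 — the L5 mean sits just
  above the printed dispersion).  At conductance 20 the laminar
  asymmetry reproduces categorically on every seed (L2/3 ignition
  recruits more of the network than L5 ignition, which never sweeps it),
  but L2/3 ignition recruits ~60% of the cells rather than all of them —
  the mV-calibrated conductances cannot recruit the high-rheobase tail.
* **Gaussian-weight control.**  Replacing log-normal weights by
  truncated Gaussians of equal moments barely changes CV/CC(0) here,
  rather than inducing the published strong bursting (CV 1.81); the
  effect evidently requires the original (nS-scale) weight magnitudes,
  under which this build has no in-vivo-like baseline at all.
* The LFP proxy ignores extracellular space and active currents; the
  surrogate reference distributions stand in for unavailable recordings,
  so agreement with them shows harness correctness, not physiological
  validity.
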