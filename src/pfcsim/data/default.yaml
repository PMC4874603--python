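# Default model configuration: single-column rodent PFC microcircuit.
# Units: capacitance pF, conductance nS, voltage mV, time ms, current pA,
# length um. All distribution entries are [mean, sd].

neurons:
  # Distribution family per intrinsic parameter. Gamma and exponential
  # families are moment-matched to the given mean/sd.
  families:
    C: gaussian
    g_L: gaussian
    E_L: gaussian
    Delta_T: gamma
    tau_w: gamma
    b: exponential
    V_r: gaussian
    V_th: gaussian
    V_up: gaussian
  types:
    PC-L23: {C: [164.96, 59.11], g_L: [7.04, 1.72], E_L: [-85.00, 5.40],
             Delta_T: [21.44, 6.42], tau_w: [121.78, 41.19], b: [7.29, 6.80],
             V_r: [-118.20, 38.14], V_th: [-52.40, 5.43], V_up: [-45.91, 7.22]}
    FS:     {C: [59.58, 10.59], g_L: [5.34, 0.91], E_L: [-85.15, 5.81],
             Delta_T: [19.58, 8.50], tau_w: [15.15, 2.71], b: [34.87, 37.88],
             V_r: [-90.16, 15.16], V_th: [-58.79, 9.82], V_up: [-51.01, 5.59]}
    BT:     {C: [79.36, 14.83], g_L: [3.99, 0.51], E_L: [-84.63, 4.71],
             Delta_T: [19.02, 4.08], tau_w: [43.56, 21.89], b: [6.65, 7.19],
             V_r: [-152.67, 49.15], V_th: [-59.95, 4.67], V_up: [-55.46, 4.39]}
    MC:     {C: [81.12, 28.96], g_L: [2.98, 0.55], E_L: [-72.20, 7.64],
             Delta_T: [22.30, 10.44], tau_w: [60.13, 15.05], b: [5.37, 5.78],
             V_r: [-55.89, 9.65], V_th: [-38.01, 6.03], V_up: [-36.94, 2.55]}
    PC-L5:  {C: [251.81, 82.61], g_L: [7.62, 2.09], E_L: [-80.57, 6.71],
             Delta_T: [24.47, 5.96], tau_w: [107.48, 64.08], b: [8.27, 12.66],
             V_r: [-69.98, 14.45], V_th: [-48.69, 7.18], V_up: [-44.12, 7.28]}

# Cell-type composition of one column. IN-CC (cross-column basket cells)
# use the pyramidal intrinsic-parameter distribution of their layer but are
# GABAergic.
populations:
  L23:
    PC:    {fraction: 0.470, model: PC-L23, excitatory: true}
    IN-L:  {fraction: 0.031, model: FS,     excitatory: false}
    IN-CL: {fraction: 0.026, model: BT,     excitatory: false}
    IN-CC: {fraction: 0.026, model: PC-L23, excitatory: false}
    IN-F:  {fraction: 0.021, model: MC,     excitatory: false}
  L5:
    PC:    {fraction: 0.380, model: PC-L5,  excitatory: true}
    IN-L:  {fraction: 0.005, model: FS,     excitatory: false}
    IN-CL: {fraction: 0.005, model: BT,     excitatory: false}
    IN-CC: {fraction: 0.018, model: PC-L5,  excitatory: false}
    IN-F:  {fraction: 0.018, model: MC,     excitatory: false}

# Pairwise connection table. pre/post use "LAYER/TYPE"; "IN" alone lumps all
# interneuron subtypes of that layer. Missing IN-CC rows inherit IN-L rows
# (both are basket cells). g_max quotes unitary PSP amplitude targets in mV
# (see synapses.g_unit), drawn log-normally; tau_D is Gaussian.
connectivity:
  - {pre: L23/PC,    post: L23/PC,    p_con: 0.139, g_max: [0.84, 0.49], tau_D: [1.55, 0.31]}
  - {pre: L23/PC,    post: L5/PC,     p_con: 0.233, g_max: [0.95, 0.39], tau_D: [1.91, 0.17]}
  - {pre: L5/PC,     post: L23/PC,    p_con: 0.045, g_max: [0.84, 0.28], tau_D: [2.75, 0.18]}
  - {pre: L5/PC,     post: L5/PC,     p_con: 0.081, g_max: [0.88, 0.67], tau_D: [1.56, 0.44]}
  - {pre: L23/PC,    post: L23/IN-L,  p_con: 0.325, g_max: [1.34, 1.09], tau_D: [0.96, 0.25]}
  - {pre: L23/PC,    post: L23/IN-CL, p_con: 0.159, g_max: [0.47, 0.20], tau_D: [0.96, 0.25]}
  - {pre: L23/PC,    post: L23/IN-F,  p_con: 0.290, g_max: [0.25, 0.20], tau_D: [0.96, 0.25]}
  - {pre: L23/PC,    post: L5/IN-L,   p_con: 0.087, g_max: [0.77, 0.86], tau_D: [1.18, 0.13]}
  - {pre: L23/PC,    post: L5/IN-CL,  p_con: 0.080, g_max: [0.27, 0.16], tau_D: [1.18, 0.13]}
  - {pre: L23/PC,    post: L5/IN-F,   p_con: 0.150, g_max: [0.14, 0.16], tau_D: [1.18, 0.13]}
  - {pre: L5/PC,     post: L23/IN-L,  p_con: 0.188, g_max: [1.52, 0.63], tau_D: [1.05, 0.08]}
  - {pre: L5/PC,     post: L23/IN-CL, p_con: 0.092, g_max: [0.53, 0.12], tau_D: [1.05, 0.08]}
  - {pre: L5/PC,     post: L23/IN-F,  p_con: 0.168, g_max: [0.28, 0.12], tau_D: [1.05, 0.08]}
  - {pre: L5/PC,     post: L5/IN-L,   p_con: 0.333, g_max: [1.74, 1.12], tau_D: [0.60, 0.20]}
  - {pre: L5/PC,     post: L5/IN-CL,  p_con: 0.080, g_max: [0.88, 0.70], tau_D: [0.60, 0.20]}
  - {pre: L5/PC,     post: L5/IN-F,   p_con: 0.362, g_max: [0.28, 0.30], tau_D: [0.60, 0.20]}
  - {pre: L23/IN-L,  post: L23/PC,    p_con: 0.466, g_max: [2.30, 1.98], tau_D: [1.25, 0.18]}
  - {pre: L23/IN-CL, post: L23/PC,    p_con: 0.301, g_max: [0.13, 0.48], tau_D: [1.25, 0.18]}
  - {pre: L23/IN-F,  post: L23/PC,    p_con: 0.710, g_max: [1.91, 3.83], tau_D: [1.25, 0.18]}
  - {pre: L23/IN-L,  post: L5/PC,     p_con: 0.217, g_max: [1.07, 0.92], tau_D: [1.54, 0.10]}
  - {pre: L23/IN-CL, post: L5/PC,     p_con: 0.140, g_max: [0.06, 0.22], tau_D: [1.54, 0.10]}
  - {pre: L23/IN-F,  post: L5/PC,     p_con: 0.330, g_max: [0.89, 1.78], tau_D: [1.54, 0.10]}
  - {pre: L5/IN-L,   post: L23/PC,    p_con: 0.039, g_max: [0.10, 0.01], tau_D: [1.44, 0.04]}
  - {pre: L5/IN-CL,  post: L23/PC,    p_con: 0.027, g_max: [0.04, 0.01], tau_D: [1.44, 0.04]}
  - {pre: L5/IN-F,   post: L23/PC,    p_con: 0.040, g_max: [0.07, 0.06], tau_D: [1.44, 0.04]}
  - {pre: L5/IN-L,   post: L5/PC,     p_con: 0.274, g_max: [0.69, 0.10], tau_D: [0.82, 0.09]}
  - {pre: L5/IN-CL,  post: L5/PC,     p_con: 0.173, g_max: [0.30, 0.05], tau_D: [0.82, 0.09]}
  - {pre: L5/IN-F,   post: L5/PC,     p_con: 0.282, g_max: [0.50, 0.40], tau_D: [0.82, 0.09]}
  - {pre: L23/IN,    post: L23/IN,    p_con: 0.250, g_max: [1.35, 0.35], tau_D: [1.10, 0.40]}
  - {pre: L5/IN,     post: L5/IN,     p_con: 0.600, g_max: [1.35, 0.35], tau_D: [1.11, 0.40]}

synapses:
  kinetics:
    AMPA:   {tau_on: 1.4, tau_off: 10.0, E_rev: 0.0}
    GABA_A: {tau_on: 3.0, tau_off: 40.0, E_rev: -70.0}
    NMDA:   {tau_on: 4.3, tau_off: 75.0, E_rev: 0.0}
  nmda_ratio: 1.09      # NMDA peak conductance = 1.09 x AMPA
  p_fail: 0.30          # release-failure probability per spike
  delay_min: 0.1        # truncation floor for Gaussian delays (ms)
  peak_normalized: true # scale double-exponential so its maximum is 1
  g_unit: psp_mv        # connection-table g_max entries are unitary PSP
                        # amplitudes (mV), converted to nS per postsynaptic
                        # type; set "nS" to read them as conductances
  ipsp_holding: -55.0   # holding potential for the IPSP conversion (mV)
  stp_normalized: true  # scale release efficacies by 1/U so a naive
                        # synapse's first PSP equals its g_max calibration

stp:
  classes:
    E1: {U: [0.28, 0.02], tau_rec: [194, 18],  tau_fac: [507, 37]}
    E2: {U: [0.25, 0.02], tau_rec: [671, 17],  tau_fac: [17, 5]}
    E3: {U: [0.29, 0.03], tau_rec: [329, 53],  tau_fac: [326, 66]}
    I1: {U: [0.16, 0.10], tau_rec: [45, 21],   tau_fac: [376, 253]}
    I2: {U: [0.25, 0.13], tau_rec: [706, 405], tau_fac: [21, 9]}
    I3: {U: [0.32, 0.14], tau_rec: [144, 80],  tau_fac: [62, 31]}
  # Class-probability map keyed by pre/post kind (PC, IN-L, IN-CL, IN-CC,
  # IN-F), by class (PC, IN) or the wildcard "*"; the most specific key
  # wins.  Facilitation-leaning inhibition onto pyramidal cells and
  # depressing basket-type synapses (PC->fast-spiking, IN->IN) follow the
  # paired-recording literature.
  map:
    PC->PC:    {E1: 0.334, E2: 0.333, E3: 0.333}
    PC->IN-L:  {E2: 1.0}
    PC->IN-CC: {E2: 1.0}
    PC->IN-CL: {E1: 1.0}
    PC->IN-F:  {E1: 1.0}
    IN->PC:    {I1: 0.5, I3: 0.5}
    IN->IN:    {I2: 1.0}

wiring:
  reciprocity: 0.47          # target reciprocal fraction among PC-PC pairs (within layer)
  common_neighbor_beta: 1.0  # linear common-neighbor boost coefficient

space:
  L_C: 300.0   # column width (um)
  l_E: 114.0   # spatial decay constant, excitatory projections (um)
  l_I: 95.0    # spatial decay constant, inhibitory projections (um)

background:
  I_ex: 250.0   # constant DC onto pyramidal cells (pA)
  I_inh: 200.0  # constant DC onto interneurons (pA)
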