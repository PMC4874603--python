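"""Canned reproduction experiments over the default-configuration network.

Each function builds its own network(s) from a seed and returns the
summary quantities of one published-protocol experiment: the resting-state
run, the layer-propagation volley, the reduced-inhibition ignition test
and the Gaussian-weight control.  The test suite and the reproduction
script both run through these entry points.
"""

from __future__ import annotations

import numpy as np

from .analysis import (
    evoked_latency,
    evoked_spike_count,
    isi_statistics,
    population_cc0,
    vm_fluctuation_sd,
)
from .network import build_network
from .neuron import rheobase
from .simulate import BackgroundCurrents, StimulusSpec, run

DEFAULT_BG = BackgroundCurrents.uniform(250.0, 200.0)
RATE_CUT_HZ = 10.0 / 30.0  # "spiking neuron": more than 10 spikes in 30 s


def default_run(seed: int, duration: float = 30_000.0, n_neurons: int = 1000,
                weight_dist: str = "lognormal", record_v: bool = True):
    """Build and simulate the standard single-column network."""
    graph = build_network(n_neurons, seed=seed, weight_dist=weight_dist)
    rec = run(graph, DEFAULT_BG, duration, seed=seed + 1,
              record_cfg={"v_ids": "pc"} if record_v else None)
    return graph, rec


def resting_state_summary(graph, rec) -> dict:
    """Spiking fraction, rheobase split, membrane statistics of one run.

    Keys: fraction_spiking (percent), rheobase_spiking / rheobase_nonspiking
    (pA), vm_sd (mV, mean over firing pyramidal cells), v_minus_threshold
    (mV, mean over pyramidal cells), cv, mean_isi, cc0.
    """
    n = graph.n_neurons
    dur_s = rec.duration / 1000.0
    counts = rec.spike_counts(n)
    spiking = counts / dur_s > RATE_CUT_HZ
    rheo = np.asarray([rheobase(nrn) for nrn in graph.neurons])

    trains = rec.spike_trains(n)
    cvs, mean_isis = [], []
    for t in trains:
        st = isi_statistics(t)
        if st.included:
            cvs.append(st.cv)
            mean_isis.append(st.mean_isi)
    cc0 = population_cc0(trains, n_pairs=500, bin_ms=200.0,
                         t_range=(0.0, rec.duration), seed=0)

    vup = graph.neuron_array("V_up")
    sds, dists = [], []
    for j, nid in enumerate(rec.v_ids):
        dists.append(rec.V[j].mean() - vup[nid])
        if counts[nid] > 0:
            sds.append(vm_fluctuation_sd(rec.V[j], rec.t_grid, trains[nid]))
    return {
        "fraction_spiking": 100.0 * spiking.mean(),
        "rheobase_spiking": float(rheo[spiking].mean()) if spiking.any() else np.nan,
        "rheobase_nonspiking": float(rheo[~spiking].mean()) if (~spiking).any() else np.nan,
        "vm_sd": float(np.mean(sds)) if sds else np.nan,
        "v_minus_threshold": float(np.mean(dists)) if dists else np.nan,
        "cv": float(np.mean(cvs)) if cvs else np.nan,
        "mean_isi": float(np.mean(mean_isis)) if mean_isis else np.nan,
        "cc0": float(cc0.mean()) if len(cc0) else np.nan,
        "n_spiking_trains": len(cvs),
    }


def propagation_latencies(seed: int, n_volleys: int = 6,
                          spacing: float = 1000.0, onset0: float = 1500.0):
    """Volley-evoked population latencies in L2/3 and L5 (ms).

    One network run carrying ``n_volleys`` repetitions of the standard
    250-spike/5 ms stimulus onto 10% of L2/3 pyramidal cells; the latency
    is the time from volley onset to the smoothed population-PSTH peak of
    each layer's pyramidal cells.
    """
    graph = build_network(1000, seed=seed)
    onsets = [onset0 + spacing * k for k in range(n_volleys)]
    stims = [StimulusSpec(n_spikes=250, window=(t0, t0 + 5.0), seed=seed + k)
             for k, t0 in enumerate(onsets)]
    rec = run(graph, DEFAULT_BG, onsets[-1] + 500.0, stimuli=stims,
              seed=seed + 101)
    m23 = np.isin(rec.spike_neuron, graph.layout.ids("L23", "PC"))
    m5 = np.isin(rec.spike_neuron, graph.layout.ids("L5", "PC"))
    lat23, lat5 = [], []
    for t0 in onsets:
        l1 = evoked_latency(rec.spike_t[m23], t0)
        l2 = evoked_latency(rec.spike_t[m5], t0)
        if l1 is not None:
            lat23.append(l1)
        if l2 is not None:
            lat5.append(l2)
    return np.asarray(lat23), np.asarray(lat5)


def reduced_inhibition_count(seed: int, layer: str, g_stim: float = 2.0,
                             n_spikes: int = 500, window: float = 200.0,
                             inhibition_scale: float = 0.3) -> float:
    """Evoked network spikes for the disinhibited ignition protocol.

    Inhibitory weights are scaled to ``inhibition_scale``; a strong volley
    (``n_spikes`` in 5 ms, stimulus conductance ``g_stim`` nS) targets 10%
    of the given layer's pyramidal cells at t = 1 s.  The evoked count is
    the spike count in the post-onset window minus the expectation from a
    seed-matched no-stimulus control run.
    """
    graph = build_network(1000, seed=seed).scale_inhibition(inhibition_scale)
    stim = StimulusSpec(n_spikes=n_spikes, window=(1000.0, 1005.0),
                        population=(layer, "PC"), g_max_stim=g_stim,
                        distribute=True, seed=seed)
    rec = run(graph, DEFAULT_BG, 1000.0 + window + 100.0, stimuli=[stim],
              seed=seed + 55)
    ctrl = run(graph, DEFAULT_BG, 1000.0 + window + 100.0, seed=seed + 55)
    n_stim = evoked_spike_count(rec, 1000.0, window=window)
    n_ctrl = evoked_spike_count(ctrl, 1000.0, window=window)
    return max(n_stim - n_ctrl, 0.0)


def ignition_recruitment(seed: int, layer: str, g_stim: float = 20.0,
                         window: float = 500.0) -> float:
    """Fraction of all neurons recruited by the strong ignition stimulus."""
    graph = build_network(1000, seed=seed).scale_inhibition(0.3)
    stim = StimulusSpec(n_spikes=500, window=(1000.0, 1005.0),
                        population=(layer, "PC"), g_max_stim=g_stim,
                        distribute=True, seed=seed)
    rec = run(graph, DEFAULT_BG, 1000.0 + window, stimuli=[stim],
              seed=seed + 77)
    sel = (rec.spike_t >= 1000.0) & (rec.spike_t < 1000.0 + window)
    return len(np.unique(rec.spike_neuron[sel])) / graph.n_neurons


def gaussian_weight_control(seed: int, duration: float = 30_000.0) -> dict:
    """CV and CC(0) of the normal-weight (equal mean/SD) control network."""
    graph, rec = default_run(seed, duration=duration, weight_dist="normal",
                             record_v=False)
    trains = rec.spike_trains(graph.n_neurons)
    cvs = [isi_statistics(t).cv for t in trains
           if isi_statistics(t).included]
    cc0 = population_cc0(trains, n_pairs=500, bin_ms=200.0,
                         t_range=(0.0, duration), seed=0)
    return {"cv": float(np.mean(cvs)) if cvs else np.nan,
            "cc0": float(cc0.mean()) if len(cc0) else np.nan,
            "n_spiking_trains": len(cvs)}
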