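"""Network simulation driver: background currents, stimuli, recording.

``run`` wraps the compiled engine; ``ReferenceSimulator`` is a transparent
pure-Python integrator with identical semantics (used as an oracle on
small problems).  All neurons start at V(0) = E_L, w(0) = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _engine
from .network import NetworkGraph
from .synapse import STPParams, STPState, kernel_norm, stp_efficacy


@dataclass
class BackgroundCurrents:
    """Constant (noise-free) DC drive per layer and cell class, pA."""

    I_ex_L23: float = 250.0
    I_ex_L5: float = 250.0
    I_inh_L23: float = 200.0
    I_inh_L5: float = 200.0

    @classmethod
    def uniform(cls, I_ex: float, I_inh: float) -> "BackgroundCurrents":
        return cls(I_ex, I_ex, I_inh, I_inh)

    def per_neuron(self, layout) -> np.ndarray:
        out = np.empty(layout.N_total)
        for gi, (layer, kind) in enumerate(layout.groups):
            sel = layout.group_index == gi
            if kind == "PC":
                out[sel] = self.I_ex_L23 if layer == "L23" else self.I_ex_L5
            else:
                out[sel] = self.I_inh_L23 if layer == "L23" else self.I_inh_L5
        return out


@dataclass
class StimulusSpec:
    """A brief high-rate volley from a virtual input population.

    ``n_spikes`` spikes are drawn uniformly in ``window`` and delivered,
    through one stimulus synapse per target (AMPA + NMDA companion, with
    short-term plasticity and release failures), to a random ``fraction``
    of the named population.
    """

    n_spikes: int = 250
    window: tuple[float, float] = (0.0, 5.0)
    population: tuple[str, str] = ("L23", "PC")
    fraction: float = 0.1
    g_max_stim: float | None = None  # default: PC L2/3 -> PC L2/3 table mean
    distribute: bool = False         # True: each volley spike contacts one target only
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.window[1] > self.window[0]:
            raise ValueError("stimulus window must have positive length")
        if not 0 < self.fraction <= 1:
            raise ValueError("target fraction must lie in (0, 1]")


@dataclass
class RecordingSet:
    """Simulation output: spikes, sampled voltages, LFP proxy, metadata."""

    duration: float
    spike_neuron: np.ndarray          # neuron id per spike, time-ordered
    spike_t: np.ndarray               # spike time (ms)
    v_ids: np.ndarray                 # neurons with recorded voltage
    V: np.ndarray                     # float32, (len(v_ids), n_samples)
    t_grid: np.ndarray                # sample times (ms)
    lfp: np.ndarray                   # summed synaptic current (pA)
    isyn_mean: np.ndarray             # time-averaged synaptic current per neuron
    metadata: dict = field(default_factory=dict)

    def spike_trains(self, n_neurons: int | None = None) -> list[np.ndarray]:
        n = n_neurons or (int(self.spike_neuron.max()) + 1 if len(self.spike_neuron) else 0)
        trains = [[] for _ in range(n)]
        for i, t in zip(self.spike_neuron, self.spike_t):
            trains[i].append(t)
        return [np.asarray(tr) for tr in trains]

    def spike_counts(self, n_neurons: int) -> np.ndarray:
        return np.bincount(self.spike_neuron, minlength=n_neurons)

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["duration"] = self.duration
            for k, v in self.metadata.items():
                f.attrs[k] = v
            f.create_dataset("spike_neuron", data=self.spike_neuron)
            f.create_dataset("spike_t", data=self.spike_t)
            f.create_dataset("v_ids", data=self.v_ids)
            f.create_dataset("V", data=self.V, compression="gzip")
            f.create_dataset("t_grid", data=self.t_grid)
            f.create_dataset("lfp", data=self.lfp)
            f.create_dataset("isyn_mean", data=self.isyn_mean)

    @classmethod
    def load(cls, path) -> "RecordingSet":
        import h5py

        with h5py.File(path, "r") as f:
            meta = {k: f.attrs[k] for k in f.attrs if k != "duration"}
            return cls(
                duration=float(f.attrs["duration"]),
                spike_neuron=f["spike_neuron"][:],
                spike_t=f["spike_t"][:],
                v_ids=f["v_ids"][:],
                V=f["V"][:],
                t_grid=f["t_grid"][:],
                lfp=f["lfp"][:],
                isyn_mean=f["isyn_mean"][:],
                metadata=meta,
            )


# ---------------------------------------------------------------------------
# stimulus construction


def make_stimulus(
    spec: StimulusSpec, graph: NetworkGraph, rng: np.random.Generator | None = None
):
    """Expand a stimulus into exact delivery events.

    Returns ``(ext_t, ext_post, ext_gA, ext_gG, ext_gN, volley_times,
    targets)``; the GABA amplitudes are zero (the virtual input population
    is excitatory).
    The volley is carried by one virtual input unit per spike; by default
    every unit contacts every selected target, with ``distribute`` each
    unit contacts one randomly chosen target.  Every contact is a naive synapse (parameters
    follow the PC L2/3 -> PC L2/3 table row with ``g_max`` overridden;
    first-release efficacy; independent release failures and delays), so a
    many-unit volley is not attenuated by short-term depression.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    cfg = graph.config
    layout = graph.layout
    pool = layout.ids(*spec.population)
    if len(pool) == 0:
        raise ValueError(f"empty target population {spec.population}")
    n_tgt = max(1, int(round(spec.fraction * len(pool))))
    targets = rng.choice(pool, size=n_tgt, replace=False)

    t0, t1 = spec.window
    volley = np.sort(rng.uniform(t0, t1, spec.n_spikes))

    row = next(r for r in cfg["connectivity"]
               if r["pre"] == "L23/PC" and r["post"] == "L23/PC")
    # an explicit g_max_stim is a model-internal conductance in nS (the
    # swept quantity of the ignition experiments); the default mimics the
    # unitary PC L2/3 -> PC L2/3 synapse, so the table value is converted
    # like any other connection entry
    if spec.g_max_stim is not None:
        g_stim = float(spec.g_max_stim)
    else:
        from .network import _g_scale, conductance_calibration

        calib = conductance_calibration(cfg)
        post_model = cfg["populations"][spec.population[0]][spec.population[1]]["model"]
        g_stim = float(row["g_max"][0]) * _g_scale(cfg, calib, True, post_model)
    nmda_ratio = float(cfg["synapses"]["nmda_ratio"])
    p_fail = float(cfg["synapses"]["p_fail"])
    delay_min = float(cfg["synapses"]["delay_min"])

    from .network import _resolve_stp_class
    from .synapse import sample_stp_params

    normalized = bool(cfg["synapses"].get("stp_normalized", True))
    ts, posts, gAs, gNs = [], [], [], []
    for t_sp in volley:
        recipients = ([targets[rng.integers(len(targets))]] if spec.distribute
                      else targets)
        for tgt in recipients:
            delay = max(float(rng.normal(*row["tau_D"])), delay_min)
            if normalized:
                a = 1.0  # first release of a calibrated synapse
            else:
                cls = _resolve_stp_class("PC", "PC", cfg["stp"], rng)
                a = sample_stp_params(cls, cfg["stp"], rng).U
            if rng.random() >= p_fail:
                ts.append(t_sp + delay)
                posts.append(tgt)
                gAs.append(a * g_stim)
                gNs.append(a * g_stim * nmda_ratio)
    return (np.asarray(ts, dtype=float), np.asarray(posts, dtype=np.int64),
            np.asarray(gAs, dtype=float), np.zeros(len(ts)),
            np.asarray(gNs, dtype=float), volley, targets)


# ---------------------------------------------------------------------------
# engine packing and the main entry point


def _pack_graph(graph: NetworkGraph):
    order = np.argsort(graph.pre, kind="stable")
    N = graph.n_neurons
    out_ptr = np.zeros(N + 1, dtype=np.int64)
    np.add.at(out_ptr[1:], graph.pre, 1)
    out_ptr = np.cumsum(out_ptr)
    # with normalized short-term dynamics the first release of a naive
    # synapse produces g_max on average (efficacies enter as u*R/U_class;
    # the class-mean baseline utilization avoids amplifying the tail of
    # tiny per-synapse U draws)
    if graph.config["synapses"].get("stp_normalized", True) and len(graph.U):
        class_u = {name: row["U"][0]
                   for name, row in graph.config["stp"]["classes"].items()}
        u_scale = 1.0 / np.array([class_u[c] for c in graph.stp_class])
    else:
        u_scale = np.ones(len(graph.U))
    arrays = dict(
        out_ptr=out_ptr,
        out_idx=order.astype(np.int64),
        syn_post=graph.post.astype(np.int64),
        syn_gA=graph.g_ampa.astype(float) * u_scale,
        syn_gG=graph.g_gaba.astype(float) * u_scale,
        syn_gN=graph.g_nmda.astype(float) * u_scale,
        syn_delay=graph.delay.astype(float),
        syn_U=graph.U.astype(float),
        syn_taurec=graph.tau_rec.astype(float),
        syn_taufac=graph.tau_fac.astype(float),
        syn_pfail=graph.p_fail.astype(float),
    )
    for name in ("C", "g_L", "E_L", "Delta_T", "tau_w", "b", "V_r", "V_th", "V_up"):
        arrays[name] = graph.neuron_array(name)
    return arrays


def _kinetics(cfg):
    kin = cfg["synapses"]["kinetics"]
    out = {}
    for rec, key in (("AMPA", "A"), ("GABA_A", "G"), ("NMDA", "N")):
        out[f"tau_on{key}"] = float(kin[rec]["tau_on"])
        out[f"tau_off{key}"] = float(kin[rec]["tau_off"])
        out[f"Erev{key}"] = float(kin[rec]["E_rev"])
        if cfg["synapses"].get("peak_normalized", True):
            out[f"norm{key}"] = kernel_norm(kin[rec]["tau_on"], kin[rec]["tau_off"])
        else:
            out[f"norm{key}"] = 1.0
    return out


def run(
    graph: NetworkGraph,
    bg: BackgroundCurrents,
    duration: float,
    stimuli: list[StimulusSpec] | None = None,
    record_cfg: dict | None = None,
    seed: int = 0,
    dt_max: float = 0.05,
    event_split: bool = False,
    initial_state: tuple[np.ndarray, np.ndarray] | None = None,
) -> RecordingSet:
    """Simulate the network for ``duration`` ms.

    All stochasticity during the run (release failures, stimulus spike
    times and targets) derives from ``seed``; two runs with the same seed
    are bit-identical.  ``record_cfg`` keys: ``v_ids`` (array of neuron
    ids, "pc", "all" or None) and ``sample_dt`` (ms, default 1.0).
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    record_cfg = record_cfg or {}
    sample_dt = float(record_cfg.get("sample_dt", 1.0))
    v_sel = record_cfg.get("v_ids", None)
    if isinstance(v_sel, str):
        if v_sel == "pc":
            v_ids = graph.layout.ids(kind="PC")
        elif v_sel == "all":
            v_ids = np.arange(graph.n_neurons)
        else:
            raise ValueError(f"unknown v_ids selector {v_sel!r}")
    elif v_sel is None:
        v_ids = np.empty(0, dtype=np.int64)
    else:
        v_ids = np.asarray(v_sel, dtype=np.int64)

    t_grid = np.arange(int(round(duration / sample_dt)) + 1) * sample_dt
    if duration == 0:
        return RecordingSet(
            duration=0.0,
            spike_neuron=np.empty(0, dtype=np.int64),
            spike_t=np.empty(0),
            v_ids=v_ids,
            V=np.tile(graph.neuron_array("E_L")[v_ids, None].astype(np.float32), 1),
            t_grid=t_grid,
            lfp=np.zeros(1),
            isyn_mean=np.zeros(graph.n_neurons),
            metadata={"seed": seed},
        )

    rng = np.random.default_rng(seed)
    ext_parts = [make_stimulus(s, graph, np.random.default_rng(
        [seed, s.seed, k])) for k, s in enumerate(stimuli or [])]
    extra = record_cfg.get("external_events")
    if extra is not None:
        ext_parts = ext_parts + [extra]
    if ext_parts:
        ext_t = np.concatenate([np.asarray(p[0], dtype=float) for p in ext_parts])
        ext_post = np.concatenate([np.asarray(p[1], dtype=np.int64) for p in ext_parts])
        ext_gA = np.concatenate([np.asarray(p[2], dtype=float) for p in ext_parts])
        ext_gG = np.concatenate([np.asarray(p[3], dtype=float) for p in ext_parts])
        ext_gN = np.concatenate([np.asarray(p[4], dtype=float) for p in ext_parts])
    else:
        ext_t = np.empty(0)
        ext_post = np.empty(0, dtype=np.int64)
        ext_gA = np.empty(0)
        ext_gG = np.empty(0)
        ext_gN = np.empty(0)

    arrays = _pack_graph(graph)
    kin = _kinetics(graph.config)
    engine_seed = int(rng.integers(0, 2**31 - 1))

    status, t_end, sp_nrn, sp_t, Vrec, lfp, isyn_int, V, w = _engine.run_core(
        arrays["C"], arrays["g_L"], arrays["E_L"], arrays["Delta_T"],
        arrays["tau_w"], arrays["b"], arrays["V_r"], arrays["V_th"],
        arrays["V_up"], bg.per_neuron(graph.layout),
        arrays["out_ptr"], arrays["out_idx"], arrays["syn_post"],
        arrays["syn_gA"], arrays["syn_gG"], arrays["syn_gN"],
        arrays["syn_delay"], arrays["syn_U"], arrays["syn_taurec"],
        arrays["syn_taufac"], arrays["syn_pfail"],
        ext_t, ext_post, ext_gA, ext_gG, ext_gN,
        kin["tau_onA"], kin["tau_offA"], kin["tau_onG"], kin["tau_offG"],
        kin["tau_onN"], kin["tau_offN"],
        kin["normA"], kin["normG"], kin["normN"],
        kin["ErevA"], kin["ErevG"], kin["ErevN"],
        float(duration), float(dt_max), engine_seed, sample_dt,
        v_ids.astype(np.int64), bool(event_split), len(v_ids) > 0,
        (arrays["E_L"].copy() if initial_state is None
         else np.asarray(initial_state[0], dtype=float)),
        (np.zeros(graph.n_neurons) if initial_state is None
         else np.asarray(initial_state[1], dtype=float)),
    )
    if status == _engine.STATUS_DIVERGED:
        raise RuntimeError(
            f"simulation diverged at t = {t_end:.3f} ms (|V| > 1000 mV); "
            "check synaptic scaling and input currents")

    order = np.argsort(sp_t, kind="stable")
    return RecordingSet(
        duration=float(duration),
        spike_neuron=sp_nrn[order],
        spike_t=sp_t[order],
        v_ids=v_ids,
        V=Vrec,
        t_grid=t_grid,
        lfp=lfp,
        isyn_mean=isyn_int / duration,
        metadata={"seed": seed, "engine_seed": engine_seed,
                  "event_split": int(event_split), "dt_max": dt_max},
    )


# ---------------------------------------------------------------------------
# transparent Python reference integrator


class ReferenceSimulator:
    """Slow, readable twin of the compiled engine (event-split semantics).

    Operates on the same packed arrays; release failures can be disabled
    (``p_fail`` zeroed) so trajectories are deterministic and directly
    comparable with the compiled path.  Intended for tests and tiny nets.
    """

    def __init__(self, graph: NetworkGraph, bg: BackgroundCurrents,
                 dt_max: float = 0.05, fail_rng: np.random.Generator | None = None):
        self.a = _pack_graph(graph)
        self.kin = _kinetics(graph.config)
        self.Ibg = bg.per_neuron(graph.layout)
        self.dt_max = dt_max
        self.N = graph.n_neurons
        self.V = self.a["E_L"].copy()
        self.w = np.zeros(self.N)
        self.x = {k: np.zeros(self.N) for k in
                  ("Aon", "Aoff", "Gon", "Goff", "Non", "Noff")}
        self.t = 0.0
        self.queue: list[tuple[float, int, float, float, float]] = []
        self.stp = [STPState() for _ in range(len(self.a["syn_post"]))]
        self.fail_rng = fail_rng
        self.spikes: list[tuple[int, float]] = []

    # -- pieces -----------------------------------------------------------
    def _g(self, x):
        return (x["Aoff"] - x["Aon"], x["Goff"] - x["Gon"], x["Noff"] - x["Non"])

    def _deriv(self, V, w, gA, gG, gN):
        a, kin = self.a, self.kin
        sN = 1.08 / (1.0 + 0.19 * np.exp(-0.064 * V))
        Isyn = (gA * (V - kin["ErevA"]) + gG * (V - kin["ErevG"])
                + gN * sN * (V - kin["ErevN"]))
        I = self.Ibg - Isyn
        eT = np.exp((V - a["V_th"]) / a["Delta_T"])
        wv = -a["g_L"] * (V - a["E_L"]) + a["g_L"] * a["Delta_T"] * eT + I
        r = np.minimum((a["C"] / a["g_L"]) / a["tau_w"], 0.95)
        dV = (wv - w) / a["C"]
        above = (w - wv) > r * wv
        outside = np.abs(w - wv) > r * wv
        dw = np.where(outside | (V >= a["V_th"]), 0.0,
                      (1.0 - r) * a["g_L"] * (eT - 1.0) * dV)
        return dV, dw, wv, above, Isyn

    def _decay(self, x, h):
        kin = self.kin
        return {
            "Aon": x["Aon"] * np.exp(-h / kin["tau_onA"]),
            "Aoff": x["Aoff"] * np.exp(-h / kin["tau_offA"]),
            "Gon": x["Gon"] * np.exp(-h / kin["tau_onG"]),
            "Goff": x["Goff"] * np.exp(-h / kin["tau_offG"]),
            "Non": x["Non"] * np.exp(-h / kin["tau_onN"]),
            "Noff": x["Noff"] * np.exp(-h / kin["tau_offN"]),
        }

    def _apply_due(self):
        kin = self.kin
        due = [e for e in self.queue if e[0] <= self.t + 1e-9]
        self.queue = [e for e in self.queue if e[0] > self.t + 1e-9]
        for _, p, dgA, dgG, dgN in due:
            self.x["Aon"][p] += dgA * kin["normA"]
            self.x["Aoff"][p] += dgA * kin["normA"]
            self.x["Gon"][p] += dgG * kin["normG"]
            self.x["Goff"][p] += dgG * kin["normG"]
            self.x["Non"][p] += dgN * kin["normN"]
            self.x["Noff"][p] += dgN * kin["normN"]

    # -- one event-exact RK2 step ----------------------------------------
    def advance(self) -> float:
        """One step: boundary lands on the earliest pending event."""
        if not np.all(np.isfinite(self.V)) or not np.all(np.isfinite(self.w)):
            raise FloatingPointError("non-finite state")
        self._apply_due()
        t_next = self.t + self.dt_max
        if self.queue:
            t_next = min(t_next, min(e[0] for e in self.queue))
        h = t_next - self.t
        if h < 1e-9:
            self.t = t_next
            return self.t
        a = self.a
        dV1, dw1, _, above0, _ = self._deriv(self.V, self.w, *self._g(self.x))
        xm = self._decay(self.x, h / 2)
        Vm = self.V + h / 2 * dV1
        wm = self.w + h / 2 * dw1
        dV2, dw2, _, _, _ = self._deriv(Vm, wm, *self._g(xm))
        Vn = self.V + h * dV2
        wn = self.w + h * dw2
        xe = self._decay(xm, h / 2)
        gAe, gGe, gNe = self._g(xe)
        _, _, wve, above_e, _ = self._deriv(Vn, wn, gAe, gGe, gNe)
        proj = above0 & ~above_e
        r = np.minimum((a["C"] / a["g_L"]) / a["tau_w"], 0.95)
        wn = np.where(proj, (1.0 - r) * wve, wn)
        # hyperpolarization floor, mirrors the compiled engine
        floor = Vn < -200.0
        if np.any(floor):
            Vn = np.where(floor, -200.0, Vn)
            _, _, wvf, _, _ = self._deriv(Vn, wn, gAe, gGe, gNe)
            wn = np.where(floor & (wn > (1 + r) * wvf), (1 + r) * wvf, wn)

        def _scalar_deriv(i, Vx, wx):
            kin = self.kin
            sN = 1.08 / (1.0 + 0.19 * np.exp(-0.064 * Vx))
            I = self.Ibg[i] - (gAe[i] * (Vx - kin["ErevA"])
                               + gGe[i] * (Vx - kin["ErevG"])
                               + gNe[i] * sN * (Vx - kin["ErevN"]))
            eT = np.exp((Vx - a["V_th"][i]) / a["Delta_T"][i])
            wv = -a["g_L"][i] * (Vx - a["E_L"][i]) \
                + a["g_L"][i] * a["Delta_T"][i] * eT + I
            ri = min((a["C"][i] / a["g_L"][i]) / a["tau_w"][i], 0.95)
            dV = (wv - wx) / a["C"][i]
            if abs(wx - wv) > ri * wv or Vx >= a["V_th"][i]:
                dw = 0.0
            else:
                dw = (1.0 - ri) * a["g_L"][i] * (eT - 1.0) * dV
            return dV, dw

        crossed = Vn > a["V_up"]
        for i in np.flatnonzero(crossed):
            frac = (a["V_up"][i] - self.V[i]) / (Vn[i] - self.V[i])
            frac = float(np.clip(frac, 0.0, 1.0))
            tc = self.t + frac * h
            self.spikes.append((int(i), float(tc)))
            wn[i] += a["b"][i]
            Vn[i] = a["V_r"][i]
            h_rem = (1.0 - frac) * h
            if h_rem > 1e-9:  # post-reset remainder, conductances frozen
                for _ in range(2):
                    hh = 0.5 * h_rem
                    dV1, dw1 = _scalar_deriv(i, Vn[i], wn[i])
                    dV2, dw2 = _scalar_deriv(i, Vn[i] + 0.5 * hh * dV1,
                                             wn[i] + 0.5 * hh * dw1)
                    Vn[i] += hh * dV2
                    wn[i] += hh * dw2
                if Vn[i] > a["V_up"][i]:
                    Vn[i] = a["V_up"][i]  # re-crossing parked for next step
            for jj in range(a["out_ptr"][i], a["out_ptr"][i + 1]):
                s = a["out_idx"][jj]
                eff, self.stp[s] = stp_efficacy(
                    STPParams(a["syn_U"][s], a["syn_taurec"][s], a["syn_taufac"][s]),
                    self.stp[s], tc)
                fail_p = a["syn_pfail"][s]
                if fail_p > 0 and self.fail_rng is not None \
                        and self.fail_rng.random() < fail_p:
                    continue
                self.queue.append((
                    tc + a["syn_delay"][s], int(a["syn_post"][s]),
                    eff * a["syn_gA"][s], eff * a["syn_gG"][s],
                    eff * a["syn_gN"][s]))
        self.V, self.w, self.x = Vn, wn, xe
        self.t = t_next
        return self.t

    def run_until(self, T: float):
        while self.t < T - 1e-9:
            self.advance()
        return self
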