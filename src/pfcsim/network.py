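"""Construction of the layered PFC microcircuit graph.

Two laminar components (L2/3 and L5), each holding pyramidal cells (PC) and
four interneuron classes: local basket cells (IN-L, fast-spiking),
cross-layer bitufted cells (IN-CL), cross-column basket cells (IN-CC,
pyramidal-like intrinsic parameters but GABAergic) and far-reaching
Martinotti cells (IN-F).  Wiring is Bernoulli per cell-type pair with
table-based probabilities, augmented by a common-neighbor clustering rule
and a fixed reciprocity target among same-layer PC-PC pairs.  Peak
conductances are log-normal, delays Gaussian, and every excitatory contact
carries an NMDA component alongside AMPA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .neuron import NeuronParams, ParamDistributionSpec, sample_population
from .synapse import STPParams, SynapseSpec, sample_stp_params

LAYERS = ("L23", "L5")
KINDS = ("PC", "IN-L", "IN-CL", "IN-CC", "IN-F")


# ---------------------------------------------------------------------------
# population layout


@dataclass
class PopulationLayout:
    """Resolved per-group cell counts and per-neuron group/column labels."""

    N_total: int
    groups: list[tuple[str, str]]          # (layer, kind), fixed order
    counts: dict[tuple[str, str], int]
    group_index: np.ndarray                # per neuron, index into groups
    column: np.ndarray                     # per neuron, integer column
    excitatory: np.ndarray                 # per neuron, bool
    model: dict[tuple[str, str], str]      # intrinsic-parameter distribution

    def ids(self, layer: str | None = None, kind: str | None = None) -> np.ndarray:
        """Neuron ids of a (layer, kind) selection; None matches all."""
        sel = np.zeros(self.N_total, dtype=bool)
        for gi, (lay, knd) in enumerate(self.groups):
            if (layer is None or lay == layer) and (kind is None or knd == kind):
                sel |= self.group_index == gi
        return np.flatnonzero(sel)


def build_population(N_total: int, cfg: dict, n_columns: int = 1) -> PopulationLayout:
    """Distribute ``N_total`` cells over the ten (layer, type) groups.

    Counts are round(fraction * N) with a largest-remainder correction so
    they sum exactly to ``N_total``.  With several columns, each group is
    split as evenly as possible across columns.
    """
    if N_total < 100:
        raise ValueError("N_total must be at least 100")
    groups, fracs, models, excit = [], [], [], []
    for layer in LAYERS:
        for kind in KINDS:
            row = cfg["populations"][layer][kind]
            groups.append((layer, kind))
            fracs.append(float(row["fraction"]))
            models.append(row["model"])
            excit.append(bool(row["excitatory"]))
    fracs = np.asarray(fracs)
    raw = fracs / fracs.sum() * N_total
    counts = np.floor(raw).astype(int)
    remainder = N_total - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1

    group_index = np.repeat(np.arange(len(groups)), counts)
    column = np.zeros(N_total, dtype=np.int64)
    pos = 0
    for c in counts:
        column[pos:pos + c] = np.arange(c) % n_columns
        pos += c
    excitatory = np.asarray(excit)[group_index]
    return PopulationLayout(
        N_total=N_total,
        groups=groups,
        counts={g: int(c) for g, c in zip(groups, counts)},
        group_index=group_index,
        column=column,
        excitatory=excitatory,
        model={g: m for g, m in zip(groups, models)},
    )


# ---------------------------------------------------------------------------
# connectivity specification


@dataclass
class ConnectivitySpec:
    """Lookup of (p_con, g_max mean/sd, tau_D mean/sd) per type pair."""

    rows: list[dict]
    reciprocity: float
    common_neighbor_beta: float
    L_C: float
    l_E: float
    l_I: float
    delay_min: float

    @classmethod
    def from_config(cls, cfg: dict) -> "ConnectivitySpec":
        return cls(
            rows=list(cfg["connectivity"]),
            reciprocity=float(cfg["wiring"]["reciprocity"]),
            common_neighbor_beta=float(cfg["wiring"]["common_neighbor_beta"]),
            L_C=float(cfg["space"]["L_C"]),
            l_E=float(cfg["space"]["l_E"]),
            l_I=float(cfg["space"]["l_I"]),
            delay_min=float(cfg["synapses"]["delay_min"]),
        )

    def lookup(self, pre: tuple[str, str], post: tuple[str, str]) -> dict | None:
        """Resolve the table row for an ordered group pair.

        IN-CC inherits the IN-L rows (both basket cells); interneuron to
        interneuron wiring uses the lumped within-layer IN->IN rows.
        """
        def alias(g):
            layer, kind = g
            return layer, ("IN-L" if kind == "IN-CC" else kind)

        pre_a, post_a = alias(pre), alias(post)
        key_pre = f"{pre_a[0]}/{pre_a[1]}"
        key_post = f"{post_a[0]}/{post_a[1]}"
        for row in self.rows:
            if row["pre"] == key_pre and row["post"] == key_post:
                return row
        if pre[1] != "PC" and post[1] != "PC":
            for row in self.rows:
                if row["pre"] == f"{pre[0]}/IN" and row["post"] == f"{post[0]}/IN":
                    return row
        return None


# ---------------------------------------------------------------------------
# synapse sampling


@dataclass
class SampledSynapse:
    spec: SynapseSpec           # AMPA (excitatory pre) or GABA_A (inhibitory pre)
    stp: STPParams
    nmda: SynapseSpec | None    # companion NMDA channel for excitatory contacts


def psp_unit_response(C: float, g_L: float, E_L: float, tau_on: float,
                      tau_off: float, E_rev: float,
                      holding: float | None = None) -> float:
    """Peak somatic PSP (mV) evoked by a 1 nS peak-conductance transient.

    Linearized passive response of a cell with capacitance ``C`` and leak
    ``g_L``: the peak-normalized double-exponential conductance is
    convolved with the membrane filter at the holding potential
    (``E_L`` unless ``holding`` is given).  Used to translate the
    connection table, which lists PSP-amplitude calibration targets in mV,
    into peak conductances.
    """
    from .synapse import kernel_norm

    Vh = E_L if holding is None else holding
    driving = abs(Vh - E_rev)
    dt = 0.05
    t = np.arange(0.0, 10.0 * tau_off, dt)
    K = kernel_norm(tau_on, tau_off) * (np.exp(-t / tau_off) - np.exp(-t / tau_on))
    memb = np.exp(-t / (C / g_L))
    v = np.convolve(K, memb)[:len(t)] * dt * driving / C
    return float(v.max())


_CALIB_CACHE: dict[tuple, dict] = {}


def _calib_key(cfg: dict) -> tuple:
    kin = cfg["synapses"]["kinetics"]
    return (
        tuple((r, kin[r]["tau_on"], kin[r]["tau_off"], kin[r]["E_rev"])
              for r in ("AMPA", "GABA_A")),
        float(cfg["synapses"].get("ipsp_holding", -55.0)),
        tuple((m, row["C"][0], row["g_L"][0], row["E_L"][0])
              for m, row in cfg["neurons"]["types"].items()),
    )


def conductance_calibration(cfg: dict) -> dict:
    """mV-per-nS factors per (receptor, postsynaptic model type).

    The shipped connection table follows the source literature in quoting
    synaptic strength as unitary PSP amplitude (mV); dividing by these
    factors yields the peak conductance in nS.  EPSPs are referenced at
    the postsynaptic resting potential, IPSPs at the depolarized holding
    potential conventional in paired recordings (GABA_A reverses near
    rest, so a resting-potential reference would be degenerate).
    """
    key = _calib_key(cfg)
    if key in _CALIB_CACHE:
        return _CALIB_CACHE[key]
    kin = cfg["synapses"]["kinetics"]
    hold_ipsp = float(cfg["synapses"].get("ipsp_holding", -55.0))
    out = {}
    for model, row in cfg["neurons"]["types"].items():
        C, g_L, E_L = row["C"][0], row["g_L"][0], row["E_L"][0]
        out[("AMPA", model)] = psp_unit_response(
            C, g_L, E_L, kin["AMPA"]["tau_on"], kin["AMPA"]["tau_off"],
            kin["AMPA"]["E_rev"])
        out[("GABA_A", model)] = psp_unit_response(
            C, g_L, E_L, kin["GABA_A"]["tau_on"], kin["GABA_A"]["tau_off"],
            kin["GABA_A"]["E_rev"], holding=hold_ipsp)
    _CALIB_CACHE[key] = out
    return out


def _g_scale(cfg, calib, excitatory: bool, post_model: str) -> float:
    """Factor converting a table g_max entry into nS for one contact."""
    if cfg["synapses"].get("g_unit", "psp_mv") == "nS":
        return 1.0
    receptor = "AMPA" if excitatory else "GABA_A"
    return 1.0 / calib[(receptor, post_model)]


def _lognormal_moment_matched(mean, sd, rng, size=None):
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - 0.5 * sigma2
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def _resolve_stp_class(pre_kind: str, post_kind: str, stp_cfg: dict,
                       rng: np.random.Generator) -> str:
    pre_k = "PC" if pre_kind == "PC" else pre_kind
    post_k = "PC" if post_kind == "PC" else post_kind
    pre_c = "PC" if pre_k == "PC" else "IN"
    post_c = "PC" if post_k == "PC" else "IN"
    mapping = stp_cfg["map"]
    for key in (f"{pre_k}->{post_k}", f"{pre_k}->{post_c}",
                f"{pre_c}->{post_k}", f"{pre_c}->{post_c}",
                f"{pre_k}->*", f"*->{post_k}", "*->*"):
        if key in mapping:
            probs = mapping[key]
            names = list(probs)
            p = np.asarray([probs[n] for n in names], dtype=float)
            return names[rng.choice(len(names), p=p / p.sum())]
    raise KeyError(f"no STP class mapping for {pre_kind}->{post_kind}")


def sample_synapse(
    pre_type: tuple[str, str],
    post_type: tuple[str, str],
    column_distance: int,
    spec: ConnectivitySpec,
    cfg: dict,
    rng: np.random.Generator,
    calib: dict | None = None,
) -> SampledSynapse:
    """Draw one synapse's parameters for a connected (pre, post) pair.

    g_max is log-normal (moment-matched to the table mean/sd), attenuated
    by exp(-d*L_C/l) across ``column_distance`` columns; tau_D is Gaussian,
    truncated at ``delay_min`` and scaled by (1 + d).  Excitatory contacts
    receive an NMDA companion at 1.09 x the AMPA peak conductance sharing
    the AMPA delay and presynaptic dynamics.
    """
    row = spec.lookup(pre_type, post_type)
    if row is None:
        raise KeyError(f"no connectivity entry for {pre_type} -> {post_type}")
    syn_cfg = cfg["synapses"]
    excitatory = pre_type[1] == "PC"
    if calib is None:
        calib = conductance_calibration(cfg)
    post_model = cfg["populations"][post_type[0]][post_type[1]]["model"]
    scale = _g_scale(cfg, calib, excitatory, post_model)
    g = float(_lognormal_moment_matched(row["g_max"][0] * scale,
                                        row["g_max"][1] * scale, rng))
    if column_distance > 0:
        l = spec.l_E if excitatory else spec.l_I
        g *= np.exp(-column_distance * spec.L_C / l)
    tau_D = max(float(rng.normal(*row["tau_D"])), spec.delay_min)
    tau_D *= 1.0 + column_distance
    stp_class = _resolve_stp_class(pre_type[1], post_type[1], cfg["stp"], rng)
    stp = sample_stp_params(stp_class, cfg["stp"], rng)
    p_fail = float(syn_cfg["p_fail"])

    kin = syn_cfg["kinetics"]
    if excitatory:
        ampa = SynapseSpec("AMPA", g, kin["AMPA"]["tau_on"], kin["AMPA"]["tau_off"],
                           tau_D, kin["AMPA"]["E_rev"], stp_class, p_fail)
        nmda = SynapseSpec("NMDA", g * float(syn_cfg["nmda_ratio"]),
                           kin["NMDA"]["tau_on"], kin["NMDA"]["tau_off"],
                           tau_D, kin["NMDA"]["E_rev"], stp_class, p_fail)
        return SampledSynapse(spec=ampa, stp=stp, nmda=nmda)
    gaba = SynapseSpec("GABA_A", g, kin["GABA_A"]["tau_on"], kin["GABA_A"]["tau_off"],
                       tau_D, kin["GABA_A"]["E_rev"], stp_class, p_fail)
    return SampledSynapse(spec=gaba, stp=stp, nmda=None)


# ---------------------------------------------------------------------------
# wiring


def _bernoulli_block(n_pre, n_post, p, rng, no_self=False):
    adj = rng.random((n_pre, n_post)) < p
    if no_self:
        np.fill_diagonal(adj, False)
    return adj


def _common_neighbor_pass(adj: np.ndarray, p: float, beta: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Resample a square PC-PC block with linear common-neighbor boost.

    Pairwise probability p_ij = p * (1 + beta * n_ij / <n>) / (1 + beta)
    where n_ij counts shared partners (either direction) in the base graph;
    the denominator renormalizes so the expected overall density stays p.
    """
    n = adj.shape[0]
    und = (adj | adj.T).astype(np.float32)
    n_common = und @ und.T
    np.fill_diagonal(n_common, 0.0)
    mean_nc = n_common.sum() / (n * (n - 1))
    if mean_nc <= 0:
        return adj
    p_pair = p * (1.0 + beta * n_common / mean_nc) / (1.0 + beta)
    np.clip(p_pair, 0.0, 1.0, out=p_pair)
    new = rng.random((n, n)) < p_pair
    np.fill_diagonal(new, False)
    return new


def _adjust_reciprocity(adj: np.ndarray, target: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Convert unidirectional and bidirectional pairs into one another until
    the reciprocal fraction of connected pairs matches ``target``, keeping
    the total directed edge count fixed."""
    adj = adj.copy()
    iu, ju = np.triu_indices(adj.shape[0], k=1)
    fwd, bwd = adj[iu, ju], adj[ju, iu]
    bi = np.flatnonzero(fwd & bwd)
    uni = np.flatnonzero(fwd ^ bwd)
    B, U = len(bi), len(uni)
    if B + U == 0:
        return adj
    k = int(round((target * (B + U) - B) / (1.0 + target)))
    if k > 0:
        k = min(k, U // 2)
        chosen = rng.choice(uni, size=2 * k, replace=False)
        gain, lose = chosen[:k], chosen[k:]
        for idx in gain:  # add the missing direction
            adj[iu[idx], ju[idx]] = True
            adj[ju[idx], iu[idx]] = True
        for idx in lose:  # disconnect entirely
            adj[iu[idx], ju[idx]] = False
            adj[ju[idx], iu[idx]] = False
    elif k < 0:
        m = min(-k, B, adj.size)
        split = rng.choice(bi, size=m, replace=False)
        # candidate unconnected pairs to receive the freed edges
        empty = np.flatnonzero(~(fwd | bwd))
        recv = rng.choice(empty, size=m, replace=False)
        for s_idx, r_idx in zip(split, recv):
            if rng.random() < 0.5:
                adj[iu[s_idx], ju[s_idx]] = False
            else:
                adj[ju[s_idx], iu[s_idx]] = False
            if rng.random() < 0.5:
                adj[iu[r_idx], ju[r_idx]] = True
            else:
                adj[ju[r_idx], iu[r_idx]] = True
    return adj


@dataclass
class NetworkGraph:
    """Fully sampled network: neurons plus a flat directed synapse table.

    Synapse arrays are aligned; excitatory contacts have ``g_ampa`` and
    ``g_nmda`` set, inhibitory ones ``g_gaba``.  ``stp_class`` stores the
    class label per contact.
    """

    layout: PopulationLayout
    neurons: list[NeuronParams]
    pre: np.ndarray
    post: np.ndarray
    g_ampa: np.ndarray
    g_gaba: np.ndarray
    g_nmda: np.ndarray
    delay: np.ndarray
    U: np.ndarray
    tau_rec: np.ndarray
    tau_fac: np.ndarray
    p_fail: np.ndarray
    stp_class: np.ndarray
    config: dict

    @property
    def n_neurons(self) -> int:
        return self.layout.N_total

    @property
    def n_synapses(self) -> int:
        return len(self.pre)

    def neuron_array(self, name: str) -> np.ndarray:
        return np.asarray([getattr(nrn, name) for nrn in self.neurons])

    def scale_inhibition(self, factor: float) -> "NetworkGraph":
        """Copy of the graph with all GABA_A peak conductances scaled."""
        import copy as _copy

        g = _copy.copy(self)
        g.g_gaba = self.g_gaba * factor
        return g

    def to_edge_frame(self):
        """Edge-list export (CSV-friendly)."""
        import pandas as pd

        receptor = np.where(self.g_gaba > 0, "GABA_A", "AMPA+NMDA")
        return pd.DataFrame({
            "pre_id": self.pre, "post_id": self.post, "receptor": receptor,
            "g_ampa": self.g_ampa, "g_gaba": self.g_gaba, "g_nmda": self.g_nmda,
            "tau_D": self.delay, "stp_class": self.stp_class,
        })


def wire(layout: PopulationLayout, spec: ConnectivitySpec,
         rng: np.random.Generator) -> dict[tuple[int, int], np.ndarray]:
    """Sample the Bernoulli adjacency per group pair.

    Same-layer PC-PC blocks get (i) a common-neighbor resampling pass and
    (ii) the reciprocity adjustment toward the configured target.  Returns
    {(pre_group_idx, post_group_idx): boolean adjacency}.
    """
    blocks: dict[tuple[int, int], np.ndarray] = {}
    for gi, pre_g in enumerate(layout.groups):
        ids_pre = layout.ids(*pre_g)
        if len(ids_pre) == 0:
            continue
        for gj, post_g in enumerate(layout.groups):
            ids_post = layout.ids(*post_g)
            if len(ids_post) == 0:
                continue
            row = spec.lookup(pre_g, post_g)
            if row is None or row["p_con"] <= 0:
                continue
            same = gi == gj
            adj = _bernoulli_block(len(ids_pre), len(ids_post), row["p_con"],
                                   rng, no_self=same)
            if same and pre_g[1] == "PC":
                adj = _common_neighbor_pass(adj, row["p_con"],
                                            spec.common_neighbor_beta, rng)
                adj = _adjust_reciprocity(adj, spec.reciprocity, rng)
            blocks[(gi, gj)] = adj
    return blocks


def build_network(
    N_total: int = 1000,
    seed: int = 0,
    cfg: dict | None = None,
    n_columns: int = 1,
    weight_dist: str = "lognormal",
) -> NetworkGraph:
    """Sample a complete network (population, parameters, wiring, synapses).

    ``weight_dist='normal'`` replaces every log-normal peak-conductance draw
    by a Gaussian with identical mean and SD (truncated at zero), the
    control used to probe the role of the heavy tail.
    """
    from .config import default_config

    if cfg is None:
        cfg = default_config()
    if weight_dist not in ("lognormal", "normal"):
        raise ValueError("weight_dist must be 'lognormal' or 'normal'")
    rng = np.random.default_rng(seed)
    layout = build_population(N_total, cfg, n_columns=n_columns)
    dist_spec = ParamDistributionSpec.from_config(cfg)

    neurons: list[NeuronParams] = [None] * N_total
    for g in layout.groups:
        ids = layout.ids(*g)
        if len(ids) == 0:
            continue
        for nid, params in zip(ids, sample_population(dist_spec, layout.model[g],
                                                      len(ids), rng)):
            neurons[nid] = params

    conn = ConnectivitySpec.from_config(cfg)
    blocks = wire(layout, conn, rng)
    calib = conductance_calibration(cfg)

    syn_cfg = cfg["synapses"]
    kin = syn_cfg["kinetics"]
    nmda_ratio = float(syn_cfg["nmda_ratio"])
    p_fail = float(syn_cfg["p_fail"])
    stp_cfg = cfg["stp"]

    pre_l, post_l = [], []
    gA_l, gG_l, gN_l, d_l = [], [], [], []
    U_l, tr_l, tf_l, cls_l = [], [], [], []
    for (gi, gj), adj in blocks.items():
        pre_g, post_g = layout.groups[gi], layout.groups[gj]
        ids_pre, ids_post = layout.ids(*pre_g), layout.ids(*post_g)
        row = conn.lookup(pre_g, post_g)
        ii, jj = np.nonzero(adj)
        m = len(ii)
        if m == 0:
            continue
        pre_ids, post_ids = ids_pre[ii], ids_post[jj]
        dcol = np.abs(layout.column[pre_ids] - layout.column[post_ids])
        excitatory = pre_g[1] == "PC"
        post_model = cfg["populations"][post_g[0]][post_g[1]]["model"]
        scale = _g_scale(cfg, calib, excitatory, post_model)
        g_mean, g_sd = row["g_max"][0] * scale, row["g_max"][1] * scale
        if weight_dist == "lognormal":
            g = _lognormal_moment_matched(g_mean, g_sd, rng, m)
        else:
            g = np.maximum(rng.normal(g_mean, g_sd, m), 0.0)
        if n_columns > 1:
            l = conn.l_E if excitatory else conn.l_I
            g = g * np.exp(-dcol * conn.L_C / l)
        tau_D = np.maximum(rng.normal(row["tau_D"][0], row["tau_D"][1], m),
                           conn.delay_min) * (1.0 + dcol)
        classes = np.array([_resolve_stp_class(pre_g[1], post_g[1], stp_cfg, rng)
                            for _ in range(m)])
        stp_rows = [sample_stp_params(c, stp_cfg, rng) for c in classes]
        pre_l.append(pre_ids)
        post_l.append(post_ids)
        gA_l.append(g if excitatory else np.zeros(m))
        gG_l.append(np.zeros(m) if excitatory else g)
        gN_l.append(g * nmda_ratio if excitatory else np.zeros(m))
        d_l.append(tau_D)
        U_l.append([s.U for s in stp_rows])
        tr_l.append([s.tau_rec for s in stp_rows])
        tf_l.append([s.tau_fac for s in stp_rows])
        cls_l.append(classes)

    cat = lambda parts, dtype=float: (
        np.concatenate([np.asarray(p, dtype=dtype) for p in parts])
        if parts else np.empty(0, dtype=dtype))
    graph = NetworkGraph(
        layout=layout,
        neurons=neurons,
        pre=cat(pre_l, np.int64),
        post=cat(post_l, np.int64),
        g_ampa=cat(gA_l),
        g_gaba=cat(gG_l),
        g_nmda=cat(gN_l),
        delay=cat(d_l),
        U=cat(U_l),
        tau_rec=cat(tr_l),
        tau_fac=cat(tf_l),
        p_fail=np.full(sum(map(len, pre_l)) if pre_l else 0, p_fail),
        stp_class=cat(cls_l, object) if cls_l else np.empty(0, dtype=object),
        config=cfg,
    )
    # check kinetics are non-degenerate up front
    for rec in ("AMPA", "GABA_A", "NMDA"):
        if not kin[rec]["tau_on"] < kin[rec]["tau_off"]:
            raise ValueError(f"degenerate kinetics for {rec}")
    return graph


# ---------------------------------------------------------------------------
# LSPS rescaling utility


def lsps_rescale(p_con: np.ndarray, g_max: np.ndarray,
                 I_LSPS: np.ndarray) -> np.ndarray:
    """Element-wise scale factors aligning p_con*g_max with an LSPS map.

    s_ij = (I_LSPS_ij / sum(I_LSPS)) / (p_ij g_ij / sum(p*g)); multiplying
    p_con*g_max by s makes it proportional to the photostimulation-derived
    total-input map.  The shipped connection table is already post-scaling;
    this utility audits it or imports new maps.
    """
    p_con, g_max, I_LSPS = map(np.asarray, (p_con, g_max, I_LSPS))
    if not p_con.shape == g_max.shape == I_LSPS.shape:
        raise ValueError("matrices must be conformable")
    pg = p_con * g_max
    return (I_LSPS / I_LSPS.sum()) / (pg / pg.sum())
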