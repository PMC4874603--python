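"""Equivalent-population estimate of the constant background currents.

The explicitly simulated column stands in a much larger network.  The
missing surround is replaced by constant currents whose realistic range is
estimated here: count the input neurons a cell of each class would collect
from a cylinder of given density and radius (connection probability
decaying exponentially with distance), then measure the time-averaged
synaptic current produced by an equivalent Poisson bombardment through
type-averaged synapses on a single model neuron.

Only L2/3 pyramidal cells and the cross-column (IN-CC) and far-reaching
(IN-F) interneurons project beyond their column, which sets the
cross-column participation fractions f_N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import default_config
from .network import ConnectivitySpec, KINDS, LAYERS
from .synapse import STPParams

TARGET_CLASSES = ("PC-L23", "PC-L5", "IN-L23", "IN-L5")

# interneuron subtypes that send axons beyond their own column
_CROSS_COLUMN_IN = ("IN-CC", "IN-F")


# ---------------------------------------------------------------------------
# geometry


def radial_count(D: float, p_con: float, l: float, L1: float, L2: float,
                 height_um: float = 1000.0) -> float:
    """Closed form of 2*pi*D*p_con * integral_{L1}^{L2} x exp(-x/l) dx.

    ``D`` is in neurons/mm^3, lengths in um; the cylinder height defaults
    to 1 mm.  The antiderivative of x e^{-x/l} is -l (x + l) e^{-x/l}.
    """
    if L2 < L1:
        raise ValueError("outer radius must be at least the inner radius")
    D_um = D * 1e-9  # neurons per um^3
    integral = l * ((L1 + l) * np.exp(-L1 / l) - (L2 + l) * np.exp(-L2 / l))
    return 2.0 * np.pi * D_um * height_um * p_con * integral


@dataclass
class EmbeddingSpec:
    """Geometry and composition of the virtual embedding network."""

    D: float                       # neuron density, mm^-3
    N_C: int                       # number of columns (radius = N_C * L_C)
    L_C: float = 300.0
    l_E: float = 114.0
    l_I: float = 95.0
    height_um: float = 1000.0
    cfg: dict = field(default_factory=default_config)

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("density must be positive")
        if self.N_C < 1:
            raise ValueError("need at least one column")

    @property
    def L(self) -> float:
        return self.N_C * self.L_C


def _class_fractions(cfg) -> dict:
    """Table-derived composition fractions used for f_C / f_N."""
    pops = cfg["populations"]
    frac = {(lay, kind): float(pops[lay][kind]["fraction"])
            for lay in LAYERS for kind in KINDS}
    exc_total = sum(v for (lay, kind), v in frac.items() if kind == "PC")
    inh_total = sum(v for (lay, kind), v in frac.items() if kind != "PC")
    exc_cross = frac[("L23", "PC")]
    inh_cross = sum(frac[(lay, kind)] for lay in LAYERS
                    for kind in _CROSS_COLUMN_IN)
    return {
        "frac": frac,
        "f_C": {"E": 1.0, "I": 1.0},
        "f_N": {"E": exc_cross / exc_total, "I": inh_cross / inh_total},
        "exc_total": exc_total,
        "inh_total": inh_total,
    }


def _target_groups(cell_type: str):
    layer = "L23" if cell_type.endswith("L23") else "L5"
    if cell_type.startswith("PC"):
        return [(layer, "PC")]
    return [(layer, k) for k in KINDS if k != "PC"]


def _mean_over_pairs(cfg, conn: ConnectivitySpec, cell_type: str,
                     source: str, quantity: str) -> float:
    """Composition-weighted mean of p_con or g_max over (pre, post) pairs.

    ``source`` is "E" (pyramidal presynaptic) or "I" (interneuron
    presynaptic); postsynaptic subtypes of a lumped interneuron target are
    weighted by their fractions.  The mean connection probability is
    weighted by composition alone; the mean peak conductance (returned in
    nS, unit conversion included) is additionally weighted by p_con so it
    averages over realized connections.
    """
    from .network import _g_scale, conductance_calibration

    comp = _class_fractions(cfg)
    calib = conductance_calibration(cfg)
    pres = [(lay, kind) for lay in LAYERS for kind in KINDS
            if (kind == "PC") == (source == "E")]
    posts = _target_groups(cell_type)
    num = den = 0.0
    for post in posts:
        w_post = comp["frac"][post]
        post_model = cfg["populations"][post[0]][post[1]]["model"]
        scale = _g_scale(cfg, calib, source == "E", post_model)
        for pre in pres:
            w = comp["frac"][pre] * w_post
            row = conn.lookup(pre, post)
            if row is None:
                continue
            if quantity == "p_con":
                val = row["p_con"]
            else:
                val = row["g_max"][0] * scale
                w *= row["p_con"]
            num += w * val
            den += w
    return num / den if den > 0 else 0.0


@dataclass
class NSynCounts:
    E: float
    I: float

    @property
    def total(self) -> float:
        return self.E + self.I


def n_syn(cell_type: str, spec: EmbeddingSpec) -> NSynCounts:
    """Expected excitatory/inhibitory input counts for one cell.

    N_syn = f_C * N_D(0, L_C) + f_N * N_D(L_C, L) with N_D the radial
    integral of the exponentially decaying connection probability over a
    1 mm high hollow cylinder.
    """
    if cell_type not in TARGET_CLASSES:
        raise KeyError(f"unknown target class {cell_type!r}")
    if spec.L < spec.L_C:
        raise ValueError("outer radius below the column radius")
    cfg = spec.cfg
    conn = ConnectivitySpec.from_config(cfg)
    comp = _class_fractions(cfg)
    out = {}
    for source, l in (("E", spec.l_E), ("I", spec.l_I)):
        p_eff = _mean_over_pairs(cfg, conn, cell_type, source, "p_con")
        density = spec.D * (comp["exc_total"] if source == "E"
                            else comp["inh_total"])
        inner = radial_count(density, p_eff, l, 0.0, spec.L_C, spec.height_um)
        outer = radial_count(density, p_eff, l, spec.L_C, spec.L, spec.height_um)
        out[source] = comp["f_C"][source] * inner + comp["f_N"][source] * outer
    return NSynCounts(E=out["E"], I=out["I"])


# ---------------------------------------------------------------------------
# lumped-Poisson current measurement


def _mean_neuron_params(cfg, cell_type: str) -> dict:
    """Composition-weighted Table-of-means intrinsic parameters."""
    from .neuron import PARAM_NAMES

    comp = _class_fractions(cfg)
    groups = _target_groups(cell_type)
    out = {name: 0.0 for name in PARAM_NAMES}
    den = 0.0
    for (lay, kind) in groups:
        w = comp["frac"][(lay, kind)]
        model = cfg["populations"][lay][kind]["model"]
        row = cfg["neurons"]["types"][model]
        for name in PARAM_NAMES:
            out[name] += w * row[name][0]
        den += w
    return {k: v / den for k, v in out.items()}


def _stp_steady_state(p: STPParams, delta_ms: float) -> float:
    """Fixed point of the utilization/resource recursion at constant ISI."""
    u, R = p.U, 1.0
    for _ in range(500):
        u_new = p.U + u * (1.0 - p.U) * np.exp(-delta_ms / p.tau_fac)
        R_new = 1.0 + (R - u * R - 1.0) * np.exp(-delta_ms / p.tau_rec)
        if abs(u_new - u) < 1e-12 and abs(R_new - R) < 1e-12:
            u, R = u_new, R_new
            break
        u, R = u_new, R_new
    return u * R


def _mean_stp_params(cfg, source: str) -> STPParams:
    """Map-weighted mean STP parameters for E or I inputs onto any cell."""
    classes = cfg["stp"]["classes"]
    names = [n for n in classes if n.startswith("E" if source == "E" else "I")]
    U = float(np.mean([classes[n]["U"][0] for n in names]))
    tr = float(np.mean([classes[n]["tau_rec"][0] for n in names]))
    tf = float(np.mean([classes[n]["tau_fac"][0] for n in names]))
    return STPParams(U=U, tau_rec=tr, tau_fac=tf)


def lumped_current(
    cell_type: str,
    n_inputs: NSynCounts | dict,
    rate_per_input: dict,
    duration: float = 3000.0,
    seed: int = 0,
    cfg: dict | None = None,
    I_bg: float | None = None,
) -> float:
    """Time-averaged net synaptic current (pA) onto one averaged neuron.

    A single cell with the composition-averaged intrinsic parameters of
    ``cell_type`` receives Poisson trains whose total rates mimic
    ``n_inputs`` excitatory/inhibitory partners firing at
    ``rate_per_input`` = {"E": Hz, "I": Hz}.  Short-term plasticity enters
    through the per-input steady-state efficacy at the given rate, and
    release failures thin the train.  Positive values depolarize.
    """
    cfg = cfg or default_config()
    if isinstance(n_inputs, dict):
        n_inputs = NSynCounts(**n_inputs)
    rng = np.random.default_rng(seed)
    if n_inputs.total == 0:
        return 0.0

    from .network import NetworkGraph
    from .neuron import NeuronParams
    from .simulate import BackgroundCurrents, run

    # one-neuron graph (no recurrent synapses)
    mean_p = _mean_neuron_params(cfg, cell_type)
    neuron = NeuronParams(**mean_p, cell_type=cell_type)

    conn = ConnectivitySpec.from_config(cfg)
    p_fail = float(cfg["synapses"]["p_fail"])
    nmda_ratio = float(cfg["synapses"]["nmda_ratio"])

    parts_t, parts_gA, parts_gG, parts_gN = [], [], [], []
    for source in ("E", "I"):
        n_src = getattr(n_inputs, source)
        rate = float(rate_per_input.get(source, 0.0))
        if n_src <= 0 or rate <= 0:
            continue
        g_mean = _mean_over_pairs(cfg, conn, cell_type, source, "g_max")
        stp_mean = _mean_stp_params(cfg, source)
        a_ss = _stp_steady_state(stp_mean, 1000.0 / rate)
        if cfg["synapses"].get("stp_normalized", True):
            a_ss /= stp_mean.U
        total_rate = n_src * rate * (1.0 - p_fail) / 1000.0  # events per ms
        n_ev = rng.poisson(total_rate * duration)
        times = np.sort(rng.uniform(0.0, duration, n_ev))
        amp = a_ss * g_mean
        parts_t.append(times)
        if source == "E":
            parts_gA.append(np.full(n_ev, amp))
            parts_gG.append(np.zeros(n_ev))
            parts_gN.append(np.full(n_ev, amp * nmda_ratio))
        else:
            parts_gA.append(np.zeros(n_ev))
            parts_gG.append(np.full(n_ev, amp))
            parts_gN.append(np.zeros(n_ev))

    if not parts_t:
        return 0.0
    ext = (np.concatenate(parts_t), np.zeros(sum(map(len, parts_t)), dtype=np.int64),
           np.concatenate(parts_gA), np.concatenate(parts_gG),
           np.concatenate(parts_gN))

    graph = NetworkGraph(
        layout=_single_neuron_layout(),
        neurons=[neuron],
        pre=np.empty(0, dtype=np.int64), post=np.empty(0, dtype=np.int64),
        g_ampa=np.empty(0), g_gaba=np.empty(0), g_nmda=np.empty(0),
        delay=np.empty(0), U=np.empty(0), tau_rec=np.empty(0),
        tau_fac=np.empty(0), p_fail=np.empty(0),
        stp_class=np.empty(0, dtype=object), config=cfg,
    )
    if I_bg is None:
        bg_cfg = cfg.get("background", {"I_ex": 250.0, "I_inh": 200.0})
        I_bg = float(bg_cfg["I_ex"] if cell_type.startswith("PC")
                     else bg_cfg["I_inh"])
    rec = run(graph, BackgroundCurrents.uniform(I_bg, I_bg), duration,
              record_cfg={"external_events": ext},
              seed=int(rng.integers(0, 2**31 - 1)))
    return float(rec.isyn_mean[0])


def _single_neuron_layout():
    from .network import PopulationLayout

    return PopulationLayout(
        N_total=1,
        groups=[("L23", "PC")],
        counts={("L23", "PC"): 1},
        group_index=np.zeros(1, dtype=np.int64),
        column=np.zeros(1, dtype=np.int64),
        excitatory=np.ones(1, dtype=bool),
        model={("L23", "PC"): "PC-L23"},
    )


# ---------------------------------------------------------------------------
# grid scan


def scan_network_size(
    n_columns: list[int],
    densities: list[float],
    rates: dict,
    duration: float = 2000.0,
    seed: int = 0,
    cfg: dict | None = None,
    admissible_band: tuple[float, float] | None = None,
):
    """CurrentTable over an (N_C, D) grid for the four target classes.

    ``rates`` maps "E"/"I" to per-input firing rates (Hz), normally the
    per-class mean rates of a reference simulation (self-consistency run
    once).  Returns a DataFrame with columns N_C, D, layer, cls, n_E, n_I,
    I_mean_pA and, when ``admissible_band=(lo, hi)`` is given, a boolean
    ``admissible`` flag.
    """
    import pandas as pd

    cfg = cfg or default_config()
    rows = []
    rng = np.random.default_rng(seed)
    for nc in n_columns:
        for D in densities:
            spec = EmbeddingSpec(D=D, N_C=nc, cfg=cfg)
            for cls in TARGET_CLASSES:
                counts = n_syn(cls, spec)
                I = lumped_current(cls, counts, rates, duration=duration,
                                   seed=int(rng.integers(0, 2**31 - 1)),
                                   cfg=cfg)
                row = {
                    "N_C": nc, "D": D,
                    "layer": "L23" if cls.endswith("L23") else "L5",
                    "cls": "PC" if cls.startswith("PC") else "IN",
                    "n_E": counts.E, "n_I": counts.I, "I_mean_pA": I,
                }
                if admissible_band is not None:
                    lo, hi = admissible_band
                    row["admissible"] = lo <= I <= hi
                rows.append(row)
    return pd.DataFrame(rows)
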