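"""simpAdEx single-neuron model.

A two-variable reduction of the adaptive exponential integrate-and-fire
neuron: membrane potential V and adaptation current w.  The voltage obeys

    C dV/dt = -g_L (V - E_L) + g_L * Delta_T * exp((V - V_th)/Delta_T) + I - w
            = w_V(V, I) - w

where ``w_V`` is the V-nullcline.  The adaptation variable does not follow
its own linear ODE; instead the phase plane is split into regimes by the
band of half-width (tau_m/tau_w)*w_V around the nullcline:

* outside the band, |w - w_V| > (tau_m/tau_w) * w_V:  dw/dt = 0
  (adaptation is slow; the fast V-transit happens at frozen w),
* inside the band (the slow crawl along the nullcline): w tracks a scaled
  copy of the nullcline,
  dw/dt = Heaviside(V_th - V) * (1 - tau_m/tau_w) * (dw_V/dV) * (dV/dt),
* on reaching the upper boundary w = (1 + tau_m/tau_w) w_V from above, w
  is projected onto the lower edge: w -> (1 - tau_m/tau_w) * w_V
  (the fast relaxation across the nullcline).

A spike is recorded when V crosses the absolute threshold V_up; then
V -> V_r and w -> w + b.  This construction permits closed-form f-I curves
while reproducing the spike patterns of the full AdEx.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CELL_TYPES = ("PC-L23", "FS", "BT", "MC", "PC-L5")

PARAM_NAMES = ("C", "g_L", "E_L", "Delta_T", "tau_w", "b", "V_r", "V_th", "V_up")


@dataclass
class NeuronParams:
    """Intrinsic parameters of one simpAdEx cell.

    Units: C pF, g_L nS, voltages mV, times ms, b pA.  ``tau_m`` is the
    derived membrane time constant C/g_L.
    """

    C: float
    g_L: float
    E_L: float
    Delta_T: float
    tau_w: float
    b: float
    V_r: float
    V_th: float
    V_up: float
    cell_type: str = ""
    tau_m: float = field(init=False)

    def __post_init__(self) -> None:
        if self.C <= 0 or self.g_L <= 0 or self.Delta_T <= 0 or self.tau_w <= 0:
            raise ValueError("C, g_L, Delta_T and tau_w must be positive")
        if self.b < 0:
            raise ValueError("b must be non-negative")
        if not self.V_r < self.V_up:
            raise ValueError("reset V_r must lie below the spike threshold V_up")
        self.tau_m = self.C / self.g_L


@dataclass
class NeuronState:
    """Dynamic state (V in mV, w in pA)."""

    V: float
    w: float


def v_nullcline(p: NeuronParams, V: float, I: float) -> float:
    """w_V(V, I): the adaptation current at which dV/dt = 0."""
    return -p.g_L * (V - p.E_L) + p.g_L * p.Delta_T * np.exp((V - p.V_th) / p.Delta_T) + I


def _dwv_dv(p: NeuronParams, V: float) -> float:
    return -p.g_L + p.g_L * np.exp((V - p.V_th) / p.Delta_T)


def derivatives(p: NeuronParams, s: NeuronState, I_total: float) -> tuple[float, float]:
    """(dV/dt, dw/dt) in (mV/ms, pA/ms) for the piecewise simpAdEx flow.

    ``I_total`` is the summed synaptic plus background current (pA).
    """
    if not (np.isfinite(s.V) and np.isfinite(s.w)):
        raise FloatingPointError("non-finite neuron state")
    wv = v_nullcline(p, s.V, I_total)
    dV = (wv - s.w) / p.C
    r = band_ratio(p)
    if abs(s.w - wv) > r * wv or s.V >= p.V_th:
        dw = 0.0
    else:
        dw = (1.0 - r) * _dwv_dv(p, s.V) * dV
    return dV, dw


def band_ratio(p: NeuronParams) -> float:
    """tau_m/tau_w, capped just below one.

    The slow-adaptation construction assumes tau_w > tau_m; the rare
    sampled cells violating this are integrated with a ratio of 0.95
    (weak nullcline tracking) rather than rejected.
    """
    return min(p.tau_m / p.tau_w, 0.95)


def above_band(p: NeuronParams, s: NeuronState, I_total: float) -> bool:
    """True when the state lies beyond the upper band edge (1+r) w_V."""
    wv = v_nullcline(p, s.V, I_total)
    return s.w - wv > band_ratio(p) * wv


def project_onto_band(p: NeuronParams, s: NeuronState, I_total: float) -> NeuronState:
    """Apply the boundary projection w -> (1 - tau_m/tau_w) * w_V."""
    wv = v_nullcline(p, s.V, I_total)
    return NeuronState(V=s.V, w=(1.0 - band_ratio(p)) * wv)


def handle_spike(p: NeuronParams, s: NeuronState) -> NeuronState:
    """Reset after a threshold crossing: V -> V_r, w -> w + b.

    Must only be called with s.V > V_up.
    """
    if not s.V > p.V_up:
        raise ValueError("handle_spike called below the spike threshold V_up")
    return NeuronState(V=p.V_r, w=s.w + p.b)


def rheobase(p: NeuronParams) -> float:
    """Minimal constant current (pA) for repetitive firing.

    Saddle-node condition of the V-equation at frozen adaptation: the
    maximum of -g_L(V-E_L) + g_L*Delta_T*exp((V-V_th)/Delta_T) sits at
    V = V_th, giving I_rh = g_L (V_th - E_L) - g_L * Delta_T.  Negative
    values mark cells that fire without input ("generator neurons").
    """
    return p.g_L * (p.V_th - p.E_L) - p.g_L * p.Delta_T


def integrate_constant_current(
    p: NeuronParams,
    I: float,
    duration: float,
    dt: float = 0.05,
    record: bool = False,
):
    """Reference RK2 (midpoint) integration of one neuron at constant drive.

    Returns ``(spike_times, trace)``; ``trace`` is an (n, 3) array of
    (t, V, w) when ``record`` else None.  Spike times are located by linear
    interpolation of the V-trajectory crossing V_up.  This is the slow,
    transparent integrator used as an oracle for the compiled engine.
    """
    V, w = p.E_L, 0.0
    t = 0.0
    spikes: list[float] = []
    rows = [(0.0, V, w)] if record else None
    n_steps = int(np.ceil(duration / dt))
    for k in range(n_steps):
        h = min(dt, duration - t)
        if h <= 0:
            break
        s0 = NeuronState(V, w)
        above0 = above_band(p, s0, I)
        dV1, dw1 = derivatives(p, s0, I)
        sm = NeuronState(V + 0.5 * h * dV1, w + 0.5 * h * dw1)
        dV2, dw2 = derivatives(p, sm, I)
        Vn, wn = V + h * dV2, w + h * dw2
        sn = NeuronState(Vn, wn)
        if above0 and not above_band(p, sn, I):
            sn = project_onto_band(p, sn, I)
            Vn, wn = sn.V, sn.w
        if Vn > p.V_up:
            frac = (p.V_up - V) / (Vn - V)
            t_cross = t + frac * h
            spikes.append(t_cross)
            # reset at the crossing, then advance the remainder of the step
            sr = handle_spike(p, NeuronState(p.V_up + 1e-9, wn))
            Vn, wn = sr.V, sr.w
            h_rem = (1.0 - frac) * h
            if h_rem > 0:
                dV1, dw1 = derivatives(p, NeuronState(Vn, wn), I)
                sm = NeuronState(Vn + 0.5 * h_rem * dV1, wn + 0.5 * h_rem * dw1)
                dV2, dw2 = derivatives(p, sm, I)
                Vn, wn = Vn + h_rem * dV2, wn + h_rem * dw2
        V, w = Vn, wn
        t += h
        if record:
            rows.append((t, V, w))
    trace = np.asarray(rows) if record else None
    return np.asarray(spikes), trace


@dataclass
class ParamDistributionSpec:
    """Marginal distribution (family, mean, sd) per parameter per cell type."""

    families: dict[str, str]
    types: dict[str, dict[str, tuple[float, float]]]

    @classmethod
    def from_config(cls, cfg: dict) -> "ParamDistributionSpec":
        sec = cfg["neurons"]
        types = {
            name: {k: (float(v[0]), float(v[1])) for k, v in params.items()}
            for name, params in sec["types"].items()
        }
        return cls(families=dict(sec["families"]), types=types)


def _draw(family: str, mean: float, sd: float, size: int, rng: np.random.Generator):
    if family == "gaussian":
        return rng.normal(mean, sd, size)
    if family == "gamma":
        shape = (mean / sd) ** 2
        scale = sd**2 / mean
        return rng.gamma(shape, scale, size)
    if family == "exponential":
        # An exponential has sd = mean; matched on the mean.
        return rng.exponential(mean, size)
    raise ValueError(f"unknown distribution family {family!r}")


def sample_population(
    spec: ParamDistributionSpec,
    cell_type: str,
    n: int,
    rng_seed: int | np.random.Generator,
) -> list[NeuronParams]:
    """Draw ``n`` independent parameter sets for one cell type.

    Each parameter is drawn from its marginal family.  Hard invariants
    (positivity of C, g_L, Delta_T, tau_w; V_r < V_up; V_th < V_up) are
    enforced by rejection-resampling only the offending parameter (the
    V_th/V_up pair jointly), so the unconstrained marginals keep their
    table moments exactly.  Cells drawn with tau_w <= tau_m are kept; the
    integrators cap the band ratio tau_m/tau_w just below one for them.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if cell_type not in spec.types:
        raise KeyError(f"unknown cell type {cell_type!r}")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    table = spec.types[cell_type]
    cols = {
        name: _draw(spec.families[name], *table[name], n, rng)
        for name in PARAM_NAMES
    }

    def _redraw(mask, names):
        idx = np.flatnonzero(mask)
        for name in names:
            cols[name][idx] = _draw(spec.families[name], *table[name],
                                    len(idx), rng)

    for _ in range(1000):
        bad_pos = {name: cols[name] <= 0 for name in ("C", "g_L", "Delta_T",
                                                      "tau_w")}
        bad_vth = cols["V_th"] >= cols["V_up"]
        bad_vr = cols["V_r"] >= cols["V_up"]
        # membrane time constant floor: a C draw near zero would put the
        # voltage dynamics far below the integration step
        bad_taum = cols["C"] / cols["g_L"] < 1.0
        if not (any(m.any() for m in bad_pos.values()) or bad_vth.any()
                or bad_vr.any() or bad_taum.any()):
            break
        for name, mask in bad_pos.items():
            _redraw(mask, [name])
        _redraw(bad_vth, ["V_th", "V_up"])
        _redraw(bad_vr, ["V_r"])
        _redraw(bad_taum, ["C"])
    else:  # pragma: no cover - pathological configuration
        raise RuntimeError("invariant resampling did not converge")

    return [
        NeuronParams(
            **{name: float(cols[name][i]) for name in PARAM_NAMES},
            cell_type=cell_type,
        )
        for i in range(n)
    ]


def population_to_frame(cells: list[NeuronParams]):
    """One row per neuron, columns = parameter names (CSV-exportable)."""
    import pandas as pd

    return pd.DataFrame(
        [{**{k: getattr(c, k) for k in PARAM_NAMES},
          "tau_m": c.tau_m, "cell_type": c.cell_type} for c in cells]
    )
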