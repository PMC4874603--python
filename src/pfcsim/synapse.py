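"""Conductance-based synapses: kinetics, NMDA gating, short-term plasticity.

Receptor currents follow a double-exponential conductance time course

    I_X = g_max^X * s(V) * sum_k a_k * K(t - t_k - tau_D) * (V - E_rev^X)

with kernel K(t) = exp(-t/tau_off) - exp(-t/tau_on) for t >= 0, scaled here
so that its maximum equals one (``g_max`` is then literally the peak
conductance).  ``s(V)`` models the magnesium block of NMDA receptors and is
one for AMPA/GABA_A.  ``I_X`` is positive for V above the reversal
potential and enters the membrane equation with a minus sign, so an AMPA
event depolarizes and a GABA_A event hyperpolarizes a cell above -70 mV.

Release amplitudes a_k follow the corrected Tsodyks-Markram short-term
plasticity recursion with per-synapse (U, tau_rec, tau_fac), and each
presynaptic spike fails to release with probability ``p_fail``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

RECEPTORS = ("AMPA", "GABA_A", "NMDA")
STP_CLASSES = ("E1", "E2", "E3", "I1", "I2", "I3", "none")


def kernel_peak_time(tau_on: float, tau_off: float) -> float:
    """Time of the double-exponential maximum after onset."""
    return tau_on * tau_off / (tau_off - tau_on) * np.log(tau_off / tau_on)


def kernel_norm(tau_on: float, tau_off: float) -> float:
    """Scale factor making the kernel peak equal one."""
    if tau_off <= tau_on:
        raise ValueError("degenerate kernel: requires tau_on < tau_off")
    tp = kernel_peak_time(tau_on, tau_off)
    return 1.0 / (np.exp(-tp / tau_off) - np.exp(-tp / tau_on))


@dataclass
class SynapseSpec:
    """Static description of one connection's receptor channel."""

    receptor: str
    g_max: float  # peak conductance, nS
    tau_on: float
    tau_off: float
    tau_D: float  # transmission delay, ms
    E_rev: float
    stp_class: str = "none"
    p_fail: float = 0.0

    def __post_init__(self) -> None:
        if self.receptor not in RECEPTORS:
            raise ValueError(f"unknown receptor {self.receptor!r}")
        if not 0 < self.tau_on < self.tau_off:
            raise ValueError("requires 0 < tau_on < tau_off")
        if self.g_max < 0:
            raise ValueError("g_max must be non-negative")
        if not 0 <= self.p_fail < 1:
            raise ValueError("p_fail must lie in [0, 1)")
        if self.stp_class not in STP_CLASSES:
            raise ValueError(f"unknown STP class {self.stp_class!r}")


@dataclass
class STPParams:
    U: float        # baseline utilization
    tau_rec: float  # resource recovery constant, ms
    tau_fac: float  # facilitation decay constant, ms

    def __post_init__(self) -> None:
        if not 0 < self.U <= 1:
            raise ValueError("U must lie in (0, 1]")
        if self.tau_rec <= 0 or self.tau_fac <= 0:
            raise ValueError("time constants must be positive")


@dataclass
class STPState:
    """Utilization/resources after the last presynaptic spike."""

    u: float = 0.0
    R: float = 1.0
    t_last: float = field(default=-np.inf)


def stp_efficacy(p: STPParams, s: STPState, t_spike: float) -> tuple[float, STPState]:
    """Release efficacy a_k = u_k * R_k for a presynaptic spike at ``t_spike``.

    First spike: u_1 = U, R_1 = 1, a_1 = U.  Subsequent spikes at interval
    Delta = t_spike - t_last apply

        u_k = U + u_{k-1} (1 - U) exp(-Delta/tau_fac)
        R_k = 1 + (R_{k-1} - u_{k-1} R_{k-1} - 1) exp(-Delta/tau_rec)

    Returns the efficacy and the updated state.
    """
    if not np.isfinite(s.t_last):  # first spike
        u, R = p.U, 1.0
    else:
        delta = t_spike - s.t_last
        if delta <= 0:
            raise ValueError("presynaptic spike times must be increasing")
        u = p.U + s.u * (1.0 - p.U) * np.exp(-delta / p.tau_fac)
        R = 1.0 + (s.R - s.u * s.R - 1.0) * np.exp(-delta / p.tau_rec)
    return u * R, STPState(u=u, R=R, t_last=t_spike)


def nmda_gate(V, receptor: str = "NMDA"):
    """Voltage-dependent magnesium unblock; one for non-NMDA receptors."""
    if receptor != "NMDA":
        return np.ones_like(np.asarray(V, dtype=float))[()] if np.ndim(V) else 1.0
    return 1.08 / (1.0 + 0.19 * np.exp(-0.064 * np.asarray(V, dtype=float)))[()]


def synaptic_current(
    spec: SynapseSpec,
    event_efficacies: list[tuple[float, float]],
    t: float,
    V_post: float,
) -> float:
    """Instantaneous receptor current I_X (pA) at time ``t``.

    ``event_efficacies`` holds (presynaptic spike time, efficacy a) pairs;
    events whose delay has not yet elapsed contribute zero.  Positive
    values are outward for V above E_rev; the membrane equation receives
    -I_X.
    """
    norm = kernel_norm(spec.tau_on, spec.tau_off)
    g = 0.0
    for t_sp, a in event_efficacies:
        dt = t - t_sp - spec.tau_D
        if dt < 0:
            continue
        g += a * (np.exp(-dt / spec.tau_off) - np.exp(-dt / spec.tau_on))
    gate = nmda_gate(V_post, spec.receptor)
    return spec.g_max * norm * g * gate * (V_post - spec.E_rev)


def draw_transmission(p_fail: float, rng: np.random.Generator) -> bool:
    """True (vesicle released) with probability 1 - p_fail."""
    if not 0 <= p_fail < 1:
        raise ValueError("p_fail must lie in [0, 1)")
    return bool(rng.random() >= p_fail)


def sample_stp_params(
    class_name: str, cfg_stp: dict, rng: np.random.Generator
) -> STPParams:
    """Draw per-synapse (U, tau_rec, tau_fac) from the class table.

    Gaussian draws around the class mean/sd, rejection-resampled into the
    valid region (0 < U <= 1, time constants >= 1 ms).
    """
    row = cfg_stp["classes"][class_name]
    while True:
        U = rng.normal(*row["U"])
        tr = rng.normal(*row["tau_rec"])
        tf = rng.normal(*row["tau_fac"])
        if 0.0 < U <= 1.0 and tr >= 1.0 and tf >= 1.0:
            return STPParams(U=U, tau_rec=tr, tau_fac=tf)
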