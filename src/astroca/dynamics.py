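"""Per-pixel calcium/IP3/glutamate kinetics.

State variables per pixel: cytosolic Ca2+ ``ca_c``, ER Ca2+ ``ca_er``,
cytosolic IP3 ``ip3`` (all uM), extracellular glutamate ``glu`` (uM) and the
slow IP3-receptor inactivation gate ``q`` in [0, 1].

The local dynamics are a Li-Rinzel-type IP3R model with dynamic ER calcium,
glutamate-driven plasma-membrane Ca2+ entry and plasma-membrane IP3
production, all weighted by the morphology parameter ``s`` (SVR weight):

    d ca_c / dt = (1 - s) J_ER + s J_pm (+ diffusion)
    d ca_er/ dt = -(1 - s)/c1 * J_ER
    d ip3  / dt = s (I_Glu + I_Ca) - (ip3 - ip3_0)/tau_ip3 (+ diffusion)
    d glu  / dt = (glu_amb - glu)/tau_glu + xi(t) (+ diffusion)
    d q    / dt = a2 [d2 (ip3 + d1)/(ip3 + d3)] (1 - q) - a2 ca_c q

with ER exchange J_ER = J_IP3 + J_leak - J_pump and plasma-membrane exchange
J_pm = J_in + J_Glu - J_out.  In leaflets s ~ 1: dynamics are dominated by
plasma-membrane fluxes and IP3 production; in the soma s ~ 0: ER exchange
(CICR) dominates.  ``xi`` is the stochastic synaptic glutamate source (see
:mod:`astroca.drive`).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from .morphology import avf_to_svr

__all__ = ["ParameterSet", "ModelState", "flux_er", "flux_pm", "ip3_rhs",
           "gate_rhs", "point_rhs", "resting_state"]

#: where each default value comes from; serialized alongside the config
PROVENANCE = {
    "v4": "table1", "v5": "table1", "k1": "table1", "k3": "table1",
    "tau_glu": "table1", "p_syn": "table1", "A": "table1",
    "glu_amb": "table1", "D_ca": "table1", "D_ip3": "table1",
    "D_glu": "table1", "r_min": "table1", "dt": "table1", "dx": "table1",
    "c1": "prototype-default", "v1": "prototype-default",
    "v2": "prototype-default", "v3": "prototype-default",
    "v6": "prototype-default", "k2": "prototype-default",
    "k4": "prototype-default", "d1": "prototype-default",
    "d2": "prototype-default", "d3": "prototype-default",
    "d5": "prototype-default", "a2": "prototype-default",
    "alpha_frac": "prototype-default", "v_glu": "prototype-default",
    "k_glu": "prototype-default", "n_glu": "prototype-default",
    "tau_ip3": "prototype-default", "ip3_0": "prototype-default",
    "gamma": "calibrated", "d_rel": "calibrated",
    "svr_slope": "design", "save_stride": "design",
}


@dataclass
class ParameterSet:
    """All rate constants, diffusivities and numerical settings.

    Units: concentrations uM, rates uM/s or 1/s, diffusivities um^2/s,
    times s, lengths um.  Defaults marked "table1" in :data:`PROVENANCE`
    are the published operating point; "prototype-default" values are the
    standard constants of the underlying Li-Rinzel/Ullah-type kinetics;
    "calibrated" values are fixed by the package's own calibration
    procedures and recorded in the serialized config.
    """

    # calcium handling (table1 overrides of the prototype kinetics)
    v4: float = 0.1        # max rate of Ca-stimulated IP3 production, uM/s
    v5: float = 0.01       # plasma-membrane Ca leak, uM/s
    k1: float = 1.0        # Ca extrusion rate constant, 1/s
    k3: float = 0.05       # ER pump activation constant, uM
    # glutamate drive
    tau_glu: float = 0.1   # perisynaptic glutamate clearance time constant, s
    p_syn: float = 0.005   # Poisson rate of quantal release per pixel, Hz
    A: float = 27.0        # instantaneous rise in glutamate release rate, uM/s
    glu_amb: float = 0.0   # ambient extracellular glutamate, uM
    gamma: float = 7.0     # glutamate-gated Ca entry gain J_Glu = gamma*glu, 1/s
    d_rel: float = 0.0618  # quantal release duration (calibrated), s
    # diffusion
    D_ca: float = 10.0     # cytosolic Ca2+, um^2/s
    D_ip3: float = 10.0    # cytosolic IP3, um^2/s
    D_glu: float = 0.02    # extracellular glutamate, um^2/s
    # morphology
    r_min: float = 0.085   # minimal AVF on astrocyte pixels
    svr_slope: float = 0.1 # slope constant of the AVF -> SVR logistic
    # prototype-model constants (ER/IP3R kinetics)
    c1: float = 0.185      # ER/cytosol volume ratio
    v1: float = 6.0        # max IP3R channel flux, 1/s
    v2: float = 0.11       # ER leak rate constant, 1/s
    v3: float = 0.9        # max ER pump rate, uM/s
    v6: float = 0.2        # max IP3-stimulated Ca entry, uM/s
    k2: float = 1.0        # half-activation of IP3-stimulated entry, uM
    k4: float = 1.1        # PLC-delta Ca dissociation constant, uM
    d1: float = 0.13       # IP3 dissociation constant of the IP3R, uM
    d2: float = 1.049      # Ca inactivation dissociation constant, uM
    d3: float = 0.9434     # IP3 dissociation constant (inactivation), uM
    d5: float = 0.08234    # Ca activation dissociation constant, uM
    a2: float = 0.2        # IP3R inactivation rate, 1/(uM s)
    alpha_frac: float = 0.8  # Ca-independent fraction of PLC-delta activity
    v_glu: float = 0.062   # max glutamate-driven IP3 production, uM/s
    k_glu: float = 0.78    # half-activation of glutamate IP3 production, uM
    n_glu: float = 0.7     # Hill exponent of glutamate IP3 production
    tau_ip3: float = 7.143 # IP3 equilibration time constant, s
    ip3_0: float = 0.42    # resting IP3 level, uM
    # numerics
    dt: float = 0.002      # RK4 time step, s
    dx: float = 0.275      # grid step, um (0.55 for network templates)
    save_stride: float = 0.5  # recording interval, s

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name not in ("glu_amb",) and v < 0:
                raise ValueError(f"{f.name} must be non-negative")
        if not 0 < self.r_min < 1:
            raise ValueError("r_min must lie in (0, 1)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def replace(self, **kw) -> "ParameterSet":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["_provenance"] = dict(PROVENANCE)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        d = {k: v for k, v in d.items() if not k.startswith("_")}
        return cls(**d)


@dataclass
class ModelState:
    """Point state (scalar or per-pixel arrays)."""

    ca_c: np.ndarray | float
    ca_er: np.ndarray | float
    ip3: np.ndarray | float
    glu: np.ndarray | float
    q: np.ndarray | float

    def validate(self) -> None:
        for name in ("ca_c", "ca_er", "ip3", "glu"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"negative concentration in {name}")
        qa = np.asarray(self.q)
        if np.any(qa < 0) or np.any(qa > 1):
            raise ValueError("q must lie in [0, 1]")

    def as_arrays(self):
        return tuple(np.asarray(getattr(self, n), dtype=float)
                     for n in ("ca_c", "ca_er", "ip3", "glu", "q"))


def flux_er(state: ModelState, p: ParameterSet):
    """Total ER<->cytosol Ca2+ flux J_ER = J_IP3 + J_leak - J_pump (uM/s)."""
    ca, er, ip3, _, q = state.as_arrays()
    m_inf = ip3 / (ip3 + p.d1)
    n_inf = ca / (ca + p.d5)
    j_ip3 = p.c1 * p.v1 * (m_inf * n_inf * q) ** 3 * (er - ca)
    j_leak = p.c1 * p.v2 * (er - ca)
    j_pump = p.v3 * ca**2 / (p.k3**2 + ca**2)
    return j_ip3 + j_leak - j_pump


def flux_pm(state: ModelState, p: ParameterSet):
    """Plasma-membrane Ca2+ flux J_pm = J_in + J_Glu - J_out (uM/s)."""
    ca, _, ip3, glu, _ = state.as_arrays()
    j_in = p.v5 + p.v6 * ip3**2 / (p.k2**2 + ip3**2)
    j_glu = p.gamma * glu
    j_out = p.k1 * ca
    return j_in + j_glu - j_out


def _i_ca(ca, p: ParameterSet):
    """Ca-stimulated (PLC-delta) IP3 production, saturating at v4."""
    return p.v4 * (ca + (1.0 - p.alpha_frac) * p.k4) / (ca + p.k4)


def _i_glu(glu, p: ParameterSet):
    """Glutamate-driven (PLC-beta) IP3 production, Hill exponent n_glu."""
    g = np.maximum(np.asarray(glu, dtype=float), 0.0)
    gn = np.where(g > 0, g, 1.0) ** p.n_glu
    return np.where(g > 0, p.v_glu * gn / (gn + p.k_glu**p.n_glu), 0.0)


def ip3_rhs(state: ModelState, p: ParameterSet, s):
    """d[IP3]/dt excluding diffusion: s(I_Glu + I_Ca) - (ip3 - ip3_0)/tau."""
    ca, _, ip3, glu, _ = state.as_arrays()
    i_eq = (ip3 - p.ip3_0) / p.tau_ip3
    return s * (_i_glu(glu, p) + _i_ca(ca, p)) - i_eq


def gate_rhs(state: ModelState, p: ParameterSet):
    """IP3R inactivation gate kinetics dq/dt."""
    ca, _, ip3, _, q = state.as_arrays()
    alpha_q = p.a2 * p.d2 * (ip3 + p.d1) / (ip3 + p.d3)
    return alpha_q * (1.0 - q) - p.a2 * ca * q


def point_rhs(state: ModelState, p: ParameterSet, r, xi=0.0):
    """Full point right-hand side at AVF ``r`` (diffusion excluded).

    Parameters
    ----------
    r :
        local AVF; the SVR weight is ``s = avf_to_svr(r)``.
    xi :
        exogenous glutamate release rate, uM/s.

    Returns
    -------
    tuple ``(dca_c, dca_er, dip3, dglu, dq)`` in uM/s (dq in 1/s).
    """
    state.validate()
    s = avf_to_svr(r, slope=p.svr_slope)
    j_er = flux_er(state, p)
    j_pm = flux_pm(state, p)
    dca = (1.0 - s) * j_er + s * j_pm
    der = -(1.0 - s) / p.c1 * j_er
    dip3 = ip3_rhs(state, p, s)
    dglu = (p.glu_amb - np.asarray(state.glu, dtype=float)) / p.tau_glu + xi
    dq = gate_rhs(state, p)
    return (dca, der, dip3, dglu, dq)


def resting_state(p: ParameterSet, r, tol: float = 1e-9,
                  max_iter: int = 2000) -> ModelState:
    """Zero-drive rest state at AVF ``r`` (scalar or array).

    Solved by damped fixed-point iteration on (ca_c, ip3) using the
    equilibrium conditions J_pm = 0 and IP3 balance, then q and ca_er from
    their own equilibria (J_ER = 0).  For s = 0 pixels the plasma-membrane
    solution is kept as the continuous limit (the ER subsystem is then
    neutrally stable in total calcium and any J_ER = 0 pair is a rest
    state).  Deterministic; raises if the residual exceeds ``tol``.
    """
    r_arr = np.asarray(r, dtype=float)
    s = avf_to_svr(r_arr, slope=p.svr_slope)
    glu = np.full_like(r_arr, float(p.glu_amb))
    ca = np.full_like(r_arr, 0.05)
    ip3 = np.full_like(r_arr, p.ip3_0)
    damp = 0.5
    for _ in range(max_iter):
        j_in = p.v5 + p.v6 * ip3**2 / (p.k2**2 + ip3**2) + p.gamma * glu
        ca_new = j_in / p.k1
        ip3_new = p.ip3_0 + p.tau_ip3 * s * (_i_ca(ca, p) + _i_glu(glu, p))
        dca = np.max(np.abs(ca_new - ca))
        dip = np.max(np.abs(ip3_new - ip3))
        ca = (1 - damp) * ca + damp * ca_new
        ip3 = (1 - damp) * ip3 + damp * ip3_new
        if max(dca, dip) < 1e-13:
            break
    alpha_q = p.d2 * (ip3 + p.d1) / (ip3 + p.d3)
    q = alpha_q / (alpha_q + ca)
    m_inf = ip3 / (ip3 + p.d1)
    n_inf = ca / (ca + p.d5)
    j_pump = p.v3 * ca**2 / (p.k3**2 + ca**2)
    er = ca + j_pump / (p.c1 * (p.v1 * (m_inf * n_inf * q) ** 3 + p.v2))
    st = ModelState(ca_c=ca, ca_er=er, ip3=ip3, glu=glu, q=q)
    resid = np.max([np.max(np.abs(np.asarray(d)))
                    for d in point_rhs(st, p, r_arr)])
    if resid > tol:
        raise RuntimeError(f"resting_state did not converge: residual {resid:.3e}")
    return st
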