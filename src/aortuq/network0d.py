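"""0D forward hemodynamic model: one junction feeding four RCR outlets.

A prescribed inlet flow Q_in(t) enters a single junction whose pressure
P_j(t) is common to all outlet proximal resistances (zero branch
impedance, so the outlet parameter sets alone decide the flow split).
Each outlet i carries one state, the pressure P_c,i on its compliance:

    dP_c,i/dt = (Q_i − P_c,i/Rd_i) / C_i,      Q_i = (P_j − P_c,i)/Rp_i,

and P_j is eliminated at every evaluation from mass conservation
Σ Q_i = Q_in, which for the linear network gives

    P_j = (Q_in + Σ P_c,i/Rp_i) / (Σ 1/Rp_i).

An optional nonlinear stenosis element can be placed in series on the
descending-aorta pathway, adding ΔP = K·(ρ/2)·(Q_DA/A_CoA)²·sign(Q_DA);
it is off by default because the α redistribution already carries the
coarctation resistance.

Time integration is classical RK4 on the compliance states with the
junction pressure recomputed per stage; cycles are repeated until the
junction-pressure waveform is periodic to a relative tolerance.  This
module is a surrogate for a 3D CFD solve behind a minimal contract: any
substitute must map (inflow, OutletBCSet) → SimResult and conserve flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import BLOOD_DENSITY, OUTLET_NAMES, OutletBCSet, Waveform

__all__ = ["SolverSettings", "SimResult", "simulate"]


@dataclass(frozen=True)
class SolverSettings:
    dt: float = 0.002          # s
    max_cycles: int = 6
    periodicity_tol: float = 1e-6  # relative junction-pressure change per cycle

    def validate(self, period: float) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.dt >= period / 20:
            raise ValueError("dt must resolve the cycle (dt < period/20)")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be at least 1")


@dataclass
class SimResult:
    """Per-outlet flows, junction pressure, DA terminal pressure and ΔP."""

    outlet_flows: dict          # name -> Waveform (cm³/s)
    junction_pressure: Waveform  # barye
    distal_pressure_da: Waveform  # barye, at the DA compliance node
    dp: Waveform                 # barye, junction minus DA terminal
    converged: bool = True
    cycles_run: int = 0
    residual: float = 0.0


def _da_flow_nonlinear(head: np.ndarray, rp: float, c2: float):
    """Solve rp·Q + c2·Q·|Q| = head for Q (c2 > 0)."""
    sign = np.sign(head)
    q = (np.sqrt(rp * rp + 4.0 * c2 * np.abs(head)) - rp) / (2.0 * c2)
    return sign * q


def _junction(pc: np.ndarray, q_in: float, rp: np.ndarray,
              coa_c2: float) -> tuple[float, np.ndarray]:
    """Junction pressure and outlet flows satisfying Σ Qᵢ = Q_in."""
    g = 1.0 / rp
    if coa_c2 == 0.0:
        p_j = (q_in + np.dot(pc, g)) / g.sum()
        q = (p_j - pc) * g
        return p_j, q
    # Nonlinear DA element: Newton on f(P_j) = Σ Qᵢ(P_j) − Q_in, which is
    # strictly increasing in P_j.
    i_da = len(pc) - 1
    g_lin = g.copy()
    g_lin[i_da] = 0.0
    p_j = (q_in + np.dot(pc, g)) / g.sum()  # linear guess
    for _ in range(50):
        head = p_j - pc[i_da]
        q_da = _da_flow_nonlinear(head, rp[i_da], coa_c2)
        f = np.dot(p_j - pc, g_lin) + q_da - q_in
        dq_da = 1.0 / np.sqrt(rp[i_da] ** 2 + 4.0 * coa_c2 * abs(head))
        step = f / (g_lin.sum() + dq_da)
        p_j -= step
        if abs(step) < 1e-10 * max(1.0, abs(p_j)):
            break
    q = (p_j - pc) * g
    q[i_da] = _da_flow_nonlinear(p_j - pc[i_da], rp[i_da], coa_c2)
    # Enforce exact conservation by assigning the residual-free DA flow.
    q[i_da] = q_in - q[:i_da].sum()
    return p_j, q


def simulate(inflow: Waveform, bcs: OutletBCSet,
             settings: SolverSettings | None = None,
             coa_element: float = 0.0,
             coa_area: float | None = None) -> SimResult:
    """Run the 0D network to its periodic state and return the last cycle.

    Parameters
    ----------
    inflow : prescribed inlet flow over one cycle (cm³/s).
    bcs : RCR triplets for the four outlets.
    settings : time step, cycle budget and periodicity tolerance.
    coa_element : dimensionless loss coefficient K of the optional
        stenosis element on the DA pathway (0 disables it).
    coa_area : coarctation area (cm²) used by the stenosis element;
        required when coa_element > 0.
    """
    if settings is None:
        settings = SolverSettings()
    settings.validate(inflow.period)
    if coa_element < 0:
        raise ValueError("coa_element must be nonnegative")
    if coa_element > 0 and (coa_area is None or coa_area <= 0):
        raise ValueError("coa_area must be positive when the stenosis element is on")
    coa_c2 = 0.0 if coa_element == 0 else coa_element * BLOOD_DENSITY / (2.0 * coa_area ** 2)

    params = [bcs[n] for n in OUTLET_NAMES]
    rp = np.array([p.rp for p in params])
    rd = np.array([p.rd for p in params])
    c = np.array([p.c for p in params])

    T = inflow.period
    dt = settings.dt
    n = int(round(T / dt))
    t_grid = np.arange(n) * (T / n)
    dt = T / n  # snap so an integer number of steps covers one cycle
    # Inlet flow at the RK4 stage times (t, t + dt/2) for every step.
    q_nodes = inflow(t_grid)
    q_half = inflow(t_grid + 0.5 * dt)
    q_next = np.roll(q_nodes, -1)

    # Initial state: each compliance at its mean periodic operating point.
    q_mean = inflow.time_average()
    r_out = rp + rd
    p_j0 = q_mean / np.sum(1.0 / r_out)
    pc = p_j0 * rd / r_out

    def rhs(pc_state, q_in):
        p_j, q = _junction(pc_state, q_in, rp, coa_c2)
        return (q - pc_state / rd) / c

    pj_trace = np.empty(n)
    q_trace = np.empty((n, 4))
    prev_pj = None
    converged = False
    residual = np.inf
    cycles = 0
    for cycle in range(settings.max_cycles):
        cycles = cycle + 1
        for k in range(n):
            p_j, q = _junction(pc, q_nodes[k], rp, coa_c2)
            pj_trace[k] = p_j
            q_trace[k] = q
            k1 = rhs(pc, q_nodes[k])
            k2 = rhs(pc + 0.5 * dt * k1, q_half[k])
            k3 = rhs(pc + 0.5 * dt * k2, q_half[k])
            k4 = rhs(pc + dt * k3, q_next[k])
            pc = pc + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if prev_pj is not None:
            residual = float(np.max(np.abs(pj_trace - prev_pj)) / np.max(np.abs(pj_trace)))
            if residual < settings.periodicity_tol:
                converged = True
                break
        prev_pj = pj_trace.copy()

    # Rebuild the last-cycle traces from the final (periodic) state so the
    # reported waveforms correspond to a single consistent cycle.
    pc_da = np.empty(n)
    i_da = OUTLET_NAMES.index("da")
    for k in range(n):
        p_j, q = _junction(pc, q_nodes[k], rp, coa_c2)
        pj_trace[k] = p_j
        q_trace[k] = q
        pc_da[k] = pc[i_da]
        k1 = rhs(pc, q_nodes[k])
        k2 = rhs(pc + 0.5 * dt * k1, q_half[k])
        k3 = rhs(pc + 0.5 * dt * k2, q_half[k])
        k4 = rhs(pc + dt * k3, q_next[k])
        pc = pc + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)

    def wf(vals, kind, unit):
        return Waveform(times=t_grid, values=vals, period=T, kind=kind, unit=unit)

    flows = {name: wf(q_trace[:, i], "flow", "cm3/s")
             for i, name in enumerate(OUTLET_NAMES)}
    junction = wf(pj_trace, "pressure", "barye")
    distal_da = wf(pc_da, "pressure", "barye")
    dp = wf(pj_trace - pc_da, "pressure", "barye")
    return SimResult(outlet_flows=flows, junction_pressure=junction,
                     distal_pressure_da=distal_da, dp=dp,
                     converged=converged, cycles_run=cycles,
                     residual=residual if np.isfinite(residual) else 0.0)
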