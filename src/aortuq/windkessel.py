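"""Closed-form pressure response of a three-element Windkessel model.

The RCR circuit driven by a prescribed flow Q(t) admits the explicit
solution

    P(t) = [P(0) − Rp Q(0)] e^{−t/τ} + Rp Q(t)
           + (1/C) ∫₀ᵗ e^{−(t−t*)/τ} Q(t*) dt*,       τ = Rd C.

The convolution integral is evaluated by the trapezoidal rule on the flow
waveform's own grid, using the recursion
I(t_{k+1}) = e^{−Δt/τ} I(t_k) + trapezoid over [t_k, t_{k+1}], which is
O(n) and algebraically identical to the naive O(n²) sum.
"""

from __future__ import annotations

import numpy as np

from .datamodel import (
    PressureSummary,
    Waveform,
    WindkesselParams,
    convert_pressure,
)

__all__ = ["wk_pressure", "wk_periodic_p0", "summarize_pressure"]


def _conv_integral(times: np.ndarray, q: np.ndarray, tau: float) -> np.ndarray:
    """I(t_k) = ∫₀^{t_k} e^{−(t_k−s)/τ} q(s) ds by recursive trapezoid."""
    n = times.size
    out = np.empty(n)
    out[0] = 0.0
    dt = np.diff(times)
    decay = np.exp(-dt / tau)
    for k in range(n - 1):
        out[k + 1] = decay[k] * out[k] + 0.5 * dt[k] * (decay[k] * q[k] + q[k + 1])
    return out


def wk_pressure(params: WindkesselParams, inflow: Waveform, p0: float) -> Waveform:
    """Pressure waveform (barye) at the inflow sample times, given P(0) = p0."""
    if inflow.kind != "flow":
        raise ValueError("inflow waveform must be of kind 'flow'")
    tau = params.tau
    t = inflow.times
    q = inflow.values
    integral = _conv_integral(t, q, tau)
    p = (p0 - params.rp * q[0]) * np.exp(-(t - t[0]) / tau) + params.rp * q + integral / params.c
    return inflow.with_values(p, kind="pressure", unit="barye")


def wk_periodic_p0(params: WindkesselParams, inflow: Waveform) -> float:
    """The unique P(0) making the response periodic, P(T) = P(0).

    The solution is affine in P(0); imposing periodicity over one cycle
    gives P(0) = Rp Q(0) + I(T)/C / (1 − e^{−T/τ}).  This is the state the
    system relaxes to after the start-up transient has decayed, so it
    replaces multi-cycle warm-up runs exactly.
    """
    tau = params.tau
    T = inflow.period
    efac = -np.expm1(-T / tau)  # 1 - e^{-T/tau}, accurate for small T/tau
    if efac <= 0 or efac < 1e-14:
        raise ValueError("period/tau too small: periodic state ill-conditioned")
    # Extend the grid to t = T with the wrapped sample Q(T) = Q(0).
    t_ext = np.concatenate([inflow.times, [inflow.times[0] + T]])
    q_ext = np.concatenate([inflow.values, [inflow.values[0]]])
    i_T = _conv_integral(t_ext, q_ext, tau)[-1]
    return float(params.rp * inflow.values[0] + (i_T / params.c) / efac)


def wk_periodic_pressure(params: WindkesselParams, inflow: Waveform) -> Waveform:
    """Convenience: the periodic pressure response (P(0) chosen periodic)."""
    return wk_pressure(params, inflow, wk_periodic_p0(params, inflow))


def summarize_pressure(p: Waveform) -> PressureSummary:
    """Max, min and cycle-mean of a pressure waveform, reported in mmHg."""
    if p.kind != "pressure":
        raise ValueError("expected a pressure waveform")
    vals = convert_pressure(p.values, p.unit, "mmHg")
    mean = convert_pressure(p.time_average(), p.unit, "mmHg")
    return PressureSummary(pmax=float(np.max(vals)), pmin=float(np.min(vals)),
                           pmean=float(mean))
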