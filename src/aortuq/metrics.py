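"""Quantities of interest derived from forward-model results.

Pressure drop between a proximal and a distal station, time-averaged wall
shear stress (TAWSS) of an externally supplied |WSS| field, and the
peak-flow agreement errors used to compare simulated with measured
waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import Waveform

__all__ = ["WSSField", "pressure_drop", "tawss", "flow_error", "flow_rms_error"]


@dataclass
class WSSField:
    """|WSS|(s, t) sampled at abstract wall sites s over one cycle (dyn/cm²)."""

    positions: list
    times: np.ndarray
    magnitudes: np.ndarray  # shape (n_positions, n_times)
    period: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if self.magnitudes.shape != (len(self.positions), self.times.size):
            raise ValueError("magnitudes must be (n_positions, n_times)")
        if np.any(self.magnitudes < 0):
            raise ValueError("|WSS| magnitudes must be nonnegative")
        if self.period <= 0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("invalid time grid")


def pressure_drop(proximal: Waveform, distal: Waveform) -> Waveform:
    """ΔP(t) = P_proximal(t) − P_distal(t), on the proximal time grid."""
    if proximal.period != distal.period:
        raise ValueError("waveform periods differ")
    if proximal.unit != distal.unit:
        raise ValueError("pressure units differ; convert first")
    if np.array_equal(proximal.times, distal.times):
        dvals = distal.values
    else:
        dvals = distal(proximal.times)
    return proximal.with_values(proximal.values - dvals)


def tawss(field: WSSField) -> np.ndarray:
    """Per-position time average (1/T)∫₀ᵀ |WSS| dt with periodic closure."""
    t = np.concatenate([field.times, [field.times[0] + field.period]])
    m = np.concatenate([field.magnitudes, field.magnitudes[:, :1]], axis=1)
    return np.trapezoid(m, t, axis=1) / field.period


def flow_error(sim: Waveform, ref: Waveform) -> tuple[float, float]:
    """Peak-flow disagreement: (max(sim) − max(ref), its percentage of max(ref))."""
    if sim.period != ref.period:
        raise ValueError("waveform periods differ")
    ref_peak = float(np.max(ref.values))
    if ref_peak == 0:
        raise ValueError("reference peak flow is zero")
    diff = float(np.max(sim.values)) - ref_peak
    return diff, 100.0 * diff / ref_peak


def flow_rms_error(sim: Waveform, ref: Waveform) -> float:
    """Secondary metric: RMS of sim − ref over the cycle (ref resampled)."""
    if sim.period != ref.period:
        raise ValueError("waveform periods differ")
    rv = ref(sim.times)
    return float(np.sqrt(np.mean((sim.values - rv) ** 2)))
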