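"""Domain types and I/O shared by every stage of the pipeline.

All internal computation uses the CGS unit system (g, cm, s): flows in
cm³/s, pressures in barye (dyn/cm²), resistances in g cm⁻⁴ s⁻¹ and
compliances in g⁻¹ cm⁴ s².  Clinical pressures are expressed in mmHg and
are converted at the I/O boundary only.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MMHG_TO_BARYE",
    "BLOOD_DENSITY",
    "convert_pressure",
    "Waveform",
    "read_waveform",
    "write_waveform",
    "OutletGeometry",
    "WindkesselParams",
    "OutletBCSet",
    "PressureSummary",
    "OUTLET_NAMES",
]

#: 1 mmHg in barye (dyn/cm²).
MMHG_TO_BARYE = 1333.22

#: Blood density in g/cm³.
BLOOD_DENSITY = 1.060

#: Outlet order used throughout: the three supra-aortic branches
#: (brachiocephalic, left common carotid, left subclavian) and the
#: descending aorta.
OUTLET_NAMES = ("bca", "lcca", "lsa", "da")

_PRESSURE_UNITS = {"mmHg", "barye"}


def convert_pressure(value, from_unit: str, to_unit: str):
    """Convert a pressure (scalar or array) between mmHg and barye."""
    for u in (from_unit, to_unit):
        if u not in _PRESSURE_UNITS:
            raise ValueError(f"unknown pressure unit {u!r}; expected mmHg or barye")
    if from_unit == to_unit:
        return value
    if from_unit == "mmHg":
        return np.multiply(value, MMHG_TO_BARYE)
    return np.divide(value, MMHG_TO_BARYE)


@dataclass
class Waveform:
    """A periodic sampled time series over one cardiac cycle.

    Samples live on [0, period); the value at arbitrary t is obtained by
    linear interpolation with periodic wrap-around, so ``w(t) == w(t + T)``
    for every t.
    """

    times: np.ndarray
    values: np.ndarray
    period: float
    kind: str = "flow"  # "flow" or "pressure"
    unit: str = "cm3/s"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size == 0:
            raise ValueError("waveform must have at least one sample")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("non-monotonic times")
        if self.times[0] < 0 or self.times[-1] >= self.period:
            raise ValueError("times must satisfy 0 <= t < period")

    @property
    def n_samples(self) -> int:
        return self.times.size

    def _wrapped_grid(self):
        """Sample grid extended with the periodic closure point (T, v[0])."""
        t = np.concatenate([self.times, [self.times[0] + self.period]])
        v = np.concatenate([self.values, [self.values[0]]])
        return t, v

    def __call__(self, t):
        """Periodic linear interpolation at time(s) t."""
        tg, vg = self._wrapped_grid()
        tm = np.mod(np.asarray(t, dtype=float) - self.times[0], self.period) + self.times[0]
        return np.interp(tm, tg, vg)

    def time_average(self) -> float:
        """Cycle mean (1/T)∫₀ᵀ v dt, trapezoidal with periodic closure."""
        tg, vg = self._wrapped_grid()
        return float(np.trapezoid(vg, tg) / self.period)

    def with_values(self, values, kind=None, unit=None) -> "Waveform":
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            kind=kind if kind is not None else self.kind,
            unit=unit if unit is not None else self.unit,
        )

    def resample(self, n: int) -> "Waveform":
        t = np.linspace(0.0, self.period, n, endpoint=False)
        return replace(self, times=t, values=self(t))


_HEADER_RE = re.compile(r"#\s*units=(\S+)\s+period=(\S+)(?:\s+kind=(\S+))?")


def write_waveform(w: Waveform, path) -> None:
    """Write a waveform as CSV with a ``# units=... period=...`` header."""
    with open(path, "w") as fh:
        fh.write(f"# units={w.unit} period={w.period!r} kind={w.kind}\n")
        fh.write("time,value\n")
        for t, v in zip(w.times, w.values):
            fh.write(f"{float(t)!r},{float(v)!r}\n")


def read_waveform(path) -> Waveform:
    """Read a waveform CSV written by :func:`write_waveform`."""
    with open(path) as fh:
        header = fh.readline()
        m = _HEADER_RE.match(header)
        if not m:
            raise ValueError(f"missing '# units=... period=...' header in {path}")
        unit, period_s, kind = m.group(1), m.group(2), m.group(3) or "flow"
        period = float(period_s)
        if period <= 0:
            raise ValueError("negative or zero period in header")
        body = fh.read()
    data = np.genfromtxt(io.StringIO(body), delimiter=",", skip_header=1)
    data = np.atleast_2d(data)
    return Waveform(times=data[:, 0], values=data[:, 1], period=period,
                    kind=kind, unit=unit)


@dataclass(frozen=True)
class OutletGeometry:
    """Outlet cross-sectional areas of the four-branch aortic model (cm²).

    ``da_area_mode`` selects which area represents the descending-aorta
    pathway when distributing lumped parameters: the minimum coarctation
    cross-section (``"coa"``, appropriate before stenting, where the
    narrowing adds resistance) or the descending-aorta section itself
    (``"da"``, after stenting).
    """

    area_bca: float
    area_lcca: float
    area_lsa: float
    area_da: float
    area_coa: float
    da_area_mode: str = "coa"

    def __post_init__(self):
        for name in ("area_bca", "area_lcca", "area_lsa", "area_da", "area_coa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.area_coa > self.area_da:
            raise ValueError("coarctation area cannot exceed the descending-aorta area")
        if self.da_area_mode not in ("coa", "da"):
            raise ValueError("da_area_mode must be 'coa' or 'da'")

    @property
    def supra_areas(self) -> tuple:
        return (self.area_bca, self.area_lcca, self.area_lsa)

    @property
    def da_pathway_area(self) -> float:
        return self.area_coa if self.da_area_mode == "coa" else self.area_da


@dataclass(frozen=True)
class WindkesselParams:
    """One RCR triplet: proximal resistance, distal resistance, compliance.

    Units: resistances g cm⁻⁴ s⁻¹, compliance g⁻¹ cm⁴ s².
    """

    rp: float
    rd: float
    c: float

    def __post_init__(self):
        if self.rp <= 0 or self.rd <= 0 or self.c <= 0:
            raise ValueError("Windkessel parameters must be positive")

    @property
    def tau(self) -> float:
        """Exponential time constant τ = Rd·C of the distal RC pair (s)."""
        return self.rd * self.c

    @property
    def r_total(self) -> float:
        return self.rp + self.rd

    def as_array(self) -> np.ndarray:
        return np.array([self.rp, self.rd, self.c])


@dataclass(frozen=True)
class OutletBCSet:
    """RCR triplets for the four outlets plus the split value α used."""

    bca: WindkesselParams
    lcca: WindkesselParams
    lsa: WindkesselParams
    da: WindkesselParams
    alpha: float = 0.0

    def items(self):
        return [(n, getattr(self, n)) for n in OUTLET_NAMES]

    def __getitem__(self, name: str) -> WindkesselParams:
        if name not in OUTLET_NAMES:
            raise KeyError(name)
        return getattr(self, name)


@dataclass(frozen=True)
class PressureSummary:
    """Max / min / cycle-mean pressure in mmHg."""

    pmax: float
    pmin: float
    pmean: float

    def __post_init__(self):
        # tolerate float roundoff on flat waveforms, where the quadrature
        # mean can exceed the sampled max by a few ulps
        tol = 1e-9 * max(1.0, abs(self.pmax))
        if self.pmean > self.pmax + tol or self.pmean < self.pmin - tol:
            raise ValueError("require pmin <= pmean <= pmax")
        clamped = min(max(self.pmean, self.pmin), self.pmax)
        object.__setattr__(self, "pmean", clamped)

    def as_array(self) -> np.ndarray:
        return np.array([self.pmax, self.pmin, self.pmean])
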