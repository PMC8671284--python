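"""Synthetic inputs: physiological inflow pulses and the published
patient numbers, so the whole pipeline runs without any external data.

The patient flow waveforms exist only as figures in the source study, so
tests and examples use a single-peaked half-sine systolic pulse with the
study's cycle lengths.  The clinical scalars (catheter pressures, outlet
cross-sections, calibrated totals) are reproduced verbatim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datamodel import (
    MMHG_TO_BARYE,
    OutletGeometry,
    PressureSummary,
    Waveform,
    WindkesselParams,
)
from .metrics import WSSField

__all__ = ["PulseSpec", "make_inflow", "PatientFixture", "patient_fixture",
           "make_wss_field"]


@dataclass(frozen=True)
class PulseSpec:
    """Shape of a synthetic inlet flow pulse.

    A half-sine systolic lobe of width ``systolic_fraction·period`` rises
    from ``diastolic_level`` to ``peak``; the rest of the cycle sits at the
    diastolic level.  Mean flow has the closed form
    d + (2/π)·s·(peak − d).  Optional Gaussian sample noise (sd
    ``noise_sd``) is added when ``seed`` is set; the amplitude default is
    arbitrary, chosen merely to be visible against the pulse.
    """

    period: float = 0.7          # s
    peak: float = 400.0          # cm³/s
    systolic_fraction: float = 0.4
    diastolic_level: float = 0.0  # cm³/s
    seed: int | None = None
    noise_sd: float = 2.0        # cm³/s, used only when seed is set

    def __post_init__(self):
        if not 0 < self.systolic_fraction < 1:
            raise ValueError("systolic_fraction must be in (0, 1)")
        if not self.peak >= self.diastolic_level >= 0:
            raise ValueError("require peak >= diastolic_level >= 0")
        if self.period <= 0:
            raise ValueError("period must be positive")

    @property
    def mean_flow(self) -> float:
        """Closed-form cycle mean of the noise-free pulse (cm³/s)."""
        return self.diastolic_level + (2.0 / math.pi) * self.systolic_fraction * (
            self.peak - self.diastolic_level)


def make_inflow(spec: PulseSpec, n_samples: int = 256) -> Waveform:
    """Sample the pulse on a uniform grid over [0, period)."""
    if n_samples < 32:
        raise ValueError("need at least 32 samples per cycle")
    t = np.linspace(0.0, spec.period, n_samples, endpoint=False)
    t_sys = spec.systolic_fraction * spec.period
    q = np.full(n_samples, float(spec.diastolic_level))
    lobe = t < t_sys
    q[lobe] += (spec.peak - spec.diastolic_level) * np.sin(np.pi * t[lobe] / t_sys)
    if spec.seed is not None and spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        q = q + rng.normal(0.0, spec.noise_sd, n_samples)
    return Waveform(times=t, values=q, period=spec.period, kind="flow", unit="cm3/s")


@dataclass(frozen=True)
class PatientFixture:
    geometry: OutletGeometry
    targets: PressureSummary
    totals: WindkesselParams
    period: float
    pulse: PulseSpec


# Minimum coarctation diameter (cm); its circular area, 0.754 cm², is the
# printed 0.75 cm² coarctation cross-section at full precision and
# reproduces the published per-outlet resistance tables noticeably better
# than the rounded value.
COA_DIAMETER = 0.98
COA_AREA = math.pi * (COA_DIAMETER / 2.0) ** 2


def _pulse_for(targets: PressureSummary, totals: WindkesselParams,
               period: float) -> PulseSpec:
    # Peak chosen so the pulse's mean flow equals Pmean/(R̄p+R̄d): the
    # fixture pressures and fixture totals are then mutually consistent,
    # enabling closed-loop calibration round trips.
    mean_q = targets.pmean * MMHG_TO_BARYE / totals.r_total
    frac = 0.4
    peak = mean_q * math.pi / (2.0 * frac)
    return PulseSpec(period=period, peak=peak, systolic_fraction=frac,
                     diastolic_level=0.0)


def patient_fixture(stage: str) -> PatientFixture:
    """Published clinical numbers for the pre- or post-stenting stage.

    Pre-stenting: supra-aortic areas 1.44/0.28/1.36 cm², DA 2.27 cm²,
    coarctation 0.754 cm² (from the 0.98 cm minimum diameter), catheter
    pressures 97/64/80 mmHg, calibrated totals (56.32, 845.56, 1.06e-3),
    cycle 0.7 s.  Post-stenting: BCA area 1.06 cm², pressures 85/63/74
    mmHg, totals (37.05, 910.49, 2.3e-3), cycle 1.0 s, DA pathway taken as
    the descending-aorta section itself.
    """
    if stage == "pre":
        geom = OutletGeometry(area_bca=1.44, area_lcca=0.28, area_lsa=1.36,
                              area_da=2.27, area_coa=COA_AREA, da_area_mode="coa")
        targets = PressureSummary(pmax=97.0, pmin=64.0, pmean=80.0)
        totals = WindkesselParams(rp=56.32, rd=845.56, c=1.06e-3)
        period = 0.7
    elif stage == "post":
        geom = OutletGeometry(area_bca=1.06, area_lcca=0.28, area_lsa=1.36,
                              area_da=2.27, area_coa=COA_AREA, da_area_mode="da")
        targets = PressureSummary(pmax=85.0, pmin=63.0, pmean=74.0)
        totals = WindkesselParams(rp=37.05, rd=910.49, c=2.3e-3)
        period = 1.0
    else:
        raise ValueError("stage must be 'pre' or 'post'")
    return PatientFixture(geometry=geom, targets=targets, totals=totals,
                          period=period,
                          pulse=_pulse_for(targets, totals, period))


def make_wss_field(n_positions: int, pattern: str = "pulse", seed: int = 0,
                   n_times: int = 160, period: float = 0.7) -> WSSField:
    """Synthetic |WSS| fields with closed-form time averages.

    Patterns: ``constant`` — position s holds 5+s everywhere (TAWSS 5+s);
    ``pulse`` — 10 dyn/cm² for the first 30% of the cycle, 2 elsewhere
    (TAWSS 4.4 by the duty-cycle average); ``noise`` — seeded positive
    lognormal samples.
    """
    if n_positions < 1:
        raise ValueError("need at least one position")
    t = np.linspace(0.0, period, n_times, endpoint=False)
    if pattern == "constant":
        mags = np.repeat((5.0 + np.arange(n_positions))[:, None], n_times, axis=1)
    elif pattern == "pulse":
        # duty cycle defined by sample count so the 30% edge sits exactly
        # on the grid and the trapezoidal average is the closed form
        n_high = int(round(0.3 * n_times))
        row = np.where(np.arange(n_times) < n_high, 10.0, 2.0)
        mags = np.repeat(row[None, :], n_positions, axis=0)
    elif pattern == "noise":
        rng = np.random.default_rng(seed)
        mags = rng.lognormal(mean=1.0, sigma=0.4, size=(n_positions, n_times))
    else:
        raise ValueError("pattern must be constant, pulse or noise")
    return WSSField(positions=list(range(n_positions)), times=t,
                    magnitudes=mags, period=period)
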