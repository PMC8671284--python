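"""Distribution of total Windkessel parameters to the four outlets.

The total proximal resistance R̄p, distal resistance R̄d and compliance C̄
obtained by calibration describe the whole downstream circulation; they are
shared among the outlets in inverse proportion to outlet cross-sectional
area (resistances) and in direct proportion (compliances).  For the
descending aorta the minimum coarctation cross-section stands in for the
outlet area before stenting, so the narrowing's extra resistance enters
geometrically.

A dimensionless split value α further redistributes flow: each
supra-aortic branch total resistance is scaled by (1+α) and the
descending-aorta resistance is raised (for α < 0) through the requirement
that the parallel total resistance of the system stays exactly R̄p + R̄d.
"""

from __future__ import annotations

import numpy as np

from .datamodel import OutletBCSet, OutletGeometry, WindkesselParams

__all__ = [
    "total_area",
    "distribute_by_area",
    "coa_k_factor",
    "apply_alpha",
    "parallel_total_resistance",
]


def total_area(geom: OutletGeometry) -> float:
    """Sum of the three supra-aortic areas plus the DA pathway area (cm²)."""
    return float(sum(geom.supra_areas) + geom.da_pathway_area)


def _outlet_areas(geom: OutletGeometry) -> dict:
    return {
        "bca": geom.area_bca,
        "lcca": geom.area_lcca,
        "lsa": geom.area_lsa,
        "da": geom.da_pathway_area,
    }


def distribute_by_area(total: WindkesselParams, geom: OutletGeometry) -> OutletBCSet:
    """Area-proportional split of the totals: Rᵢ = R̄·A_tot/Aᵢ, Cᵢ = C̄·Aᵢ/A_tot."""
    a_tot = total_area(geom)
    triplets = {}
    for name, a_i in _outlet_areas(geom).items():
        triplets[name] = WindkesselParams(
            rp=total.rp * a_tot / a_i,
            rd=total.rd * a_tot / a_i,
            c=total.c * a_i / a_tot,
        )
    return OutletBCSet(alpha=0.0, **triplets)


def coa_k_factor(geom: OutletGeometry, alpha: float) -> float:
    """Compact factor k = A_CoA / (A_tot − Σᵢ Aᵢ/(1+α)) for the DA resistance.

    Σᵢ runs over the supra-aortic branches.  k = 1 at α = 0; the
    denominator must stay positive, which bounds how negative α may be for
    a given geometry.
    """
    a_tot = total_area(geom)
    supra_sum = sum(geom.supra_areas)
    denom = a_tot - supra_sum / (1.0 + alpha)
    if denom <= 0:
        raise ValueError(
            f"alpha={alpha} outside the admissible range: the implied "
            "descending-aorta resistance is infinite or negative"
        )
    return float(geom.da_pathway_area / denom)


def apply_alpha(total: WindkesselParams, geom: OutletGeometry, alpha: float) -> OutletBCSet:
    """α-redistributed outlet set.

    Supra-aortic branch i: R_i = (1+α)·R_tot·A_tot/A_i.
    Descending aorta:      R_DA = k·R_tot·A_tot/A_DA-pathway.
    Each outlet total splits into proximal and distal parts in the fixed
    ratio R̄p : R̄d, and compliances are the α-independent area fractions
    of C̄ (both choices match the published per-outlet tables row by row).
    """
    base = distribute_by_area(total, geom)
    if alpha == 0.0:
        return base
    k = coa_k_factor(geom, alpha)
    r_tot = total.r_total
    a_tot = total_area(geom)
    frac_p = total.rp / r_tot
    areas = _outlet_areas(geom)
    triplets = {}
    for name, a_i in areas.items():
        scale = k if name == "da" else (1.0 + alpha)
        r_i = scale * r_tot * a_tot / a_i
        triplets[name] = WindkesselParams(
            rp=frac_p * r_i,
            rd=(1.0 - frac_p) * r_i,
            c=base[name].c,
        )
    return OutletBCSet(alpha=alpha, **triplets)


def parallel_total_resistance(bcs: OutletBCSet) -> float:
    """Harmonic (parallel-circuit) total: 1/R = Σ 1/(rpᵢ + rdᵢ)."""
    inv = sum(1.0 / (p.rp + p.rd) for _, p in bcs.items())
    return float(1.0 / inv)


def admissible_alpha_lower_bound(geom: OutletGeometry) -> float:
    """Infimum of α for which the k denominator stays positive."""
    supra_sum = sum(geom.supra_areas)
    return float(supra_sum / total_area(geom) - 1.0)
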