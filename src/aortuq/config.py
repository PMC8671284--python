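"""Structured configuration shared by all CLI commands.

A single YAML (or JSON) document carries the geometry, the pressure
targets, the GA settings, the α interval and the 0D solver settings, so a
whole study is reproducible from one file plus one inflow CSV.
"""

from __future__ import annotations

import json

import yaml

from .calibration import DEFAULT_LOWER, DEFAULT_UPPER, GASettings
from .datamodel import OutletGeometry, PressureSummary
from .fixtures import PatientFixture
from .gpc import UncertainParam
from .network0d import SolverSettings

__all__ = ["load_config", "save_config", "default_config",
           "geometry_from_config", "targets_from_config",
           "ga_settings_from_config", "alpha_param_from_config",
           "solver_settings_from_config"]


def load_config(path) -> dict:
    with open(path) as fh:
        text = fh.read()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        if str(path).endswith(".json"):
            json.dump(cfg, fh, indent=2)
        else:
            yaml.safe_dump(cfg, fh, sort_keys=False)


def default_config(fixture: PatientFixture) -> dict:
    g = fixture.geometry
    t = fixture.targets
    return {
        "geometry": {
            "bca": g.area_bca, "lcca": g.area_lcca, "lsa": g.area_lsa,
            "da": g.area_da, "coa": g.area_coa, "da_area_mode": g.da_area_mode,
        },
        "pressure_targets": {"pmax": t.pmax, "pmin": t.pmin, "pmean": t.pmean},
        "ga": {
            "population_size": 40, "generations": 250,
            "p_crossover": 0.5, "p_mutation": 0.1, "p_selection": 0.05,
            "grid_points": 1024, "seed": 0,
            "lower_bounds": list(DEFAULT_LOWER),
            "upper_bounds": list(DEFAULT_UPPER),
            "eps_max": 0.001, "eps_min": 0.001, "eps_run": 0.5,
        },
        "alpha": {"low": -0.15, "high": -0.08, "order": 3},
        "solver": {"dt": 0.002, "cycles": 6, "tol": 1e-6},
        "period": fixture.period,
    }


def geometry_from_config(cfg: dict) -> OutletGeometry:
    g = cfg["geometry"]
    return OutletGeometry(area_bca=g["bca"], area_lcca=g["lcca"],
                          area_lsa=g["lsa"], area_da=g["da"],
                          area_coa=g["coa"],
                          da_area_mode=g.get("da_area_mode", "coa"))


def targets_from_config(cfg: dict) -> PressureSummary:
    t = cfg["pressure_targets"]
    return PressureSummary(pmax=t["pmax"], pmin=t["pmin"], pmean=t["pmean"])


def ga_settings_from_config(cfg: dict, seed: int | None = None) -> GASettings:
    g = cfg.get("ga", {})
    return GASettings(
        population_size=g.get("population_size", 40),
        generations=g.get("generations", 250),
        p_crossover=g.get("p_crossover", 0.5),
        p_mutation=g.get("p_mutation", 0.1),
        p_selection=g.get("p_selection", 0.05),
        grid_points=g.get("grid_points", 1024),
        seed=seed if seed is not None else g.get("seed", 0),
        penalty_weight=g.get("penalty_weight", 1e3),
        eps_run=g.get("eps_run", 0.5),
    )


def calibration_bounds_from_config(cfg: dict):
    g = cfg.get("ga", {})
    lower = tuple(g.get("lower_bounds", DEFAULT_LOWER))
    upper = tuple(g.get("upper_bounds", DEFAULT_UPPER))
    eps_max = g.get("eps_max", 0.001)
    eps_min = g.get("eps_min", 0.001)
    return lower, upper, eps_max, eps_min


def alpha_param_from_config(cfg: dict) -> UncertainParam:
    a = cfg.get("alpha", {})
    return UncertainParam(low=a.get("low", -0.15), high=a.get("high", -0.08),
                          order=a.get("order", 3))


def solver_settings_from_config(cfg: dict) -> SolverSettings:
    s = cfg.get("solver", {})
    return SolverSettings(dt=s.get("dt", 0.002), max_cycles=s.get("cycles", 6),
                          periodicity_tol=s.get("tol", 1e-6))
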