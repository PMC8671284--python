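"""Constrained genetic-algorithm estimation of the total RCR triplet.

Given catheter pressure statistics (Pmax, Pmin, Pmean) and an inlet flow
waveform, find total parameters (R̄p, R̄d, C̄) whose periodic Windkessel
pressure response matches them:

    minimize   ((1/T)∫ P dt − Pmean)²
    subject to |max P − Pmax| ≤ ε_max,  |min P − Pmin| ≤ ε_min,
               l_b ≤ x ≤ u_b.

The optimizer is a single-objective genetic algorithm of the MOGA-II
family: each parameter axis is discretized into a uniform grid, the
initial population is a Sobol sequence snapped to that grid, and the
population evolves by directional crossover (probability 0.5), uniform
mutation to a random grid value (0.1) and selection, i.e. replacement by a
copy of a better individual (0.05), with elitism.  Constraints are handled
by a static penalty with feasibility-first ranking.

Three scalar targets cannot pin down three parameters plus a waveform
shape uniquely; what the search guarantees is the pressure summary, not
the triplet itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

from .datamodel import PressureSummary, Waveform, WindkesselParams
from .windkessel import summarize_pressure, wk_periodic_p0, wk_pressure

__all__ = [
    "GASettings",
    "CalibrationProblem",
    "objective_and_constraints",
    "sobol_population",
    "ga_step",
    "calibrate_total_wk",
]

# Default search box: brackets the published pre- and post-stenting totals
# by roughly a factor of five on each side.
DEFAULT_LOWER = (5.0, 100.0, 1e-4)
DEFAULT_UPPER = (300.0, 5000.0, 1e-2)


@dataclass(frozen=True)
class GASettings:
    population_size: int = 40
    generations: int = 250
    p_crossover: float = 0.5
    p_mutation: float = 0.1
    p_selection: float = 0.05
    grid_points: int = 1024
    seed: int = 0
    penalty_weight: float = 1e3  # mmHg² per mmHg of constraint violation
    eps_run: float = 0.5         # mmHg band used for feasibility ranking

    def __post_init__(self):
        for p in (self.p_crossover, self.p_mutation, self.p_selection):
            if not 0.0 <= p <= 1.0:
                raise ValueError("operator probabilities must lie in [0, 1]")
        if self.population_size < 4:
            raise ValueError("population_size must be at least 4")
        if self.grid_points < 2:
            raise ValueError("grid_points must be at least 2")


@dataclass(frozen=True)
class CalibrationProblem:
    targets: PressureSummary
    inflow: Waveform
    lower_bounds: tuple = DEFAULT_LOWER
    upper_bounds: tuple = DEFAULT_UPPER
    eps_max: float = 0.001  # mmHg, as printed; rarely attainable in practice
    eps_min: float = 0.001

    def __post_init__(self):
        lb = np.asarray(self.lower_bounds, dtype=float)
        ub = np.asarray(self.upper_bounds, dtype=float)
        if lb.shape != (3,) or ub.shape != (3,):
            raise ValueError("bounds must be (rp, rd, c) triples")
        if np.any(lb >= ub) or np.any(lb <= 0):
            raise ValueError("require 0 < lower < upper componentwise")
        if self.eps_max < 0 or self.eps_min < 0:
            raise ValueError("tolerances must be nonnegative")

    def simulated_summary(self, x: WindkesselParams) -> PressureSummary:
        p0 = wk_periodic_p0(x, self.inflow)
        return summarize_pressure(wk_pressure(x, self.inflow, p0))


def objective_and_constraints(x: WindkesselParams, prob: CalibrationProblem):
    """Squared mean-pressure error and clipped max/min violations (mmHg)."""
    s = prob.simulated_summary(x)
    obj = (s.pmean - prob.targets.pmean) ** 2
    vmax = max(abs(s.pmax - prob.targets.pmax) - prob.eps_max, 0.0)
    vmin = max(abs(s.pmin - prob.targets.pmin) - prob.eps_min, 0.0)
    return obj, (vmax, vmin)


def _grids(prob: CalibrationProblem, settings: GASettings):
    return [np.linspace(lo, hi, settings.grid_points)
            for lo, hi in zip(prob.lower_bounds, prob.upper_bounds)]


def _snap(x: np.ndarray, prob: CalibrationProblem, settings: GASettings) -> np.ndarray:
    """Clip to bounds and round each coordinate to the nearest grid value."""
    lb = np.asarray(prob.lower_bounds)
    ub = np.asarray(prob.upper_bounds)
    step = (ub - lb) / (settings.grid_points - 1)
    idx = np.rint((np.clip(x, lb, ub) - lb) / step)
    return lb + idx * step


def sobol_population(prob: CalibrationProblem, settings: GASettings) -> np.ndarray:
    """Initial population: a Sobol sequence snapped to the parameter grid."""
    sampler = qmc.Sobol(d=3, scramble=True, seed=settings.seed)
    m = max(int(np.ceil(np.log2(settings.population_size))), 1)
    u = sampler.random_base2(m)[: settings.population_size]
    lb = np.asarray(prob.lower_bounds)
    ub = np.asarray(prob.upper_bounds)
    return _snap(lb + u * (ub - lb), prob, settings)


def _evaluate(pop: np.ndarray, prob: CalibrationProblem):
    objs = np.empty(len(pop))
    viols = np.empty((len(pop), 2))
    for i, row in enumerate(pop):
        obj, (vmax, vmin) = objective_and_constraints(
            WindkesselParams(*row), prob)
        objs[i] = obj
        viols[i] = (vmax, vmin)
    return objs, viols


def _rank_keys(objs, viols, settings: GASettings):
    """Feasibility-first penalized fitness; lower is better.

    Feasibility during search uses the practical band eps_run on top of
    the problem's printed tolerances.
    """
    slack = np.maximum(viols - settings.eps_run, 0.0).sum(axis=1)
    feasible = slack <= 0
    penalized = objs + settings.penalty_weight * slack
    # Infeasible individuals are pushed behind every feasible one.
    return np.where(feasible, penalized, penalized + 1e12), feasible


def ga_step(population: np.ndarray, prob: CalibrationProblem,
            settings: GASettings, rng: np.random.Generator,
            fitness=None) -> np.ndarray:
    """One generation: crossover, mutation, selection, elitist replacement.

    Each individual breeds one offspring through the three operators; the
    offspring takes the parent's slot only if its penalized fitness is not
    worse, so the population is monotonically non-worsening and the best
    individual is always preserved.
    """
    pop = np.asarray(population, dtype=float)
    n = len(pop)
    if fitness is None:
        objs, viols = _evaluate(pop, prob)
        keys, _ = _rank_keys(objs, viols, settings)
    else:
        keys = np.asarray(fitness, dtype=float)
    grids = _grids(prob, settings)

    new = pop.copy()
    for i in range(n):
        x = pop[i].copy()
        changed = False
        if rng.random() < settings.p_crossover:
            j = int(rng.integers(n))
            if j != i:
                # Move toward a better individual, away from a worse one.
                direction = 1.0 if keys[j] < keys[i] else -1.0
                u = rng.random(3)
                x = x + u * direction * (pop[j] - x)
                changed = True
        if rng.random() < settings.p_mutation:
            axis = int(rng.integers(3))
            x[axis] = grids[axis][rng.integers(settings.grid_points)]
            changed = True
        if rng.random() < settings.p_selection:
            better = np.flatnonzero(keys < keys[i])
            if better.size:
                x = pop[int(rng.choice(better))].copy()
                changed = True
        if not changed:
            continue
        x = _snap(x, prob, settings)
        child_obj, (cvmax, cvmin) = objective_and_constraints(
            WindkesselParams(*x), prob)
        child_key, _ = _rank_keys(np.array([child_obj]),
                                  np.array([[cvmax, cvmin]]), settings)
        if child_key[0] <= keys[i]:
            new[i] = x
    return new


def calibrate_total_wk(prob: CalibrationProblem, settings: GASettings | None = None):
    """Run the GA and return (best WindkesselParams, diagnostics dict).

    The best individual is the feasible one (violations within the
    configured bands) with the smallest mean-pressure objective seen over
    the whole run; if nothing feasible was encountered, the
    least-violating individual is returned instead.
    """
    if settings is None:
        settings = GASettings()
    t = prob.targets
    if not (t.pmin <= t.pmean <= t.pmax):
        raise ValueError("infeasible targets: require pmin <= pmean <= pmax")

    rng = np.random.default_rng(settings.seed + 1)
    pop = sobol_population(prob, settings)
    trace = []
    best_key = np.inf
    best_x = None
    for gen in range(settings.generations):
        objs, viols = _evaluate(pop, prob)
        keys, feas = _rank_keys(objs, viols, settings)
        i = int(np.argmin(keys))
        if keys[i] < best_key:
            best_key = keys[i]
            best_x = pop[i].copy()
        trace.append({"generation": gen, "best_objective": float(objs[i]),
                      "best_violation": float(viols[i].sum()),
                      "feasible": bool(feas[i])})
        pop = ga_step(pop, prob, settings, rng, fitness=keys)

    params = WindkesselParams(*best_x)
    achieved = prob.simulated_summary(params)
    diagnostics = {
        "trace": trace,
        "achieved": achieved,
        "feasible": bool(best_key < 1e12),
        "best_objective_mmhg2": float(best_key if best_key < 1e12 else np.nan),
    }
    return params, diagnostics
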