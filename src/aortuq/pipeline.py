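"""End-to-end propagation of the uncertain split value α.

Runs the tune → simulate chain at each collocation node of α, projects
every quantity of interest onto the polynomial-chaos basis and returns the
expansions, from which stochastic means, standard deviations and sampled
probability densities follow.  Also provides the file form of the
forward-model contract, so externally computed per-outlet results (e.g.
from a 3D CFD run) can be post-processed identically.
"""

from __future__ import annotations

import json
import os

import numpy as np

from .datamodel import (
    OUTLET_NAMES,
    OutletGeometry,
    Waveform,
    WindkesselParams,
    read_waveform,
    write_waveform,
)
from .gpc import GPCExpansion, UncertainParam, project, quadrature_nodes
from .network0d import SimResult, SolverSettings, simulate
from .tuning import apply_alpha

__all__ = ["propagate_alpha", "write_sim_result", "read_sim_result"]


def propagate_alpha(totals: WindkesselParams, geom: OutletGeometry,
                    inflow: Waveform, param: UncertainParam,
                    n_nodes: int = 4,
                    settings: SolverSettings | None = None,
                    coa_element: float = 0.0) -> dict:
    """Build gPC surrogates of the forward-model outputs over α.

    Returns a dict with the collocation ``nodes``, the output ``times``
    grid, and one :class:`GPCExpansion` per quantity: each outlet flow
    (``flow_bca`` ... ``flow_da``), the junction pressure
    (``junction_pressure``) and the pressure drop (``dp``).
    """
    if n_nodes < param.order + 1:
        raise ValueError("need at least order + 1 collocation nodes")
    nodes, weights = quadrature_nodes(param, n_nodes)
    results = []
    for a in nodes:
        bcs = apply_alpha(totals, geom, float(a))
        coa_area = geom.area_coa if coa_element > 0 else None
        results.append(simulate(inflow, bcs, settings,
                                coa_element=coa_element, coa_area=coa_area))
    times = results[0].junction_pressure.times
    out = {"nodes": nodes, "weights": weights, "times": times,
           "period": inflow.period}
    for name in OUTLET_NAMES:
        evals = np.stack([r.outlet_flows[name].values for r in results])
        out[f"flow_{name}"] = project(evals, param)
    out["junction_pressure"] = project(
        np.stack([r.junction_pressure.values for r in results]), param)
    out["dp"] = project(np.stack([r.dp.values for r in results]), param)
    return out


def write_sim_result(res: SimResult, out_dir) -> None:
    """Serialize a SimResult as a bundle of waveform CSVs plus a JSON index."""
    os.makedirs(out_dir, exist_ok=True)
    index = {"converged": res.converged, "cycles_run": res.cycles_run,
             "residual": res.residual, "files": {}}
    for name, wf in res.outlet_flows.items():
        fn = f"flow_{name}.csv"
        write_waveform(wf, os.path.join(out_dir, fn))
        index["files"][f"flow_{name}"] = fn
    for key, wf in (("junction_pressure", res.junction_pressure),
                    ("distal_pressure_da", res.distal_pressure_da),
                    ("dp", res.dp)):
        fn = f"{key}.csv"
        write_waveform(wf, os.path.join(out_dir, fn))
        index["files"][key] = fn
    with open(os.path.join(out_dir, "index.json"), "w") as fh:
        json.dump(index, fh, indent=2)


def read_sim_result(in_dir) -> SimResult:
    """Load a SimResult bundle; the import path of the forward contract.

    The per-outlet flows may come from any solver (including a 3D CFD
    export) as long as they conserve the inlet flow.
    """
    with open(os.path.join(in_dir, "index.json")) as fh:
        index = json.load(fh)
    files = index["files"]
    flows = {name: read_waveform(os.path.join(in_dir, files[f"flow_{name}"]))
             for name in OUTLET_NAMES}
    junction = read_waveform(os.path.join(in_dir, files["junction_pressure"]))
    distal = read_waveform(os.path.join(in_dir, files["distal_pressure_da"]))
    dp = read_waveform(os.path.join(in_dir, files["dp"]))
    return SimResult(outlet_flows=flows, junction_pressure=junction,
                     distal_pressure_da=distal, dp=dp,
                     converged=index.get("converged", True),
                     cycles_run=index.get("cycles_run", 0),
                     residual=index.get("residual", 0.0))
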