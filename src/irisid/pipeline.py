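"""Inverse identification pipeline.

Wires the stages into the identification loop: the genetic optimizer
proposes a candidate (mu1, alpha1, mu2, alpha2); the forward model is
solved under the experimental pressure program with the lens translation
prescribed by the fitted ACD-pressure line; simulated displacements are
extracted at the tracked characteristic points and compared to the
experimental tracks through the mismatch functional; the lowest value over
the full evaluation budget wins.

Forward-solve failures map to a large penalty objective so the search
never aborts; evaluations are memoized on the Gray-quantized candidate
(the 16-bit encoding makes quantization error far below the biological
parameter scatter, and caching cannot change results because equal keys
imply equal forward problems).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .forward import (BoundaryConditions, ForwardSolveError, LoadProgram,
                      SolverOptions, extract_point_displacements,
                      run_forward)
from .geometry import GeometryConfig, build_reference_geometry
from .measurements import (ACDFit, ACDSeries, DisplacementTrack,
                           fit_acd_vs_pressure)
from .miga import MIGAConfig, OptimizationTrace, optimize
from .objective import objective_functional
from .ogden import OgdenParameters
from .synthetic import SyntheticExperiment

__all__ = ["IdentificationResult", "identify", "identify_experiment"]

log = logging.getLogger(__name__)


@dataclass
class IdentificationResult:
    best_parameters: OgdenParameters     # canonical order (descending mu)
    best_epsilon: float                  # mm^2
    trace: OptimizationTrace
    n_forward_failures: int
    unreliable: bool                     # > 50% forward failures
    miga_config: MIGAConfig
    geometry_config: GeometryConfig


def identify(experimental: Sequence[DisplacementTrack],
             points: Sequence[tuple[float, float]],
             geometry_config: GeometryConfig | dict | None = None,
             acd: ACDSeries | ACDFit | float | None = None,
             miga_config: MIGAConfig | None = None,
             seed: int | None = None,
             D: float = 1e-6,
             solver_options: SolverOptions | None = None,
             memoize: bool = True,
             forward_cache: dict | None = None) -> IdentificationResult:
    """Identify second-order Ogden parameters from displacement tracks.

    ``points`` gives the reference (r, y) location of each experimental
    track (same order).  ``acd`` may be an ACD series (fitted here), a
    fitted line, or a plain slope in mm/mmHg.  ``seed`` overrides the seed
    in ``miga_config``.

    ``forward_cache`` may be a dict shared across calls that identify the
    *same forward problem* (geometry, points, pressure grid, ACD line): it
    stores simulated tracks per quantized candidate, which are independent
    of the experimental data, so sharing can only save solves — never
    change results.
    """
    if len(experimental) == 0:
        raise ValueError("no experimental tracks")
    if len(points) != len(experimental):
        raise ValueError("one reference point per experimental track")
    if geometry_config is None:
        geometry_config = GeometryConfig()
    elif isinstance(geometry_config, dict):
        geometry_config = GeometryConfig.from_dict(geometry_config)
    cfg = miga_config or MIGAConfig()
    if seed is not None:
        from dataclasses import replace
        cfg = replace(cfg, seed=seed)
    if acd is None:
        slope = 0.0
    elif isinstance(acd, ACDSeries):
        slope = fit_acd_vs_pressure(acd).slope
    elif hasattr(acd, "slope"):
        slope = acd.slope
    else:
        slope = float(acd)

    grids = {tuple(t.dp) for t in experimental}
    if len(grids) != 1:
        raise ValueError("experimental tracks must share one pressure grid")
    dp_grid = np.asarray(experimental[0].dp, dtype=float)

    mesh = build_reference_geometry(geometry_config)
    bc = BoundaryConditions(lens_translation=slope)
    load = LoadProgram(pressure_levels=dp_grid, n_increments=5)
    sopt = solver_options or SolverOptions(max_total_iterations=800)
    exp_tracks = list(experimental)
    point_ids = [t.point_id for t in exp_tracks]

    failures = [0]
    cache = forward_cache if forward_cache is not None else {}
    step = np.array([(hi - lo) / (2**cfg.bits_per_parameter - 1)
                     for lo, hi in cfg.bounds])
    lo = np.array([b[0] for b in cfg.bounds])

    def simulate(x: np.ndarray):
        """Simulated displacement matrix at the candidate, or None."""
        try:
            params = OgdenParameters(mu=[x[0], x[2]], alpha=[x[1], x[3]],
                                     D=D)
            sol = run_forward(params, mesh, bc, load, sopt)
            sim = extract_point_displacements(sol, mesh, points,
                                              point_ids=point_ids)
            return np.vstack([t.interpolated(dp_grid).uy for t in sim])
        except ForwardSolveError:
            return None

    def evaluate(x: np.ndarray) -> float:
        key = tuple(np.rint((x - lo) / step).astype(int))
        if memoize and key in cache:
            sim_uy = cache[key]
        else:
            sim_uy = simulate(x)
            if memoize:
                cache[key] = sim_uy
        if sim_uy is None:
            failures[0] += 1
            return cfg.penalty
        sim = [DisplacementTrack(pid, dp_grid, uy, source="simulated")
               for pid, uy in zip(point_ids, sim_uy)]
        return objective_functional(exp_tracks, sim).epsilon

    best_x, best_val, trace = optimize(evaluate, cfg)
    if failures[0] == trace.total_evaluations:
        raise RuntimeError("every forward solve failed during the search")
    unreliable = failures[0] > 0.5 * trace.total_evaluations
    if unreliable:
        log.warning("identification unreliable: %d of %d forward solves "
                    "failed", failures[0], trace.total_evaluations)
    params = OgdenParameters(mu=[best_x[0], best_x[2]],
                             alpha=[best_x[1], best_x[3]], D=D).canonical()
    return IdentificationResult(
        best_parameters=params, best_epsilon=best_val, trace=trace,
        n_forward_failures=failures[0], unreliable=unreliable,
        miga_config=cfg, geometry_config=geometry_config)


def identify_experiment(experiment: SyntheticExperiment,
                        miga_config: MIGAConfig | None = None,
                        seed: int | None = None,
                        **kwargs) -> IdentificationResult:
    """Convenience wrapper: identify a synthetic experiment's material
    from its own tracks, geometry and ACD series."""
    return identify(experiment.tracks, experiment.points,
                    geometry_config=experiment.geometry_config,
                    acd=experiment.acd_series, miga_config=miga_config,
                    seed=seed, **kwargs)
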