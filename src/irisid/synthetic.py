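"""Synthetic "in vivo experiments" for testing the inverse method.

Real inputs to the identification are displacement-vs-pressure tracks of a
few characteristic points on the iris surface plus an anterior chamber
depth (ACD) series; neither is publicly available.  This module fabricates
both from a known ground-truth Ogden material: the forward model is run at
the truth, characteristic points are sampled on the mid-segment of the
anterior surface (where an observer would mark them on an ultrasound
image), and an independent multiplicative error

    u -> u * (1 + eta),   eta ~ Uniform(-noise_level, +noise_level)

is applied per point per nonzero pressure level, emulating digitization
error of up to ``noise_level`` relative magnitude (the stability analyses
use 0.10).  The ACD series is built from the configured linear
ACD-pressure relation with the same noise model on the depth changes.

Everything is reproducible bit-for-bit from (truth, configs, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datasets import reference_acd_series, reference_cohort
from .forward import (BoundaryConditions, LoadProgram, SolverOptions,
                      ForwardSolveError, extract_point_displacements,
                      run_forward)
from .geometry import GeometryConfig, build_reference_geometry
from .measurements import (ACDSeries, DisplacementTrack, fit_acd_vs_pressure,
                           write_acd_csv, write_tracks_csv)
from .ogden import OgdenParameters

__all__ = ["SyntheticExperiment", "generate_experiment", "generate_cohort",
           "GenerationError", "default_truth_sampler"]

#: linear ACD-pressure relation fitted to the reference perfusion series
_REF_FIT = fit_acd_vs_pressure(reference_acd_series())


class GenerationError(RuntimeError):
    """The forward model failed at the requested ground truth."""


@dataclass
class SyntheticExperiment:
    """One synthetic eye: ground truth, observables and provenance."""

    ground_truth: OgdenParameters
    geometry_config: GeometryConfig
    acd_series: ACDSeries
    tracks: list[DisplacementTrack]
    points: list[tuple[float, float]]     # reference (r, y) of tracked points
    noise_level: float
    seed: int
    pressure_levels: np.ndarray
    acd_slope: float
    acd_intercept: float

    def write(self, directory: str | Path) -> None:
        """Write the measurement CSV dialects plus a manifest JSON."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_tracks_csv(self.tracks, directory / "tracks.csv")
        write_acd_csv(self.acd_series, directory / "acd.csv")
        manifest = {
            "ground_truth": json.loads(self.ground_truth.to_json()),
            "geometry": self.geometry_config.to_dict(),
            "points": [list(p) for p in self.points],
            "noise_level": self.noise_level,
            "seed": self.seed,
            "pressure_levels": list(map(float, self.pressure_levels)),
            "acd_slope": self.acd_slope,
            "acd_intercept": self.acd_intercept,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest,
                                                            indent=1))


def _characteristic_points(mesh, n_points: int) -> list[tuple[float, float]]:
    """Reference locations of the tracked points: anterior-surface nodes
    nearest to evenly spaced radii over the middle segment of the span."""
    cfg = mesh.config
    ant = mesh.node_sets["anterior_surface"]
    fractions = np.linspace(0.35, 0.65, n_points)
    radii = cfg.pupil_radius + fractions * (cfg.root_radius
                                            - cfg.pupil_radius)
    pts = []
    for r in radii:
        nid = ant[np.argmin(np.abs(mesh.nodes[ant, 0] - r))]
        pts.append(tuple(mesh.nodes[nid]))
    return pts


def generate_experiment(
        truth: OgdenParameters,
        geometry_config: GeometryConfig | dict | None = None,
        pressure_levels=None,
        n_points: int = 3,
        noise_level: float = 0.0,
        seed: int = 0,
        acd_slope: float | None = None,
        acd_intercept: float | None = None,
        noise_mode: str = "multiplicative",
        solver_options: SolverOptions | None = None) -> SyntheticExperiment:
    """Fabricate one synthetic experiment from a known material.

    Defaults: pressure levels 0..25 mmHg in 5-mmHg steps, 3 characteristic
    points, ACD relation from the reference perfusion series.
    """
    if not 0.0 <= noise_level <= 0.5:
        raise ValueError("noise_level must lie in [0, 0.5]")
    if n_points < 1:
        raise ValueError("n_points >= 1")
    if noise_mode not in ("multiplicative", "additive"):
        raise ValueError("noise_mode must be multiplicative or additive")
    if geometry_config is None:
        geometry_config = GeometryConfig()
    elif isinstance(geometry_config, dict):
        geometry_config = GeometryConfig.from_dict(geometry_config)
    levels = (np.linspace(0.0, 25.0, 6) if pressure_levels is None
              else np.asarray(pressure_levels, dtype=float))
    slope = _REF_FIT.slope if acd_slope is None else float(acd_slope)
    intercept = (_REF_FIT.intercept if acd_intercept is None
                 else float(acd_intercept))

    mesh = build_reference_geometry(geometry_config)
    bc = BoundaryConditions(lens_translation=slope)
    # 5 nominal sub-increments: the stepper refines adaptively; solutions
    # match 10-increment runs to ~1e-10 mm at half the cost
    load = LoadProgram(pressure_levels=levels, n_increments=5)
    try:
        sol = run_forward(truth, mesh, bc, load, solver_options)
    except ForwardSolveError as err:
        raise GenerationError(
            f"forward model failed at the ground truth: {err}") from err

    points = _characteristic_points(mesh, n_points)
    clean = extract_point_displacements(sol, mesh, points)

    rng = np.random.default_rng(seed)
    tracks = []
    for t in clean:
        uy = t.uy.copy()
        if noise_level > 0:
            eta = rng.uniform(-noise_level, noise_level, len(uy) - 1)
            if noise_mode == "multiplicative":
                uy[1:] = uy[1:] * (1.0 + eta)
            else:
                uy[1:] = uy[1:] + eta * np.abs(uy[1:]).max()
        tracks.append(DisplacementTrack(t.point_id, t.dp, uy,
                                        source="experimental",
                                        reference_point=t.reference_point))

    depth_change = slope * levels
    if noise_level > 0:
        eta = rng.uniform(-noise_level, noise_level, len(levels) - 1)
        depth_change[1:] = depth_change[1:] * (1.0 + eta)
    acd = ACDSeries(dp=levels, acd=intercept + depth_change)

    return SyntheticExperiment(
        ground_truth=truth, geometry_config=geometry_config,
        acd_series=acd, tracks=tracks, points=points,
        noise_level=noise_level, seed=seed, pressure_levels=levels,
        acd_slope=slope, acd_intercept=intercept)


def default_truth_sampler(rng: np.random.Generator,
                          bounds=((0.001, 1.0), (1.0, 100.0),
                                  (0.001, 1.0), (1.0, 100.0))
                          ) -> OgdenParameters:
    """Independent Gaussians at the reference cohort mean/SD, truncated to
    the search bounds (the distribution the cohort generator assumes)."""
    df = reference_cohort()
    means = df[["mu1", "alpha1", "mu2", "alpha2"]].mean().to_numpy()
    sds = df[["mu1", "alpha1", "mu2", "alpha2"]].std(ddof=1).to_numpy()
    for _ in range(100):
        draw = rng.normal(means, sds)
        if all(lo <= v <= hi for v, (lo, hi) in zip(draw, bounds)):
            return OgdenParameters(mu=[draw[0], draw[2]],
                                   alpha=[draw[1], draw[3]], D=1e-6)
    raise GenerationError("truth sampler failed to produce valid parameters")


def generate_cohort(n_specimens: int,
                    truth_sampler=None,
                    master_seed: int = 0,
                    **experiment_kwargs) -> list[SyntheticExperiment]:
    """Generate a cohort of synthetic eyes with per-specimen truths.

    Truths are drawn by ``truth_sampler(rng)`` (default: Gaussians at the
    reference cohort mean/SD); per-specimen seeds derive deterministically
    from the master seed.
    """
    if n_specimens < 1:
        raise ValueError("n_specimens >= 1")
    sampler = truth_sampler or default_truth_sampler
    rng = np.random.default_rng(master_seed)
    out = []
    for k in range(n_specimens):
        truth = sampler(rng)
        seed = int(rng.integers(0, 2**31 - 1))
        out.append(generate_experiment(truth, seed=seed,
                                       **experiment_kwargs))
    return out
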