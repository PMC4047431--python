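"""Study-level analyses on synthetic cohorts.

Three analyses mirror how an in vivo identification study is reported:

* ``run_cohort_study`` — identify every specimen of a (synthetic) cohort
  and tabulate per-specimen parameters with Mean / SD rows.
* ``stability_analysis`` — perturb one experiment's displacement data with
  up-to-10% multiplicative random error, re-identify, and tabulate the
  relative parameter changes against the unperturbed baseline.
* ``sensitivity_analysis`` — vary each material parameter one at a time by
  +/-25% about a baseline and record the displacement-vs-pressure response
  at one characteristic point, ranking parameters by mean absolute curve
  deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .forward import (BoundaryConditions, ForwardSolveError, LoadProgram,
                      SolverOptions, extract_point_displacements,
                      run_forward)
from .geometry import GeometryConfig, build_reference_geometry
from .measurements import DisplacementTrack
from .miga import MIGAConfig
from .ogden import OgdenParameters
from .pipeline import IdentificationResult, identify, identify_experiment
from .synthetic import SyntheticExperiment

__all__ = ["CohortStudy", "StabilityReport", "SensitivityReport",
           "run_cohort_study", "stability_analysis", "sensitivity_analysis"]

_PARAM_COLS = ["mu1", "alpha1", "mu2", "alpha2"]


def _param_row(p: OgdenParameters) -> list[float]:
    return [p.mu[0], p.alpha[0], p.mu[1], p.alpha[1]]


@dataclass
class CohortStudy:
    results: list                      # IdentificationResult or None
    table: pd.DataFrame                # per-specimen rows + Mean + SD
    errors: dict[int, str]


@dataclass
class StabilityReport:
    baseline: OgdenParameters
    replicate_parameters: list[OgdenParameters]
    relative_changes: pd.DataFrame     # % per parameter per replicate
    noise_level: float
    seeds: list[int]


@dataclass
class SensitivityReport:
    baseline: OgdenParameters
    point: tuple[float, float]
    curves: pd.DataFrame               # parameter, factor, dp_mmHg, uy_mm
    metrics: pd.Series                 # mean |deviation| per parameter (mm)
    ranking: list[str]
    failed: list[str]


def run_cohort_study(cohort: list[SyntheticExperiment],
                     miga_config: MIGAConfig | None = None,
                     seed: int = 0,
                     **identify_kwargs) -> CohortStudy:
    """Identify each specimen independently and tabulate the cohort.

    Per-specimen identification errors are recorded and do not abort the
    remaining specimens.  The Mean / SD rows recompute exactly from the
    per-specimen rows.
    """
    if not cohort:
        raise ValueError("empty cohort")
    results, errors, rows = [], {}, []
    for k, exp in enumerate(cohort):
        try:
            res = identify_experiment(exp, miga_config=miga_config,
                                      seed=seed + k, **identify_kwargs)
            results.append(res)
            rows.append([k + 1, *_param_row(res.best_parameters),
                         res.best_epsilon])
        except Exception as err:           # keep the other specimens alive
            results.append(None)
            errors[k + 1] = str(err)
    table = pd.DataFrame(rows, columns=["specimen", *_PARAM_COLS, "epsilon"])
    stats = table[_PARAM_COLS + ["epsilon"]]
    mean = ["Mean", *stats.mean().tolist()]
    sd = ["SD", *stats.std(ddof=1).fillna(0.0).tolist()]
    summary = pd.DataFrame([mean, sd],
                           columns=["specimen", *_PARAM_COLS, "epsilon"])
    return CohortStudy(results=results,
                       table=pd.concat([table, summary], ignore_index=True),
                       errors=errors)


def stability_analysis(experiment: SyntheticExperiment,
                       noise_level: float = 0.10,
                       n_replicates: int = 3,
                       miga_config: MIGAConfig | None = None,
                       master_seed: int = 0,
                       baseline: IdentificationResult | None = None,
                       ga_seed: int | None = None,
                       **identify_kwargs) -> StabilityReport:
    """Robustness of the identification to bounded data error.

    The baseline identification runs on the experiment as supplied; each
    replicate multiplies every nonzero-level displacement by (1 + eta),
    eta ~ U(-noise_level, +noise_level), re-identifies, and the relative
    change |q_new - q_base| / q_base * 100 is tabulated per parameter.

    With ``ga_seed`` set, every identification (baseline and replicates)
    uses that one optimizer seed, isolating the effect of the data
    perturbation from optimizer scatter; at noise 0 all relative changes
    are then exactly zero.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates >= 1")
    rng = np.random.default_rng(master_seed)
    if baseline is None:
        baseline = identify_experiment(
            experiment, miga_config=miga_config,
            seed=(ga_seed if ga_seed is not None
                  else int(rng.integers(0, 2**31 - 1))),
            **identify_kwargs)
    base_p = baseline.best_parameters
    base_vals = np.array(_param_row(base_p))

    reps, rows, seeds = [], [], []
    for r in range(n_replicates):
        noise_seed = int(rng.integers(0, 2**31 - 1))
        rep_ga_seed = (ga_seed if ga_seed is not None
                       else int(rng.integers(0, 2**31 - 1)))
        seeds.append(noise_seed)
        nrng = np.random.default_rng(noise_seed)
        tracks = []
        for t in experiment.tracks:
            uy = t.uy.copy()
            if noise_level > 0:
                eta = nrng.uniform(-noise_level, noise_level, len(uy) - 1)
                uy[1:] = uy[1:] * (1.0 + eta)
            tracks.append(DisplacementTrack(t.point_id, t.dp, uy,
                                            source="experimental",
                                            reference_point=t.reference_point))
        res = identify(tracks, experiment.points,
                       geometry_config=experiment.geometry_config,
                       acd=experiment.acd_series, miga_config=miga_config,
                       seed=rep_ga_seed, **identify_kwargs)
        reps.append(res.best_parameters)
        new_vals = np.array(_param_row(res.best_parameters))
        rows.append([r + 1, *(np.abs(new_vals - base_vals)
                              / base_vals * 100.0)])

    table = pd.DataFrame(rows, columns=["replicate", *_PARAM_COLS])
    return StabilityReport(baseline=base_p, replicate_parameters=reps,
                           relative_changes=table, noise_level=noise_level,
                           seeds=seeds)


def sensitivity_analysis(baseline: OgdenParameters,
                         geometry_config: GeometryConfig | dict | None = None,
                         load: LoadProgram | None = None,
                         point: tuple[float, float] | None = None,
                         variation: float = 0.25,
                         acd_slope: float = 0.004848459564646648,
                         solver_options: SolverOptions | None = None
                         ) -> SensitivityReport:
    """One-at-a-time +/-variation study of the forward response.

    For each of mu1, alpha1, mu2, alpha2 the parameter is scaled by
    (1 - variation) and (1 + variation) with the others fixed, and the
    |u_y|-vs-pressure curve at ``point`` (default: the mid-segment
    characteristic point) is recorded.  The summary metric per parameter
    is the mean absolute deviation from the baseline curve across levels
    and both perturbations; parameters are ranked by it.  Non-converging
    perturbed solves are flagged and skipped.
    """
    if geometry_config is None:
        geometry_config = GeometryConfig()
    elif isinstance(geometry_config, dict):
        geometry_config = GeometryConfig.from_dict(geometry_config)
    load = load or LoadProgram(n_increments=5)
    mesh = build_reference_geometry(geometry_config)
    bc = BoundaryConditions(lens_translation=acd_slope)
    if point is None:
        cfg = geometry_config
        r_mid = 0.5 * (cfg.pupil_radius + cfg.root_radius)
        point = (r_mid, -cfg.thickness / 2.0)

    def curve(params):
        sol = run_forward(params, mesh, bc, load, solver_options)
        track = extract_point_displacements(sol, mesh, [point])[0]
        return np.abs(track.uy)

    base_curve = curve(baseline)
    rows = [("baseline", 1.0, d, u)
            for d, u in zip(load.pressure_levels, base_curve)]
    deviations = {}
    failed = []
    for i, name in enumerate(_PARAM_COLS):
        devs = []
        for factor in (1.0 - variation, 1.0 + variation):
            mu = list(baseline.mu)
            alpha = list(baseline.alpha)
            if name.startswith("mu"):
                mu[int(name[-1]) - 1] *= factor
            else:
                alpha[int(name[-1]) - 1] *= factor
            try:
                c = curve(OgdenParameters(mu=mu, alpha=alpha,
                                          D=baseline.D))
            except ForwardSolveError:
                failed.append(f"{name} x{factor:g}")
                continue
            rows += [(name, factor, d, u)
                     for d, u in zip(load.pressure_levels, c)]
            devs.append(np.abs(c - base_curve).mean())
        deviations[name] = float(np.mean(devs)) if devs else np.nan
    metrics = pd.Series(deviations, name="mean_abs_deviation_mm")
    ranking = list(metrics.sort_values(ascending=False).index)
    return SensitivityReport(
        baseline=baseline, point=point,
        curves=pd.DataFrame(rows, columns=["parameter", "factor",
                                           "dp_mmHg", "uy_mm"]),
        metrics=metrics, ranking=ranking, failed=failed)
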