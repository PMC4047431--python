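"""Synthetic-experiment generator: noise model, determinism, consistency."""

import numpy as np
import pytest

from irisid import (BoundaryConditions, LoadProgram, OgdenParameters,
                    build_reference_geometry, extract_point_displacements,
                    fit_acd_vs_pressure, generate_cohort,
                    generate_experiment, objective_functional, run_forward)
from irisid.synthetic import GenerationError, default_truth_sampler

MEAN = OgdenParameters([0.0861, 0.0754], [54.2546, 48.0716], 1e-6)


@pytest.fixture(scope="module")
def coarse_kwargs(coarse_geometry):
    return dict(geometry_config=coarse_geometry, n_points=2)


class TestGenerate:
    def test_noise_free_matches_forward_extraction(self, coarse_geometry):
        exp = generate_experiment(MEAN, coarse_geometry, noise_level=0.0,
                                  n_points=2, seed=4)
        mesh = build_reference_geometry(coarse_geometry)
        bc = BoundaryConditions(lens_translation=exp.acd_slope)
        sol = run_forward(MEAN, mesh, bc,
                          LoadProgram(pressure_levels=exp.pressure_levels,
                                      n_increments=5))
        clean = extract_point_displacements(sol, mesh, exp.points)
        for t, c in zip(exp.tracks, clean):
            assert np.array_equal(t.uy, c.uy)

    def test_same_seed_bit_identical(self, coarse_kwargs):
        e1 = generate_experiment(MEAN, noise_level=0.1, seed=9,
                                 **coarse_kwargs)
        e2 = generate_experiment(MEAN, noise_level=0.1, seed=9,
                                 **coarse_kwargs)
        for t1, t2 in zip(e1.tracks, e2.tracks):
            assert np.array_equal(t1.uy, t2.uy)
        assert np.array_equal(e1.acd_series.acd, e2.acd_series.acd)

    def test_noise_zero_at_reference_level(self, coarse_kwargs):
        exp = generate_experiment(MEAN, noise_level=0.3, seed=2,
                                  **coarse_kwargs)
        for t in exp.tracks:
            assert t.uy[0] == 0.0

    def test_noise_level_validation(self, coarse_kwargs):
        with pytest.raises(ValueError):
            generate_experiment(MEAN, noise_level=0.9, **coarse_kwargs)

    def test_unstable_truth_raises_generation_error(self, coarse_geometry):
        # extremely soft material far outside the physiological range
        floppy = OgdenParameters([1e-4, 1e-4], [1.2, 1.1], 1e-6)
        with pytest.raises(GenerationError):
            generate_experiment(floppy, coarse_geometry, n_points=1)

    def test_objective_zero_against_fresh_forward(self, coarse_geometry):
        """Noise-free generation + fresh simulation at truth -> eps = 0."""
        exp = generate_experiment(MEAN, coarse_geometry, noise_level=0.0,
                                  n_points=2, seed=1)
        mesh = build_reference_geometry(coarse_geometry)
        bc = BoundaryConditions(lens_translation=exp.acd_slope)
        sol = run_forward(MEAN, mesh, bc,
                          LoadProgram(pressure_levels=exp.pressure_levels,
                                      n_increments=5))
        sim = extract_point_displacements(
            sol, mesh, exp.points, point_ids=[t.point_id
                                              for t in exp.tracks])
        val = objective_functional(exp.tracks, sim)
        assert val.epsilon == 0.0

    def test_acd_fit_recovers_configured_slope(self, coarse_kwargs):
        exp = generate_experiment(MEAN, noise_level=0.0, seed=3,
                                  **coarse_kwargs)
        fit = fit_acd_vs_pressure(exp.acd_series)
        assert fit.slope == pytest.approx(exp.acd_slope, rel=1e-9)

    def test_write_outputs(self, tmp_path, coarse_kwargs):
        exp = generate_experiment(MEAN, noise_level=0.05, seed=5,
                                  **coarse_kwargs)
        exp.write(tmp_path)
        assert (tmp_path / "tracks.csv").exists()
        assert (tmp_path / "acd.csv").exists()
        assert (tmp_path / "manifest.json").exists()


class TestNoiseDistribution:
    def test_multiplicative_uniform_noise_statistics(self, coarse_geometry):
        """Pooled relative errors are within the bound with mean |eta|
        about half the noise level (uniform distribution)."""
        kwargs = dict(geometry_config=coarse_geometry, n_points=4)
        clean = generate_experiment(MEAN, noise_level=0.0, seed=0, **kwargs)
        ref = {t.point_id: t.uy for t in clean.tracks}
        etas = []
        for seed in range(50):
            noisy = generate_experiment(MEAN, noise_level=0.1, seed=seed,
                                        **kwargs)
            for t in noisy.tracks:
                base = ref[t.point_id][1:]
                etas.append(t.uy[1:] / base - 1.0)
        etas = np.concatenate(etas)
        assert len(etas) >= 1e3
        assert np.max(np.abs(etas)) <= 0.1 + 1e-12
        assert np.mean(np.abs(etas)) == pytest.approx(0.05, abs=0.005)


class TestCohort:
    def test_degenerate_sampler_returns_mean(self, coarse_kwargs):
        def sampler(rng):
            return MEAN
        (exp,) = generate_cohort(1, truth_sampler=sampler, master_seed=1,
                                 **coarse_kwargs)
        assert exp.ground_truth == MEAN

    def test_distinct_reproducible_truths(self, coarse_kwargs):
        c1 = generate_cohort(3, master_seed=12, **coarse_kwargs)
        c2 = generate_cohort(3, master_seed=12, **coarse_kwargs)
        mus = [e.ground_truth.mu[0] for e in c1]
        assert len(set(mus)) == 3
        assert mus == [e.ground_truth.mu[0] for e in c2]

    def test_sampler_mean_matches_reference(self):
        """Sample mean of mu1 within 3 SE of the configured 0.0861."""
        rng = np.random.default_rng(77)
        draws = np.array([default_truth_sampler(rng).mu[0]
                          for _ in range(800)])
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - 0.0861) < 3 * se
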