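"""Material-model oracles: closed forms, finite differences, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from irisid import (DeformationState, InvalidDeformationError,
                    OgdenParameters, principal_cauchy_stress, strain_energy,
                    tangent_moduli, uniaxial_nominal_stress)

MEAN = OgdenParameters([0.0861, 0.0754], [54.2546, 48.0716], 1e-6)


def uniaxial_state(lam):
    return DeformationState((lam, lam**-0.5, lam**-0.5))


class TestParameters:
    def test_validation(self):
        with pytest.raises(ValueError):
            OgdenParameters([-0.1], [2.0], 1e-6)
        with pytest.raises(ValueError):
            OgdenParameters([0.1], [0.0], 1e-6)
        with pytest.raises(ValueError):
            OgdenParameters([0.1], [2.0], -1e-6)
        with pytest.raises(ValueError):
            OgdenParameters([0.1, 0.2], [2.0], 1e-6)

    def test_scalar_D_replicated(self):
        p = OgdenParameters([0.1, 0.2], [2.0, 4.0], 1e-6)
        assert p.D == (1e-6, 1e-6)

    def test_json_roundtrip(self):
        q = OgdenParameters.from_json(MEAN.to_json())
        assert q == MEAN

    def test_canonical_sorts_by_mu(self):
        p = OgdenParameters([0.05, 0.09], [30.0, 60.0], 1e-6)
        c = p.canonical()
        assert c.mu == (0.09, 0.05) and c.alpha == (60.0, 30.0)
        # canonicalization never changes the material response
        st_ = uniaxial_state(1.04)
        assert strain_energy(p, st_) == pytest.approx(
            strain_energy(c, st_), rel=1e-14)


class TestStrainEnergy:
    def test_reference_state_zero(self):
        assert strain_energy(MEAN, DeformationState((1, 1, 1))) == 0.0

    def test_neo_hookean_reduction(self):
        # N = 1, alpha = 2 is the incompressible Neo-Hookean solid
        p = OgdenParameters([0.1], [2.0], 1e-6)
        lam = 2.0
        expected = 0.1 / 2 * (lam**2 + 2 / lam - 3)
        assert strain_energy(p, uniaxial_state(lam)) == pytest.approx(
            expected, rel=1e-12)
        assert expected == pytest.approx(0.1)

    def test_mean_parameters_symbolic_oracle(self):
        # frozen from an independent sympy evaluation of the energy at
        # uniaxial lambda = 1.05, J = 1
        assert strain_energy(MEAN, uniaxial_state(1.05)) == pytest.approx(
            1.207010664353381e-3, rel=1e-12)

    def test_overflow_guarded(self):
        with pytest.raises(InvalidDeformationError):
            strain_energy(MEAN, uniaxial_state(30.0))

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(st.tuples(*[st.floats(0.55, 1.8) for _ in range(3)]),
           st.floats(0.01, 0.5), st.floats(0.5, 8.0))
    def test_energy_nonnegative(self, lams, mu, alpha):
        p = OgdenParameters([mu], [alpha], 1e-3)
        U = strain_energy(p, DeformationState(lams))
        assert U >= -1e-14

    def test_deviatoric_term_dilatation_invariant(self):
        # scaling all stretches by c changes only the volumetric term
        lam = np.array([1.1, 0.95, 1.02])
        base = DeformationState(tuple(lam))
        scaled = DeformationState(tuple(1.07 * lam))
        assert base.deviatoric_stretches == pytest.approx(
            scaled.deviatoric_stretches, rel=1e-12)
        big_D = OgdenParameters(MEAN.mu, MEAN.alpha, 1e12)  # no vol energy
        assert strain_energy(big_D, base) == pytest.approx(
            strain_energy(big_D, scaled), rel=1e-9)


class TestStress:
    def test_identity_stress_free(self):
        sig = principal_cauchy_stress(MEAN, DeformationState((1, 1, 1)))
        assert np.allclose(sig, 0.0)

    def test_neo_hookean_stress_difference(self):
        p = OgdenParameters([0.1], [2.0], 1e-6)
        lam = (1.3, 1.3**-0.5, 1.3**-0.5)
        sig = principal_cauchy_stress(p, DeformationState(lam))
        assert sig[0] - sig[2] == pytest.approx(
            0.1 * (lam[0]**2 - lam[2]**2), rel=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_energy_finite_differences(self, seed):
        # sigma_a = (lam_a / J) dU/dlam_a, checked over random states
        rng = np.random.default_rng(seed)
        for _ in range(25):
            lam = np.exp(rng.uniform(-0.05, 0.05, 3))
            state = DeformationState(tuple(lam))
            sig = principal_cauchy_stress(MEAN, state)
            h = 1e-6
            for a in range(3):
                lp, lm = lam.copy(), lam.copy()
                lp[a] += h
                lm[a] -= h
                dU = (strain_energy(MEAN, DeformationState(tuple(lp)))
                      - strain_energy(MEAN, DeformationState(tuple(lm)))) \
                    / (2 * h)
                fd = lam[a] * dU / state.volume_ratio
                assert sig[a] == pytest.approx(fd, rel=2e-5, abs=1e-8)


class TestTangent:
    def test_identity_small_strain_limit(self):
        # N=1, alpha=2: tangent = isotropic tensor with shear mu, bulk 2/D
        mu, D = 0.1, 1e-3
        p = OgdenParameters([mu], [2.0], D)
        tg = tangent_moduli(p, DeformationState((1, 1, 1)))
        kappa = 2.0 / D
        lame = kappa - 2 * mu / 3
        assert np.allclose(tg.normal, lame + 2 * mu * np.eye(3), rtol=1e-9)
        assert np.allclose(tg.shear, mu, rtol=1e-9)

    def test_matches_stress_finite_differences(self, rng):
        for _ in range(30):
            lam = np.exp(rng.uniform(-0.04, 0.04, 3))
            tg = tangent_moduli(MEAN, DeformationState(tuple(lam)))
            h = 1e-6
            fd = np.zeros((3, 3))
            for b in range(3):
                lp, lm = lam.copy(), lam.copy()
                lp[b] += h
                lm[b] -= h
                fd[:, b] = (principal_cauchy_stress(
                    MEAN, DeformationState(tuple(lp)))
                    - principal_cauchy_stress(
                        MEAN, DeformationState(tuple(lm)))) / (2 * h)
            scale = np.abs(fd).max()
            assert np.allclose(tg.normal, fd, rtol=1e-5, atol=1e-5 * scale)

    def test_continuous_across_coincident_stretches(self):
        lam_eq = DeformationState((1.04, 1.04, 0.93))
        lam_near = DeformationState((1.04, 1.04 * (1 + 2e-7), 0.93))
        tq = tangent_moduli(MEAN, lam_eq)
        tn = tangent_moduli(MEAN, lam_near)
        assert np.allclose(tq.shear, tn.shear, rtol=1e-4)

    def test_rejects_nonpositive_stretch(self):
        with pytest.raises(InvalidDeformationError):
            DeformationState((1.0, -0.2, 1.0))


class TestUniaxialNominalStress:
    def test_reference_zero(self):
        assert uniaxial_nominal_stress(MEAN, 1.0) == 0.0

    def test_neo_hookean_closed_form(self):
        p = OgdenParameters([0.1], [2.0], 1e-6)
        assert uniaxial_nominal_stress(p, 2.0) == pytest.approx(
            0.1 * (2.0 - 2.0**-2), rel=1e-12)

    def test_mean_parameters_symbolic_oracle(self):
        # frozen from sympy differentiation of the uniaxial energy
        assert uniaxial_nominal_stress(MEAN, 1.03) == pytest.approx(
            2.505249338518379e-2, rel=1e-12)

    def test_monotone_near_reference(self):
        lams = np.linspace(0.95, 1.1, 31)
        P = [uniaxial_nominal_stress(MEAN, l) for l in lams]
        assert np.all(np.diff(P) > 0)
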