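"""Nearly incompressible Ogden hyperelasticity in principal stretches.

The strain energy density (per unit reference volume, MPa) of an order-N
Ogden solid is

    U = sum_i 2 mu_i / alpha_i**2 * (lb1**a_i + lb2**a_i + lb3**a_i - 3)
      + sum_i (1 / D_i) * (J - 1)**(2 i)

where ``lb_a = J**(-1/3) * lam_a`` are the deviatoric principal stretches,
``J = lam1 lam2 lam3`` the volume ratio, and (mu_i, alpha_i, D_i) material
constants.  With this prefactor convention the small-strain shear modulus
is ``mu0 = sum mu_i`` and the bulk modulus ``2 / D_1``.  With ``D = 1e-6 MPa^-1`` the solid is
nearly incompressible (kappa / mu0 ~ 1e5-1e7 for soft-tissue moduli), which
is how the iris is modelled here.

This module provides the energy, the principal Cauchy stresses, consistent
tangents (with the coincident-stretch limit handled), a closed-form
incompressible uniaxial nominal stress used as a patch-test oracle, and
vectorized second Piola-Kirchhoff stress/tangent kernels (deviatoric and
volumetric parts split) consumed by the axisymmetric FE solver.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "InvalidDeformationError",
    "OgdenParameters",
    "DeformationState",
    "OgdenTangent",
    "strain_energy",
    "principal_cauchy_stress",
    "tangent_moduli",
    "uniaxial_nominal_stress",
]

#: cap on |alpha * log(lambda_bar)|; beyond this the power terms overflow
#: any physically meaningful range and the state is declared invalid.
_LOG_CAP = 120.0


class InvalidDeformationError(ValueError):
    """Raised when a deformation state produces a non-finite Ogden response."""


@dataclass(frozen=True)
class OgdenParameters:
    """Material constants (mu_i [MPa], alpha_i [-], D_i [MPa^-1]) of an
    order-N Ogden solid.

    ``mu_i > 0``, ``alpha_i != 0`` (the energy divides by alpha_i**2) and
    ``D_i > 0`` are enforced.  The search space of the inverse problem is
    further restricted to ``alpha_i > 0`` so that the uniaxial response is
    monotone, but negative alpha is accepted here for forward evaluation.
    """

    mu: tuple[float, ...]
    alpha: tuple[float, ...]
    D: tuple[float, ...]

    def __init__(
        self,
        mu: Sequence[float],
        alpha: Sequence[float],
        D: Sequence[float] | float = 1e-6,
    ):
        mu = tuple(float(m) for m in np.atleast_1d(mu))
        alpha = tuple(float(a) for a in np.atleast_1d(alpha))
        if np.isscalar(D):
            # a single volumetric compliance is replicated to every order,
            # matching the common "single D" usage for soft tissue
            D = (float(D),) * len(mu)
        else:
            D = tuple(float(d) for d in np.atleast_1d(D))
            if len(D) < len(mu):
                D = D + (D[0],) * (len(mu) - len(D))
        if not (len(mu) == len(alpha) == len(D)) or len(mu) < 1:
            raise ValueError("mu, alpha, D must have equal length >= 1")
        if any(m <= 0 for m in mu):
            raise ValueError("all mu_i must be > 0")
        if any(a == 0 for a in alpha):
            raise ValueError("all alpha_i must be nonzero")
        if any(d <= 0 for d in D):
            raise ValueError("all D_i must be > 0")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "D", D)

    @property
    def order(self) -> int:
        return len(self.mu)

    @property
    def shear_modulus(self) -> float:
        """Small-strain (consistent linearization) shear modulus, MPa.

        With the 2 mu_i / alpha_i**2 prefactor each series term linearizes
        to mu_i * |dev eps|**2, so mu0 = sum(mu_i).
        """
        return float(np.sum(self.mu))

    @property
    def bulk_modulus(self) -> float:
        """Small-strain bulk modulus 2/D_1, MPa."""
        return 2.0 / self.D[0]

    def canonical(self) -> "OgdenParameters":
        """Return the same material with terms sorted by descending mu.

        The Ogden series is invariant under permutation of its (mu_i,
        alpha_i, D_i) terms, so identified parameter sets are only defined
        up to relabelling; sorting removes that ambiguity.
        """
        idx = np.argsort(self.mu)[::-1]
        return OgdenParameters(
            [self.mu[i] for i in idx],
            [self.alpha[i] for i in idx],
            [self.D[i] for i in idx],
        )

    def to_json(self) -> str:
        return json.dumps(
            {"order": self.order, "mu": list(self.mu),
             "alpha": list(self.alpha), "D": list(self.D)}
        )

    @classmethod
    def from_json(cls, text: str) -> "OgdenParameters":
        obj = json.loads(text)
        p = cls(obj["mu"], obj["alpha"], obj.get("D", 1e-6))
        if "order" in obj and obj["order"] != p.order:
            raise ValueError("order field inconsistent with mu/alpha length")
        return p


@dataclass(frozen=True)
class DeformationState:
    """Principal stretches, volume ratio and deviatoric stretches."""

    principal_stretches: tuple[float, float, float]
    volume_ratio: float = field(init=False)
    deviatoric_stretches: tuple[float, float, float] = field(init=False)

    def __post_init__(self):
        lam = np.asarray(self.principal_stretches, dtype=float)
        if lam.shape != (3,):
            raise ValueError("three principal stretches required")
        if np.any(lam <= 0):
            raise InvalidDeformationError("principal stretches must be > 0")
        J = float(np.prod(lam))
        lb = lam * J ** (-1.0 / 3.0)
        object.__setattr__(self, "principal_stretches", tuple(lam))
        object.__setattr__(self, "volume_ratio", J)
        object.__setattr__(self, "deviatoric_stretches", tuple(lb))


@dataclass(frozen=True)
class OgdenTangent:
    """Consistent tangent of the principal Cauchy stresses.

    ``normal[a, b] = d sigma_a / d lambda_b`` (3x3), and ``shear[k]`` is the
    spatial shear coefficient c_abab for the pair (a, b) in the order
    (1,2), (1,3), (2,3):

        c_abab = (sigma_a lam_b**2 - sigma_b lam_a**2) / (lam_a**2 - lam_b**2)

    with the L'Hopital limit at coincident stretches.  At the reference
    state each shear coefficient equals the small-strain shear modulus.
    """

    normal: np.ndarray
    shear: np.ndarray


# ---------------------------------------------------------------------------
# vectorized kernels (shape (..., 3) in x = lambda**2); used by the FE solver
# ---------------------------------------------------------------------------

def _powers(alpha: np.ndarray, x: np.ndarray):
    """e[..., i, a] = lb_a**alpha_i with overflow guard; also J, log lb."""
    if np.any(x <= 0):
        raise InvalidDeformationError("non-positive squared stretch")
    loglam = 0.5 * np.log(x)
    logJ = np.sum(loglam, axis=-1, keepdims=True)
    loglb = loglam - logJ / 3.0
    arg = alpha.reshape((1,) * (x.ndim - 1) + (-1, 1)) * loglb[..., None, :]
    if np.any(np.abs(arg) > _LOG_CAP):
        raise InvalidDeformationError("Ogden power term overflow")
    e = np.exp(arg)
    J = np.exp(logJ[..., 0])
    return e, J


def _dev_energy(mu, alpha, x):
    e, _ = _powers(alpha, x)
    c_over_a = 2.0 * mu / alpha**2
    return np.einsum("i,...i->...", c_over_a, np.sum(e, axis=-1) - 3.0)


def _vol_energy(D, J):
    i = np.arange(1, len(D) + 1)
    t = (J[..., None] - 1.0) ** (2 * i)
    return np.einsum("i,...i->...", 1.0 / D, t)


def _vol_pressure(D, J):
    """p = dU_vol/dJ and p' = d2U_vol/dJ2."""
    i = np.arange(1, len(D) + 1)
    dJ = J[..., None] - 1.0
    p = np.einsum("i,...i->...", 2.0 * i / D, dJ ** (2 * i - 1))
    pp = np.einsum("i,...i->...", 2.0 * i * (2 * i - 1) / D,
                   dJ ** np.maximum(2 * i - 2, 0))
    return p, pp


def _dev_pk2_and_tangent(mu, alpha, x, need_tangent: bool = True):
    """Deviatoric 2nd Piola-Kirchhoff principal stresses and dS_a/dx_b.

    Returns (S[..., 3], dS[..., 3, 3]) with x = squared principal
    stretches; dS is None when ``need_tangent`` is false.
    """
    e, _ = _powers(alpha, x)                      # (..., N, 3)
    c = 2.0 * mu / alpha                          # (N,)
    E = np.sum(e, axis=-1, keepdims=True)         # (..., N, 1)
    dev = e - E / 3.0                             # (..., N, 3)
    tau = np.einsum("i,...ia->...a", c, dev)      # deviatoric Kirchhoff
    S = tau / x
    if not need_tangent:
        return S, None
    eye = np.eye(3)
    # d tau_a / d x_b = sum_i c_i alpha_i [e_a (delta_ab - 1/3)
    #                                      - (e_b - E/3)/3] / (2 x_b)
    ca = c * alpha
    t1 = np.einsum("i,...ia,ab->...ab", ca, e, eye - 1.0 / 3.0)
    t2 = np.einsum("i,...ib->...b", ca, dev)[..., None, :] / 3.0
    dtau = (t1 - t2) / (2.0 * x[..., None, :])
    dS = dtau / x[..., :, None] - eye * (tau / x**2)[..., :, None]
    return S, dS


def _vol_pk2_and_tangent(D, x):
    """Volumetric 2nd PK principal stresses S_a = p J / x_a and dS_a/dx_b."""
    J = np.sqrt(np.prod(x, axis=-1))
    p, pp = _vol_pressure(D, J)
    S = (p * J)[..., None] / x
    eye = np.eye(3)
    dS = ((pp * J + p) * J / 2.0)[..., None, None] \
        / (x[..., :, None] * x[..., None, :]) \
        - eye * (p * J)[..., None, None] / (x**2)[..., :, None]
    return S, dS


# ---------------------------------------------------------------------------
# public scalar API
# ---------------------------------------------------------------------------

def _arrays(params: OgdenParameters):
    return (np.asarray(params.mu), np.asarray(params.alpha),
            np.asarray(params.D))


def strain_energy(params: OgdenParameters, state: DeformationState) -> float:
    """Strain energy density U (MPa = mJ/mm^3); 0 at the reference state."""
    mu, alpha, D = _arrays(params)
    x = np.asarray(state.principal_stretches) ** 2
    U = float(_dev_energy(mu, alpha, x) + _vol_energy(D, np.asarray(state.volume_ratio)))
    if not np.isfinite(U):
        raise InvalidDeformationError("non-finite strain energy")
    return U


def principal_cauchy_stress(
    params: OgdenParameters, state: DeformationState
) -> np.ndarray:
    """Principal Cauchy stresses sigma_a = (lam_a / J) dU/dlam_a (MPa)."""
    mu, alpha, D = _arrays(params)
    lam = np.asarray(state.principal_stretches)
    x = lam**2
    e, J = _powers(alpha, x)
    c = 2.0 * mu / alpha
    dev = e - np.sum(e, axis=-1, keepdims=True) / 3.0
    tau = np.einsum("i,ia->a", c, dev)
    p, _ = _vol_pressure(D, J)
    sig = tau / J + p
    if not np.all(np.isfinite(sig)):
        raise InvalidDeformationError("non-finite stress")
    return sig


def _dsigma_dlam(params: OgdenParameters, lam: np.ndarray) -> np.ndarray:
    """Analytic d sigma_a / d lam_b (3x3)."""
    mu, alpha, D = _arrays(params)
    x = lam**2
    e, J = _powers(alpha, x)
    c = 2.0 * mu / alpha
    E = np.sum(e, axis=-1, keepdims=True)
    dev = e - E / 3.0
    tau = np.einsum("i,ia->a", c, dev)
    ca = c * alpha
    eye = np.eye(3)
    t1 = np.einsum("i,ia,ab->ab", ca, e, eye - 1.0 / 3.0)
    t2 = np.einsum("i,ib->b", ca, dev)[None, :] / 3.0
    dtau_dlam = (t1 - t2) / lam[None, :]          # chain through log lb
    p, pp = _vol_pressure(D, J)
    # sigma = tau/J + p;  dJ/dlam_b = J/lam_b
    return (dtau_dlam / J
            - np.outer(tau, 1.0 / lam) / J
            + pp * J / lam[None, :] * np.ones((3, 1)))


_PAIRS = ((0, 1), (0, 2), (1, 2))


def tangent_moduli(params: OgdenParameters, state: DeformationState) -> OgdenTangent:
    """Consistent principal tangent (normal block and shear coefficients).

    The shear coefficients switch to the L'Hopital limit

        c_abab -> (lam/2) (d sigma_b/d lam_b - d sigma_a/d lam_b) - sigma_a

    when |x_a - x_b| < 1e-7 * max(x), which keeps the tangent continuous
    across coincident stretches.
    """
    lam = np.asarray(state.principal_stretches, dtype=float)
    if np.any(lam <= 0):
        raise InvalidDeformationError("principal stretches must be > 0")
    normal = _dsigma_dlam(params, lam)
    sig = principal_cauchy_stress(params, state)
    x = lam**2
    shear = np.empty(3)
    for k, (a, b) in enumerate(_PAIRS):
        if abs(x[a] - x[b]) > 1e-7 * max(x[a], x[b]):
            shear[k] = (sig[a] * x[b] - sig[b] * x[a]) / (x[a] - x[b])
        else:
            shear[k] = 0.5 * lam[a] * (normal[b, b] - normal[a, b]) - sig[a]
    if not (np.all(np.isfinite(normal)) and np.all(np.isfinite(shear))):
        raise InvalidDeformationError("non-finite tangent")
    return OgdenTangent(normal=normal, shear=shear)


def uniaxial_nominal_stress(params: OgdenParameters, stretch: float) -> float:
    """Incompressible uniaxial nominal (first PK) stress P(lam), MPa.

    Closed form for lam_axial = lam, lam_lateral = lam**-1/2, J = 1:

        P(lam) = sum_i (2 mu_i / alpha_i) (lam**(a_i-1) - lam**(-a_i/2-1))

    Used as the independent oracle for the single-element patch test.
    """
    if stretch <= 0:
        raise ValueError("stretch must be > 0")
    mu, alpha, _ = _arrays(params)
    lam = float(stretch)
    P = float(np.sum(2.0 * mu / alpha
                     * (lam ** (alpha - 1.0) - lam ** (-alpha / 2.0 - 1.0))))
    if not np.isfinite(P):
        raise InvalidDeformationError("non-finite nominal stress")
    return P
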