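"""Axisymmetric finite-deformation FE solver for the pressurized iris.

Total-Lagrangian formulation on 4-node quadrilaterals and 3-node
triangles with a hybrid (constant-pressure) treatment of near-
incompressibility: the deviatoric Ogden response is integrated at 2x2
Gauss points (1 point on triangles), while the volumetric response is
carried by an element-constant pressure unknown conjugate to the
element-mean volume ratio (perturbed-Lagrangian form, statically
condensed at each Newton iteration).  With D ~ 1e-6 MPa^-1 a pure
displacement penalty makes Newton's method diverge — any finite rotation
increment creates O(kappa * theta**2) spurious volumetric residuals — so
the independent pressure is essential, not cosmetic; it mirrors the
"hybrid, constant pressure" axisymmetric elements standard for this
problem class.

Loads: the pressure differential is a follower load on the current anterior
surface (consistent load vector and exact, nonsymmetric load stiffness);
the rigid lens is an analytical sphere translated axially per the
anterior-chamber-depth/pressure relation, with penalty normal contact and
penalty-regularized Coulomb friction against posterior-side nodes.

A Newton solve with load incrementation and step-halving cutbacks is run to
each requested pressure level.  Units: mm, MPa, N; pressures in mmHg are
converted with 1 mmHg = 1.33322e-4 MPa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geometry import AxisymMesh, GeometryError
from .measurements import DisplacementTrack
from .ogden import (InvalidDeformationError, OgdenParameters,
                    _dev_pk2_and_tangent, _vol_pk2_and_tangent)
from ._kernels import ASSEMBLE as _ASSEMBLE

__all__ = ["MMHG_TO_MPA", "BoundaryConditions", "LoadProgram",
           "SolverOptions", "FieldSolution", "ForwardSolveError",
           "PointMatchError", "run_forward", "extract_point_displacements"]

MMHG_TO_MPA = 1.33322e-4


class ForwardSolveError(RuntimeError):
    """Newton failed to converge; carries the converged prefix solution."""

    def __init__(self, msg: str, partial: "FieldSolution | None" = None):
        super().__init__(msg)
        self.partial = partial


class PointMatchError(ValueError):
    """A query point is too far from any surface node."""


@dataclass
class BoundaryConditions:
    """Kinematic/contact boundary data for the forward model.

    ``lens_translation`` is either None (lens fixed), a float slope in
    mm/mmHg (axial posterior translation = slope * dp, the change in
    anterior chamber depth), or a (dp_array, translation_array) table that
    is linearly interpolated.  ``contact_penalty`` holds (normal,
    tangential) penalty intensities in MPa/mm; None selects
    1e3 * mu_1 / thickness for the normal and a tenth of that for the
    tangential stiffness.
    """

    clamped_set: str = "root_edge"
    lens_translation: object = None
    friction_coefficient: float = 0.1
    contact_penalty: tuple[float, float] | None = None
    contact: bool = True
    prescribed: dict[int, tuple[float | None, float | None]] | None = None

    def __post_init__(self):
        if self.friction_coefficient < 0:
            raise ValueError("friction coefficient must be >= 0")
        if self.contact_penalty is not None and any(
                k <= 0 for k in self.contact_penalty):
            raise ValueError("contact penalties must be > 0")

    def lens_translation_at(self, dp: float) -> float:
        if self.lens_translation is None:
            return 0.0
        if np.isscalar(self.lens_translation):
            return float(self.lens_translation) * dp
        dps, vals = self.lens_translation
        return float(np.interp(dp, np.asarray(dps, float),
                               np.asarray(vals, float)))


@dataclass
class LoadProgram:
    """Pressure-differential program (mmHg), starting at 0.

    ``pressure_levels`` are the output levels at which displacement fields
    are stored; the solver additionally sub-increments with
    ``n_increments`` uniform steps to the maximum.
    """

    pressure_levels: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 25.0, 6))
    n_increments: int = 10

    def __post_init__(self):
        lv = np.asarray(self.pressure_levels, dtype=float)
        if lv.ndim != 1 or len(lv) < 1 or lv[0] != 0.0:
            raise ValueError("pressure levels must start at 0")
        if len(lv) > 1 and np.any(np.diff(lv) <= 0):
            raise ValueError("pressure levels must be strictly increasing")
        if self.n_increments < 1:
            raise ValueError("n_increments must be >= 1")
        self.pressure_levels = lv


@dataclass
class SolverOptions:
    rtol: float = 1e-8
    atol: float = 1e-12
    max_iter: int = 25
    max_cutbacks: int = 6
    #: abort when any displacement exceeds this (mm); states this far
    #: outside the anterior-chamber scale are physically meaningless
    max_displacement: float = 4.0
    #: overall Newton-iteration budget for one load program
    max_total_iterations: int = 1200


@dataclass
class FieldSolution:
    """Per-level nodal displacements and convergence metadata."""

    levels: np.ndarray                 # (P,) pressure differentials, mmHg
    displacements: np.ndarray          # (P, n_nodes, 2) (u_r, u_y), mm
    newton_iterations: list
    residual_norms: list
    contact_nodes: list                # per level: array of node ids in contact
    max_volume_error: np.ndarray       # (P,) max |J - 1| over elements


# ---------------------------------------------------------------------------
# element precomputation
# ---------------------------------------------------------------------------

_QGP = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]]) / np.sqrt(3.0)
_QW = np.ones(4)


def _quad_shape(xi, eta):
    N = 0.25 * np.array([(1 - xi) * (1 - eta), (1 + xi) * (1 - eta),
                         (1 + xi) * (1 + eta), (1 - xi) * (1 + eta)])
    dN = 0.25 * np.array([[-(1 - eta), -(1 - xi)], [(1 - eta), -(1 + xi)],
                          [(1 + eta), (1 + xi)], [-(1 + eta), (1 - xi)]])
    return N, dN


class _Group:
    """Precomputed quadrature data for one element block.

    ``dev_idx`` lists the quadrature points carrying the deviatoric
    response; ``vol_idx`` is the single constant-pressure point (the
    centroid for quads; for triangles both coincide)."""

    def __init__(self, conn: np.ndarray, nodes: np.ndarray,
                 gp: np.ndarray, gw: np.ndarray, parts: tuple,
                 dev_idx=None, vol_idx=None):
        self.conn = conn
        self.parts = parts
        self.dev_idx = dev_idx
        self.vol_idx = vol_idx
        ne, nen = conn.shape
        ngp = len(gw)
        X = nodes[conn]                              # (ne, nen, 2)
        self.N = np.empty((ngp, nen))
        self.dNdX = np.empty((ne, ngp, nen, 2))
        self.wgt = np.empty((ne, ngp))
        self.R = np.empty((ne, ngp))
        for g in range(ngp):
            if nen == 4:
                N, dN = _quad_shape(*gp[g])
            else:
                N = np.array([1, 1, 1]) / 3.0
                dN = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])
            J = np.einsum("eki,kj->eij", X, dN)       # (ne, 2, 2)
            detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
            if np.any(detJ <= 0):
                raise GeometryError("non-positive reference Jacobian")
            Jinv = np.empty_like(J)
            Jinv[:, 0, 0] = J[:, 1, 1] / detJ
            Jinv[:, 1, 1] = J[:, 0, 0] / detJ
            Jinv[:, 0, 1] = -J[:, 0, 1] / detJ
            Jinv[:, 1, 0] = -J[:, 1, 0] / detJ
            self.N[g] = N
            self.dNdX[:, g] = np.einsum("kj,eji->eki", dN, Jinv)
            R = X[:, :, 0] @ N
            self.R[:, g] = R
            self.wgt[:, g] = detJ * gw[g] * 2.0 * np.pi * R
        edof = np.empty((ne, 2 * nen), dtype=int)
        edof[:, 0::2] = 2 * conn
        edof[:, 1::2] = 2 * conn + 1
        self.edof = edof
        self.edof_flat = edof.ravel()
        self.rows = np.repeat(edof, 2 * nen, axis=1)
        self.cols = np.tile(edof, (1, 2 * nen))


class _Model:
    """Mesh-level precomputation shared across Newton iterations."""

    def __init__(self, mesh: AxisymMesh):
        self.mesh = mesh
        self.ndof = 2 * mesh.n_nodes
        self.groups = []
        if len(mesh.quads):
            gp = np.vstack([_QGP, [[0.0, 0.0]]])
            gw = np.array([1.0, 1.0, 1.0, 1.0, 4.0])
            self.groups.append(_Group(mesh.quads, mesh.nodes, gp, gw,
                                      ("dev", "vol"),
                                      dev_idx=np.arange(4), vol_idx=4))
        if len(mesh.tris):
            self.groups.append(_Group(mesh.tris, mesh.nodes,
                                      np.zeros((1, 2)), np.array([0.5]),
                                      ("dev", "vol"),
                                      dev_idx=np.arange(1), vol_idx=0))
        # contact candidates: posterior surface + pupil margin
        sets = mesh.node_sets
        self.contact_nodes = np.unique(np.concatenate(
            [sets["posterior_surface"], sets["pupil_margin"]]))
        self.contact_area = self._tributary(self.contact_nodes)

    def _tributary(self, nodes_idx: np.ndarray) -> np.ndarray:
        """2*pi*r-weighted tributary widths of the contact chain."""
        pts = self.mesh.nodes[nodes_idx]
        order = np.argsort(pts[:, 0])
        chain = pts[order]
        seg = np.linalg.norm(np.diff(chain, axis=0), axis=1)
        half = np.zeros(len(chain))
        half[:-1] += 0.5 * seg
        half[1:] += 0.5 * seg
        area = np.empty(len(chain))
        area[:] = 2.0 * np.pi * np.maximum(chain[:, 0], 1e-6) * half
        out = np.empty_like(area)
        out[order] = area
        return out


def _group_force_stiffness(group: _Group, u: np.ndarray, params_arrays,
                           p_e: np.ndarray | None = None,
                           need_K: bool = True):
    """Internal force and tangent contributions of one element group.

    For groups carrying the volumetric part, ``p_e`` is the element
    pressure state; the return then includes the constraint data
    (g_el, r_p, coef) used for static condensation, else None.

    Returns (f_el (ne, ndpe), K_el (ne, ndpe, ndpe), Jgp, g_el, r_p, coef)
    in element-local dof ordering, or raises InvalidDeformationError for
    inverted / overflowing states.
    """
    mu, alpha, D = params_arrays
    conn, dNdX, N, R, wgt = group.conn, group.dNdX, group.N, group.R, group.wgt
    ne, ngp, nen, _ = dNdX.shape
    uel = u.reshape(-1, 2)[conn]                     # (ne, nen, 2)

    if _ASSEMBLE is not None:
        ok, f_el, K_el, Jvk, g_el, r_p, coef = _ASSEMBLE(
            uel, dNdX, N, R, wgt, mu, alpha, D[0], p_e,
            len(group.dev_idx), group.vol_idx, need_K)
        if not ok:
            raise InvalidDeformationError("invalid element state")
        return (f_el, K_el if need_K else None, Jvk[:, None],
                g_el, r_p, coef)

    gradu = np.einsum("eki,egkj->egij", uel, dNdX)   # (ne, ngp, 2, 2)
    F11 = 1.0 + gradu[..., 0, 0]
    F12 = gradu[..., 0, 1]
    F21 = gradu[..., 1, 0]
    F22 = 1.0 + gradu[..., 1, 1]
    ur_gp = np.einsum("ek,gk->eg", uel[:, :, 0], N)
    F33 = 1.0 + ur_gp / R

    C11 = F11**2 + F21**2
    C22 = F12**2 + F22**2
    C12 = F11 * F12 + F21 * F22
    x3 = F33**2
    m = 0.5 * (C11 + C22)
    d = 0.5 * (C11 - C22)
    disc = np.sqrt(d**2 + C12**2)
    x1 = m + disc
    x2 = m - disc
    if np.any(x2 <= 0) or np.any(x3 <= 0):
        raise InvalidDeformationError("element inversion")

    x = np.stack([x1, x2, x3], axis=-1)              # (ne, ngp, 3)
    S = np.zeros_like(x)
    dS = np.zeros(x.shape + (3,)) if need_K else None
    di, vi = group.dev_idx, group.vol_idx
    Sd, dSd = _dev_pk2_and_tangent(mu, alpha, x[:, di], need_K)
    S[:, di] += Sd
    if need_K:
        dS[:, di] += dSd
    # hybrid constant-pressure volumetric part S_vol = p J C^-1 at the
    # element pressure state, carried by the single vol point
    xv = x[:, vi]                                     # (ne, 3)
    Jv = np.sqrt(xv[:, 0] * xv[:, 1] * xv[:, 2])      # (ne,)
    Stil = Jv[:, None] / xv                           # J C^-1, principal
    S[:, vi] += p_e[:, None] * Stil
    if need_K:
        eye3 = np.eye(3)
        dS[:, vi] += p_e[:, None, None] * (
            (Jv / 2.0)[:, None, None] / (xv[:, :, None] * xv[:, None, :])
            - eye3 * Jv[:, None, None] / (xv**2)[:, :, None])
    if not np.all(np.isfinite(S)):
        raise InvalidDeformationError("non-finite stress state")

    # principal directions in the (r, y) plane (no trig needed)
    safe = disc > 1e-12 * np.maximum(x1, 1.0)
    c2 = np.where(safe, d / np.where(safe, disc, 1.0), 1.0)
    s2 = np.where(safe, C12 / np.where(safe, disc, 1.0), 0.0)
    cc = 0.5 * (1.0 + c2)        # cos^2
    ss = 0.5 * (1.0 - c2)        # sin^2
    cs = 0.5 * s2                # cos*sin

    zeros = np.zeros_like(cc)
    ones = np.ones_like(cc)
    mvec = np.stack([
        np.stack([cc, ss, zeros, cs], axis=-1),
        np.stack([ss, cc, zeros, -cs], axis=-1),
        np.stack([zeros, zeros, ones, zeros], axis=-1),
    ], axis=-2)                                       # (ne, ngp, 3, 4)
    wvec = np.stack([-cs, cs, zeros, 0.5 * (cc - ss)], axis=-1)

    Svoigt = np.einsum("ega,egai->egi", S, mvec)      # (ne, ngp, 4)

    # strain-displacement matrix (rows RR, YY, TT, 2RY)
    B = np.zeros((ne, ngp, 4, 2 * nen))
    dNr = dNdX[..., 0]
    dNy = dNdX[..., 1]
    NoverR = N[None, :, :] / R[..., None]
    B[:, :, 0, 0::2] = F11[..., None] * dNr
    B[:, :, 0, 1::2] = F21[..., None] * dNr
    B[:, :, 1, 0::2] = F12[..., None] * dNy
    B[:, :, 1, 1::2] = F22[..., None] * dNy
    B[:, :, 2, 0::2] = F33[..., None] * NoverR
    B[:, :, 3, 0::2] = F11[..., None] * dNy + F12[..., None] * dNr
    B[:, :, 3, 1::2] = F21[..., None] * dNy + F22[..., None] * dNr
    BT = B.swapaxes(-1, -2)                           # (ne, ngp, 2nen, 4)

    f_el = (BT @ (wgt[..., None, None] * Svoigt[..., None]))[..., 0].sum(axis=1)
    Jgp = Jv[:, None]

    Stil_v = np.einsum("ea,eai->ei", Stil, mvec[:, vi])
    g_el = (BT[:, vi] * wgt[:, vi, None, None]) @ Stil_v[..., None]
    g_el = g_el[..., 0]
    W = wgt[:, vi]
    r_p = W * (Jv - 1.0 - 0.5 * D[0] * p_e)
    coef = 2.0 / (D[0] * W)
    if not need_K:
        return f_el, None, Jgp, g_el, r_p, coef

    A = 2.0 * dS
    gap12 = x1 - x2
    G = np.where(gap12 > 1e-9 * np.maximum(x1, 1.0),
                 (S[..., 0] - S[..., 1]) / np.where(gap12 > 0, gap12, 1.0),
                 dS[..., 0, 0] - dS[..., 0, 1])
    Am = mvec.swapaxes(-1, -2) @ A @ mvec             # rotate to (r,y) frame
    Cv = Am + 4.0 * G[..., None, None] * (wvec[..., :, None]
                                          * wvec[..., None, :])
    K_el = (BT @ ((wgt[..., None, None] * Cv) @ B)).sum(axis=1)

    # geometric (initial-stress) stiffness via the 2x2 stress blocks
    Sm = np.empty((ne, ngp, 2, 2))
    Sm[..., 0, 0] = Svoigt[..., 0]
    Sm[..., 1, 1] = Svoigt[..., 1]
    Sm[..., 0, 1] = Sm[..., 1, 0] = Svoigt[..., 3]
    geo = (dNdX @ (wgt[..., None, None] * Sm)
           @ dNdX.swapaxes(-1, -2)).sum(axis=1)
    hoop = np.einsum("eg,egk,egl->ekl", wgt * Svoigt[..., 2], NoverR, NoverR)
    K_el[:, 0::2, 0::2] += geo + hoop
    K_el[:, 1::2, 1::2] += geo
    # static condensation of the element pressure
    K_el += coef[:, None, None] * g_el[:, :, None] * g_el[:, None, :]
    return f_el, K_el, Jgp, g_el, r_p, coef


def _pressure_load(mesh: AxisymMesh, u: np.ndarray, p: float, ndof: int):
    """Follower pressure on the current anterior surface.

    Returns (f (ndof,), K_load (ndof, ndof) contribution as dense triplets
    list [(rows, cols, vals)]) with f entering the external force and
    K_load subtracted from the tangent.
    """
    f = np.zeros(ndof)
    trips = []
    if p == 0.0 or not len(mesh.anterior_edges):
        return f, trips
    n1 = mesh.anterior_edges[:, 0]
    n2 = mesh.anterior_edges[:, 1]
    X = mesh.nodes + u.reshape(-1, 2)
    r1, y1 = X[n1, 0], X[n1, 1]
    r2, y2 = X[n2, 0], X[n2, 1]
    Dr, Dy = r2 - r1, y2 - y1
    k = p * 2.0 * np.pi / 6.0
    A = 2 * r1 + r2
    Bc = r1 + 2 * r2
    # traction = -p * outward normal; outward (anterior) normal ~ (Dy, -Dr)
    f1r, f1y = -k * A * Dy, k * A * Dr
    f2r, f2y = -k * Bc * Dy, k * Bc * Dr
    np.add.at(f, 2 * n1, f1r)
    np.add.at(f, 2 * n1 + 1, f1y)
    np.add.at(f, 2 * n2, f2r)
    np.add.at(f, 2 * n2 + 1, f2y)

    ne = len(n1)
    Kl = np.zeros((ne, 4, 4))       # dofs (r1, y1, r2, y2)
    Kl[:, 0, 0] = -2 * k * Dy
    Kl[:, 0, 1] = k * A
    Kl[:, 0, 2] = -k * Dy
    Kl[:, 0, 3] = -k * A
    Kl[:, 1, 0] = k * (2 * Dr - A)
    Kl[:, 1, 2] = k * (Dr + A)
    Kl[:, 2, 0] = -k * Dy
    Kl[:, 2, 1] = k * Bc
    Kl[:, 2, 2] = -2 * k * Dy
    Kl[:, 2, 3] = -k * Bc
    Kl[:, 3, 0] = k * (Dr - Bc)
    Kl[:, 3, 2] = k * (2 * Dr + Bc)
    edof = np.column_stack([2 * n1, 2 * n1 + 1, 2 * n2, 2 * n2 + 1])
    rows = np.repeat(edof, 4, axis=1).ravel()
    cols = np.tile(edof, (1, 4)).ravel()
    trips.append((rows, cols, Kl.ravel()))
    return f, trips


_CONTACT_SMOOTH = 1e-4   # mm; width of the C1-smoothed penalty force law


def _contact(model: _Model, u: np.ndarray, translation: float,
             anchors: np.ndarray, kn_nodes: np.ndarray, kt_nodes: np.ndarray,
             mu_f: float):
    """Penalty contact of candidate nodes against the rigid lens sphere.

    The normal force law is the C1 regularization
    fn = kn/2 * (sqrt(g**2 + eps**2) - g), which equals kn*|g| for
    penetrations beyond a few eps and decays ~ kn eps^2/(4g) outside;
    the smoothing suppresses the active-set chattering a hard
    complementarity law causes on very compliant structures.

    Returns (f_c, triplets for K_c, active mask, penetration depth).
    """
    mesh = model.mesh
    idx = model.contact_nodes
    ndof = model.ndof
    f = np.zeros(ndof)
    trips = []
    lens = mesh.lens_surface
    if lens is None:
        return f, trips, np.zeros(0, bool), 0.0
    X = mesh.nodes[idx] + u.reshape(-1, 2)[idx]
    g = lens.gap(X, translation)
    active = g < 0.0
    eps = _CONTACT_SMOOTH
    n = lens.normal(X, translation)                   # (nc, 2)
    root = np.sqrt(g**2 + eps**2)
    fn = 0.5 * kn_nodes * (root - g)                  # >= 0, smooth
    dfn = 0.5 * kn_nodes * (g / root - 1.0)           # <= 0
    fvec = fn[:, None] * n
    dist = g + lens.radius
    eye = np.eye(2)
    nn = n[:, :, None] * n[:, None, :]
    Kc = (-dfn)[:, None, None] * nn \
        - (fn / dist)[:, None, None] * (eye - nn)
    # Coulomb friction, penalty-regularized stick around the anchor point
    if mu_f > 0:
        xi = X - anchors
        xi_t = xi - (np.sum(xi * n, axis=1))[:, None] * n
        ft_trial = -kt_nodes[:, None] * xi_t
        ft_mag = np.linalg.norm(ft_trial, axis=1)
        limit = mu_f * fn
        stick = ft_mag <= limit + 1e-30
        scale = np.where(stick, 1.0, limit / np.maximum(ft_mag, 1e-30))
        fvec = fvec + scale[:, None] * ft_trial
        Kc = Kc + np.where(stick, kt_nodes, 0.0)[:, None, None] * (eye - nn)
    rows = np.repeat(2 * idx, 2) + np.tile([0, 1], len(idx))
    f[rows] = f[rows] + fvec.ravel()
    rr = np.repeat(rows.reshape(-1, 2), 2, axis=1).ravel()
    cc = np.tile(rows.reshape(-1, 2), (1, 2)).ravel()
    trips.append((rr, cc, Kc.ravel()))
    return f, trips, active, float(max(0.0, -g.min()))


def run_forward(params: OgdenParameters, mesh: AxisymMesh,
                bc: BoundaryConditions | None = None,
                load: LoadProgram | None = None,
                options: SolverOptions | None = None) -> FieldSolution:
    """Solve the incremental equilibrium problem over the load program.

    Raises :class:`ForwardSolveError` (carrying the converged prefix) if an
    increment fails after the cutback budget.
    """
    bc = bc or BoundaryConditions()
    load = load or LoadProgram()
    opt = options or SolverOptions()
    model = _Model(mesh)
    ndof = model.ndof
    pa = (np.asarray(params.mu), np.asarray(params.alpha),
          np.asarray(params.D))

    fixed = np.zeros(ndof, dtype=bool)
    target = np.zeros(ndof)
    clamped = mesh.node_sets[bc.clamped_set]
    fixed[2 * clamped] = True
    fixed[2 * clamped + 1] = True
    if bc.prescribed:
        for nid, (vr, vy) in bc.prescribed.items():
            if vr is not None:
                fixed[2 * nid] = True
                target[2 * nid] = vr
            if vy is not None:
                fixed[2 * nid + 1] = True
                target[2 * nid + 1] = vy

    thick = mesh.config.thickness if mesh.config else 0.4
    kn_int, kt_int = bc.contact_penalty or (1e3 * params.mu[0] / thick,
                                            10.0 * params.mu[0] / thick)
    kn_nodes = kn_int * model.contact_area
    kt_nodes = kt_int * model.contact_area
    do_contact = bc.contact and mesh.lens_surface is not None
    anchors = mesh.nodes[model.contact_nodes].copy()

    dp_max = float(load.pressure_levels[-1])
    nlev = len(load.pressure_levels)
    if dp_max > 0:
        out_tau = load.pressure_levels / dp_max
    elif bc.prescribed:
        # pure prescribed-displacement ramp (patch tests): final state at
        # the last output level
        out_tau = (np.linspace(0.0, 1.0, nlev) if nlev > 1
                   else np.array([1.0]))
    else:
        return FieldSolution(levels=load.pressure_levels.copy(),
                             displacements=np.zeros((nlev, mesh.n_nodes, 2)),
                             newton_iterations=[0] * nlev,
                             residual_norms=[0.0] * nlev,
                             contact_nodes=[np.zeros(0, dtype=int)] * nlev,
                             max_volume_error=np.zeros(nlev))
    u = np.zeros(ndof)
    out_disp = np.zeros((len(out_tau), mesh.n_nodes, 2))
    iters, resnorms, contacts = [], [], []
    maxJ = np.zeros(len(out_tau))
    if out_tau[0] == 0.0:
        out_i = 1
        contacts.append(np.zeros(0, dtype=int))
        iters.append(0)
        resnorms.append(0.0)
    else:
        out_i = 0

    vol_groups = [i for i, g in enumerate(model.groups) if "vol" in g.parts]

    def system(u, pstate, pres, trans, need_K):
        """Residual (and tangent) at state (u, element pressures)."""
        K = np.zeros((ndof, ndof)) if need_K else None
        f_int = np.zeros(ndof)
        rhs_extra = np.zeros(ndof)
        cond = {}
        Jmax = 0.0
        vmax = 0.0
        for gi, grp in enumerate(model.groups):
            pe = pstate.get(gi)
            f_el, K_el, Jgp, g_el, r_p, coef = _group_force_stiffness(
                grp, u, pa, p_e=pe, need_K=need_K)
            f_int += np.bincount(grp.edof_flat, f_el.ravel(),
                                 minlength=ndof)
            if need_K:
                flat = grp.rows.ravel() * ndof + grp.cols.ravel()
                K.ravel()[:] += np.bincount(flat, K_el.ravel(),
                                            minlength=ndof * ndof)
            if g_el is not None:
                rhs_extra += np.bincount(
                    grp.edof_flat,
                    (coef[:, None] * r_p[:, None] * g_el).ravel(),
                    minlength=ndof)
                cond[gi] = (g_el, r_p, coef)
                Jmax = max(Jmax, float(np.abs(Jgp - 1.0).max()))
                vmax = max(vmax, float(np.abs(r_p / grp.wgt[:, 0]).max()))
        f_ext, ltrips = _pressure_load(mesh, u, pres, ndof)
        if do_contact:
            f_c, ctrips, active, _pen = _contact(
                model, u, trans, anchors, kn_nodes, kt_nodes,
                bc.friction_coefficient)
        else:
            f_c = np.zeros(ndof)
            ctrips, active = [], np.zeros(0, bool)
        res = f_int - f_ext - f_c
        res[fixed] = 0.0
        rhs_extra[fixed] = 0.0
        ref = max(np.linalg.norm(f_ext) + np.linalg.norm(f_c), opt.atol)
        if need_K:
            for rows, cols, vals in ltrips:
                K.ravel()[:] -= np.bincount(
                    rows * ndof + cols, vals, minlength=ndof * ndof)
            for rows, cols, vals in ctrips:
                K.ravel()[:] += np.bincount(
                    rows * ndof + cols, vals, minlength=ndof * ndof)
        return res, rhs_extra, cond, ref, K, active, Jmax, vmax

    budget = {"left": opt.max_total_iterations}

    def newton(u0, pstate0, tau):
        """Return (u, pstate, n_iter, res, active, Jmax) or None."""
        u = u0.copy()
        pstate = {k: v.copy() for k, v in pstate0.items()}
        pres = tau * dp_max * MMHG_TO_MPA
        trans = bc.lens_translation_at(tau * dp_max)
        u[fixed] = np.where(target[fixed] != 0.0, tau * target[fixed], 0.0)
        uphill = 0
        fast = False       # skip the line-search probe while converging well
        backup = None
        rn_prev = np.inf
        for it in range(opt.max_iter):
            if budget["left"] <= 0:
                return None
            budget["left"] -= 1
            try:
                res, rhs_x, cond, ref, K, active, Jmax, vmax = system(
                    u, pstate, pres, trans, True)
            except (InvalidDeformationError, np.linalg.LinAlgError):
                if backup is not None:
                    u, pstate, rn_prev = backup
                    backup = None
                    fast = False
                    continue
                return None
            rn = np.linalg.norm(res)
            if rn <= opt.rtol * ref + opt.atol and vmax <= 1e-9:
                return u, pstate, it, rn, active, Jmax
            if rn >= rn_prev:
                fast = False     # leave the probe-free regime
            try:
                K[fixed, :] = 0.0
                K[:, fixed] = 0.0
                K[fixed, fixed] = 1.0
                du = np.linalg.solve(K, -(res + rhs_x))
            except np.linalg.LinAlgError:
                return None
            if not np.all(np.isfinite(du)):
                return None
            dp = {}
            for gi in vol_groups:
                g_el, r_p, coef = cond[gi]
                du_el = du[model.groups[gi].edof]
                dp[gi] = coef * (r_p + np.einsum("ei,ei->e", g_el, du_el))
            if fast:
                # quadratic-convergence regime: take the full step and let
                # the next residual evaluation arbitrate (backup restores
                # the state if it turns out invalid)
                backup = (u, pstate, rn)
                u = u + du
                pstate = {gi: pstate[gi] + dp[gi] for gi in dp}
                rn_prev = rn
                continue
            # full step preferred; back off when a shorter step has a
            # strictly smaller residual
            best = None
            for s in (1.0, 0.5, 0.25, 0.125):
                try:
                    ut = u + s * du
                    pt = {gi: pstate[gi] + s * dp[gi] for gi in dp}
                    rt, *_rest = system(ut, pt, pres, trans, False)
                    rtn = np.linalg.norm(rt)
                except InvalidDeformationError:
                    continue
                if best is None or rtn < best[0]:
                    best = (rtn, ut, pt, s)
                if rtn < rn:
                    break
            if best is None:
                return None
            if best[0] >= rn:
                uphill += 1      # transient growth right after a load step
                if uphill > 4:
                    return None
            fast = best[3] == 1.0 and best[0] < 0.3 * rn
            backup = (u, pstate, rn)
            u, pstate = best[1], best[2]
            rn_prev = best[0]
        return None

    pstate = {gi: np.zeros(len(model.groups[gi].conn)) for gi in vol_groups}
    dtau_nom = min(1.0 / load.n_increments, np.diff(
        np.concatenate([[0.0], out_tau[out_tau > 0]])).min()
        if np.any(out_tau > 0) else 1.0)
    dtau_min = dtau_nom / 2 ** opt.max_cutbacks
    tau = 0.0
    # displacement-trust step control: size the first increment from the
    # linear response so the predicted step displacement stays near
    # ``u_trust`` (the unloaded bending regime is ultra-compliant and
    # material-dependent; a fixed first step either crawls or diverges)
    u_trust = 0.3
    dtau = dtau_nom
    if dp_max > 0:
        try:
            res0, rhs0, cond0, ref0, K0, *_rest = system(
                np.zeros(ndof), pstate, dp_max * MMHG_TO_MPA, 0.0, True)
            K0[fixed, :] = 0.0
            K0[:, fixed] = 0.0
            K0[fixed, fixed] = 1.0
            u_lin = np.linalg.solve(K0, -(res0 + rhs0))
            peak = np.abs(u_lin).max()
            if np.isfinite(peak) and peak > 0:
                dtau = float(np.clip(u_trust / peak, dtau_min, dtau_nom))
        except (InvalidDeformationError, np.linalg.LinAlgError):
            pass
    u_last = None
    dtau_last = None

    def fail(tau_at):
        partial = FieldSolution(
            levels=load.pressure_levels[:out_i],
            displacements=out_disp[:out_i],
            newton_iterations=iters, residual_norms=resnorms,
            contact_nodes=contacts, max_volume_error=maxJ[:out_i])
        raise ForwardSolveError(
            f"Newton failed at load fraction {tau_at:.4f}", partial)

    while tau < 1.0 - 1e-12:
        ahead = out_tau[out_tau > tau + 1e-12]
        nxt = ahead[0] if len(ahead) else 1.0
        # snap to the next output level rather than leaving a stub step
        tau_try = nxt if tau + 1.4 * dtau >= nxt else tau + dtau
        step = tau_try - tau
        if u_last is not None and dtau_last and dtau_last > 0:
            guess = u + (u - u_last) * (step / dtau_last)
        else:
            guess = u
        result = newton(guess, pstate, tau_try)
        if result is None and np.any(guess != u) and budget["left"] > 0:
            result = newton(u, pstate, tau_try)   # retry without predictor
        if result is None:
            if step <= dtau_min * (1 + 1e-9) or budget["left"] <= 0:
                fail(tau_try)
            dtau = max(0.5 * step, dtau_min)
            continue
        unew, pstate, nit, rn, active, Jmax = result
        if np.abs(unew).max() > opt.max_displacement:
            fail(tau_try)
        du_peak = np.abs(unew - u).max()
        u_last, u = u, unew
        dtau_last = step
        tau = tau_try
        if nit <= 10:
            grow = u_trust / du_peak if du_peak > 0 else 2.0
            dtau = float(np.clip(step * np.clip(grow, 0.5, 2.5),
                                 dtau_min, dtau_nom))
        if do_contact:    # update friction anchors at convergence
            trans = bc.lens_translation_at(tau * dp_max)
            _update_anchors(model, u, trans, anchors, kn_nodes, kt_nodes,
                            bc.friction_coefficient)
        if out_i < len(out_tau) and np.isclose(tau, out_tau[out_i]):
            out_disp[out_i] = u.reshape(-1, 2)
            iters.append(nit)
            resnorms.append(rn)
            contacts.append(model.contact_nodes[active]
                            if len(active) else np.zeros(0, dtype=int))
            maxJ[out_i] = Jmax
            out_i += 1

    return FieldSolution(levels=load.pressure_levels.copy(),
                         displacements=out_disp,
                         newton_iterations=iters, residual_norms=resnorms,
                         contact_nodes=contacts, max_volume_error=maxJ)


def _update_anchors(model, u, translation, anchors, kn_nodes, kt_nodes,
                    mu_f):
    """Slide friction anchors so stored tangential stretch obeys Coulomb."""
    lens = model.mesh.lens_surface
    idx = model.contact_nodes
    X = model.mesh.nodes[idx] + u.reshape(-1, 2)[idx]
    g = lens.gap(X, translation)
    active = g < 0
    anchors[~active] = X[~active]
    if not np.any(active) or mu_f <= 0:
        return
    n = lens.normal(X[active], translation)
    xi = X[active] - anchors[active]
    xi_t = xi - np.sum(xi * n, axis=1)[:, None] * n
    kt = kt_nodes[active]
    ft = kt * np.linalg.norm(xi_t, axis=1)
    limit = mu_f * (-kn_nodes[active] * g[active])
    slip = ft > limit
    if np.any(slip):
        ratio = (1.0 - limit[slip] / np.maximum(ft[slip], 1e-30))[:, None]
        anchors_a = anchors[active]
        anchors_a[slip] = anchors_a[slip] + ratio * xi_t[slip]
        anchors[active] = anchors_a


def extract_point_displacements(
        sol: FieldSolution, mesh: AxisymMesh,
        points: Sequence[tuple[float, float]],
        point_ids: Sequence[str] | None = None,
        tol: float = 0.25) -> list[DisplacementTrack]:
    """Y-displacement tracks at reference surface points.

    Each query point is matched to the nearest node of ``surface_all``
    within ``tol`` (mm); two queries matching the same node produce
    identical tracks and a warning.  Track values are the signed axial
    displacements (positive posterior); they are 0 at the zero level.
    """
    surf = mesh.node_sets["surface_all"]
    tree = cKDTree(mesh.nodes[surf])
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    dist, pos = tree.query(pts)
    bad = dist > tol
    if np.any(bad):
        raise PointMatchError(
            f"points {pts[bad].tolist()} farther than {tol} mm "
            "from any surface node")
    nodes = surf[pos]
    if len(np.unique(nodes)) < len(nodes):
        warnings.warn("multiple query points matched the same surface node")
    ids = (list(point_ids) if point_ids is not None
           else [f"p{i}" for i in range(len(pts))])
    tracks = []
    for pid, nid in zip(ids, nodes):
        uy = sol.displacements[:, nid, 1].copy()
        tracks.append(DisplacementTrack(point_id=str(pid),
                                        dp=sol.levels.copy(), uy=uy,
                                        source="simulated",
                                        reference_point=tuple(mesh.nodes[nid])))
    return tracks
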