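"""Compiled element kernel for the axisymmetric assembly.

A numba translation of the element loop in :mod:`irisid.forward` (same
mathematics: total-Lagrangian B-matrices, principal-stretch Ogden
deviatoric response on the dev quadrature points, element-constant
pressure volumetric part on the vol point, spectral tangent with the
coincident-eigenvalue limit, geometric stiffness, pressure-condensation
data).  The pure-numpy implementation remains the reference; this kernel
exists because assembly dominates the inverse-identification runtime and
the per-call numpy overhead is otherwise irreducible.

Falls back gracefully: ``ASSEMBLE = None`` when numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
except ImportError:                                    # pragma: no cover
    njit = None

_LOG_CAP = 120.0


def _build():
    @njit(cache=True, fastmath=False)
    def assemble(uel, dNdX, Ns, R, wgt, mu, alpha, D1, p_e,
                 n_dev, vol_gp, need_K):
        """Element forces/stiffness for one group.

        uel (ne, nen, 2); dNdX (ne, ngp, nen, 2); Ns (ngp, nen);
        R, wgt (ne, ngp); mu, alpha (nmat,); p_e (ne,).  Quadrature points
        0..n_dev-1 carry the deviatoric part, point vol_gp the volumetric
        part (they may coincide for triangles).

        Returns (ok, f_el, K_el, Jv, g_el, r_p, coef).
        """
        ne, ngp, nen, _ = dNdX.shape
        nd = 2 * nen
        nmat = mu.shape[0]
        f_el = np.zeros((ne, nd))
        K_el = np.zeros((ne, nd, nd)) if need_K else np.zeros((1, 1, 1))
        Jv = np.zeros(ne)
        g_el = np.zeros((ne, nd))
        r_p = np.zeros(ne)
        coef = np.zeros(ne)
        B = np.zeros((4, nd))
        mrow = np.zeros((3, 4))
        wv = np.zeros(4)
        Cv = np.zeros((4, 4))
        CB = np.zeros((4, nd))
        A = np.zeros((3, 3))
        S = np.zeros(3)
        dS = np.zeros((3, 3))
        e_pow = np.zeros((nmat, 3))

        for el in range(ne):
            for g in range(ngp):
                # deformation gradient (2x2 block + hoop)
                g00 = 0.0
                g01 = 0.0
                g10 = 0.0
                g11 = 0.0
                ur = 0.0
                for k in range(nen):
                    g00 += uel[el, k, 0] * dNdX[el, g, k, 0]
                    g01 += uel[el, k, 0] * dNdX[el, g, k, 1]
                    g10 += uel[el, k, 1] * dNdX[el, g, k, 0]
                    g11 += uel[el, k, 1] * dNdX[el, g, k, 1]
                    ur += uel[el, k, 0] * Ns[g, k]
                F11 = 1.0 + g00
                F12 = g01
                F21 = g10
                F22 = 1.0 + g11
                F33 = 1.0 + ur / R[el, g]

                C11 = F11 * F11 + F21 * F21
                C22 = F12 * F12 + F22 * F22
                C12 = F11 * F12 + F21 * F22
                x3 = F33 * F33
                m = 0.5 * (C11 + C22)
                d = 0.5 * (C11 - C22)
                disc = np.sqrt(d * d + C12 * C12)
                x1 = m + disc
                x2 = m - disc
                if x2 <= 0.0 or x3 <= 0.0:
                    return False, f_el, K_el, Jv, g_el, r_p, coef

                # principal direction cosines (no trig)
                if disc > 1e-12 * max(x1, 1.0):
                    c2 = d / disc
                    s2 = C12 / disc
                else:
                    c2 = 1.0
                    s2 = 0.0
                cc = 0.5 * (1.0 + c2)
                ss = 0.5 * (1.0 - c2)
                cs = 0.5 * s2

                ll1 = 0.5 * np.log(x1)
                ll2 = 0.5 * np.log(x2)
                ll3 = 0.5 * np.log(x3)
                logJ = ll1 + ll2 + ll3
                J = np.exp(logJ)

                for a in range(3):
                    S[a] = 0.0
                    for b in range(3):
                        dS[a, b] = 0.0

                is_dev = g < n_dev
                is_vol = g == vol_gp
                if is_dev:
                    lb1 = ll1 - logJ / 3.0
                    lb2 = ll2 - logJ / 3.0
                    lb3 = ll3 - logJ / 3.0
                    for i in range(nmat):
                        a1 = alpha[i] * lb1
                        a2 = alpha[i] * lb2
                        a3 = alpha[i] * lb3
                        if (abs(a1) > _LOG_CAP or abs(a2) > _LOG_CAP
                                or abs(a3) > _LOG_CAP):
                            return False, f_el, K_el, Jv, g_el, r_p, coef
                        e_pow[i, 0] = np.exp(a1)
                        e_pow[i, 1] = np.exp(a2)
                        e_pow[i, 2] = np.exp(a3)
                    xs0 = x1
                    xs1 = x2
                    xs2 = x3
                    xv3 = (xs0, xs1, xs2)
                    for i in range(nmat):
                        c = 2.0 * mu[i] / alpha[i]
                        E = e_pow[i, 0] + e_pow[i, 1] + e_pow[i, 2]
                        for a in range(3):
                            S[a] += c * (e_pow[i, a] - E / 3.0) / xv3[a]
                    if need_K:
                        # d tau_a / d x_b then dS
                        for i in range(nmat):
                            c = 2.0 * mu[i] / alpha[i]
                            ca = c * alpha[i]
                            E = e_pow[i, 0] + e_pow[i, 1] + e_pow[i, 2]
                            for a in range(3):
                                for b in range(3):
                                    dab = 1.0 if a == b else 0.0
                                    t = ca * (e_pow[i, a] * (dab - 1.0 / 3.0)
                                              - (e_pow[i, b] - E / 3.0) / 3.0)
                                    dS[a, b] += (t / (2.0 * xv3[b])) / xv3[a]
                        # subtract the S/x diagonal part (chain rule)
                        for a in range(3):
                            tau_a = S[a] * xv3[a]
                            dS[a, a] -= tau_a / (xv3[a] * xv3[a])
                if is_vol:
                    pe = p_e[el]
                    xv = (x1, x2, x3)
                    for a in range(3):
                        S[a] += pe * J / xv[a]
                    if need_K:
                        for a in range(3):
                            for b in range(3):
                                dS[a, b] += pe * (J / 2.0) / (xv[a] * xv[b])
                            dS[a, a] -= pe * J / (xv[a] * xv[a])
                    Jv[el] = J

                # Voigt projection vectors (rows: principal dirs)
                mrow[0, 0] = cc
                mrow[0, 1] = ss
                mrow[0, 2] = 0.0
                mrow[0, 3] = cs
                mrow[1, 0] = ss
                mrow[1, 1] = cc
                mrow[1, 2] = 0.0
                mrow[1, 3] = -cs
                mrow[2, 0] = 0.0
                mrow[2, 1] = 0.0
                mrow[2, 2] = 1.0
                mrow[2, 3] = 0.0

                Sv0 = S[0] * mrow[0, 0] + S[1] * mrow[1, 0]
                Sv1 = S[0] * mrow[0, 1] + S[1] * mrow[1, 1]
                Sv2 = S[2]
                Sv3 = S[0] * mrow[0, 3] + S[1] * mrow[1, 3]

                # B matrix (rows RR, YY, TT, 2RY)
                w = wgt[el, g]
                for k in range(nen):
                    dr = dNdX[el, g, k, 0]
                    dy = dNdX[el, g, k, 1]
                    NoR = Ns[g, k] / R[el, g]
                    B[0, 2 * k] = F11 * dr
                    B[0, 2 * k + 1] = F21 * dr
                    B[1, 2 * k] = F12 * dy
                    B[1, 2 * k + 1] = F22 * dy
                    B[2, 2 * k] = F33 * NoR
                    B[2, 2 * k + 1] = 0.0
                    B[3, 2 * k] = F11 * dy + F12 * dr
                    B[3, 2 * k + 1] = F21 * dy + F22 * dr

                for j in range(nd):
                    f_el[el, j] += w * (B[0, j] * Sv0 + B[1, j] * Sv1
                                        + B[2, j] * Sv2 + B[3, j] * Sv3)

                if is_vol:
                    # g vector: J C^-1 projected through B
                    xv = (x1, x2, x3)
                    St0 = (J / xv[0]) * mrow[0, 0] + (J / xv[1]) * mrow[1, 0]
                    St1 = (J / xv[0]) * mrow[0, 1] + (J / xv[1]) * mrow[1, 1]
                    St2 = J / xv[2]
                    St3 = (J / xv[0]) * mrow[0, 3] + (J / xv[1]) * mrow[1, 3]
                    for j in range(nd):
                        g_el[el, j] = w * (B[0, j] * St0 + B[1, j] * St1
                                           + B[2, j] * St2 + B[3, j] * St3)
                    r_p[el] = w * (J - 1.0 - 0.5 * D1 * p_e[el])
                    coef[el] = 2.0 / (D1 * w)

                if need_K:
                    # material tangent in Voigt form
                    for a in range(3):
                        for b in range(3):
                            A[a, b] = 2.0 * dS[a, b]
                    gap12 = x1 - x2
                    if gap12 > 1e-9 * max(x1, 1.0):
                        G = (S[0] - S[1]) / gap12
                    else:
                        G = dS[0, 0] - dS[0, 1]
                    wv[0] = -cs
                    wv[1] = cs
                    wv[2] = 0.0
                    wv[3] = 0.5 * (cc - ss)
                    for i4 in range(4):
                        for j4 in range(4):
                            acc = 4.0 * G * wv[i4] * wv[j4]
                            for a in range(3):
                                for b in range(3):
                                    acc += A[a, b] * mrow[a, i4] * mrow[b, j4]
                            Cv[i4, j4] = acc
                    for i4 in range(4):
                        for j in range(nd):
                            CB[i4, j] = (Cv[i4, 0] * B[0, j]
                                         + Cv[i4, 1] * B[1, j]
                                         + Cv[i4, 2] * B[2, j]
                                         + Cv[i4, 3] * B[3, j])
                    for i in range(nd):
                        for j in range(nd):
                            K_el[el, i, j] += w * (B[0, i] * CB[0, j]
                                                   + B[1, i] * CB[1, j]
                                                   + B[2, i] * CB[2, j]
                                                   + B[3, i] * CB[3, j])
                    # geometric stiffness
                    for k in range(nen):
                        drk = dNdX[el, g, k, 0]
                        dyk = dNdX[el, g, k, 1]
                        NoRk = Ns[g, k] / R[el, g]
                        for l in range(nen):
                            drl = dNdX[el, g, l, 0]
                            dyl = dNdX[el, g, l, 1]
                            NoRl = Ns[g, l] / R[el, g]
                            geo = w * (drk * Sv0 * drl + dyk * Sv1 * dyl
                                       + Sv3 * (drk * dyl + dyk * drl))
                            hoop = w * NoRk * Sv2 * NoRl
                            K_el[el, 2 * k, 2 * l] += geo + hoop
                            K_el[el, 2 * k + 1, 2 * l + 1] += geo
            if need_K:
                cf = coef[el]
                for i in range(nd):
                    gi = g_el[el, i]
                    for j in range(nd):
                        K_el[el, i, j] += cf * gi * g_el[el, j]
        return True, f_el, K_el, Jv, g_el, r_p, coef

    return assemble


ASSEMBLE = _build() if njit is not None else None
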