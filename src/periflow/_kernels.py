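"""Numba-compiled inner loops of the flow solver.

These kernels are numerically identical to the (slower) pure-numpy
formulation they replaced; they exist only to keep the 3 s implant fill
transient a desk-scale computation.  All loops are deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["sweep_kernel", "momentum_kernel", "face_forces_kernel",
           "curvature_kernel"]


@njit(cache=False, fastmath=False)
def sweep_kernel(al, cc, u, dt, h, inlet_mask, open_mask, m, has_m,
                 conc_in, flux_edges):
    """One conservative x-direction MUSCL/superbee sweep.

    ``flux_edges`` receives the liquid sums [influx, outflux_lo,
    outflux_hi] in slots 0-2 and the species sums in slots 3-5 (plain sums
    of F; the caller multiplies by h).  ``conc_in`` is the pre-sweep
    concentration used for species upwinding.  Returns (al_new, m_new).
    """
    ny, nx = al.shape
    F = np.zeros((ny, nx + 1))
    Fm = np.zeros((ny, nx + 1))
    for j in range(ny):
        for i in range(nx + 1):
            uf = u[j, i]
            if not (open_mask[j, i] or inlet_mask[j, i]):
                continue
            # Ghost-padded neighbour values (zero-gradient at array edges).
            iD = i - 1 if uf > 0 else i
            iU = i - 2 if uf > 0 else i + 1
            iA = i if uf > 0 else i - 1
            aD = al[j, min(max(iD, 0), nx - 1)]
            aU = al[j, min(max(iU, 0), nx - 1)]
            aA = al[j, min(max(iA, 0), nx - 1)]
            cou = abs(uf) * dt / h
            denom = aA - aD
            if abs(denom) > 1e-12:
                r = (aD - aU) / denom
                # superbee limiter
                phi = max(0.0, max(min(2.0 * r, 1.0), min(r, 2.0)))
            else:
                phi = 0.0
            aface = aD + 0.5 * phi * (1.0 - cou) * denom
            if aface < 0.0:
                aface = 0.0
            elif aface > 1.0:
                aface = 1.0
            if inlet_mask[j, i]:
                aface = 1.0
            F[j, i] = uf * dt * aface
            if has_m:
                if inlet_mask[j, i]:
                    cf = 1.0
                else:
                    ic = i - 1 if uf > 0 else i
                    cf = conc_in[j, min(max(ic, 0), nx - 1)]
                Fm[j, i] = cf * F[j, i]
            if inlet_mask[j, i]:
                flux_edges[0] += abs(F[j, i])
                if has_m:
                    flux_edges[3] += abs(Fm[j, i])
            elif i == 0 and open_mask[j, i]:
                flux_edges[1] += -F[j, i]
                if has_m:
                    flux_edges[4] += -Fm[j, i]
            elif i == nx and open_mask[j, i]:
                flux_edges[2] += F[j, i]
                if has_m:
                    flux_edges[5] += Fm[j, i]

    al_new = np.empty_like(al)
    m_new = np.empty_like(al)
    for j in range(ny):
        for i in range(nx):
            div = (u[j, i + 1] - u[j, i]) / h
            al_new[j, i] = al[j, i] - (F[j, i + 1] - F[j, i]) / h \
                + dt * cc[j, i] * div
            if has_m:
                m_new[j, i] = m[j, i] - (Fm[j, i + 1] - Fm[j, i]) / h \
                    + dt * conc_in[j, i] * cc[j, i] * div
    return al_new, m_new


@njit(cache=False, fastmath=False)
def momentum_kernel(u, v, rho, mu, fx, fy, drag, dt, h, gx, gy,
                    sgn_left, sgn_right, sgn_bottom, sgn_top, has_drag):
    """Explicit momentum predictor on the staggered grid.

    Upwind advection, variable-viscosity Laplacian with reflecting ghosts
    at domain edges, combined face forces ``fx``/``fy`` (surface tension +
    wetting + wicking), gravity, then implicit per-face texture drag.
    Returns (u_star, v_star).
    """
    ny, nxp = u.shape
    nx = nxp - 1
    u_star = np.zeros_like(u)
    v_star = np.zeros_like(v)

    for j in range(ny):
        for i in range(nxp):
            uc = u[j, i]
            # neighbours with ghosts
            uW = u[j, i - 1] if i - 1 >= 0 else uc * sgn_left
            uE = u[j, i + 1] if i + 1 <= nx else uc * sgn_right
            uS = u[j - 1, i] if j - 1 >= 0 else uc * sgn_bottom
            uN = u[j + 1, i] if j + 1 < ny else uc * sgn_top
            if 0 < i < nx:
                vau = 0.25 * (v[j, i] + v[j, i - 1] + v[j + 1, i] + v[j + 1, i - 1])
                rho_f = 0.5 * (rho[j, i] + rho[j, i - 1])
                mu_f = 0.5 * (mu[j, i] + mu[j, i - 1])
                dcoef = 0.5 * (drag[j, i] + drag[j, i - 1]) if has_drag else 0.0
            else:
                vau = 0.0
                ii = 0 if i == 0 else nx - 1
                rho_f = rho[j, ii]
                mu_f = mu[j, ii]
                dcoef = 0.0
            dudx = (uc - uW) / h if uc > 0 else (uE - uc) / h
            dudy = (uc - uS) / h if vau > 0 else (uN - uc) / h
            adv = uc * dudx + vau * dudy
            lap = (uW + uE + uS + uN - 4.0 * uc) / (h * h)
            val = uc + dt * (-adv + (mu_f * lap + fx[j, i]) / rho_f + gx)
            if has_drag and dcoef > 0.0:
                val /= (1.0 + dt * dcoef)
            u_star[j, i] = val

    nyp = ny + 1
    for j in range(nyp):
        for i in range(nx):
            vc = v[j, i]
            vW = v[j, i - 1] if i - 1 >= 0 else vc * sgn_left
            vE = v[j, i + 1] if i + 1 < nx else vc * sgn_right
            vS = v[j - 1, i] if j - 1 >= 0 else vc * sgn_bottom
            vN = v[j + 1, i] if j + 1 <= ny else vc * sgn_top
            if 0 < j < ny:
                uav = 0.25 * (u[j, i] + u[j, i + 1] + u[j - 1, i] + u[j - 1, i + 1])
                rho_f = 0.5 * (rho[j, i] + rho[j - 1, i])
                mu_f = 0.5 * (mu[j, i] + mu[j - 1, i])
                dcoef = 0.5 * (drag[j, i] + drag[j - 1, i]) if has_drag else 0.0
            else:
                uav = 0.0
                jj = 0 if j == 0 else ny - 1
                rho_f = rho[jj, i]
                mu_f = mu[jj, i]
                dcoef = 0.0
            dvdx = (vc - vW) / h if uav > 0 else (vE - vc) / h
            dvdy = (vc - vS) / h if vc > 0 else (vN - vc) / h
            adv = uav * dvdx + vc * dvdy
            lap = (vW + vE + vS + vN - 4.0 * vc) / (h * h)
            val = vc + dt * (-adv + (mu_f * lap + fy[j, i]) / rho_f + gy)
            if has_drag and dcoef > 0.0:
                val /= (1.0 + dt * dcoef)
            v_star[j, i] = val
    return u_star, v_star


@njit(cache=False, fastmath=False)
def curvature_kernel(als, h):
    """Interface curvature kappa = -div(grad als / |grad als|), clipped to
    the grid scale.  One-sided zeros at array edges (matching the numpy
    version)."""
    ny, nx = als.shape
    nxh = np.zeros((ny, nx))
    nyh = np.zeros((ny, nx))
    for j in range(ny):
        for i in range(nx):
            gx = (als[j, i + 1] - als[j, i - 1]) / (2 * h) if 0 < i < nx - 1 else 0.0
            gy = (als[j + 1, i] - als[j - 1, i]) / (2 * h) if 0 < j < ny - 1 else 0.0
            mag = np.sqrt(gx * gx + gy * gy)
            if mag > 1e-12:
                nxh[j, i] = gx / mag
                nyh[j, i] = gy / mag
    kappa = np.zeros((ny, nx))
    lim = 1.0 / h
    for j in range(ny):
        for i in range(nx):
            dnx = (nxh[j, i + 1] - nxh[j, i - 1]) / (2 * h) if 0 < i < nx - 1 else 0.0
            dny = (nyh[j + 1, i] - nyh[j - 1, i]) / (2 * h) if 0 < j < ny - 1 else 0.0
            k = -(dnx + dny)
            if k > lim:
                k = lim
            elif k < -lim:
                k = -lim
            kappa[j, i] = k
    return kappa


@njit(cache=False, fastmath=False)
def face_forces_kernel(al, kappa, cos_theta, band, layer, sigma, wick_p, h,
                       fx, fy):
    """Combined surface-tension (CSF), contact-line wetting, and texture
    wicking face forces, accumulated into fx (u-faces) and fy (v-faces)."""
    ny, nx = al.shape
    for j in range(ny):
        for i in range(1, nx):
            dal = (al[j, i] - al[j, i - 1]) / h
            if dal == 0.0:
                continue
            f = 0.0
            if sigma > 0.0:
                f += sigma * 0.5 * (kappa[j, i] + kappa[j, i - 1]) * dal
                if band[j, i] and band[j, i - 1]:
                    cq = 0.5 * (cos_theta[j, i] + cos_theta[j, i - 1])
                    f += -sigma * cq / h * dal
            if wick_p > 0.0:
                recv = i - 1 if dal > 0 else i
                if layer[j, recv]:
                    f += -wick_p * dal
            fx[j, i] += f
    for j in range(1, ny):
        for i in range(nx):
            dal = (al[j, i] - al[j - 1, i]) / h
            if dal == 0.0:
                continue
            f = 0.0
            if sigma > 0.0:
                f += sigma * 0.5 * (kappa[j, i] + kappa[j - 1, i]) * dal
                if band[j, i] and band[j - 1, i]:
                    cq = 0.5 * (cos_theta[j, i] + cos_theta[j - 1, i])
                    f += -sigma * cq / h * dal
            if wick_p > 0.0:
                recv = j - 1 if dal > 0 else j
                if layer[recv, i]:
                    f += -wick_p * dal
            fy[j, i] += f
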