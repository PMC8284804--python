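"""Numba inner loops for the particle mechanics.

All kernels operate on flat numpy arrays so that the whole quasistatic
constriction run (hundreds of energy minimizations of ~10^3 particles)
stays fast on a single core.  Pair interactions are given as index arrays
``pi, pj`` with a boolean ``conn`` flag per pair: connected neighbors
interact through the full spring (attractive + repulsive), unconnected
pairs through the repulsive branch only.  Distances use the minimum-image
convention in a periodic (Lx, Ly) box.

Optional boundary tethers (implicit-mesoderm springs) are passed as
``(spring_idx, spring_anchor, k_eff)``; pass empty arrays to disable.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "compute_forces",
    "potential_energy",
    "fire_minimize",
    "damped_verlet_minimize",
    "stress_sums",
    "tessellate_labels",
]


@njit(cache=True, fastmath=True)
def compute_forces(pos, diam, pi, pj, conn, Lx, Ly, eps,
                   spring_idx, spring_anchor, k_eff, forces):
    """Accumulate forces into ``forces`` (zeroed here); return potential energy."""
    n = pos.shape[0]
    for a in range(n):
        forces[a, 0] = 0.0
        forces[a, 1] = 0.0
    energy = 0.0
    for k in range(pi.shape[0]):
        i = pi[k]
        j = pj[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dx -= Lx * np.rint(dx / Lx)
        dy -= Ly * np.rint(dy / Ly)
        r = np.sqrt(dx * dx + dy * dy)
        dij = 0.5 * (diam[i] + diam[j])
        if not conn[k] and r >= dij:
            continue
        if r <= 0.0:
            continue
        delta = 1.0 - r / dij
        # f > 0 repulsive, f < 0 attractive (radial component)
        f = (eps / dij) * delta
        energy += 0.5 * eps * delta * delta
        fx = f * dx / r
        fy = f * dy / r
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[j, 0] -= fx
        forces[j, 1] -= fy
    for k in range(spring_idx.shape[0]):
        i = spring_idx[k]
        dx = pos[i, 0] - spring_anchor[k, 0]
        dy = pos[i, 1] - spring_anchor[k, 1]
        # tethers are local anchors: no minimum image
        forces[i, 0] -= k_eff * dx
        forces[i, 1] -= k_eff * dy
        energy += 0.5 * k_eff * (dx * dx + dy * dy)
    return energy


@njit(cache=True, fastmath=True)
def potential_energy(pos, diam, pi, pj, conn, Lx, Ly, eps,
                     spring_idx, spring_anchor, k_eff):
    energy = 0.0
    for k in range(pi.shape[0]):
        i = pi[k]
        j = pj[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dx -= Lx * np.rint(dx / Lx)
        dy -= Ly * np.rint(dy / Ly)
        r = np.sqrt(dx * dx + dy * dy)
        dij = 0.5 * (diam[i] + diam[j])
        if not conn[k] and r >= dij:
            continue
        delta = 1.0 - r / dij
        energy += 0.5 * eps * delta * delta
    for k in range(spring_idx.shape[0]):
        i = spring_idx[k]
        dx = pos[i, 0] - spring_anchor[k, 0]
        dy = pos[i, 1] - spring_anchor[k, 1]
        energy += 0.5 * k_eff * (dx * dx + dy * dy)
    return energy


@njit(cache=True, fastmath=True)
def fire_minimize(pos, diam, pi, pj, conn, Lx, Ly, eps,
                  spring_idx, spring_anchor, k_eff,
                  dt0, dt_max, ftol, max_iter, max_disp):
    """FIRE energy minimization (in place).

    Standard FIRE parameters (alpha0=0.1, f_inc=1.1, f_dec=0.5, N_min=5).
    Returns (n_iter, max_force, status) with status 0 = converged
    (max net force < ftol), 1 = a particle moved more than ``max_disp``
    since entry so the caller must rebuild the candidate pair list
    (Verlet-skin criterion), 2 = iteration budget exhausted.
    """
    n = pos.shape[0]
    pos0 = pos.copy()
    max_disp2 = max_disp * max_disp
    vel = np.zeros((n, 2))
    forces = np.zeros((n, 2))
    dt = dt0
    alpha = 0.1
    n_pos = 0
    compute_forces(pos, diam, pi, pj, conn, Lx, Ly, eps,
                   spring_idx, spring_anchor, k_eff, forces)
    it = 0
    while it < max_iter:
        it += 1
        # velocity Verlet half-kick + drift
        moved = False
        for a in range(n):
            vel[a, 0] += 0.5 * dt * forces[a, 0]
            vel[a, 1] += 0.5 * dt * forces[a, 1]
            pos[a, 0] += dt * vel[a, 0]
            pos[a, 1] += dt * vel[a, 1]
            ddx = pos[a, 0] - pos0[a, 0]
            ddy = pos[a, 1] - pos0[a, 1]
            if ddx * ddx + ddy * ddy > max_disp2:
                moved = True
        compute_forces(pos, diam, pi, pj, conn, Lx, Ly, eps,
                       spring_idx, spring_anchor, k_eff, forces)
        fmax = 0.0
        power = 0.0
        vnorm = 0.0
        fnorm = 0.0
        for a in range(n):
            vel[a, 0] += 0.5 * dt * forces[a, 0]
            vel[a, 1] += 0.5 * dt * forces[a, 1]
            power += vel[a, 0] * forces[a, 0] + vel[a, 1] * forces[a, 1]
            vnorm += vel[a, 0] * vel[a, 0] + vel[a, 1] * vel[a, 1]
            fnorm += forces[a, 0] * forces[a, 0] + forces[a, 1] * forces[a, 1]
            fm = np.sqrt(forces[a, 0] ** 2 + forces[a, 1] ** 2)
            if fm > fmax:
                fmax = fm
        if moved:
            return it, fmax, 1
        if fmax < ftol:
            return it, fmax, 0
        if power > 0.0:
            n_pos += 1
            scale = 0.0
            if fnorm > 0.0:
                scale = np.sqrt(vnorm / fnorm)
            for a in range(n):
                vel[a, 0] = (1.0 - alpha) * vel[a, 0] + alpha * scale * forces[a, 0]
                vel[a, 1] = (1.0 - alpha) * vel[a, 1] + alpha * scale * forces[a, 1]
            if n_pos > 5:
                dt = min(dt * 1.1, dt_max)
                alpha *= 0.99
        else:
            n_pos = 0
            dt *= 0.5
            alpha = 0.1
            for a in range(n):
                vel[a, 0] = 0.0
                vel[a, 1] = 0.0
    compute_forces(pos, diam, pi, pj, conn, Lx, Ly, eps,
                   spring_idx, spring_anchor, k_eff, forces)
    fmax = 0.0
    for a in range(n):
        fm = np.sqrt(forces[a, 0] ** 2 + forces[a, 1] ** 2)
        if fm > fmax:
            fmax = fm
    return max_iter, fmax, 2


@njit(cache=True, fastmath=True)
def _add_dissipative(pos, vel, diam, pi, pj, conn, Lx, Ly, b_damp, drag, forces):
    """Pairwise damping -b (v_ij . r_hat) r_hat within interaction range + global drag."""
    n = pos.shape[0]
    for k in range(pi.shape[0]):
        i = pi[k]
        j = pj[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dx -= Lx * np.rint(dx / Lx)
        dy -= Ly * np.rint(dy / Ly)
        r = np.sqrt(dx * dx + dy * dy)
        dij = 0.5 * (diam[i] + diam[j])
        if not conn[k] and r >= dij:
            continue
        if r <= 0.0:
            continue
        vx = vel[i, 0] - vel[j, 0]
        vy = vel[i, 1] - vel[j, 1]
        vr = (vx * dx + vy * dy) / r
        fx = -b_damp * vr * dx / r
        fy = -b_damp * vr * dy / r
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[j, 0] -= fx
        forces[j, 1] -= fy
    for a in range(n):
        forces[a, 0] -= drag * vel[a, 0]
        forces[a, 1] -= drag * vel[a, 1]


@njit(cache=True, fastmath=True)
def damped_verlet_minimize(pos, diam, pi, pj, conn, Lx, Ly, eps,
                           spring_idx, spring_anchor, k_eff,
                           dt, b_damp, drag, energy_tol, window, max_iter,
                           max_disp):
    """Damped velocity-Verlet relaxation (in place).

    Stops when the relative potential-energy change over ``window`` steps
    falls below ``energy_tol``.  Returns (n_iter, final_energy, status):
    0 = converged, 1 = pair list invalidated (a particle moved more than
    ``max_disp``), 2 = iteration budget exhausted.
    """
    n = pos.shape[0]
    pos0 = pos.copy()
    max_disp2 = max_disp * max_disp
    vel = np.zeros((n, 2))
    forces = np.zeros((n, 2))
    e_prev = compute_forces(pos, diam, pi, pj, conn, Lx, Ly, eps,
                            spring_idx, spring_anchor, k_eff, forces)
    _add_dissipative(pos, vel, diam, pi, pj, conn, Lx, Ly, b_damp, drag, forces)
    it = 0
    energy = e_prev
    while it < max_iter:
        for _ in range(window):
            it += 1
            moved = False
            for a in range(n):
                vel[a, 0] += 0.5 * dt * forces[a, 0]
                vel[a, 1] += 0.5 * dt * forces[a, 1]
                pos[a, 0] += dt * vel[a, 0]
                pos[a, 1] += dt * vel[a, 1]
                ddx = pos[a, 0] - pos0[a, 0]
                ddy = pos[a, 1] - pos0[a, 1]
                if ddx * ddx + ddy * ddy > max_disp2:
                    moved = True
            energy = compute_forces(pos, diam, pi, pj, conn, Lx, Ly, eps,
                                    spring_idx, spring_anchor, k_eff, forces)
            _add_dissipative(pos, vel, diam, pi, pj, conn, Lx, Ly,
                             b_damp, drag, forces)
            for a in range(n):
                vel[a, 0] += 0.5 * dt * forces[a, 0]
                vel[a, 1] += 0.5 * dt * forces[a, 1]
            if moved:
                return it, energy, 1
        denom = abs(energy)
        if denom < 1e-12:
            denom = 1e-12
        if abs(energy - e_prev) / denom < energy_tol:
            return it, energy, 0
        e_prev = energy
    return it, energy, 2


@njit(cache=True, fastmath=True)
def stress_sums(pos, diam, pi, pj, conn, Lx, Ly, eps):
    """Per-particle triggering stress and virial stress tensor.

    Returns (sigma, S) where sigma[i] = -eps^-1 sum_j d_ij f_ij (positive
    under net tension) and S[i] = (Sxx, Syy, Sxy) with
    S_ab(i) = -(1/2 eps) sum_j r_ij,a f_ij,b.
    """
    n = pos.shape[0]
    sigma = np.zeros(n)
    S = np.zeros((n, 3))
    for k in range(pi.shape[0]):
        i = pi[k]
        j = pj[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dx -= Lx * np.rint(dx / Lx)
        dy -= Ly * np.rint(dy / Ly)
        r = np.sqrt(dx * dx + dy * dy)
        dij = 0.5 * (diam[i] + diam[j])
        if not conn[k] and r >= dij:
            continue
        if r <= 0.0:
            continue
        f = (eps / dij) * (1.0 - r / dij)
        sigma[i] -= dij * f / eps
        sigma[j] -= dij * f / eps
        # force vector on i: f * r_hat; r_ij = r_i - r_j
        c = -0.5 * f / (eps * r)
        S[i, 0] += c * dx * dx
        S[i, 1] += c * dy * dy
        S[i, 2] += c * dx * dy
        # for j: r_ji = -r_ij and f_ji = -f_ij, product unchanged
        S[j, 0] += c * dx * dx
        S[j, 1] += c * dy * dy
        S[j, 2] += c * dx * dy
    return sigma, S


@njit(cache=True)
def tessellate_labels(px, py, pos, Dxx, Dyy, Dxy, Lx, Ly, sqrt_form):
    """Assign each grid point to the particle minimizing the weighted distance.

    rho_bar = rho / (rho_hat . D . rho_hat)            (division form)
    rho_bar = rho / sqrt(rho_hat . D . rho_hat)        (sqrt form)

    Ties broken by lowest particle index; a point exactly on a particle
    center gets that particle.  Labels are 1-based (0 = unassigned).
    """
    npt = px.shape[0]
    n = pos.shape[0]
    labels = np.zeros(npt, dtype=np.int32)
    for q in range(npt):
        best = 1e300
        ibest = -1
        for i in range(n):
            dx = px[q] - pos[i, 0]
            dy = py[q] - pos[i, 1]
            dx -= Lx * np.rint(dx / Lx)
            dy -= Ly * np.rint(dy / Ly)
            rho2 = dx * dx + dy * dy
            if rho2 <= 0.0:
                best = 0.0
                ibest = i
                break
            rho = np.sqrt(rho2)
            ux = dx / rho
            uy = dy / rho
            ext = Dxx[i] * ux * ux + Dyy[i] * uy * uy + 2.0 * Dxy[i] * ux * uy
            if sqrt_form:
                w = rho / np.sqrt(ext)
            else:
                w = rho / ext
            if w < best - 1e-12:
                best = w
                ibest = i
        labels[q] = ibest + 1
    return labels
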