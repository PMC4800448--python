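"""Compiled inner loops for the Metropolis chain.

The chain kernel mutates the ion position array in place and keeps the total
electrostatic energy (in k_B T at the target temperature) incrementally
updated; the coupling parameter ``lam`` = beta/beta_T in [0, 1] scales only
the electrostatic energy in the acceptance rule while hard cores are enforced
at every lam, so the lam = 0 reference is the hard-sphere fluid.

Positions are kept wrapped in the primary cell centred on the origin, so any
coordinate difference lies in (-L, L) and the minimum image reduces to a
single comparison per axis.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(inline="always")
def _mi(d, l, half):
    if d > half:
        return d - l
    if d < -half:
        return d + l
    return d


@njit(cache=True, fastmath=True)
def _delta_and_overlap(pos, q, rad, centers, np_charge, np_radius,
                       lx, ly, lz, lb, i, nx, ny, nz):
    """Energy change for moving ion i to (nx, ny, nz); (du, overlap flag)."""
    n = pos.shape[0]
    m = centers.shape[0]
    hx, hy, hz = 0.5 * lx, 0.5 * ly, 0.5 * lz
    qi = q[i]
    ri = rad[i]
    ox, oy, oz = pos[i, 0], pos[i, 1], pos[i, 2]
    du = 0.0
    for k in range(m):
        cx, cy, cz = centers[k, 0], centers[k, 1], centers[k, 2]
        dx = _mi(nx - cx, lx, hx)
        dy = _mi(ny - cy, ly, hy)
        dz = _mi(nz - cz, lz, hz)
        r2n = dx * dx + dy * dy + dz * dz
        sig = np_radius + ri
        if r2n < sig * sig:
            return 0.0, True
        dx = _mi(ox - cx, lx, hx)
        dy = _mi(oy - cy, ly, hy)
        dz = _mi(oz - cz, lz, hz)
        r2o = dx * dx + dy * dy + dz * dz
        du += qi * np_charge * lb * (1.0 / np.sqrt(r2n) - 1.0 / np.sqrt(r2o))
    for j in range(n):
        if j == i:
            continue
        px, py, pz = pos[j, 0], pos[j, 1], pos[j, 2]
        dx = _mi(nx - px, lx, hx)
        dy = _mi(ny - py, ly, hy)
        dz = _mi(nz - pz, lz, hz)
        r2n = dx * dx + dy * dy + dz * dz
        sig = ri + rad[j]
        if r2n < sig * sig:
            return 0.0, True
        dx = _mi(ox - px, lx, hx)
        dy = _mi(oy - py, ly, hy)
        dz = _mi(oz - pz, lz, hz)
        r2o = dx * dx + dy * dy + dz * dz
        du += qi * q[j] * lb * (1.0 / np.sqrt(r2n) - 1.0 / np.sqrt(r2o))
    return du, False


@njit(inline="always")
def _balls_containing(centers, lx, ly, lz, hx, hy, hz, x, y, z, r2):
    cnt = 0
    for k in range(centers.shape[0]):
        dx = _mi(x - centers[k, 0], lx, hx)
        dy = _mi(y - centers[k, 1], ly, hy)
        dz = _mi(z - centers[k, 2], lz, hz)
        if dx * dx + dy * dy + dz * dz <= r2:
            cnt += 1
    return cnt


@njit(cache=True, fastmath=True)
def run_chain(pos, q, rad, centers, np_charge, np_radius, lengths, lb, lam,
              disp, nsteps, seed, u_start, lattice, kmax, jump_prob,
              target_prob, target_radius):
    """Run ``nsteps`` single-ion Metropolis moves.

    Proposals are uniform in a cube of half-width ``disp`` (or, when
    ``lattice`` > 0, integer multiples of the lattice spacing up to ``kmax``
    per axis, which keeps a lattice toy on its sites).  With probability
    ``jump_prob`` the proposal is instead a uniform relocation anywhere in
    the cell -- a symmetric move that decorrelates the chain quickly at low
    coupling, where local moves diffuse slowly.  With probability
    ``target_prob`` the proposal is uniform inside a ball of radius
    ``target_radius`` around a uniformly chosen nanoparticle; this move is
    asymmetric and carries the exact Metropolis-Hastings proposal-density
    ratio, making counterion binding and unbinding fast in dilute boxes.
    Overlapping proposals are rejected outright.

    Returns (final energy, accepted count, sum of the energy over all steps).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    m = centers.shape[0]
    lx, ly, lz = lengths[0], lengths[1], lengths[2]
    hx, hy, hz = 0.5 * lx, 0.5 * ly, 0.5 * lz
    vcell = lx * ly * lz
    r2t = target_radius * target_radius
    vball = 4.18879020478639098 * target_radius * r2t  # (4/3) pi R^3
    p_local = 1.0 - jump_prob - target_prob
    u = u_start
    usum = 0.0
    nacc = 0
    for _ in range(nsteps):
        i = np.random.randint(0, n)
        if lattice > 0.0:
            nx = pos[i, 0] + lattice * np.random.randint(-kmax, kmax + 1)
            ny = pos[i, 1] + lattice * np.random.randint(-kmax, kmax + 1)
            nz = pos[i, 2] + lattice * np.random.randint(-kmax, kmax + 1)
        else:
            sel = np.random.random()
            if jump_prob > 0.0 and sel < jump_prob:
                nx = lx * (np.random.random() - 0.5)
                ny = ly * (np.random.random() - 0.5)
                nz = lz * (np.random.random() - 0.5)
            elif target_prob > 0.0 and sel < jump_prob + target_prob:
                # uniform point in a ball around a uniformly chosen centre
                k = np.random.randint(0, m)
                while True:
                    ex = 2.0 * np.random.random() - 1.0
                    ey = 2.0 * np.random.random() - 1.0
                    ez = 2.0 * np.random.random() - 1.0
                    if ex * ex + ey * ey + ez * ez <= 1.0:
                        break
                nx = centers[k, 0] + target_radius * ex
                ny = centers[k, 1] + target_radius * ey
                nz = centers[k, 2] + target_radius * ez
            else:
                nx = pos[i, 0] + disp * (2.0 * np.random.random() - 1.0)
                ny = pos[i, 1] + disp * (2.0 * np.random.random() - 1.0)
                nz = pos[i, 2] + disp * (2.0 * np.random.random() - 1.0)
        # wrap into the primary cell centred on the origin
        nx -= lx * np.floor(nx / lx + 0.5)
        ny -= ly * np.floor(ny / ly + 0.5)
        nz -= lz * np.floor(nz / lz + 0.5)
        du, overlap = _delta_and_overlap(pos, q, rad, centers, np_charge,
                                         np_radius, lx, ly, lz, lb, i,
                                         nx, ny, nz)
        if not overlap:
            if lattice > 0.0 or target_prob <= 0.0:
                ratio = 1.0
            else:
                # proposal-density ratio q(new->old)/q(old->new); the local
                # and jump components are symmetric and the targeted one is
                # proportional to the number of balls containing the point
                ox, oy, oz = pos[i, 0], pos[i, 1], pos[i, 2]
                in_old = _balls_containing(centers, lx, ly, lz, hx, hy, hz,
                                           ox, oy, oz, r2t)
                in_new = _balls_containing(centers, lx, ly, lz, hx, hy, hz,
                                           nx, ny, nz, r2t)
                dx = _mi(nx - ox, lx, hx)
                dy = _mi(ny - oy, ly, hy)
                dz = _mi(nz - oz, lz, hz)
                loc = 0.0
                if (abs(dx) <= disp and abs(dy) <= disp and abs(dz) <= disp):
                    loc = p_local / (8.0 * disp * disp * disp)
                base = jump_prob / vcell + loc
                q_fwd = base + target_prob * in_new / (m * vball)
                q_rev = base + target_prob * in_old / (m * vball)
                ratio = q_rev / q_fwd
            arg = ratio * np.exp(min(-lam * du, 50.0))
            if arg >= 1.0 or np.random.random() < arg:
                pos[i, 0] = nx
                pos[i, 1] = ny
                pos[i, 2] = nz
                u += du
                nacc += 1
        usum += u
    return u, nacc, usum
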