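"""Compiled inner loop for Gō-model Monte Carlo.

The Metropolis sweep over CA beads is the hot path of the whole pipeline;
this module holds a numba-jitted kernel operating on the model's packed
neighbour tables.  All randomness is pre-drawn from the caller's numpy
Generator, so trajectories are bit-reproducible for a fixed seed and do not
depend on numba's own RNG state.

Move set (matching the driver contract): single-bead Gaussian displacement
or two-bead crankshaft rotation about the axis through the flanking beads,
chosen 50/50.  Energy deltas are evaluated locally: only pair terms touching
the moved beads and the (at most five) virtual dihedrals containing them.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["go_sweeps"]


@njit(cache=True, fastmath=False)
def _local_energy(
    b0, b1, coords,
    nbr_ptr, nbr_other, nbr_kind, nbr_r0, nbr_sig2,
    bond_k, eps, rep_eps, dih_k, phi0,
):
    """Pair + dihedral energy touching beads b0 (and b1 if >= 0)."""
    e = 0.0
    n = coords.shape[0]
    for t in range(2):
        b = b0 if t == 0 else b1
        if b < 0:
            continue
        x, y, z = coords[b, 0], coords[b, 1], coords[b, 2]
        for p in range(nbr_ptr[b], nbr_ptr[b + 1]):
            o = nbr_other[p]
            if t == 1 and o == b0:
                continue  # pair inside the moved set, already counted
            dx = coords[o, 0] - x
            dy = coords[o, 1] - y
            dz = coords[o, 2] - z
            r2 = dx * dx + dy * dy + dz * dz
            k = nbr_kind[p]
            if k == 0:  # bond
                r = math.sqrt(r2)
                dr = r - nbr_r0[p]
                e += bond_k * dr * dr
            elif k == 1:  # native-contact 12-10 well
                q2 = nbr_r0[p] * nbr_r0[p] / r2
                q6 = q2 * q2 * q2
                e += eps * (q6 * q2 * q2 * (5.0 * q2 - 6.0))
            else:  # soft-sphere repulsion, truncated/shifted at sigma
                s2 = nbr_sig2[p]
                if r2 < s2:
                    q12 = (s2 / r2) ** 6
                    e += rep_eps * (q12 - 1.0)
    if dih_k != 0.0 and n >= 4:
        hi_bead = b1 if b1 >= 0 else b0
        lo = b0 - 3
        if lo < 0:
            lo = 0
        hi = hi_bead
        if hi > n - 4:
            hi = n - 4
        for d in range(lo, hi + 1):
            # dihedral over beads d, d+1, d+2, d+3
            b1x = coords[d + 1, 0] - coords[d, 0]
            b1y = coords[d + 1, 1] - coords[d, 1]
            b1z = coords[d + 1, 2] - coords[d, 2]
            b2x = coords[d + 2, 0] - coords[d + 1, 0]
            b2y = coords[d + 2, 1] - coords[d + 1, 1]
            b2z = coords[d + 2, 2] - coords[d + 1, 2]
            b3x = coords[d + 3, 0] - coords[d + 2, 0]
            b3y = coords[d + 3, 1] - coords[d + 2, 1]
            b3z = coords[d + 3, 2] - coords[d + 2, 2]
            n1x = b1y * b2z - b1z * b2y
            n1y = b1z * b2x - b1x * b2z
            n1z = b1x * b2y - b1y * b2x
            n2x = b2y * b3z - b2z * b3y
            n2y = b2z * b3x - b2x * b3z
            n2z = b2x * b3y - b2y * b3x
            b2n = math.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
            if b2n < 1e-12:
                continue
            mx = (n1y * b2z - n1z * b2y) / b2n
            my = (n1z * b2x - n1x * b2z) / b2n
            mz = (n1x * b2y - n1y * b2x) / b2n
            xx = n1x * n2x + n1y * n2y + n1z * n2z
            yy = mx * n2x + my * n2y + mz * n2z
            phi = math.atan2(yy, xx)
            e += dih_k * (1.0 - math.cos(phi - phi0[d]))
    return e


@njit(cache=True, fastmath=False)
def go_sweeps(
    coords, energy, beta, amp, crank,
    u_rand, g_rand,
    nbr_ptr, nbr_other, nbr_kind, nbr_r0, nbr_sig2,
    bond_k, eps, rep_eps, dih_k, phi0,
):
    """Run len(u_rand) Metropolis moves in place; returns updated energy.

    ``u_rand`` has shape (n_moves, 3): move-type, site and acceptance
    uniforms; ``g_rand`` has shape (n_moves, 4): displacement normals and
    crankshaft angle normal.
    """
    n = coords.shape[0]
    n_moves = u_rand.shape[0]
    old = np.empty((2, 3))
    for m in range(n_moves):
        if u_rand[m, 0] < 0.5 or n < 4:
            b0 = int(u_rand[m, 1] * n)
            if b0 >= n:
                b0 = n - 1
            b1 = -1
            e_old = _local_energy(
                b0, b1, coords, nbr_ptr, nbr_other, nbr_kind, nbr_r0,
                nbr_sig2, bond_k, eps, rep_eps, dih_k, phi0,
            )
            for c in range(3):
                old[0, c] = coords[b0, c]
                coords[b0, c] += amp * g_rand[m, c]
        else:
            k = 1 + int(u_rand[m, 1] * (n - 3))
            if k > n - 3:
                k = n - 3
            b0, b1 = k, k + 1
            e_old = _local_energy(
                b0, b1, coords, nbr_ptr, nbr_other, nbr_kind, nbr_r0,
                nbr_sig2, bond_k, eps, rep_eps, dih_k, phi0,
            )
            ax = coords[k + 2, 0] - coords[k - 1, 0]
            ay = coords[k + 2, 1] - coords[k - 1, 1]
            az = coords[k + 2, 2] - coords[k - 1, 2]
            norm = math.sqrt(ax * ax + ay * ay + az * az)
            if norm < 1e-9:
                continue
            ax /= norm; ay /= norm; az /= norm
            theta = crank * g_rand[m, 3]
            ct = math.cos(theta)
            st = math.sin(theta)
            for t in range(2):
                b = b0 if t == 0 else b1
                px = coords[b, 0] - coords[k - 1, 0]
                py = coords[b, 1] - coords[k - 1, 1]
                pz = coords[b, 2] - coords[k - 1, 2]
                dot = px * ax + py * ay + pz * az
                cx = ay * pz - az * py
                cy = az * px - ax * pz
                cz = ax * py - ay * px
                old[t, 0] = coords[b, 0]
                old[t, 1] = coords[b, 1]
                old[t, 2] = coords[b, 2]
                coords[b, 0] = coords[k - 1, 0] + px * ct + cx * st + ax * dot * (1.0 - ct)
                coords[b, 1] = coords[k - 1, 1] + py * ct + cy * st + ay * dot * (1.0 - ct)
                coords[b, 2] = coords[k - 1, 2] + pz * ct + cz * st + az * dot * (1.0 - ct)
        e_new = _local_energy(
            b0, b1, coords, nbr_ptr, nbr_other, nbr_kind, nbr_r0,
            nbr_sig2, bond_k, eps, rep_eps, dih_k, phi0,
        )
        de = e_new - e_old
        if de <= 0.0 or u_rand[m, 2] < math.exp(-beta * de):
            energy += de
        else:
            coords[b0, 0] = old[0, 0]
            coords[b0, 1] = old[0, 1]
            coords[b0, 2] = old[0, 2]
            if b1 >= 0:
                coords[b1, 0] = old[1, 0]
                coords[b1, 1] = old[1, 1]
                coords[b1, 2] = old[1, 2]
    return energy
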