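"""Numba kernel for hard-sphere chain generation.

Builds each trial chain atom by atom and rejects it at the first contact-limit
violation, which makes whole-chain rejection sampling tractable for long
chains (the expected cost of a rejected draw is proportional to the position
of its first clash, not to the full pair count). Produces exactly the same
accept/reject decisions and coordinates as the vectorized numpy path in
:mod:`dsekit.ensemble`; a regression test cross-checks the two.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["chain_batch"]


@njit(cache=True, fastmath=True)
def _place_one(ax, ay, az, bx, by, bz, cx, cy, cz, bond, ang, tor):
    bcx, bcy, bcz = cx - bx, cy - by, cz - bz
    inv = 1.0 / math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx *= inv; bcy *= inv; bcz *= inv
    abx, aby, abz = bx - ax, by - ay, bz - az
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    inv = 1.0 / math.sqrt(nx * nx + ny * ny + nz * nz)
    nx *= inv; ny *= inv; nz *= inv
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    ca_, sa_ = math.cos(ang), math.sin(ang)
    ct, st = math.cos(tor), math.sin(tor)
    dx = -ca_ * bcx + sa_ * (ct * mx + st * nx)
    dy = -ca_ * bcy + sa_ * (ct * my + st * ny)
    dz = -ca_ * bcz + sa_ * (ct * mz + st * nz)
    return cx + bond * dx, cy + bond * dy, cz + bond * dz


@njit(cache=True, fastmath=True)
def _check(coords, k, limits_row):
    """True while atom k keeps the chain clash-free against atoms < k."""
    for j in range(k):
        lim = limits_row[j]
        if lim > 0.0:
            dx = coords[k, 0] - coords[j, 0]
            dy = coords[k, 1] - coords[j, 1]
            dz = coords[k, 2] - coords[j, 2]
            if dx * dx + dy * dy + dz * dz < lim * lim:
                return False
    return True


@njit(cache=True, fastmath=True)
def chain_batch(phi, psi, omega, limits,
                n_idx, ca_idx, c_idx, o_idx, cb_idx, ha_idx, h_idx,
                bonds, angles, torsions, coords_out, ok_out, l_out):
    """Build and score a batch of chains.

    phi/psi/omega: (B, N) degrees. limits: (n_atoms, n_atoms) contact limits
    with 0 marking unscored pairs. ``*_idx``: per-residue atom row indices
    (-1 when the atom does not exist). bonds/angles/torsions: packed geometry
    (n_ca, ca_c, c_n, c_o, ca_cb, n_h, ca_ha), (ang_n_ca_c, ang_ca_c_n,
    ang_c_n_ca, ang_ca_c_o, ang_n_ca_cb, ang_c_n_h, ang_n_ca_ha) in radians,
    (tor_cb, tor_ha) in radians. Fills ok_out (accept flag), l_out (max CA-CA
    distance, only valid when accepted) and coords_out ((n_atoms, 3) scratch,
    holding the last accepted chain's coordinates).
    """
    b, n = phi.shape
    d2r = math.pi / 180.0
    b_nca, b_cac, b_cn, b_co, b_cacb, b_nh, b_caha = bonds
    a_ncac, a_cacn, a_cnca, a_caco, a_ncacb, a_cnh, a_ncaha = angles
    t_cb, t_ha = torsions
    for s in range(b):
        ok = True
        # residue 0
        coords_out[n_idx[0], 0] = 0.0
        coords_out[n_idx[0], 1] = 0.0
        coords_out[n_idx[0], 2] = 0.0
        coords_out[ca_idx[0], 0] = b_nca
        coords_out[ca_idx[0], 1] = 0.0
        coords_out[ca_idx[0], 2] = 0.0
        coords_out[c_idx[0], 0] = b_nca - b_cac * math.cos(a_ncac)
        coords_out[c_idx[0], 1] = b_cac * math.sin(a_ncac)
        coords_out[c_idx[0], 2] = 0.0
        for i in range(n):
            if i > 0:
                # backbone N, CA, C
                x, y, z = _place_one(
                    coords_out[n_idx[i - 1], 0], coords_out[n_idx[i - 1], 1],
                    coords_out[n_idx[i - 1], 2],
                    coords_out[ca_idx[i - 1], 0], coords_out[ca_idx[i - 1], 1],
                    coords_out[ca_idx[i - 1], 2],
                    coords_out[c_idx[i - 1], 0], coords_out[c_idx[i - 1], 1],
                    coords_out[c_idx[i - 1], 2],
                    b_cn, a_cacn, psi[s, i - 1] * d2r)
                k = n_idx[i]
                coords_out[k, 0], coords_out[k, 1], coords_out[k, 2] = x, y, z
                if not _check(coords_out, k, limits[k]):
                    ok = False
                    break
                x, y, z = _place_one(
                    coords_out[ca_idx[i - 1], 0], coords_out[ca_idx[i - 1], 1],
                    coords_out[ca_idx[i - 1], 2],
                    coords_out[c_idx[i - 1], 0], coords_out[c_idx[i - 1], 1],
                    coords_out[c_idx[i - 1], 2],
                    coords_out[n_idx[i], 0], coords_out[n_idx[i], 1],
                    coords_out[n_idx[i], 2],
                    b_nca, a_cnca, omega[s, i] * d2r)
                k = ca_idx[i]
                coords_out[k, 0], coords_out[k, 1], coords_out[k, 2] = x, y, z
                if not _check(coords_out, k, limits[k]):
                    ok = False
                    break
                x, y, z = _place_one(
                    coords_out[c_idx[i - 1], 0], coords_out[c_idx[i - 1], 1],
                    coords_out[c_idx[i - 1], 2],
                    coords_out[n_idx[i], 0], coords_out[n_idx[i], 1],
                    coords_out[n_idx[i], 2],
                    coords_out[ca_idx[i], 0], coords_out[ca_idx[i], 1],
                    coords_out[ca_idx[i], 2],
                    b_cac, a_ncac, phi[s, i] * d2r)
                k = c_idx[i]
                coords_out[k, 0], coords_out[k, 1], coords_out[k, 2] = x, y, z
                if not _check(coords_out, k, limits[k]):
                    ok = False
                    break
            # carbonyl O
            x, y, z = _place_one(
                coords_out[n_idx[i], 0], coords_out[n_idx[i], 1],
                coords_out[n_idx[i], 2],
                coords_out[ca_idx[i], 0], coords_out[ca_idx[i], 1],
                coords_out[ca_idx[i], 2],
                coords_out[c_idx[i], 0], coords_out[c_idx[i], 1],
                coords_out[c_idx[i], 2],
                b_co, a_caco, (psi[s, i] + 180.0) * d2r)
            k = o_idx[i]
            coords_out[k, 0], coords_out[k, 1], coords_out[k, 2] = x, y, z
            if not _check(coords_out, k, limits[k]):
                ok = False
                break
            # CB
            if cb_idx[i] >= 0:
                x, y, z = _place_one(
                    coords_out[c_idx[i], 0], coords_out[c_idx[i], 1],
                    coords_out[c_idx[i], 2],
                    coords_out[n_idx[i], 0], coords_out[n_idx[i], 1],
                    coords_out[n_idx[i], 2],
                    coords_out[ca_idx[i], 0], coords_out[ca_idx[i], 1],
                    coords_out[ca_idx[i], 2],
                    b_cacb, a_ncacb, t_cb)
                k = cb_idx[i]
                coords_out[k, 0], coords_out[k, 1], coords_out[k, 2] = x, y, z
                if not _check(coords_out, k, limits[k]):
                    ok = False
                    break
            # HA
            x, y, z = _place_one(
                coords_out[c_idx[i], 0], coords_out[c_idx[i], 1],
                coords_out[c_idx[i], 2],
                coords_out[n_idx[i], 0], coords_out[n_idx[i], 1],
                coords_out[n_idx[i], 2],
                coords_out[ca_idx[i], 0], coords_out[ca_idx[i], 1],
                coords_out[ca_idx[i], 2],
                b_caha, a_ncaha, t_ha)
            k = ha_idx[i]
            coords_out[k, 0], coords_out[k, 1], coords_out[k, 2] = x, y, z
            if not _check(coords_out, k, limits[k]):
                ok = False
                break
            # amide H
            if h_idx[i] >= 0:
                x, y, z = _place_one(
                    coords_out[o_idx[i - 1], 0], coords_out[o_idx[i - 1], 1],
                    coords_out[o_idx[i - 1], 2],
                    coords_out[c_idx[i - 1], 0], coords_out[c_idx[i - 1], 1],
                    coords_out[c_idx[i - 1], 2],
                    coords_out[n_idx[i], 0], coords_out[n_idx[i], 1],
                    coords_out[n_idx[i], 2],
                    b_nh, a_cnh, math.pi)
                k = h_idx[i]
                coords_out[k, 0], coords_out[k, 1], coords_out[k, 2] = x, y, z
                if not _check(coords_out, k, limits[k]):
                    ok = False
                    break
        ok_out[s] = ok
        if ok:
            lmax = 0.0
            for p in range(n):
                for q in range(p + 1, n):
                    dx = coords_out[ca_idx[p], 0] - coords_out[ca_idx[q], 0]
                    dy = coords_out[ca_idx[p], 1] - coords_out[ca_idx[q], 1]
                    dz = coords_out[ca_idx[p], 2] - coords_out[ca_idx[q], 2]
                    d2 = dx * dx + dy * dy + dz * dz
                    if d2 > lmax:
                        lmax = d2
            l_out[s] = math.sqrt(lmax)
        else:
            l_out[s] = 0.0
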