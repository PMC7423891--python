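"""Numba kernels: hashed cell-list pair search and pairwise forces.

Particle codes: 0 = steric bead; 1..6 = attractive sites
(1 alpha-top, 2 beta-bottom, 3 beta-top, 4 alpha-bottom, 5 lateral-left,
6 lateral-right).  Pair kinds: 0 = WCA bead-bead, 1 = intra-dimer vertical,
2 = inter-dimer vertical, 3 = lateral.  Particles of the same subunit never
interact (rigid bodies).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# pair kind from unordered site-type pair; -1 = no interaction
_SITE_KIND = -np.ones((7, 7), dtype=np.int8)
_SITE_KIND[1, 2] = _SITE_KIND[2, 1] = 1
_SITE_KIND[3, 4] = _SITE_KIND[4, 3] = 2
_SITE_KIND[5, 6] = _SITE_KIND[6, 5] = 3
SITE_KIND = _SITE_KIND


@njit(cache=True)
def build_pairs(pos, sub_id, ptype, kind_table, rlist, pi, pj, pkind):
    """Fill candidate interacting pairs within ``rlist``.

    Returns the number of pairs found; if it exceeds the capacity of the
    output arrays, filling stops but counting continues so the caller can
    reallocate (overflow is never silent).
    """
    n = pos.shape[0]
    cap = pi.shape[0]
    inv = 1.0 / rlist
    r2max = rlist * rlist

    cix = np.empty(n, np.int64)
    ciy = np.empty(n, np.int64)
    ciz = np.empty(n, np.int64)
    for p in range(n):
        cix[p] = np.int64(np.floor(pos[p, 0] * inv))
        ciy[p] = np.int64(np.floor(pos[p, 1] * inv))
        ciz[p] = np.int64(np.floor(pos[p, 2] * inv))

    nbuck = 1
    while nbuck < 2 * n:
        nbuck *= 2
    mask = nbuck - 1

    counts = np.zeros(nbuck + 1, np.int64)
    buck = np.empty(n, np.int64)
    for p in range(n):
        h = (cix[p] * 73856093) ^ (ciy[p] * 19349663) ^ (ciz[p] * 83492791)
        b = h & mask
        buck[p] = b
        counts[b + 1] += 1
    for b in range(nbuck):
        counts[b + 1] += counts[b]
    order = np.empty(n, np.int64)
    fill = counts[:-1].copy()
    for p in range(n):
        b = buck[p]
        order[fill[b]] = p
        fill[b] += 1

    npairs = 0
    for i in range(n):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        si = sub_id[i]
        ti = ptype[i]
        for ox in range(-1, 2):
            cx = cix[i] + ox
            for oy in range(-1, 2):
                cy = ciy[i] + oy
                for oz in range(-1, 2):
                    cz = ciz[i] + oz
                    h = (cx * 73856093) ^ (cy * 19349663) ^ (cz * 83492791)
                    b = h & mask
                    for idx in range(counts[b], counts[b + 1]):
                        j = order[idx]
                        if j <= i:
                            continue
                        # hash collisions: confirm j really is in this cell
                        if cix[j] != cx or ciy[j] != cy or ciz[j] != cz:
                            continue
                        if sub_id[j] == si:
                            continue
                        tj = ptype[j]
                        if ti == 0:
                            if tj != 0:
                                continue
                            kind = 0
                        else:
                            if tj == 0:
                                continue
                            kind = kind_table[ti, tj]
                            if kind < 0:
                                continue
                        dx = xi - pos[j, 0]
                        dy = yi - pos[j, 1]
                        dz = zi - pos[j, 2]
                        if dx * dx + dy * dy + dz * dz > r2max:
                            continue
                        if npairs < cap:
                            pi[npairs] = i
                            pj[npairs] = j
                            pkind[npairs] = kind
                        npairs += 1
    return npairs


@njit(cache=True)
def pair_forces(pos, pi, pj, pkind, npairs, sub_id, eps, sigma, rc_site,
                a_vals, fpart, contacts):
    """Accumulate pair forces into ``fpart``; returns potential energy.

    ``a_vals`` holds the three site strengths (intra, vertical, lateral) in
    energy units.  ``contacts`` counts engaged attractive bonds per subunit
    (used by the dissociation bookkeeping).
    """
    wca_cut2 = (2.0 ** (1.0 / 6.0) * sigma) ** 2
    rc2 = rc_site * rc_site
    pi_over_rc = np.pi / rc_site
    energy = 0.0
    for k in range(npairs):
        i = pi[k]
        j = pj[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        kind = pkind[k]
        if kind == 0:
            if r2 >= wca_cut2 or r2 < 1e-24:
                continue
            s2 = sigma * sigma / r2
            s6 = s2 * s2 * s2
            s12 = s6 * s6
            energy += 4.0 * eps * (s12 - s6) + eps
            fr = 24.0 * eps * (2.0 * s12 - s6) / r2
            fx = fr * dx
            fy = fr * dy
            fz = fr * dz
        else:
            if r2 >= rc2:
                continue
            r = np.sqrt(r2)
            a = a_vals[kind - 1]
            c = np.cos(pi_over_rc * r)
            energy += -a * (1.0 + c)
            contacts[sub_id[i]] += 1
            contacts[sub_id[j]] += 1
            if r < 1e-12:
                continue
            # dU/dr = a*(pi/rc)*sin(pi r/rc) >= 0 -> attraction
            fr = -a * pi_over_rc * np.sin(pi_over_rc * r) / r
            fx = fr * dx
            fy = fr * dy
            fz = fr * dz
        fpart[i, 0] += fx
        fpart[i, 1] += fy
        fpart[i, 2] += fz
        fpart[j, 0] -= fx
        fpart[j, 1] -= fy
        fpart[j, 2] -= fz
    return energy


@njit(cache=True)
def reduce_rigid(fpart, pos, sub_id, com, fsub, tsub):
    """Sum particle forces into per-subunit force and world-frame torque."""
    n = pos.shape[0]
    for p in range(n):
        s = sub_id[p]
        fx = fpart[p, 0]
        fy = fpart[p, 1]
        fz = fpart[p, 2]
        rx = pos[p, 0] - com[s, 0]
        ry = pos[p, 1] - com[s, 1]
        rz = pos[p, 2] - com[s, 2]
        fsub[s, 0] += fx
        fsub[s, 1] += fy
        fsub[s, 2] += fz
        tsub[s, 0] += ry * fz - rz * fy
        tsub[s, 1] += rz * fx - rx * fz
        tsub[s, 2] += rx * fy - ry * fx


@njit(cache=True)
def free_rotor(quat, angmom, inertia, dt):
    """Symplectic 5-stage principal-axis splitting of free rigid rotation.

    Advances unit quaternions and body-frame angular momenta in place.
    """
    n = quat.shape[0]
    for b in range(n):
        for stage in range(5):
            if stage == 0 or stage == 4:
                k = 2
                frac = 0.5
            elif stage == 1 or stage == 3:
                k = 1
                frac = 0.5
            else:
                k = 0
                frac = 1.0
            phi = angmom[b, k] / inertia[b, k] * (dt * frac)
            half = 0.5 * phi
            c2 = np.cos(half)
            s2 = np.sin(half)
            w = quat[b, 0]
            x = quat[b, 1]
            y = quat[b, 2]
            z = quat[b, 3]
            if k == 0:
                quat[b, 0] = w * c2 - x * s2
                quat[b, 1] = w * s2 + x * c2
                quat[b, 2] = y * c2 + z * s2
                quat[b, 3] = z * c2 - y * s2
            elif k == 1:
                quat[b, 0] = w * c2 - y * s2
                quat[b, 1] = x * c2 - z * s2
                quat[b, 2] = w * s2 + y * c2
                quat[b, 3] = x * s2 + z * c2
            else:
                quat[b, 0] = w * c2 - z * s2
                quat[b, 1] = x * c2 + y * s2
                quat[b, 2] = y * c2 - x * s2
                quat[b, 3] = w * s2 + z * c2
            k1 = (k + 1) % 3
            k2 = (k + 2) % 3
            c = np.cos(phi)
            s = np.sin(phi)
            a1 = c * angmom[b, k1] + s * angmom[b, k2]
            a2 = -s * angmom[b, k1] + c * angmom[b, k2]
            angmom[b, k1] = a1
            angmom[b, k2] = a2


@njit(cache=True)
def spring_forces(pos, si, sj, r0, kspring, fpart):
    """Harmonic bonds for the stiff-spring (flexible bead) mode."""
    energy = 0.0
    for k in range(si.shape[0]):
        i = si[k]
        j = sj[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        dr = r - r0[k]
        energy += 0.5 * kspring * dr * dr
        fr = -kspring * dr / r
        fpart[i, 0] += fr * dx
        fpart[i, 1] += fr * dy
        fpart[i, 2] += fr * dz
        fpart[j, 0] -= fr * dx
        fpart[j, 1] -= fr * dy
        fpart[j, 2] -= fr * dz
    return energy
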