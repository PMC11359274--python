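"""Numba kernels for pair energies, pair histograms and packing relaxation.

All kernels work on flat per-atom arrays with integer type codes; the
per-type-pair parameter matrices (Lorentz-Berthelot mixed LJ, charge
products, empirical-potential channel ids) are precomputed by the callers.
Distances use the minimum-image convention in a cubic box of side L.
"""
from __future__ import annotations

import numpy as np
from numba import njit

COULOMB_K = 1389.3545764438293  # kJ mol^-1 A e^-2, e^2/(4 pi eps0)


@njit(cache=True, inline="always")
def _min_image_dist2(dx, dy, dz, L):
    dx -= L * np.rint(dx / L)
    dy -= L * np.rint(dy / L)
    dz -= L * np.rint(dz / L)
    return dx * dx + dy * dy + dz * dz


@njit(cache=True, fastmath=True)
def energy_subset(pos, types, mol_ids, subset, L, rc,
                  eps_ab, sig_ab, qq_ab, ljshift_ab,
                  oo_ab, oo_min, oo_k, chan_ab, ep_table, ep_dr):
    """Intermolecular energy of the atoms in ``subset`` against all atoms of
    other molecules.  Returns (lj, coulomb, constraint, empirical, min_dist)."""
    n = pos.shape[0]
    lj = 0.0
    coul = 0.0
    cons = 0.0
    epe = 0.0
    dmin2 = 1.0e30
    invL = 1.0 / L
    rc2 = rc * rc
    invrc = 1.0 / rc
    has_ep = ep_table.shape[1] > 0
    nr_ep = ep_table.shape[1]
    for a in range(subset.shape[0]):
        i = subset[a]
        mi = mol_ids[i]
        xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
        ti = types[i]
        for j in range(n):
            if mol_ids[j] == mi:
                continue
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dz = zi - pos[j, 2]
            dx -= L * np.rint(dx * invL)
            dy -= L * np.rint(dy * invL)
            dz -= L * np.rint(dz * invL)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rc2:
                continue
            if r2 < dmin2:
                dmin2 = r2
            if r2 < 0.0025:
                continue  # degenerate overlap; caller raises on dmin
            tj = types[j]
            r = np.sqrt(r2)
            eps = eps_ab[ti, tj]
            if eps > 0.0:
                sr2 = sig_ab[ti, tj] * sig_ab[ti, tj] / r2
                sr6 = sr2 * sr2 * sr2
                lj += 4.0 * eps * (sr6 * sr6 - sr6) - ljshift_ab[ti, tj]
            qq = qq_ab[ti, tj]
            if qq != 0.0:
                # shifted-force Coulomb, zero energy and force at the cutoff
                coul += COULOMB_K * qq * (1.0 / r - invrc + (r - rc) * invrc * invrc)
            if oo_ab[ti, tj] and r < oo_min:
                d = oo_min - r
                cons += 0.5 * oo_k * d * d
            if has_ep:
                c = chan_ab[ti, tj]
                if c >= 0:
                    x = r / ep_dr
                    i0 = int(x)
                    if i0 < nr_ep - 1:
                        f = x - i0
                        epe += ep_table[c, i0] * (1.0 - f) + ep_table[c, i0 + 1] * f
    return lj, coul, cons, epe, np.sqrt(dmin2)


@njit(cache=True, fastmath=True)
def energy_total(pos, types, mol_ids, L, rc,
                 eps_ab, sig_ab, qq_ab, ljshift_ab,
                 oo_ab, oo_min, oo_k, chan_ab, ep_table, ep_dr):
    """Full intermolecular energy over distinct-molecule pairs (each counted
    once).  Returns (lj, coulomb, constraint, empirical, min_dist, i, j)."""
    n = pos.shape[0]
    lj = 0.0
    coul = 0.0
    cons = 0.0
    epe = 0.0
    dmin2 = 1.0e30
    imin = -1
    jmin = -1
    invL = 1.0 / L
    rc2 = rc * rc
    invrc = 1.0 / rc
    has_ep = ep_table.shape[1] > 0
    nr_ep = ep_table.shape[1]
    for i in range(n - 1):
        mi = mol_ids[i]
        xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
        ti = types[i]
        for j in range(i + 1, n):
            if mol_ids[j] == mi:
                continue
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dz = zi - pos[j, 2]
            dx -= L * np.rint(dx * invL)
            dy -= L * np.rint(dy * invL)
            dz -= L * np.rint(dz * invL)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rc2:
                continue
            if r2 < dmin2:
                dmin2 = r2
                imin = i
                jmin = j
            if r2 < 0.0025:
                continue  # degenerate overlap; caller raises on dmin
            tj = types[j]
            r = np.sqrt(r2)
            eps = eps_ab[ti, tj]
            if eps > 0.0:
                sr2 = sig_ab[ti, tj] * sig_ab[ti, tj] / r2
                sr6 = sr2 * sr2 * sr2
                lj += 4.0 * eps * (sr6 * sr6 - sr6) - ljshift_ab[ti, tj]
            qq = qq_ab[ti, tj]
            if qq != 0.0:
                coul += COULOMB_K * qq * (1.0 / r - invrc + (r - rc) * invrc * invrc)
            if oo_ab[ti, tj] and r < oo_min:
                d = oo_min - r
                cons += 0.5 * oo_k * d * d
            if has_ep:
                c = chan_ab[ti, tj]
                if c >= 0:
                    x = r / ep_dr
                    i0 = int(x)
                    if i0 < nr_ep - 1:
                        f = x - i0
                        epe += ep_table[c, i0] * (1.0 - f) + ep_table[c, i0 + 1] * f
    return lj, coul, cons, epe, np.sqrt(dmin2), imin, jmin


@njit(cache=True)
def pair_histogram(pos, types, mol_ids, chan_ab, L, dr, nbins, nchan, intra):
    """Per-channel pair-distance histograms (each unordered pair counted once).

    ``intra`` selects intramolecular (1) or intermolecular (0) pairs.
    ``chan_ab`` maps a type pair to its channel id (symmetric, -1 to skip).
    """
    n = pos.shape[0]
    counts = np.zeros((nchan, nbins), dtype=np.int64)
    rmax2 = (dr * nbins) ** 2
    for i in range(n - 1):
        mi = mol_ids[i]
        xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
        ti = types[i]
        for j in range(i + 1, n):
            same = mol_ids[j] == mi
            if intra == 1:
                if not same:
                    continue
            elif same:
                continue
            c = chan_ab[ti, types[j]]
            if c < 0:
                continue
            r2 = _min_image_dist2(xi - pos[j, 0], yi - pos[j, 1], zi - pos[j, 2], L)
            if r2 >= rmax2:
                continue
            b = int(np.sqrt(r2) / dr)
            counts[c, b] += 1
    return counts


@njit(cache=True)
def unit_overlap(pos, cls, unit_ids, sel, L, soft, strict, penalty):
    """Soft overlap energy of one unit's atoms (``sel``) against other units.

    Pairs closer than the soft floor for their class pair contribute
    (floor - r)^2; pairs under the strict floor add ``penalty`` times the
    squared strict deficit and are counted.  Returns (energy, n_strict).
    """
    e = 0.0
    nsv = 0
    n = pos.shape[0]
    for a in range(sel.shape[0]):
        i = sel[a]
        ui = unit_ids[i]
        ci = cls[i]
        for j in range(n):
            if unit_ids[j] == ui:
                continue
            r2 = _min_image_dist2(pos[i, 0] - pos[j, 0], pos[i, 1] - pos[j, 1],
                                  pos[i, 2] - pos[j, 2], L)
            ds = soft[ci, cls[j]]
            if r2 < ds * ds:
                r = np.sqrt(r2)
                e += (ds - r) ** 2
                dt = strict[ci, cls[j]]
                if r < dt:
                    nsv += 1
                    e += penalty * (dt - r) ** 2
    return e, nsv


@njit(cache=True)
def packing_state(pos, cls, unit_ids, L, soft, strict):
    """Global packing diagnostics: (soft energy, strict violation count,
    worst soft overlap, minimum inter-unit distance)."""
    e = 0.0
    nsv = 0
    worst = 0.0
    dmin = 1.0e30
    n = pos.shape[0]
    for i in range(n - 1):
        ui = unit_ids[i]
        ci = cls[i]
        for j in range(i + 1, n):
            if unit_ids[j] == ui:
                continue
            r2 = _min_image_dist2(pos[i, 0] - pos[j, 0], pos[i, 1] - pos[j, 1],
                                  pos[i, 2] - pos[j, 2], L)
            r = np.sqrt(r2)
            if r < dmin:
                dmin = r
            ds = soft[ci, cls[j]]
            if r < ds:
                e += (ds - r) ** 2
                if ds - r > worst:
                    worst = ds - r
                if r < strict[ci, cls[j]]:
                    nsv += 1
    return e, nsv, worst, dmin


@njit(cache=True)
def weighted_debye(d, chan, wq, q):
    """sum_p wq[chan[p], :] * sinc(q * d[p]) over pairs p."""
    nq = q.shape[0]
    out = np.zeros(nq)
    for p in range(d.shape[0]):
        dd = d[p]
        c = chan[p]
        for k in range(nq):
            x = q[k] * dd
            if x > 0.0:
                out[k] += wq[c, k] * np.sin(x) / x
            else:
                out[k] += wq[c, k]
    return out
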