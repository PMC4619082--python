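"""Numba-compiled inner loop of the Cellular Potts engine.

All functions operate on plain numpy arrays so that the same code path is
exercised by the high-level wrappers in :mod:`actcpm.lattice` and by the
Monte Carlo sweep itself.

Array conventions
-----------------
``spin``/``activity`` are ``(H, W)`` int32 arrays indexed ``[y, x]``;
identity 0 is the medium.  Per-cell arrays (``ctype``, ``areas``,
``perims``) are indexed by cell identity, entry 0 belonging to the medium.
Per-type parameter arrays are indexed by type id, type 0 being the medium.
The lattice is toroidal: all neighbor lookups wrap.
"""

import numpy as np
from numba import njit

# Moore neighborhood in cyclic ring order (N, NE, E, SE, S, SW, W, NW).
# Consecutive entries are lattice-adjacent, which the connectivity arc
# test relies on.
RING_DY = np.array([-1, -1, 0, 1, 1, 1, 0, -1], dtype=np.int64)
RING_DX = np.array([0, 1, 1, 1, 0, -1, -1, -1], dtype=np.int64)


@njit(cache=True)
def adhesion_delta(spin, ctype, J, uy, ux, vy, vx):
    """Change in adhesion energy when v takes u's identity.

    Only pairs involving v change, so the sum runs over v's Moore
    neighborhood; same-identity pairs contribute nothing (Kronecker
    delta in the Hamiltonian).
    """
    H, W = spin.shape
    s_new = spin[uy, ux]
    s_old = spin[vy, vx]
    t_new = ctype[s_new]
    t_old = ctype[s_old]
    dh = 0.0
    for k in range(8):
        wy = (vy + RING_DY[k]) % H
        wx = (vx + RING_DX[k]) % W
        s_w = spin[wy, wx]
        t_w = ctype[s_w]
        if s_w != s_new:
            dh += J[t_new, t_w]
        if s_w != s_old:
            dh -= J[t_old, t_w]
    return dh


@njit(cache=True)
def area_delta(areas, ctype, lam_area, tgt_area, s_gain, s_lose):
    """Change in the quadratic area penalty; the medium has no area term."""
    dh = 0.0
    if s_gain > 0:
        t = ctype[s_gain]
        d = areas[s_gain] - tgt_area[t]
        dh += lam_area[t] * ((d + 1.0) ** 2 - d * d)
    if s_lose > 0:
        t = ctype[s_lose]
        d = areas[s_lose] - tgt_area[t]
        dh += lam_area[t] * ((d - 1.0) ** 2 - d * d)
    return dh


@njit(cache=True)
def neighbor_counts(spin, vy, vx, s_gain, s_lose):
    """Number of Moore neighbors of v carrying the gaining / losing identity."""
    H, W = spin.shape
    n_gain = 0
    n_lose = 0
    for k in range(8):
        s_w = spin[(vy + RING_DY[k]) % H, (vx + RING_DX[k]) % W]
        if s_w == s_gain:
            n_gain += 1
        if s_w == s_lose:
            n_lose += 1
    return n_gain, n_lose


@njit(cache=True)
def perimeter_deltas(spin, vy, vx, s_gain, s_lose):
    """Interface-count changes (dp_gain, dp_lose) caused by the copy.

    The perimeter of a cell is the number of ordered (site, Moore
    neighbor) pairs whose identities differ.  Reassigning v changes only
    pairs incident to v: the gainer wins the 8 - n_gain foreign contacts
    of v and loses its n_gain former contacts with v, and symmetrically
    for the loser.
    """
    n_gain, n_lose = neighbor_counts(spin, vy, vx, s_gain, s_lose)
    return 8 - 2 * n_gain, 2 * n_lose - 8


@njit(cache=True)
def perimeter_energy_delta(spin, ctype, perims, lam_perim, tgt_perim,
                           vy, vx, s_gain, s_lose):
    dp_gain, dp_lose = perimeter_deltas(spin, vy, vx, s_gain, s_lose)
    dh = 0.0
    if s_gain > 0:
        t = ctype[s_gain]
        d = perims[s_gain] - tgt_perim[t]
        dh += lam_perim[t] * ((d + dp_gain) ** 2 - d * d)
    if s_lose > 0:
        t = ctype[s_lose]
        d = perims[s_lose] - tgt_perim[t]
        dh += lam_perim[t] * ((d + dp_lose) ** 2 - d * d)
    return dh


@njit(cache=True)
def gm_act(spin, act, y, x):
    """Geometric mean of activity over {u} and u's same-cell Moore neighbors.

    Zero for medium sites; zero whenever any member of the neighborhood
    is inactive (the geometric mean nullifies neighborhoods with holes).
    """
    H, W = spin.shape
    s = spin[y, x]
    if s == 0:
        return 0.0
    prod = float(act[y, x])
    n = 1
    for k in range(8):
        wy = (y + RING_DY[k]) % H
        wx = (x + RING_DX[k]) % W
        if spin[wy, wx] == s:
            prod *= act[wy, wx]
            n += 1
            if prod == 0.0:
                return 0.0
    return prod ** (1.0 / n)


@njit(cache=True)
def act_delta(spin, act, ctype, lam_act, max_act, uy, ux, vy, vx):
    """Protrusive activity bias for the copy u -> v.

    The prefactor lambda_act / max_act is the source cell's; a medium
    source (retraction) or a non-motile type contributes nothing.  The
    caller subtracts the returned value from the total energy change, so
    a positive value favors the copy.
    """
    t_src = ctype[spin[uy, ux]]
    la = lam_act[t_src]
    ma = max_act[t_src]
    if la == 0.0 or ma == 0:
        return 0.0
    return la / ma * (gm_act(spin, act, uy, ux) - gm_act(spin, act, vy, vx))


@njit(cache=True)
def chemotaxis_delta(spin, ctype, lam_chem, chem, uy, ux, vy, vx):
    """Chemotactic bias lambda * (C_v - C_u), subtracted from dH by the caller.

    The lambda is the source cell's; for retractions (medium source) the
    target cell's lambda applies.
    """
    s_u = spin[uy, ux]
    lam = lam_chem[ctype[s_u]] if s_u > 0 else lam_chem[ctype[spin[vy, vx]]]
    if lam == 0.0:
        return 0.0
    return lam * (chem[vy, vx] - chem[uy, ux])


@njit(cache=True)
def ring_arcs(spin, vy, vx, sigma):
    """Number of connected arcs of identity sigma in the 8-ring around v."""
    H, W = spin.shape
    arcs = 0
    for k in range(8):
        a = spin[(vy + RING_DY[k]) % H, (vx + RING_DX[k]) % W] == sigma
        kk = (k + 1) % 8
        b = spin[(vy + RING_DY[kk]) % H, (vx + RING_DX[kk]) % W] == sigma
        if a and not b:
            arcs += 1
    return arcs


@njit(cache=True)
def connectivity_allows(spin, areas, vy, vx):
    """Local connectivity test for the cell about to lose site v.

    Rejects the copy when the losing cell's sites in the Moore ring
    around v form more than one arc (the cell would locally split), or
    when v is the cell's last site.
    """
    s_v = spin[vy, vx]
    if areas[s_v] <= 1:
        return False
    return ring_arcs(spin, vy, vx, s_v) <= 1


@njit(cache=True)
def total_delta_h(spin, act, ctype, areas, perims, J,
                  lam_area, tgt_area, lam_perim, tgt_perim,
                  max_act, lam_act, lam_chem, chem,
                  uy, ux, vy, vx):
    """Full energy change of the copy u -> v.

    dH = dH_adhesion + dH_area + dH_perimeter - dH_act - dH_chemotaxis.
    """
    s_u = spin[uy, ux]
    s_v = spin[vy, vx]
    dh = adhesion_delta(spin, ctype, J, uy, ux, vy, vx)
    dh += area_delta(areas, ctype, lam_area, tgt_area, s_u, s_v)
    dh += perimeter_energy_delta(spin, ctype, perims, lam_perim, tgt_perim,
                                 vy, vx, s_u, s_v)
    dh -= act_delta(spin, act, ctype, lam_act, max_act, uy, ux, vy, vx)
    dh -= chemotaxis_delta(spin, ctype, lam_chem, chem, uy, ux, vy, vx)
    return dh


@njit(cache=True)
def apply_copy(spin, act, ctype, areas, perims, max_act, uy, ux, vy, vx):
    """Commit an accepted copy: identity, bookkeeping, and activity at v.

    A site freshly incorporated by a cell receives that type's maximum
    activity; a site reclaimed by the medium becomes inactive.
    """
    s_u = spin[uy, ux]
    s_v = spin[vy, vx]
    dp_gain, dp_lose = perimeter_deltas(spin, vy, vx, s_u, s_v)
    spin[vy, vx] = s_u
    if s_u > 0:
        areas[s_u] += 1
        perims[s_u] += dp_gain
        act[vy, vx] = max_act[ctype[s_u]]
    else:
        act[vy, vx] = 0
    if s_v > 0:
        areas[s_v] -= 1
        perims[s_v] += dp_lose


@njit(cache=True)
def decay_activity(act):
    """One activity tick: every positive value drops by 1 (floor at 0)."""
    H, W = act.shape
    for y in range(H):
        for x in range(W):
            if act[y, x] > 0:
                act[y, x] -= 1


@njit(cache=True)
def run_mcs_kernel(spin, act, ctype, areas, perims, J,
                   lam_area, tgt_area, lam_perim, tgt_perim,
                   max_act, lam_act, lam_chem, conn, chem,
                   temperature, n_mcs, seed):
    """Run ``n_mcs`` Monte Carlo steps in place.

    One MCS is width x height random copy attempts.  Per attempt the
    random stream is consumed in a fixed order: source row, source
    column, neighbor index, and — only when the attempt is non-trivial
    and dH >= 0 — one acceptance draw.  Trivial attempts (same identity
    on both sides) count toward the MCS budget but are not evaluated.
    Activity decays by one after each MCS.
    """
    np.random.seed(seed)
    H, W = spin.shape
    n_attempts = H * W
    for _ in range(n_mcs):
        for _ in range(n_attempts):
            uy = np.random.randint(0, H)
            ux = np.random.randint(0, W)
            k = np.random.randint(0, 8)
            vy = (uy + RING_DY[k]) % H
            vx = (ux + RING_DX[k]) % W
            s_u = spin[uy, ux]
            s_v = spin[vy, vx]
            if s_u == s_v:
                continue
            if s_v > 0 and conn[ctype[s_v]]:
                if not connectivity_allows(spin, areas, vy, vx):
                    continue
            dh = total_delta_h(spin, act, ctype, areas, perims, J,
                               lam_area, tgt_area, lam_perim, tgt_perim,
                               max_act, lam_act, lam_chem, chem,
                               uy, ux, vy, vx)
            if dh < 0.0 or np.random.random() < np.exp(-dh / temperature):
                apply_copy(spin, act, ctype, areas, perims, max_act,
                           uy, ux, vy, vx)
        decay_activity(act)
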