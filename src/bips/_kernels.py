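"""Compiled inner loops for the Brownian-dynamics engine.

Everything here works in reduced units: bead diameter sigma = 1, k_B T = 1,
friction gamma = 1 (so the free-bead diffusion coefficient D = 1 and the
unit of time is the time a free bead needs to diffuse over its own
diameter).  Inside a chunk, coordinates are kept wrapped into the periodic
box together with per-particle image counters; the caller sees unwrapped
positions, so clusters and mean-square displacements can be measured
directly.  Pair interactions always use the minimum-image convention.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by simulate_chunk
OK = 0
NEIGHBOR_OVERFLOW = 1
FENE_OVERSTRETCH = 2

WCA_CUT2 = 2.0 ** (1.0 / 3.0)  # squared cutoff of the purely repulsive LJ

_INV_2_53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=True, inline="always")
def _xs_u53(s):
    """xorshift128+ step returning a uniform double in [0, 1).

    The thermal kicks use variance-matched uniform noise instead of exact
    Gaussians (standard in Brownian/Langevin integrators: only the first two
    moments of the increment survive in the diffusion limit), which keeps the
    inner loop out of the slow library normal generator.
    """
    x = s[0]
    y = s[1]
    s[0] = y
    x ^= x << np.uint64(23)
    x ^= x >> np.uint64(17)
    x ^= y ^ (y >> np.uint64(26))
    s[1] = x
    return float((x + y) >> np.uint64(11)) * _INV_2_53


@njit(cache=True)
def _seed_xs(seed):
    """splitmix64 expansion of a small seed into xorshift128+ state."""
    s = np.empty(2, dtype=np.uint64)
    z = np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)
    for i in range(2):
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        z = z ^ (z >> np.uint64(31))
        s[i] = z if z != np.uint64(0) else np.uint64(0x1234567887654321)
        z += np.uint64(0x9E3779B97F4A7C15)
    return s


@njit(cache=True, fastmath=True)
def _build_cells(pos, box, ncell, head, nxt, stamp, cur):
    """Linked-cell binning; cells are lazily cleared via the stamp array."""
    inv = ncell / box
    n = pos.shape[0]
    for i in range(n - 1, -1, -1):
        cx = int(pos[i, 0] * inv)
        cy = int(pos[i, 1] * inv)
        cz = int(pos[i, 2] * inv)
        if cx >= ncell:
            cx = ncell - 1
        if cy >= ncell:
            cy = ncell - 1
        if cz >= ncell:
            cz = ncell - 1
        c = (cx * ncell + cy) * ncell + cz
        if stamp[c] != cur:
            stamp[c] = cur
            head[c] = i
            nxt[i] = -1
        else:
            nxt[i] = head[c]
            head[c] = i


@njit(cache=True, fastmath=True)
def _build_pairs(
    pos, n_beads, box, ncell, head, nxt, stamp, cur, r_list2, pair_i, pair_j
):
    """Half neighbor list from the cell structure; returns count or -1.

    Chain-bonded pairs (i, i+1) are excluded: their excluded-volume term is
    folded into the bond potential."""
    n = pos.shape[0]
    cap = pair_i.shape[0]
    npair = 0
    inv = ncell / box
    half = 0.5 * box
    for i in range(n):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        cx = min(int(xi * inv), ncell - 1)
        cy = min(int(yi * inv), ncell - 1)
        cz = min(int(zi * inv), ncell - 1)
        for ox in range(-1, 2):
            ax = cx + ox
            if ax < 0:
                ax += ncell
            elif ax >= ncell:
                ax -= ncell
            for oy in range(-1, 2):
                ay = cy + oy
                if ay < 0:
                    ay += ncell
                elif ay >= ncell:
                    ay -= ncell
                for oz in range(-1, 2):
                    az = cz + oz
                    if az < 0:
                        az += ncell
                    elif az >= ncell:
                        az -= ncell
                    c = (ax * ncell + ay) * ncell + az
                    if stamp[c] != cur:
                        continue
                    j = head[c]
                    while j >= 0:
                        if j > i and not (j == i + 1 and j < n_beads):
                            dx = xi - pos[j, 0]
                            if dx > half:
                                dx -= box
                            elif dx < -half:
                                dx += box
                            dy = yi - pos[j, 1]
                            if dy > half:
                                dy -= box
                            elif dy < -half:
                                dy += box
                            dz = zi - pos[j, 2]
                            if dz > half:
                                dz -= box
                            elif dz < -half:
                                dz += box
                            if dx * dx + dy * dy + dz * dz < r_list2:
                                if npair >= cap:
                                    return -1
                                pair_i[npair] = i
                                pair_j[npair] = j
                                npair += 1
                        j = nxt[j]
    return npair


@njit(cache=True, fastmath=True)
def _forces(
    pos,
    frc,
    n_beads,
    box,
    kappa,
    k_fene,
    r0_fene,
    use_wca,
    pair_i,
    pair_j,
    npair,
    bond_bead,
    bond_count,
    k_link,
    r0_link,
):
    n = pos.shape[0]
    half = 0.5 * box
    for i in range(n):
        frc[i, 0] = 0.0
        frc[i, 1] = 0.0
        frc[i, 2] = 0.0
    # FENE backbone (bond length << box/2, so min-image == true separation)
    r0sq = r0_fene * r0_fene
    for i in range(n_beads - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        if dx > half:
            dx -= box
        elif dx < -half:
            dx += box
        dy = pos[i + 1, 1] - pos[i, 1]
        if dy > half:
            dy -= box
        elif dy < -half:
            dy += box
        dz = pos[i + 1, 2] - pos[i, 2]
        if dz > half:
            dz -= box
        elif dz < -half:
            dz += box
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= r0sq:
            return FENE_OVERSTRETCH
        f = k_fene / (1.0 - r2 / r0sq)
        # the repulsive core is part of the bond potential (sets the ~0.97
        # sigma bond length) and stays on even for phantom chains
        if r2 < WCA_CUT2 and r2 > 1e-12:
            inv2 = 1.0 / r2
            inv6 = inv2 * inv2 * inv2
            f -= 24.0 * inv2 * inv6 * (2.0 * inv6 - 1.0)
        frc[i, 0] += f * dx
        frc[i, 1] += f * dy
        frc[i, 2] += f * dz
        frc[i + 1, 0] -= f * dx
        frc[i + 1, 1] -= f * dy
        frc[i + 1, 2] -= f * dz
    # Kratky-Porod bending
    if kappa > 0.0:
        for i in range(1, n_beads - 1):
            b1x = pos[i, 0] - pos[i - 1, 0]
            if b1x > half:
                b1x -= box
            elif b1x < -half:
                b1x += box
            b1y = pos[i, 1] - pos[i - 1, 1]
            if b1y > half:
                b1y -= box
            elif b1y < -half:
                b1y += box
            b1z = pos[i, 2] - pos[i - 1, 2]
            if b1z > half:
                b1z -= box
            elif b1z < -half:
                b1z += box
            b2x = pos[i + 1, 0] - pos[i, 0]
            if b2x > half:
                b2x -= box
            elif b2x < -half:
                b2x += box
            b2y = pos[i + 1, 1] - pos[i, 1]
            if b2y > half:
                b2y -= box
            elif b2y < -half:
                b2y += box
            b2z = pos[i + 1, 2] - pos[i, 2]
            if b2z > half:
                b2z -= box
            elif b2z < -half:
                b2z += box
            i1 = 1.0 / np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
            i2 = 1.0 / np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
            ux, uy, uz = b1x * i1, b1y * i1, b1z * i1
            vx, vy, vz = b2x * i2, b2y * i2, b2z * i2
            c = ux * vx + uy * vy + uz * vz
            k1 = kappa * i1
            k2 = kappa * i2
            fax = -k1 * (vx - c * ux)
            fay = -k1 * (vy - c * uy)
            faz = -k1 * (vz - c * uz)
            fcx = k2 * (ux - c * vx)
            fcy = k2 * (uy - c * vy)
            fcz = k2 * (uz - c * vz)
            frc[i - 1, 0] += fax
            frc[i - 1, 1] += fay
            frc[i - 1, 2] += faz
            frc[i + 1, 0] += fcx
            frc[i + 1, 1] += fcy
            frc[i + 1, 2] += fcz
            frc[i, 0] -= fax + fcx
            frc[i, 1] -= fay + fcy
            frc[i, 2] -= faz + fcz
    # WCA excluded volume over the neighbor list
    if use_wca:
        for p in range(npair):
            i = pair_i[p]
            j = pair_j[p]
            dx = pos[i, 0] - pos[j, 0]
            if dx > half:
                dx -= box
            elif dx < -half:
                dx += box
            dy = pos[i, 1] - pos[j, 1]
            if dy > half:
                dy -= box
            elif dy < -half:
                dy += box
            dz = pos[i, 2] - pos[j, 2]
            if dz > half:
                dz -= box
            elif dz < -half:
                dz += box
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < WCA_CUT2 and r2 > 1e-12:
                inv2 = 1.0 / r2
                inv6 = inv2 * inv2 * inv2
                f = 24.0 * inv2 * inv6 * (2.0 * inv6 - 1.0)
                frc[i, 0] += f * dx
                frc[i, 1] += f * dy
                frc[i, 2] += f * dz
                frc[j, 0] -= f * dx
                frc[j, 1] -= f * dy
                frc[j, 2] -= f * dz
    # harmonic bridge-bead links
    n_bridges = bond_bead.shape[0]
    for b in range(n_bridges):
        pb = n_beads + b
        for s in range(bond_count[b]):
            i = bond_bead[b, s]
            dx = pos[pb, 0] - pos[i, 0]
            if dx > half:
                dx -= box
            elif dx < -half:
                dx += box
            dy = pos[pb, 1] - pos[i, 1]
            if dy > half:
                dy -= box
            elif dy < -half:
                dy += box
            dz = pos[pb, 2] - pos[i, 2]
            if dz > half:
                dz -= box
            elif dz < -half:
                dz += box
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r > 1e-9:
                f = -k_link * (r - r0_link) / r
                frc[pb, 0] += f * dx
                frc[pb, 1] += f * dy
                frc[pb, 2] += f * dz
                frc[i, 0] -= f * dx
                frc[i, 1] -= f * dy
                frc[i, 2] -= f * dz
    return OK


@njit(cache=True, fastmath=True)
def _binding_sweep(
    pos,
    n_beads,
    box,
    sticky,
    bond_bead,
    bond_count,
    valence,
    eps_bind,
    r_capture,
    k_link,
    r0_link,
    ncell,
    head,
    nxt,
    stamp,
    cur,
    cand,
):
    """One Metropolis sweep over all bridges: bond deletions then creations.

    Candidate beads for creation are those within the capture radius; each
    single-bond toggle is accepted with min(1, exp(-dE)) where the
    bound-state energy is -eps_bind plus the harmonic link energy at the
    current separation.
    """
    n_bridges = bond_bead.shape[0]
    r_cap2 = r_capture * r_capture
    inv = ncell / box
    half = 0.5 * box
    for b in range(n_bridges):
        pb = n_beads + b
        # candidate pairs for this sweep: every current bond (whatever its
        # length) plus every unbonded in-range bead; each pair is *toggled*
        # at most once per sweep so the single-pair move is reversible and
        # the registry samples the Boltzmann measure
        ncand = bond_count[b]
        for s in range(ncand):
            cand[s] = bond_bead[b, s]
        cx = min(int(pos[pb, 0] * inv), ncell - 1)
        cy = min(int(pos[pb, 1] * inv), ncell - 1)
        cz = min(int(pos[pb, 2] * inv), ncell - 1)
        for ox in range(-1, 2):
            ax = cx + ox
            if ax < 0:
                ax += ncell
            elif ax >= ncell:
                ax -= ncell
            for oy in range(-1, 2):
                ay = cy + oy
                if ay < 0:
                    ay += ncell
                elif ay >= ncell:
                    ay -= ncell
                for oz in range(-1, 2):
                    az = cz + oz
                    if az < 0:
                        az += ncell
                    elif az >= ncell:
                        az -= ncell
                    c = (ax * ncell + ay) * ncell + az
                    if stamp[c] != cur:
                        continue
                    j = head[c]
                    while j >= 0:
                        if j < n_beads and sticky[j]:
                            dx = pos[pb, 0] - pos[j, 0]
                            if dx > half:
                                dx -= box
                            elif dx < -half:
                                dx += box
                            dy = pos[pb, 1] - pos[j, 1]
                            if dy > half:
                                dy -= box
                            elif dy < -half:
                                dy += box
                            dz = pos[pb, 2] - pos[j, 2]
                            if dz > half:
                                dz -= box
                            elif dz < -half:
                                dz += box
                            if dx * dx + dy * dy + dz * dz < r_cap2:
                                already = False
                                for s in range(bond_count[b]):
                                    if bond_bead[b, s] == j:
                                        already = True
                                        break
                                if not already and ncand < cand.shape[0]:
                                    cand[ncand] = j
                                    ncand += 1
                        j = nxt[j]
        # Fisher-Yates shuffle so slot competition is unbiased
        for s in range(ncand - 1, 0, -1):
            t = np.random.randint(0, s + 1)
            tmp = cand[s]
            cand[s] = cand[t]
            cand[t] = tmp
        # one Metropolis toggle per candidate pair
        for s in range(ncand):
            i = cand[s]
            dx = pos[pb, 0] - pos[i, 0]
            if dx > half:
                dx -= box
            elif dx < -half:
                dx += box
            dy = pos[pb, 1] - pos[i, 1]
            if dy > half:
                dy -= box
            elif dy < -half:
                dy += box
            dz = pos[pb, 2] - pos[i, 2]
            if dz > half:
                dz -= box
            elif dz < -half:
                dz += box
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            d = r - r0_link
            e_bond = 0.5 * k_link * d * d - eps_bind
            slot = -1
            for q in range(bond_count[b]):
                if bond_bead[b, q] == i:
                    slot = q
                    break
            if slot >= 0:
                # propose deletion: dE = -e_bond
                if e_bond >= 0.0 or np.random.random() < np.exp(e_bond):
                    bond_count[b] -= 1
                    bond_bead[b, slot] = bond_bead[b, bond_count[b]]
            elif bond_count[b] < valence:
                # propose creation: dE = +e_bond
                if e_bond <= 0.0 or np.random.random() < np.exp(-e_bond):
                    bond_bead[b, bond_count[b]] = i
                    bond_count[b] += 1


@njit(cache=True)
def _sweep_with_seed(
    pos, n_beads, box, sticky, bond_bead, bond_count, valence,
    eps_bind, r_capture, k_link, r0_link, ncell, head, nxt, stamp, cur,
    cand, seed,
):
    np.random.seed(seed)
    _binding_sweep(
        pos, n_beads, box, sticky, bond_bead, bond_count, valence,
        eps_bind, r_capture, k_link, r0_link, ncell, head, nxt, stamp, cur,
        cand,
    )


@njit(cache=True, fastmath=True)
def relax_chunk(
    pos,
    n_beads,
    bond_bead,
    bond_count,
    k_link,
    r0_link,
    kappa,
    k_fene,
    r0_fene,
    use_wca,
    box,
    n_iter,
    ncell,
    pair_cap,
):
    """Steepest-descent push-off: removes construction overlaps.

    Noise-free displacement along the force, clamped to 0.02 sigma per
    component, so bonds relax monotonically toward the potential minimum and
    deep excluded-volume overlaps cannot overstretch the backbone springs.
    """
    n = pos.shape[0]
    r_list = np.sqrt(WCA_CUT2) + 0.4
    r_list2 = r_list * r_list
    head = np.empty(ncell * ncell * ncell, dtype=np.int32)
    stamp = np.zeros(ncell * ncell * ncell, dtype=np.int32)
    nxt = np.empty(n, dtype=np.int32)
    pair_i = np.empty(pair_cap, dtype=np.int32)
    pair_j = np.empty(pair_cap, dtype=np.int32)
    frc = np.empty((n, 3), dtype=np.float64)
    for i in range(n):
        for d in range(3):
            k = np.floor(pos[i, d] / box)
            pos[i, d] -= k * box
    cur = 0
    dmax = 0.02
    for it in range(n_iter):
        if it % 10 == 0:
            cur += 1
            _build_cells(pos, box, ncell, head, nxt, stamp, cur)
            npair = _build_pairs(
                pos, n_beads, box, ncell, head, nxt, stamp, cur, r_list2,
                pair_i, pair_j,
            )
            if npair < 0:
                return NEIGHBOR_OVERFLOW
        # descend even from overstretched starts: skip the FENE status
        _forces_relaxed(
            pos, frc, n_beads, box, kappa, k_fene, r0_fene, use_wca,
            pair_i, pair_j, npair, bond_bead, bond_count, k_link, r0_link,
        )
        for i in range(n):
            for d in range(3):
                move = frc[i, d] * 1e-4
                if move > dmax:
                    move = dmax
                elif move < -dmax:
                    move = -dmax
                x = pos[i, d] + move
                if x >= box:
                    x -= box
                elif x < 0.0:
                    x += box
                pos[i, d] = x
    return OK


@njit(cache=True, fastmath=True)
def _forces_relaxed(
    pos, frc, n_beads, box, kappa, k_fene, r0_fene, use_wca,
    pair_i, pair_j, npair, bond_bead, bond_count, k_link, r0_link,
):
    """Force field variant for minimisation: FENE clamped near full
    extension instead of aborting."""
    half = 0.5 * box
    n = pos.shape[0]
    for i in range(n):
        frc[i, 0] = 0.0
        frc[i, 1] = 0.0
        frc[i, 2] = 0.0
    r0sq = r0_fene * r0_fene
    for i in range(n_beads - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        if dx > half:
            dx -= box
        elif dx < -half:
            dx += box
        dy = pos[i + 1, 1] - pos[i, 1]
        if dy > half:
            dy -= box
        elif dy < -half:
            dy += box
        dz = pos[i + 1, 2] - pos[i, 2]
        if dz > half:
            dz -= box
        elif dz < -half:
            dz += box
        r2 = dx * dx + dy * dy + dz * dz
        frac = r2 / r0sq
        if frac > 0.96:
            frac = 0.96
        f = k_fene / (1.0 - frac)
        if r2 < WCA_CUT2 and r2 > 1e-12:
            inv2 = 1.0 / r2
            inv6 = inv2 * inv2 * inv2
            f -= 24.0 * inv2 * inv6 * (2.0 * inv6 - 1.0)
        frc[i, 0] += f * dx
        frc[i, 1] += f * dy
        frc[i, 2] += f * dz
        frc[i + 1, 0] -= f * dx
        frc[i + 1, 1] -= f * dy
        frc[i + 1, 2] -= f * dz
    if use_wca:
        for p in range(npair):
            i = pair_i[p]
            j = pair_j[p]
            dx = pos[i, 0] - pos[j, 0]
            if dx > half:
                dx -= box
            elif dx < -half:
                dx += box
            dy = pos[i, 1] - pos[j, 1]
            if dy > half:
                dy -= box
            elif dy < -half:
                dy += box
            dz = pos[i, 2] - pos[j, 2]
            if dz > half:
                dz -= box
            elif dz < -half:
                dz += box
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < WCA_CUT2 and r2 > 1e-12:
                inv2 = 1.0 / r2
                inv6 = inv2 * inv2 * inv2
                f = 24.0 * inv2 * inv6 * (2.0 * inv6 - 1.0)
                frc[i, 0] += f * dx
                frc[i, 1] += f * dy
                frc[i, 2] += f * dz
                frc[j, 0] -= f * dx
                frc[j, 1] -= f * dy
                frc[j, 2] -= f * dz


@njit(cache=True, fastmath=True)
def simulate_chunk(
    pos,
    n_beads,
    sticky,
    bond_bead,
    bond_count,
    valence,
    eps_bind,
    r_capture,
    k_link,
    r0_link,
    kappa,
    k_fene,
    r0_fene,
    use_wca,
    box,
    dt,
    n_steps,
    bind_interval,
    seed,
    ncell,
    pair_cap,
):
    """Advance the system n_steps; mutates pos and the bond registry.

    Overdamped Euler-Maruyama with the deterministic displacement capped at
    0.1 sigma per component per step (protects the FENE springs against the
    enormous transient forces of deep excluded-volume overlaps).
    Returns (status, peak_pair_count).
    """
    np.random.seed(seed)  # Metropolis binding stream
    rs = _seed_xs(seed)  # thermal-noise stream
    n = pos.shape[0]
    skin = 0.7
    # the pair list only feeds WCA; cells are sized for the capture radius
    # in the wrapper, so the binding sweep can reuse them
    r_list = np.sqrt(WCA_CUT2) + skin
    r_list2 = r_list * r_list
    head = np.empty(ncell * ncell * ncell, dtype=np.int32)
    stamp = np.zeros(ncell * ncell * ncell, dtype=np.int32)
    cur = 0
    nxt = np.empty(n, dtype=np.int32)
    pair_i = np.empty(pair_cap, dtype=np.int32)
    pair_j = np.empty(pair_cap, dtype=np.int32)
    cand = np.empty(1024, dtype=np.int32)
    frc = np.empty((n, 3), dtype=np.float64)
    img = np.zeros((n, 3), dtype=np.int64)
    # wrap into the box, remembering images so the caller gets unwrapped
    for i in range(n):
        for d in range(3):
            k = np.floor(pos[i, d] / box)
            pos[i, d] -= k * box
            img[i, d] = np.int64(k)
    disp = np.zeros((n, 3), dtype=np.float64)  # true displacement since rebuild
    cur += 1
    _build_cells(pos, box, ncell, head, nxt, stamp, cur)
    npair = _build_pairs(
        pos, n_beads, box, ncell, head, nxt, stamp, cur, r_list2, pair_i, pair_j
    )
    if npair < 0:
        return NEIGHBOR_OVERFLOW, 0
    peak = npair
    # uniform kick on [-a, a] with a = sqrt(6 dt) has variance 2 D dt, D = 1
    noise = np.sqrt(6.0 * dt)
    dmax = 0.1
    half_skin = 0.5 * skin
    status = OK
    for step in range(n_steps):
        status = _forces(
            pos, frc, n_beads, box, kappa, k_fene, r0_fene, use_wca,
            pair_i, pair_j, npair, bond_bead, bond_count, k_link, r0_link,
        )
        if status != OK:
            break
        rebuild = False
        hs2 = half_skin * half_skin
        for i in range(n):
            for d in range(3):
                move = frc[i, d] * dt
                if move > dmax:
                    move = dmax
                elif move < -dmax:
                    move = -dmax
                move += noise * (2.0 * _xs_u53(rs) - 1.0)
                x = pos[i, d] + move
                if x >= box:
                    x -= box
                    img[i, d] += 1
                elif x < 0.0:
                    x += box
                    img[i, d] -= 1
                pos[i, d] = x
                disp[i, d] += move
            if (
                disp[i, 0] * disp[i, 0]
                + disp[i, 1] * disp[i, 1]
                + disp[i, 2] * disp[i, 2]
                > hs2
            ):
                rebuild = True
        do_bind = bind_interval > 0 and (step + 1) % bind_interval == 0
        if rebuild or do_bind:
            cur += 1
            _build_cells(pos, box, ncell, head, nxt, stamp, cur)
            if rebuild:
                npair = _build_pairs(
                    pos, n_beads, box, ncell, head, nxt, stamp, cur, r_list2,
                    pair_i, pair_j,
                )
                if npair < 0:
                    status = NEIGHBOR_OVERFLOW
                    break
                if npair > peak:
                    peak = npair
                disp[:, :] = 0.0
            if do_bind:
                _binding_sweep(
                    pos, n_beads, box, sticky, bond_bead, bond_count,
                    valence, eps_bind, r_capture, k_link, r0_link,
                    ncell, head, nxt, stamp, cur, cand,
                )
    # hand back unwrapped coordinates
    for i in range(n):
        for d in range(3):
            pos[i, d] += img[i, d] * box
    return status, peak
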