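"""Numba-compiled inner loops: RNG, neighbor search, forces, integrator.

Everything in this module operates on plain ndarrays so the hot loop can be
JIT-compiled.  The public modules (`forcefield`, `dynamics`) wrap these
kernels behind the documented interfaces.

Randomness uses a hand-rolled PCG32 generator (one 128-bit state per
stream).  This keeps the thermostat and bond-move streams independent,
bit-reproducible, and serializable into restart files, which a shared
global generator would not allow.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .units import FTM2V, MVV2E

TWO_PI = 6.283185307179586

# error codes returned by the step kernel
ERR_NONE = 0
ERR_UNSTABLE = 1
ERR_OVERLAP = 2
ERR_PAIRING = 3


# ---------------------------------------------------------------------------
# PCG32 random stream
# ---------------------------------------------------------------------------

_PCG_MULT = np.uint64(6364136223846793005)


def pcg_init(seed: int, stream: int = 0) -> np.ndarray:
    """Return a fresh PCG32 state vector ``[state, inc]`` for (seed, stream)."""
    state = np.zeros(2, dtype=np.uint64)
    state[1] = np.uint64((np.uint64(stream) << np.uint64(1)) | np.uint64(1))
    _pcg32(state)
    state[0] = state[0] + np.uint64(seed)
    _pcg32(state)
    return state


@njit(cache=True, inline="always")
def _pcg32(rs):
    old = rs[0]
    rs[0] = old * _PCG_MULT + rs[1]
    xorshifted = np.uint32(((old >> np.uint64(18)) ^ old) >> np.uint64(27))
    rot = np.uint32(old >> np.uint64(59))
    return np.uint32(
        (xorshifted >> rot) | (xorshifted << (np.uint32(32 - rot) & np.uint32(31)))
    )


@njit(cache=True, inline="always")
def _u01(rs):
    # uniform on (0, 1), 24-bit resolution
    return (np.float64(_pcg32(rs) >> np.uint32(8)) + 0.5) * 5.9604644775390625e-08


@njit(cache=True)
def _fill_normals(rs, out):
    """Fill a flat array with standard-normal draws (Box–Muller)."""
    n = out.size
    i = 0
    while i + 1 < n:
        r = np.sqrt(-2.0 * np.log(_u01(rs)))
        t = TWO_PI * _u01(rs)
        out[i] = r * np.cos(t)
        out[i + 1] = r * np.sin(t)
        i += 2
    if i < n:
        r = np.sqrt(-2.0 * np.log(_u01(rs)))
        out[i] = r * np.cos(TWO_PI * _u01(rs))


@njit(cache=True, inline="always")
def _randint(rs, n):
    # uniform integer in [0, n); modulo bias is negligible for n << 2**32
    return np.int64(_pcg32(rs) % np.uint32(n))


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _mi(d, L):
    # minimum-image convention for one component in a periodic box of edge L
    return d - L * np.floor(d / L + 0.5)


@njit(cache=True, inline="always")
def _mi_r2(pos, i, j, box):
    dx = _mi(pos[i, 0] - pos[j, 0], box[0])
    dy = _mi(pos[i, 1] - pos[j, 1], box[1])
    dz = _mi(pos[i, 2] - pos[j, 2], box[2])
    return dx * dx + dy * dy + dz * dz


# ---------------------------------------------------------------------------
# Neighbor search (half list, minimum image)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _build_neighbors(pos, box, rlist):
    """Half pair list (i < j) of all pairs within ``rlist`` under minimum image.

    Uses a linked-cell grid when at least 3 cells fit in every box dimension,
    otherwise falls back to the O(N²) all-pairs scan (correct for any box).
    """
    n = pos.shape[0]
    rl2 = rlist * rlist
    ncx = max(np.int64(box[0] / rlist), 1)
    ncy = max(np.int64(box[1] / rlist), 1)
    ncz = max(np.int64(box[2] / rlist), 1)

    cap = max(1024, 64 * n)
    nb_i = np.empty(cap, np.int64)
    nb_j = np.empty(cap, np.int64)
    cnt = 0

    if ncx < 3 or ncy < 3 or ncz < 3 or n < 64:
        for i in range(n - 1):
            for j in range(i + 1, n):
                if _mi_r2(pos, i, j, box) <= rl2:
                    if cnt == cap:
                        cap *= 2
                        tmp_i = np.empty(cap, np.int64)
                        tmp_j = np.empty(cap, np.int64)
                        tmp_i[:cnt] = nb_i[:cnt]
                        tmp_j[:cnt] = nb_j[:cnt]
                        nb_i, nb_j = tmp_i, tmp_j
                    nb_i[cnt] = i
                    nb_j[cnt] = j
                    cnt += 1
        return nb_i[:cnt].copy(), nb_j[:cnt].copy()

    ncell = ncx * ncy * ncz
    head = np.full(ncell, -1, np.int64)
    nxt = np.full(n, -1, np.int64)
    for i in range(n):
        cx = min(np.int64(pos[i, 0] / box[0] * ncx), ncx - 1)
        cy = min(np.int64(pos[i, 1] / box[1] * ncy), ncy - 1)
        cz = min(np.int64(pos[i, 2] / box[2] * ncz), ncz - 1)
        if cx < 0:
            cx = 0
        if cy < 0:
            cy = 0
        if cz < 0:
            cz = 0
        c = (cx * ncy + cy) * ncz + cz
        nxt[i] = head[c]
        head[c] = i

    # 13 half-shell offsets + same-cell pairs
    offs = np.array(
        [
            [1, 0, 0],
            [-1, 1, 0],
            [0, 1, 0],
            [1, 1, 0],
            [-1, -1, 1],
            [0, -1, 1],
            [1, -1, 1],
            [-1, 0, 1],
            [0, 0, 1],
            [1, 0, 1],
            [-1, 1, 1],
            [0, 1, 1],
            [1, 1, 1],
        ],
        np.int64,
    )

    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c1 = (cx * ncy + cy) * ncz + cz
                # same-cell pairs
                i = head[c1]
                while i != -1:
                    j = nxt[i]
                    while j != -1:
                        if _mi_r2(pos, i, j, box) <= rl2:
                            if cnt == cap:
                                cap *= 2
                                tmp_i = np.empty(cap, np.int64)
                                tmp_j = np.empty(cap, np.int64)
                                tmp_i[:cnt] = nb_i[:cnt]
                                tmp_j[:cnt] = nb_j[:cnt]
                                nb_i, nb_j = tmp_i, tmp_j
                            if i < j:
                                nb_i[cnt] = i
                                nb_j[cnt] = j
                            else:
                                nb_i[cnt] = j
                                nb_j[cnt] = i
                            cnt += 1
                        j = nxt[j]
                    i = nxt[i]
                # neighbor-cell pairs
                for o in range(13):
                    c2x = (cx + offs[o, 0]) % ncx
                    c2y = (cy + offs[o, 1]) % ncy
                    c2z = (cz + offs[o, 2]) % ncz
                    c2 = (c2x * ncy + c2y) * ncz + c2z
                    i = head[c1]
                    while i != -1:
                        j = head[c2]
                        while j != -1:
                            if _mi_r2(pos, i, j, box) <= rl2:
                                if cnt == cap:
                                    cap *= 2
                                    tmp_i = np.empty(cap, np.int64)
                                    tmp_j = np.empty(cap, np.int64)
                                    tmp_i[:cnt] = nb_i[:cnt]
                                    tmp_j[:cnt] = nb_j[:cnt]
                                    nb_i, nb_j = tmp_i, tmp_j
                                if i < j:
                                    nb_i[cnt] = i
                                    nb_j[cnt] = j
                                else:
                                    nb_i[cnt] = j
                                    nb_j[cnt] = i
                                cnt += 1
                            j = nxt[j]
                        i = nxt[i]
    return nb_i[:cnt].copy(), nb_j[:cnt].copy()


# ---------------------------------------------------------------------------
# Forces and energies
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _compute_forces(
    pos,
    box,
    f,
    bond_i,
    bond_j,
    Kb,
    R0b,
    ang_a,
    ang_b,
    ang_c,
    kappa,
    nb_i,
    nb_j,
    eps,
    sigma,
    rmax,
    partner,
    perm1,
    perm2,
    Es,
    R0s,
    Rcuts,
):
    """Fill ``f`` with forces; return (E_bond, E_pair, E_angle, err).

    E_bond sums permanent harmonic bonds and active sticker bonds.  LJ is
    truncated (unshifted) at ``rmax`` and excluded for 1–2 bonded pairs and
    currently bonded sticker pairs.
    """
    n = pos.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    e_bond = 0.0
    e_pair = 0.0
    e_angle = 0.0

    # permanent backbone bonds
    for b in range(bond_i.size):
        i = bond_i[b]
        j = bond_j[b]
        dx = _mi(pos[i, 0] - pos[j, 0], box[0])
        dy = _mi(pos[i, 1] - pos[j, 1], box[1])
        dz = _mi(pos[i, 2] - pos[j, 2], box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - R0b
        e_bond += Kb * dr * dr
        if r > 1e-12:
            fm = -2.0 * Kb * dr / r
            f[i, 0] += fm * dx
            f[i, 1] += fm * dy
            f[i, 2] += fm * dz
            f[j, 0] -= fm * dx
            f[j, 1] -= fm * dy
            f[j, 2] -= fm * dz

    # active sticker bonds (shifted harmonic, zero beyond the cutoff)
    if Es > 0.0:
        pref = Es / ((R0s - Rcuts) * (R0s - Rcuts))
        well = (Rcuts - R0s) * (Rcuts - R0s)
        for i in range(n):
            j = partner[i]
            if j > i:
                dx = _mi(pos[i, 0] - pos[j, 0], box[0])
                dy = _mi(pos[i, 1] - pos[j, 1], box[1])
                dz = _mi(pos[i, 2] - pos[j, 2], box[2])
                r = np.sqrt(dx * dx + dy * dy + dz * dz)
                if r < Rcuts:
                    dr = r - R0s
                    e_bond += pref * (dr * dr - well)
                    if r > 1e-12:
                        fm = -2.0 * pref * dr / r
                        f[i, 0] += fm * dx
                        f[i, 1] += fm * dy
                        f[i, 2] += fm * dz
                        f[j, 0] -= fm * dx
                        f[j, 1] -= fm * dy
                        f[j, 2] -= fm * dz

    # bending: E = kappa * (1 + cos(phi_interior)), zero for a straight chain
    for a in range(ang_a.size):
        i = ang_a[a]
        m = ang_b[a]
        k = ang_c[a]
        r1x = _mi(pos[i, 0] - pos[m, 0], box[0])
        r1y = _mi(pos[i, 1] - pos[m, 1], box[1])
        r1z = _mi(pos[i, 2] - pos[m, 2], box[2])
        r2x = _mi(pos[k, 0] - pos[m, 0], box[0])
        r2y = _mi(pos[k, 1] - pos[m, 1], box[1])
        r2z = _mi(pos[k, 2] - pos[m, 2], box[2])
        n1 = np.sqrt(r1x * r1x + r1y * r1y + r1z * r1z)
        n2 = np.sqrt(r2x * r2x + r2y * r2y + r2z * r2z)
        c = (r1x * r2x + r1y * r2y + r1z * r2z) / (n1 * n2)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        e_angle += kappa * (1.0 + c)
        inv12 = 1.0 / (n1 * n2)
        inv11 = 1.0 / (n1 * n1)
        inv22 = 1.0 / (n2 * n2)
        fix = -kappa * (r2x * inv12 - c * r1x * inv11)
        fiy = -kappa * (r2y * inv12 - c * r1y * inv11)
        fiz = -kappa * (r2z * inv12 - c * r1z * inv11)
        fkx = -kappa * (r1x * inv12 - c * r2x * inv22)
        fky = -kappa * (r1y * inv12 - c * r2y * inv22)
        fkz = -kappa * (r1z * inv12 - c * r2z * inv22)
        f[i, 0] += fix
        f[i, 1] += fiy
        f[i, 2] += fiz
        f[k, 0] += fkx
        f[k, 1] += fky
        f[k, 2] += fkz
        f[m, 0] -= fix + fkx
        f[m, 1] -= fiy + fky
        f[m, 2] -= fiz + fkz

    # truncated LJ over the half neighbor list, minus exclusions
    if eps > 0.0:
        rmax2 = rmax * rmax
        s2 = sigma * sigma
        for p in range(nb_i.size):
            i = nb_i[p]
            j = nb_j[p]
            if j == perm1[i] or j == perm2[i] or j == partner[i]:
                continue
            dx = _mi(pos[i, 0] - pos[j, 0], box[0])
            dy = _mi(pos[i, 1] - pos[j, 1], box[1])
            dz = _mi(pos[i, 2] - pos[j, 2], box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > rmax2:
                continue
            if r2 < 1e-12:
                return e_bond, e_pair, e_angle, ERR_OVERLAP
            sr2 = s2 / r2
            sr6 = sr2 * sr2 * sr2
            sr12 = sr6 * sr6
            e_pair += 4.0 * eps * (sr12 - sr6)
            fm = 24.0 * eps * (2.0 * sr12 - sr6) / r2
            f[i, 0] += fm * dx
            f[i, 1] += fm * dy
            f[i, 2] += fm * dz
            f[j, 0] -= fm * dx
            f[j, 1] -= fm * dy
            f[j, 2] -= fm * dz

    return e_bond, e_pair, e_angle, ERR_NONE


# ---------------------------------------------------------------------------
# Stochastic bond moves
# ---------------------------------------------------------------------------


@njit(cache=True)
def _attempt_bonds(
    pos,
    box,
    partner,
    sticker_idx,
    stype,
    comp,
    Rcuts,
    p_on,
    p_off,
    rng_b,
    ev_buf,
    n_ev,
    record_events,
    step,
):
    """One break-then-create pass over all stickers.

    Break: every bonded pair with minimum-image R >= Rcut breaks with
    probability p_off.  Create: candidate pairs (complementary types, both
    unpaired, R <= Rcut) are visited in uniformly random order and accepted
    with probability p_on if both members are still unpaired.  Events are
    appended to ``ev_buf`` as (step, kind, i, j); kind 0 = form, 1 = break.
    """
    ns = sticker_idx.size
    rc2 = Rcuts * Rcuts

    # break pass
    for a in range(ns):
        i = sticker_idx[a]
        j = partner[i]
        if j > i:
            if _mi_r2(pos, i, j, box) >= rc2:
                if p_off >= 1.0 or _u01(rng_b) < p_off:
                    partner[i] = -1
                    partner[j] = -1
                    if record_events:
                        ev_buf[n_ev, 0] = step
                        ev_buf[n_ev, 1] = 1
                        ev_buf[n_ev, 2] = i
                        ev_buf[n_ev, 3] = j
                        n_ev += 1

    # create pass: collect candidates (count, allocate, fill)
    ncand = 0
    for a in range(ns - 1):
        i = sticker_idx[a]
        if partner[i] != -1:
            continue
        ti = stype[i]
        for b in range(a + 1, ns):
            j = sticker_idx[b]
            if partner[j] != -1:
                continue
            if not comp[ti, stype[j]]:
                continue
            if _mi_r2(pos, i, j, box) <= rc2:
                ncand += 1
    if ncand > 0:
        cand_i = np.empty(ncand, np.int64)
        cand_j = np.empty(ncand, np.int64)
        k = 0
        for a in range(ns - 1):
            i = sticker_idx[a]
            if partner[i] != -1:
                continue
            ti = stype[i]
            for b in range(a + 1, ns):
                j = sticker_idx[b]
                if partner[j] != -1:
                    continue
                if not comp[ti, stype[j]]:
                    continue
                if _mi_r2(pos, i, j, box) <= rc2:
                    cand_i[k] = i
                    cand_j[k] = j
                    k += 1
        # Fisher–Yates shuffle for a uniformly random visiting order
        for k in range(ncand - 1, 0, -1):
            m = _randint(rng_b, k + 1)
            ti_ = cand_i[k]
            cand_i[k] = cand_i[m]
            cand_i[m] = ti_
            tj_ = cand_j[k]
            cand_j[k] = cand_j[m]
            cand_j[m] = tj_
        for k in range(ncand):
            i = cand_i[k]
            j = cand_j[k]
            if partner[i] != -1 or partner[j] != -1:
                continue
            if p_on >= 1.0 or _u01(rng_b) < p_on:
                partner[i] = j
                partner[j] = i
                if record_events:
                    ev_buf[n_ev, 0] = step
                    ev_buf[n_ev, 1] = 0
                    ev_buf[n_ev, 2] = i
                    ev_buf[n_ev, 3] = j
                    n_ev += 1
    return n_ev


# ---------------------------------------------------------------------------
# Main step loop (BAOAB Langevin splitting)
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _run_chunk(
    pos,
    img,
    vel,
    partner,
    box,
    bond_i,
    bond_j,
    ang_a,
    ang_b,
    ang_c,
    perm1,
    perm2,
    sticker_idx,
    stype,
    comp,
    Kb,
    R0b,
    kappa,
    eps,
    sigma,
    rmax,
    Es,
    R0s,
    Rcuts,
    p_on,
    p_off,
    mass,
    dt,
    t_damp,
    kT_val,
    use_thermostat,
    step0,
    n_steps,
    bond_every,
    skin,
    thermo_every,
    thermo_out,
    dump_every,
    traj_pos,
    traj_img,
    traj_steps,
    record_series,
    series_out,
    record_events,
    ev_buf,
    rng_t,
    rng_b,
):
    """Advance ``n_steps`` steps; fill output buffers; return counters.

    Per step: half kick (B) with the last conservative forces, half drift
    (A), exact Ornstein–Uhlenbeck velocity update (O), half drift (A), bond
    attempts at the configured cadence, force evaluation, half kick (B).
    With the thermostat off this reduces exactly to velocity Verlet.

    Returns (err, n_thermo, n_dump, n_series, n_events).
    """
    n = pos.shape[0]
    f = np.empty((n, 3), np.float64)
    noise = np.empty(3 * n, np.float64)
    dsum = np.zeros((n, 3), np.float64)

    if use_thermostat:
        c1 = np.exp(-dt / t_damp)
        c2 = np.sqrt((1.0 - c1 * c1) * kT_val * FTM2V / mass)
    else:
        c1 = 1.0
        c2 = 0.0

    box_min = min(box[0], min(box[1], box[2]))
    dmax_allowed = 0.25 * box_min
    use_lj = eps > 0.0
    rlist = rmax + skin
    half_skin2 = 0.25 * skin * skin

    if use_lj:
        nb_i, nb_j = _build_neighbors(pos, box, rlist)
    else:
        nb_i = np.empty(0, np.int64)
        nb_j = np.empty(0, np.int64)

    eb, ep, ea, err = _compute_forces(
        pos, box, f, bond_i, bond_j, Kb, R0b, ang_a, ang_b, ang_c, kappa,
        nb_i, nb_j, eps, sigma, rmax, partner, perm1, perm2, Es, R0s, Rcuts,
    )
    if err != ERR_NONE:
        return err, 0, 0, 0, 0
    fscale = FTM2V / mass

    n_th = 0
    n_dp = 0
    n_se = 0
    n_ev = 0

    for k in range(n_steps):
        step_new = step0 + k + 1

        # B: half kick with conservative forces
        h = 0.5 * dt * fscale
        for i in range(n):
            vel[i, 0] += h * f[i, 0]
            vel[i, 1] += h * f[i, 1]
            vel[i, 2] += h * f[i, 2]

        # A: half drift
        hd = 0.5 * dt
        dmax = 0.0
        for i in range(n):
            for d in range(3):
                dx = hd * vel[i, d]
                if np.abs(dx) > dmax:
                    dmax = np.abs(dx)
                pos[i, d] += dx
                dsum[i, d] += dx

        # O: exact Ornstein–Uhlenbeck update
        if use_thermostat:
            _fill_normals(rng_t, noise)
            for i in range(n):
                vel[i, 0] = c1 * vel[i, 0] + c2 * noise[3 * i]
                vel[i, 1] = c1 * vel[i, 1] + c2 * noise[3 * i + 1]
                vel[i, 2] = c1 * vel[i, 2] + c2 * noise[3 * i + 2]

        # A: half drift
        for i in range(n):
            for d in range(3):
                dx = hd * vel[i, d]
                if np.abs(dx) > dmax:
                    dmax = np.abs(dx)
                pos[i, d] += dx
                dsum[i, d] += dx

        if 2.0 * dmax > dmax_allowed:
            return ERR_UNSTABLE, n_th, n_dp, n_se, n_ev

        # wrap into the box, updating image flags
        for i in range(n):
            for d in range(3):
                s = np.floor(pos[i, d] / box[d])
                if s != 0.0:
                    img[i, d] += np.int64(s)
                    pos[i, d] -= s * box[d]

        # stochastic bond moves at the configured cadence
        if bond_every > 0 and step_new % bond_every == 0 and sticker_idx.size > 0:
            n_ev = _attempt_bonds(
                pos, box, partner, sticker_idx, stype, comp, Rcuts,
                p_on, p_off, rng_b, ev_buf, n_ev, record_events, step_new,
            )
            if record_series:
                np_paired = 0
                for a in range(sticker_idx.size):
                    if partner[sticker_idx[a]] != -1:
                        np_paired += 1
                series_out[n_se] = np_paired
                n_se += 1

        # neighbor list maintenance (half-skin displacement trigger)
        if use_lj:
            need = False
            for i in range(n):
                dd = (
                    dsum[i, 0] * dsum[i, 0]
                    + dsum[i, 1] * dsum[i, 1]
                    + dsum[i, 2] * dsum[i, 2]
                )
                if dd > half_skin2:
                    need = True
                    break
            if need:
                nb_i, nb_j = _build_neighbors(pos, box, rlist)
                for i in range(n):
                    dsum[i, 0] = 0.0
                    dsum[i, 1] = 0.0
                    dsum[i, 2] = 0.0

        eb, ep, ea, err = _compute_forces(
            pos, box, f, bond_i, bond_j, Kb, R0b, ang_a, ang_b, ang_c, kappa,
            nb_i, nb_j, eps, sigma, rmax, partner, perm1, perm2, Es, R0s, Rcuts,
        )
        if err != ERR_NONE:
            return err, n_th, n_dp, n_se, n_ev

        # B: half kick
        for i in range(n):
            vel[i, 0] += h * f[i, 0]
            vel[i, 1] += h * f[i, 1]
            vel[i, 2] += h * f[i, 2]

        if thermo_every > 0 and step_new % thermo_every == 0:
            ke = 0.0
            for i in range(n):
                ke += (
                    vel[i, 0] * vel[i, 0]
                    + vel[i, 1] * vel[i, 1]
                    + vel[i, 2] * vel[i, 2]
                )
            ke *= 0.5 * mass * MVV2E
            np_paired = 0
            for a in range(sticker_idx.size):
                if partner[sticker_idx[a]] != -1:
                    np_paired += 1
            thermo_out[n_th, 0] = step_new
            thermo_out[n_th, 1] = eb
            thermo_out[n_th, 2] = ep
            thermo_out[n_th, 3] = ea
            thermo_out[n_th, 4] = eb + ep + ea
            thermo_out[n_th, 5] = ke
            thermo_out[n_th, 6] = np_paired
            n_th += 1

        if dump_every > 0 and step_new % dump_every == 0:
            for i in range(n):
                for d in range(3):
                    traj_pos[n_dp, i, d] = pos[i, d]
                    traj_img[n_dp, i, d] = img[i, d]
            traj_steps[n_dp] = step_new
            n_dp += 1

    return ERR_NONE, n_th, n_dp, n_se, n_ev
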