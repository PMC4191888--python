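"""Numba-compiled inner loops of the bond-fluctuation simulator.

Everything here operates on plain numpy arrays so that the same move and
loop-update logic backs both the Python-level single-step API (used by the
tests and for didactic stepping) and the fast multi-MCS driver used by the
run protocol.  All randomness inside a kernel segment comes from numba's
legacy global RNG, seeded explicitly at segment entry, which makes a
segment a pure function of (state, seed).

Conventions
-----------
* positions: (N, 3) int64 anchor coordinates, wrapped into [0, L).
* anchor:    flat int32 array of L**3 sites, anchor[x*L*L + y*L + z] is the
             monomer anchored there or -1.  A monomer occupies the 2x2x2
             cube of sites at its anchor; two cubes overlap iff their
             anchors are within Chebyshev distance 1, so the anchor map is
             sufficient for the excluded-volume test.
* allowed:   (7, 7, 7) bool lookup, allowed[dx+3, dy+3, dz+3] for the 108
             bond vectors of the classic 3D bond-fluctuation method.
* partners/expires: (N, K) int32/int64, K = max loop bonds per monomer,
             -1 marks a free slot.
* Loop rule modes: 0 homogeneous, 1 contour-cutoff (uniform adapted),
             2 domain layout.
"""

import numpy as np
from numba import njit

# Event codes in the log buffers.
EV_FORM = 0
EV_BREAK = 1


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _mi(d, L):
    # minimum-image component; bond vectors are short (|d| <= 3 << L/2)
    if d > L // 2:
        d -= L
    elif d < -(L // 2):
        d += L
    return d


@njit(cache=True, inline="always")
def _site(x, y, z, L):
    return (x * L + y) * L + z


@njit(cache=True)
def build_anchor_map(positions, L):
    anchor = np.full(L * L * L, -1, dtype=np.int32)
    for m in range(positions.shape[0]):
        anchor[_site(positions[m, 0], positions[m, 1], positions[m, 2], L)] = m
    return anchor


@njit(cache=True)
def build_site_occupancy(positions, L):
    """Mark every site of each monomer's 2x2x2 cube (1 = occupied)."""
    occ = np.zeros(L * L * L, dtype=np.uint8)
    for m in range(positions.shape[0]):
        for a in range(2):
            x = positions[m, 0] + a
            if x >= L:
                x -= L
            for b in range(2):
                y = positions[m, 1] + b
                if y >= L:
                    y -= L
                for c in range(2):
                    z = positions[m, 2] + c
                    if z >= L:
                        z -= L
                    occ[_site(x, y, z, L)] = 1
    return occ


@njit(cache=True, inline="always")
def _wrap(x, L):
    if x >= L:
        return x - L
    if x < 0:
        return x + L
    return x


@njit(cache=True, inline="always")
def _bond_ok(pos, m_new_x, m_new_y, m_new_z, nb, L, allowed, positions):
    dx = _mi(positions[nb, 0] - m_new_x, L)
    dy = _mi(positions[nb, 1] - m_new_y, L)
    dz = _mi(positions[nb, 2] - m_new_z, L)
    if dx < -3 or dx > 3 or dy < -3 or dy > 3 or dz < -3 or dz > 3:
        return False
    return allowed[dx + 3, dy + 3, dz + 3]


@njit(cache=True)
def try_move(positions, anchor, occ, L, allowed, partners, m, direction):
    """Attempt to move monomer m one lattice unit along `direction` (0..5).

    Applies the move in place iff the target cube is free and every bond
    incident to m (backbone and loop) remains an allowed bond vector.
    Returns True iff the move was applied.

    Excluded volume is checked on the site-occupancy lattice: moving a
    2x2x2 cube one step exposes exactly 4 new sites (the advancing face),
    which never belong to the moving cube itself.
    """
    N = positions.shape[0]
    axis = direction // 2
    step = 1 if direction % 2 == 0 else -1
    ox = positions[m, 0]
    oy = positions[m, 1]
    oz = positions[m, 2]
    nx, ny, nz = ox, oy, oz
    if axis == 0:
        nx = _wrap(ox + step, L)
    elif axis == 1:
        ny = _wrap(oy + step, L)
    else:
        nz = _wrap(oz + step, L)

    # excluded volume: the 4 advancing-face sites must be empty.
    # face coordinate along the move axis: anchor+2 when moving in +,
    # anchor-1 when moving in -.
    fc = _wrap((ox if axis == 0 else oy if axis == 1 else oz)
               + (2 if step == 1 else -1), L)
    if axis == 0:
        for b in range(2):
            y = _wrap(oy + b, L)
            for c in range(2):
                if occ[_site(fc, y, _wrap(oz + c, L), L)] != 0:
                    return False
    elif axis == 1:
        for b in range(2):
            x = _wrap(ox + b, L)
            for c in range(2):
                if occ[_site(x, fc, _wrap(oz + c, L), L)] != 0:
                    return False
    else:
        for b in range(2):
            x = _wrap(ox + b, L)
            for c in range(2):
                if occ[_site(x, _wrap(oy + c, L), fc, L)] != 0:
                    return False

    # backbone bonds
    if m > 0 and not _bond_ok(positions, nx, ny, nz, m - 1, L, allowed, positions):
        return False
    if m < N - 1 and not _bond_ok(positions, nx, ny, nz, m + 1, L, allowed, positions):
        return False
    # loop bonds
    for k in range(partners.shape[1]):
        j = partners[m, k]
        if j >= 0 and not _bond_ok(positions, nx, ny, nz, j, L, allowed, positions):
            return False

    # apply: set the advancing face, clear the trailing face
    tc = _wrap((ox if axis == 0 else oy if axis == 1 else oz)
               + (0 if step == 1 else 1), L)
    if axis == 0:
        for b in range(2):
            y = _wrap(oy + b, L)
            for c in range(2):
                z = _wrap(oz + c, L)
                occ[_site(fc, y, z, L)] = 1
                occ[_site(tc, y, z, L)] = 0
    elif axis == 1:
        for b in range(2):
            x = _wrap(ox + b, L)
            for c in range(2):
                z = _wrap(oz + c, L)
                occ[_site(x, fc, z, L)] = 1
                occ[_site(x, tc, z, L)] = 0
    else:
        for b in range(2):
            x = _wrap(ox + b, L)
            for c in range(2):
                y = _wrap(oy + c, L)
                occ[_site(x, y, fc, L)] = 1
                occ[_site(x, y, tc, L)] = 0

    anchor[_site(ox, oy, oz, L)] = -1
    positions[m, 0] = nx
    positions[m, 1] = ny
    positions[m, 2] = nz
    anchor[_site(nx, ny, nz, L)] = m
    return True


@njit(cache=True, inline="always")
def pair_probability(i, j, mode, p_short, p_long, cutoff, block, linker,
                     linkers_loop):
    """Looping probability p_bond,ij for a non-adjacent proximal pair."""
    if mode == 0:
        return p_short  # homogeneous: caller passes p_short == p_long == p
    if mode == 1:
        if abs(i - j) <= cutoff:
            return p_short
        return p_long
    # mode 2: domain layout
    if linkers_loop:
        # alternate reading: every block acts as a domain
        if block[i] == block[j]:
            return p_short
        return p_long
    if linker[i] != 0 or linker[j] != 0:
        return 0.0
    if block[i] == block[j]:
        return p_short
    return p_long


@njit(cache=True)
def _remove_partner(partners, expires, i, j):
    for k in range(partners.shape[1]):
        if partners[i, k] == j:
            partners[i, k] = -1
            expires[i, k] = -1
            return


@njit(cache=True)
def _free_slots(partners, i):
    n = 0
    for k in range(partners.shape[1]):
        if partners[i, k] < 0:
            n += 1
    return n


@njit(cache=True)
def _is_bonded(partners, i, j):
    for k in range(partners.shape[1]):
        if partners[i, k] == j:
            return True
    return False


@njit(cache=True)
def loop_update(positions, anchor, L, allowed, half_vectors, partners, expires,
                mode, p_short, p_long, cutoff, block, linker, linkers_loop,
                T_bond, mcs_now, cand_i, cand_j, order,
                log_on, log_mcs, log_ev, log_i, log_j, log_life, n_log):
    """One per-MCS loop bookkeeping pass: dissociations, then formations.

    Bonds whose expiry time has been reached are removed first; then every
    currently proximal, non-adjacent, unbonded pair with free binding slots
    on both monomers is offered a Bernoulli formation trial at
    pair_probability, in a freshly shuffled order, and successful bonds get
    a Poisson(T_bond) lifetime.  cand_i/cand_j/order are scratch buffers of
    length >= N * len(half_vectors).  Returns the updated log cursor.
    """
    N = positions.shape[0]
    K = partners.shape[1]
    cap = log_mcs.shape[0]

    # --- dissociation ---
    for i in range(N):
        for k in range(K):
            j = partners[i, k]
            if j > i and expires[i, k] <= mcs_now:
                life = expires[i, k]
                partners[i, k] = -1
                expires[i, k] = -1
                _remove_partner(partners, expires, j, i)
                if log_on and n_log < cap:
                    log_mcs[n_log] = mcs_now
                    log_ev[n_log] = EV_BREAK
                    log_i[n_log] = i
                    log_j[n_log] = j
                    log_life[n_log] = life
                    n_log += 1

    # --- collect proximal candidate pairs (each unordered pair once) ---
    n_half = half_vectors.shape[0]
    n_cand = 0
    for i in range(N):
        for v in range(n_half):
            x = _wrap(positions[i, 0] + half_vectors[v, 0], L)
            y = _wrap(positions[i, 1] + half_vectors[v, 1], L)
            z = _wrap(positions[i, 2] + half_vectors[v, 2], L)
            j = anchor[_site(x, y, z, L)]
            if j >= 0 and abs(i - j) >= 2:
                cand_i[n_cand] = i
                cand_j[n_cand] = j
                n_cand += 1

    # --- formation trials in random order ---
    for k in range(n_cand):
        order[k] = k
    np.random.shuffle(order[:n_cand])
    for c in range(n_cand):
        i = cand_i[order[c]]
        j = cand_j[order[c]]
        if _is_bonded(partners, i, j):
            continue
        if _free_slots(partners, i) == 0 or _free_slots(partners, j) == 0:
            continue
        p = pair_probability(i, j, mode, p_short, p_long, cutoff,
                             block, linker, linkers_loop)
        if p <= 0.0:
            continue
        if np.random.random() >= p:
            continue
        life = np.random.poisson(T_bond) if T_bond > 0 else 0
        exp_at = mcs_now + life
        for k in range(K):
            if partners[i, k] < 0:
                partners[i, k] = j
                expires[i, k] = exp_at
                break
        for k in range(K):
            if partners[j, k] < 0:
                partners[j, k] = i
                expires[j, k] = exp_at
                break
        if log_on and n_log < cap:
            log_mcs[n_log] = mcs_now
            log_ev[n_log] = EV_FORM
            log_i[n_log] = min(i, j)
            log_j[n_log] = max(i, j)
            log_life[n_log] = life
            n_log += 1

    return n_log


@njit(cache=True)
def run_segment(positions, anchor, occ, L, allowed, half_vectors, partners,
                expires, mode, p_short, p_long, cutoff, block, linker,
                linkers_loop, T_bond, loops_on, mcs_start, n_mcs, seed,
                log_on, log_mcs, log_ev, log_i, log_j, log_life, n_log):
    """Advance the chain by n_mcs Monte Carlo steps (N move attempts each),
    running the loop-update pass after every MCS when loops_on.

    State arrays are updated in place.  Returns the log cursor."""
    np.random.seed(seed)
    N = positions.shape[0]
    n_half = half_vectors.shape[0]
    cand_i = np.empty(N * n_half, dtype=np.int32)
    cand_j = np.empty(N * n_half, dtype=np.int32)
    order = np.empty(N * n_half, dtype=np.int64)
    for t in range(n_mcs):
        for _ in range(N):
            m = np.random.randint(N)
            d = np.random.randint(6)
            try_move(positions, anchor, occ, L, allowed, partners, m, d)
        mcs_now = mcs_start + t + 1
        if loops_on:
            n_log = loop_update(positions, anchor, L, allowed, half_vectors,
                                partners, expires, mode, p_short, p_long,
                                cutoff, block, linker, linkers_loop, T_bond,
                                mcs_now, cand_i, cand_j, order,
                                log_on, log_mcs, log_ev, log_i,
                                log_j, log_life, n_log)
    return n_log
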