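"""Numba-compiled Monte-Carlo cores for the territorial random walk.

The update scheme is random-sequential: each sweep draws a fresh permutation
of the animals, every animal makes one jump attempt, and time advances by
``1 / (n_animals * F)`` per attempt.  A move is rejected (the animal stays
put) if the target site carries foreign scent younger than the active scent
time; after the attempt the animal re-marks the site it stands on.
"""

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# shared helpers


@njit(cache=True, inline="always")
def _shuffle(order):
    for k in range(order.shape[0] - 1, 0, -1):
        j = np.random.randint(0, k + 1)
        tmp = order[k]
        order[k] = order[j]
        order[j] = tmp


@njit(cache=True, inline="always")
def _active(owner, mark_t, site, t, t_as, me):
    """True if ``site`` carries active scent of an animal other than ``me``."""
    ow = owner[site]
    return ow >= 0 and ow != me and (t - mark_t[site]) < t_as


# ---------------------------------------------------------------------------
# 1D ring


@njit(cache=True)
def _arc_bounds(owner, mark_t, t, t_as, animal, lo_hi):
    """Active-scent arc [lo, hi] (hi unwrapped >= lo) of one animal.

    The sites an animal visited within the last T_AS form a contiguous arc
    on the ring (the range of a continuous path), so the arc is the
    complement of the largest circular gap between its active sites.
    Returns False if the animal currently has no active scent.
    """
    n = owner.shape[0]
    count = 0
    first = -1
    prev = -1
    max_gap = -1
    gap_end = -1
    for s in range(n):
        if owner[s] == animal and (t - mark_t[s]) < t_as:
            if first < 0:
                first = s
            else:
                g = s - prev - 1
                if g > max_gap:
                    max_gap = g
                    gap_end = s
            prev = s
            count += 1
    if count == 0:
        return False
    # wrap-around gap between last and first active site
    g = (first + n) - prev - 1
    if g >= max_gap:
        max_gap = g
        gap_end = first
    if max_gap <= 0 and count == n:
        lo_hi[0] = 0
        lo_hi[1] = n - 1
        return True
    lo = gap_end
    span = n - max_gap - 1
    lo_hi[0] = lo
    lo_hi[1] = lo + span
    return True


@njit(cache=True)
def _borders_ring(owner, mark_t, t, t_as, n_animals, out):
    """Border i = circular midpoint of the gap between the arcs of animal i
    and animal i+1 (CP order).  NaN where an arc is undefined."""
    n = owner.shape[0]
    lo = np.empty(n_animals, np.int64)
    hi = np.empty(n_animals, np.int64)
    ok = np.zeros(n_animals, np.bool_)
    tmp = np.empty(2, np.int64)
    for i in range(n_animals):
        if _arc_bounds(owner, mark_t, t, t_as, i, tmp):
            lo[i] = tmp[0]
            hi[i] = tmp[1]
            ok[i] = True
    for i in range(n_animals):
        j = (i + 1) % n_animals
        if ok[i] and ok[j]:
            gap = (lo[j] - hi[i]) % n
            out[i] = (hi[i] + 0.5 * gap) % n
        else:
            out[i] = np.nan


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def sweep_ring(n_sites, cp, pos, owner, mark_t, p_bias, t_as, jump_rate, t, order):
    """One random-sequential sweep of the ring model; returns the new time."""
    n_an = cp.shape[0]
    dt = 1.0 / (n_an * jump_rate)
    _shuffle(order)
    for k in range(n_an):
        i = order[k]
        d = (cp[i] - pos[i]) % n_sites
        if d == 0 or 2 * d == n_sites:
            step = 1 if np.random.random() < 0.5 else -1
        else:
            toward = 1 if d < n_sites - d else -1
            step = toward if np.random.random() < p_bias else -toward
        tgt = (pos[i] + step) % n_sites
        if not _active(owner, mark_t, tgt, t, t_as, i):
            pos[i] = tgt
        t += dt
        owner[pos[i]] = i
        mark_t[pos[i]] = t
    return t


@njit(cache=True)
def run_ring(n_sites, cp, p_bias, t_as, jump_rate, n_sweeps, record_stride, seed):
    """Simulate the 1D ring model.

    Returns (times, positions, borders) sampled every ``record_stride``
    sweeps; borders are ring coordinates in units of the lattice spacing.
    """
    np.random.seed(seed)
    n_an = cp.shape[0]
    pos = cp.copy()
    owner = np.full(n_sites, -1, np.int64)
    mark_t = np.zeros(n_sites, np.float64)
    n_rec = n_sweeps // record_stride + 1
    times = np.empty(n_rec, np.float64)
    pos_rec = np.empty((n_rec, n_an), np.int64)
    bord_rec = np.empty((n_rec, n_an), np.float64)
    order = np.arange(n_an)
    t = 0.0
    times[0] = 0.0
    for i in range(n_an):
        pos_rec[0, i] = pos[i]
    _borders_ring(owner, mark_t, t, t_as, n_an, bord_rec[0])
    irec = 1
    for sweep in range(1, n_sweeps + 1):
        t = sweep_ring(n_sites, cp, pos, owner, mark_t, p_bias, t_as, jump_rate, t, order)
        if sweep % record_stride == 0:
            times[irec] = t
            for i in range(n_an):
                pos_rec[irec, i] = pos[i]
            _borders_ring(owner, mark_t, t, t_as, n_an, bord_rec[irec])
            irec += 1
    return times, pos_rec, bord_rec


# ---------------------------------------------------------------------------
# 2D torus


@njit(cache=True, inline="always")
def _wrap_delta(dx, size):
    """Minimal-image displacement on a periodic axis."""
    if dx > size / 2:
        dx -= size
    elif dx < -size / 2:
        dx += size
    return dx


@njit(cache=True)
def _move_probs_2d(px, py, cx, cy, Lx, Ly, p_bias):
    """Probabilities of the four moves (+x, -x, +y, -y).

    P(+-x) = (1 +- (2p-1) ux) / 4 with u the unit vector toward the CP
    (minimal image); at the CP all four are 1/4.  Invariant under rescaling
    of the displacement vector, so the drift magnitude is independent of the
    distance to the CP.
    """
    dx = _wrap_delta(float(cx - px), Lx)
    dy = _wrap_delta(float(cy - py), Ly)
    norm = np.sqrt(dx * dx + dy * dy)
    b = 2.0 * p_bias - 1.0
    if norm == 0.0:
        ux = 0.0
        uy = 0.0
    else:
        ux = dx / norm
        uy = dy / norm
    out = np.empty(4, np.float64)
    out[0] = 0.25 * (1.0 + b * ux)
    out[1] = 0.25 * (1.0 - b * ux)
    out[2] = 0.25 * (1.0 + b * uy)
    out[3] = 0.25 * (1.0 - b * uy)
    return out


@njit(cache=True)
def _radius_profile(owner, mark_t, t, t_as, Lx, Ly, cx, cy, animal, n_rays, out):
    """March outward along each bearing; out[k] = distance (lattice units)
    to the last own-territory site before leaving its connected component.

    A scent territory is the trace of a lattice walk and contains one-site
    holes, so the march tolerates unclaimed gaps up to GAP_TOL sites wide;
    active foreign scent, or a wider gap, terminates the ray.  0 for an
    empty ray.
    """
    step = 0.5
    gap_tol = 2.0
    rmax = 0.5 * min(Lx, Ly)
    for k in range(n_rays):
        th = 2.0 * np.pi * k / n_rays
        cth = np.cos(th)
        sth = np.sin(th)
        r = 0.0
        s = 0.0
        while s <= rmax:
            x = int(np.floor(cx + s * cth + 0.5)) % Lx
            y = int(np.floor(cy + s * sth + 0.5)) % Ly
            site = y * Lx + x
            ow = owner[site]
            live = ow >= 0 and (t - mark_t[site]) < t_as
            if live and ow == animal:
                r = s
            elif live:
                break  # foreign territory starts here
            elif s - r > gap_tol:
                break  # left the connected component
            s += step
        out[k] = r


@njit(cache=True)
def sweep_torus(Lx, Ly, cps, posx, posy, owner, mark_t, p_bias, t_as, jump_rate, t, order):
    """One random-sequential sweep of the torus model; returns the new time."""
    n_an = cps.shape[0]
    dt = 1.0 / (n_an * jump_rate)
    _shuffle(order)
    for k in range(n_an):
        i = order[k]
        pr = _move_probs_2d(posx[i], posy[i], cps[i, 0], cps[i, 1], Lx, Ly, p_bias)
        u = np.random.random()
        if u < pr[0]:
            sx, sy = 1, 0
        elif u < pr[0] + pr[1]:
            sx, sy = -1, 0
        elif u < pr[0] + pr[1] + pr[2]:
            sx, sy = 0, 1
        else:
            sx, sy = 0, -1
        tx = (posx[i] + sx) % Lx
        ty = (posy[i] + sy) % Ly
        site = ty * Lx + tx
        if not _active(owner, mark_t, site, t, t_as, i):
            posx[i] = tx
            posy[i] = ty
        t += dt
        here = posy[i] * Lx + posx[i]
        owner[here] = i
        mark_t[here] = t
    return t


@njit(cache=True)
def run_torus(Lx, Ly, cps, p_bias, t_as, jump_rate, n_sweeps, record_stride, n_rays, seed):
    """Simulate the 2D torus model with hexagonally arranged CPs.

    Returns (times, positions (n_rec, n, 2), radii (n_rec, n, n_rays))
    with radii in lattice units.
    """
    np.random.seed(seed)
    n_an = cps.shape[0]
    n_sites = Lx * Ly
    posx = cps[:, 0].copy()
    posy = cps[:, 1].copy()
    owner = np.full(n_sites, -1, np.int64)
    mark_t = np.zeros(n_sites, np.float64)
    n_rec = n_sweeps // record_stride + 1
    times = np.empty(n_rec, np.float64)
    pos_rec = np.empty((n_rec, n_an, 2), np.int64)
    rad_rec = np.zeros((n_rec, n_an, n_rays), np.float64)
    order = np.arange(n_an)
    t = 0.0
    times[0] = 0.0
    for i in range(n_an):
        pos_rec[0, i, 0] = posx[i]
        pos_rec[0, i, 1] = posy[i]
    irec = 1
    for sweep in range(1, n_sweeps + 1):
        t = sweep_torus(Lx, Ly, cps, posx, posy, owner, mark_t, p_bias, t_as, jump_rate, t, order)
        if sweep % record_stride == 0:
            times[irec] = t
            for i in range(n_an):
                pos_rec[irec, i, 0] = posx[i]
                pos_rec[irec, i, 1] = posy[i]
                _radius_profile(
                    owner, mark_t, t, t_as, Lx, Ly,
                    float(cps[i, 0]), float(cps[i, 1]), i, n_rays,
                    rad_rec[irec, i],
                )
            irec += 1
    return times, pos_rec, rad_rec
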