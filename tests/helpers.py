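"""Shared oracles and utilities for the test suite.

Everything here is deliberately independent of the implementation paths it
checks: the Fokker-Planck integrator is a direct Crank-Nicolson scheme, the
confined-walker oracles are plain vectorised numpy simulations, and the KS
helpers work on raw samples.
"""

from __future__ import annotations

import numpy as np


def crank_nicolson_fp(K: float, lam: float, centre: float, lo: float, hi: float,
                      n_cells: int = 1200, dt: float | None = None, t_end: float = 60.0):
    """Integrate dP/du = K P_zz + lam (P (z - centre))_z with zero-flux walls.

    Conservative finite-volume Crank-Nicolson; returns (cell centres, P)
    after integrating to ``t_end`` (many relaxation times) from a uniform
    start.  Serves as the long-time PDE oracle for the steady-state border
    and radius formulas.
    """
    from scipy.linalg import solve_banded

    if dt is None:
        dt = t_end / 8000.0
    dz = (hi - lo) / n_cells
    z = lo + (np.arange(n_cells) + 0.5) * dz
    zf = lo + np.arange(1, n_cells) * dz        # interior faces

    # dP/dt = A P from interface fluxes J_f = -K (P_{i+1}-P_i)/dz
    #         - lam (z_f - centre) (P_i + P_{i+1})/2 ; boundary fluxes zero.
    A = np.zeros((n_cells, n_cells))
    idx = np.arange(n_cells)
    for f in range(n_cells - 1):
        a_f = lam * (zf[f] - centre)
        i = f
        # dP_i/dt += -J_f/dz ; dP_{i+1}/dt += +J_f/dz
        A[i, i] += (-K / dz + a_f / 2.0) / dz
        A[i, i + 1] += (K / dz + a_f / 2.0) / dz
        A[i + 1, i] += (K / dz - a_f / 2.0) / dz
        A[i + 1, i + 1] += (-K / dz - a_f / 2.0) / dz

    P = np.full(n_cells, 1.0 / (hi - lo))
    M1 = np.eye(n_cells) - 0.5 * dt * A
    M2 = np.eye(n_cells) + 0.5 * dt * A
    ab = np.zeros((3, n_cells))
    ab[0, 1:] = M1[idx[:-1], idx[:-1] + 1]
    ab[1, :] = M1[idx, idx]
    ab[2, :-1] = M1[idx[1:], idx[1:] - 1]
    n_steps = int(t_end / dt)
    check = max(1, n_steps // 50)
    for s in range(n_steps):
        rhs = M2 @ P
        P_new = solve_banded((1, 1), ab, rhs)
        if s % check == 0 and np.abs(P_new - P).max() < 1e-13:
            P = P_new
            break
        P = P_new
    P = np.maximum(P, 0.0)
    P /= np.sum(P) * dz
    return z, P


def walker_1d_confined(p_toward: float, n_sites_left: int, n_sites_right: int,
                       n_walkers: int, n_steps: int, seed: int):
    """Biased 1D lattice walker on sites [-n_left, n_right] with reflecting
    walls; bias toward site 0.  Returns final positions of all walkers
    pooled over the last quarter of the run."""
    rng = np.random.default_rng(seed)
    pos = np.zeros(n_walkers, dtype=np.int64)
    keep = []
    for s in range(n_steps):
        toward = -np.sign(pos)
        toward[toward == 0] = rng.integers(0, 2, size=(toward == 0).sum()) * 2 - 1
        step = np.where(rng.random(n_walkers) < p_toward, toward, -toward)
        new = pos + step
        new = np.clip(new, -n_sites_left, n_sites_right)
        pos = new
        if s >= 3 * n_steps // 4 and s % 20 == 0:
            keep.append(pos.copy())
    return np.concatenate(keep)


def walker_2d_disc(p_bias: float, R_sites: int, n_walkers: int, n_steps: int, seed: int):
    """Biased 2D lattice walker confined to a disc of radius R_sites around
    the CP at the origin (moves leaving the disc are rejected).  Bias kernel
    (1 +- (2p-1) u_i)/4 toward the origin.  Returns pooled positions."""
    rng = np.random.default_rng(seed)
    x = np.zeros(n_walkers)
    y = np.zeros(n_walkers)
    b = 2.0 * p_bias - 1.0
    keep = []
    for s in range(n_steps):
        r = np.hypot(x, y)
        ux = np.where(r > 0, -x / np.maximum(r, 1e-12), 0.0)
        uy = np.where(r > 0, -y / np.maximum(r, 1e-12), 0.0)
        pr_px = 0.25 * (1 + b * ux)
        pr_mx = 0.25 * (1 - b * ux)
        pr_py = 0.25 * (1 + b * uy)
        u = rng.random(n_walkers)
        dx = np.where(u < pr_px, 1, np.where(u < pr_px + pr_mx, -1, 0))
        dy = np.where(dx != 0, 0, np.where(u < pr_px + pr_mx + pr_py, 1, -1))
        nx, ny = x + dx, y + dy
        ok = nx * nx + ny * ny <= R_sites * R_sites
        x = np.where(ok, nx, x)
        y = np.where(ok, ny, y)
        if s >= 3 * n_steps // 4 and s % 20 == 0:
            keep.append(np.stack([x, y], axis=1))
    return np.concatenate(keep)


def ks_distance(samples: np.ndarray, cdf_grid: np.ndarray, cdf_vals: np.ndarray) -> float:
    """Sup distance between the empirical CDF of ``samples`` and a tabulated CDF."""
    s = np.sort(samples)
    emp = np.searchsorted(s, cdf_grid, side="right") / len(s)
    return float(np.abs(emp - np.clip(cdf_vals, 0, 1)).max())


def sim_positions_dimensionless(recs, cfg, burn_fraction=0.5, jitter_seed=0):
    """Pool animal positions relative to their own CP, in units of L, with a
    +-a/2 within-cell continuity correction.  1D returns signed z; 2D radii."""
    rng = np.random.default_rng(jitter_seed)
    L = cfg.cp_sites
    cps = cfg.cp_positions()
    out = []
    if cfg.dimension == 1:
        n_sites = cfg.lattice_shape[0]
        for rec in recs:
            n0 = int(rec.positions.shape[0] * burn_fraction)
            for i in range(cfg.n_animals):
                d = (rec.positions[n0:, i] - cps[i]) % n_sites
                d = np.where(d > n_sites / 2, d - n_sites, d).astype(float)
                d += rng.uniform(-0.5, 0.5, size=d.shape)
                out.append(d / L)
    else:
        Lx, Ly = cfg.lattice_shape
        for rec in recs:
            n0 = int(rec.positions.shape[0] * burn_fraction)
            m = rec.positions.shape[0] - n0
            for i in range(cfg.n_animals):
                dx = (rec.positions[n0:, i, 0] - cps[i, 0] + Lx / 2) % Lx - Lx / 2
                dy = (rec.positions[n0:, i, 1] - cps[i, 1] + Ly / 2) % Ly - Ly / 2
                dx = dx + rng.uniform(-0.5, 0.5, size=m)
                dy = dy + rng.uniform(-0.5, 0.5, size=m)
                out.append(np.hypot(dx, dy) / L)
    return np.concatenate(out)


def relocations_from_sim(rec, cfg, animals=None, jitter_seed=0, burn_fraction=0.5):
    """Relocation DataFrame from a 2D trajectory record: minimal-image
    positions around each animal's CP with within-cell jitter."""
    import pandas as pd

    rng = np.random.default_rng(jitter_seed)
    cps = cfg.cp_positions()
    Lx, Ly = cfg.lattice_shape
    n0 = int(rec.positions.shape[0] * burn_fraction)
    m = rec.positions.shape[0] - n0
    animals = range(cfg.n_animals) if animals is None else animals
    rows = []
    for i in animals:
        dx = (rec.positions[n0:, i, 0] - cps[i, 0] + Lx / 2) % Lx - Lx / 2
        dy = (rec.positions[n0:, i, 1] - cps[i, 1] + Ly / 2) % Ly - Ly / 2
        x = cps[i, 0] + dx + rng.uniform(-0.5, 0.5, size=m)
        y = cps[i, 1] + dy + rng.uniform(-0.5, 0.5, size=m)
        for k in range(m):
            rows.append((f"a{i}", x[k], y[k], float(k)))
    return pd.DataFrame(rows, columns=["animal_id", "x", "y", "t"])
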