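"""Agent-based simulator of territorial central-place foragers.

Animals are lattice random walkers with a constant-magnitude bias toward a
central place (CP).  They deposit scent on every site they visit; scent
stays *active* for the active scent time ``T_AS`` and an animal never steps
onto a site carrying active foreign scent.  The terrain thereby subdivides
into dynamic territories.  In 1D the observable of interest is the pair of
territory borders (midpoints of the interstitial gaps between adjacent
scent arcs); in 2D it is the territory radius sampled along ``n_rays``
bearings from the CP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .config import ConfigurationError, SimConfig


@dataclass
class LatticeState:
    """Full state of a simulation: positions, scent field, CPs, clock."""

    config: SimConfig
    time: float
    positions: np.ndarray       # (n,) site index in 1D, (n, 2) in 2D
    scent_owner: np.ndarray     # flat (n_sites,), -1 for no record
    scent_time: np.ndarray      # flat (n_sites,), time of last mark
    cp_positions: np.ndarray

    def active_mask(self) -> np.ndarray:
        """Per-site owner id of currently active scent, -1 elsewhere."""
        live = (self.scent_owner >= 0) & (
            self.time - self.scent_time < self.config.active_scent_time
        )
        return np.where(live, self.scent_owner, -1)


@dataclass
class TrajectoryRecord:
    """Sampled output of one run: times, positions, border observables."""

    config: SimConfig
    times: np.ndarray            # (n_rec,)
    positions: np.ndarray        # (n_rec, n) or (n_rec, n, 2), lattice units
    borders: np.ndarray          # 1D: (n_rec, n) ring coords; 2D: radii (n_rec, n, n_rays)
    border_defined: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.config.dimension == 1:
            self.border_defined = np.isfinite(self.borders).all(axis=1)
        else:
            self.border_defined = (self.borders > 0).any(axis=(1, 2))

    def borders_unwrapped(self) -> np.ndarray:
        """1D border tracks made continuous across the periodic boundary.

        Minimal-displacement continuity: successive samples of each border
        are assumed to differ by less than half the ring; leading undefined
        samples stay NaN.
        """
        if self.config.dimension != 1:
            raise ValueError("borders_unwrapped is a 1D observable")
        n_sites = self.config.lattice_shape[0]
        b = self.borders.copy()
        out = np.full_like(b, np.nan)
        for j in range(b.shape[1]):
            track = b[:, j]
            idx = np.flatnonzero(np.isfinite(track))
            if idx.size == 0:
                continue
            vals = track[idx]
            diffs = np.diff(vals)
            diffs = (diffs + n_sites / 2) % n_sites - n_sites / 2
            out[idx, j] = np.concatenate([[vals[0]], vals[0] + np.cumsum(diffs)])
        return out * self.config.lattice_spacing


# ---------------------------------------------------------------------------


def init_state(config: SimConfig) -> LatticeState:
    """Initial state: every animal at its CP, scent field empty."""
    config.validate()
    n_sites = int(np.prod(config.lattice_shape))
    cps = config.cp_positions()
    return LatticeState(
        config=config,
        time=0.0,
        positions=cps.copy(),
        scent_owner=np.full(n_sites, -1, dtype=np.int64),
        scent_time=np.zeros(n_sites, dtype=np.float64),
        cp_positions=cps,
    )


def move_probabilities_2d(pos, cp, bias_p: float, lattice_shape=None) -> np.ndarray:
    """Probabilities of the four moves (+x, -x, +y, -y) toward/away from the CP.

    With the displacement unit vector u from the animal to the CP (minimal
    image when ``lattice_shape`` is given), the probabilities are
    ``(1 +- (2 bias_p - 1) u_i) / 4``; they sum to one, are uniform at the
    CP or at the neutral bias 1/2, and depend on the CP direction only.
    """
    pos = np.asarray(pos, dtype=float)
    cp = np.asarray(cp, dtype=float)
    if lattice_shape is None:
        Lx = Ly = np.inf
    else:
        Lx, Ly = lattice_shape
    return _kernels._move_probs_2d(pos[0], pos[1], cp[0], cp[1], Lx, Ly, bias_p)


def step(state: LatticeState, seed: int | None = None) -> LatticeState:
    """Advance the state by one random-sequential sweep (in place).

    Each animal (fresh random order) attempts one jump; a blocked animal
    stays put for that attempt; the occupied site is re-marked after each
    attempt and time advances by ``1 / (n_animals * F)`` per attempt.
    """
    cfg = state.config
    if seed is not None:
        _kernels.seed_rng(seed)
    order = np.arange(cfg.n_animals)
    if cfg.dimension == 1:
        state.time = _kernels.sweep_ring(
            cfg.lattice_shape[0], state.cp_positions, state.positions,
            state.scent_owner, state.scent_time,
            cfg.bias_p, cfg.active_scent_time, cfg.jump_rate, state.time, order,
        )
    else:
        Lx, Ly = cfg.lattice_shape
        posx = np.ascontiguousarray(state.positions[:, 0])
        posy = np.ascontiguousarray(state.positions[:, 1])
        state.time = _kernels.sweep_torus(
            Lx, Ly, state.cp_positions, posx, posy,
            state.scent_owner, state.scent_time,
            cfg.bias_p, cfg.active_scent_time, cfg.jump_rate, state.time, order,
        )
        state.positions[:, 0] = posx
        state.positions[:, 1] = posy
    return state


def extract_borders_1d(state: LatticeState) -> np.ndarray:
    """Territory borders of a 1D state, in ring coordinates (units of a).

    Border ``i`` is the midpoint of the interstitial gap between the active
    scent arcs of animal ``i`` and animal ``i+1``; NaN where either animal
    has no active scent yet.
    """
    if state.config.dimension != 1:
        raise ValueError("extract_borders_1d needs a 1D state")
    out = np.empty(state.config.n_animals, dtype=np.float64)
    _kernels._borders_ring(
        state.scent_owner, state.scent_time, state.time,
        state.config.active_scent_time, state.config.n_animals, out,
    )
    return out


def extract_radius_profile_2d(state: LatticeState, animal_id: int, n_rays: int | None = None) -> np.ndarray:
    """Territory radius along equally spaced bearings from the CP (units of a).

    Marches outward along each bearing and reports the distance to the last
    site of the animal's connected scent territory; 0 for an empty ray.
    """
    if state.config.dimension != 2:
        raise ValueError("extract_radius_profile_2d needs a 2D state")
    cfg = state.config
    n_rays = cfg.n_rays if n_rays is None else n_rays
    Lx, Ly = cfg.lattice_shape
    out = np.empty(n_rays, dtype=np.float64)
    _kernels._radius_profile(
        state.scent_owner, state.scent_time, state.time, cfg.active_scent_time,
        Lx, Ly, float(cfg.cp_positions()[animal_id, 0]),
        float(cfg.cp_positions()[animal_id, 1]), animal_id, n_rays, out,
    )
    return out


def run_simulation(config: SimConfig, seed: int | None = None) -> TrajectoryRecord:
    """Run the model for ``t_max`` and record observables every ``record_every``.

    Bit-reproducible for a fixed seed.  1D records border positions (ring
    coordinates, lattice units); 2D records the radius profile of every
    territory along ``n_rays`` bearings.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    n_sweeps = max(1, round(config.t_max * config.jump_rate))
    stride = max(1, round(config.record_every * config.jump_rate))
    if n_sweeps // stride < 1:
        raise ConfigurationError("t_max must cover at least one record interval")
    if config.dimension == 1:
        times, pos, borders = _kernels.run_ring(
            config.lattice_shape[0], config.cp_positions(),
            config.bias_p, config.active_scent_time, config.jump_rate,
            n_sweeps, stride, seed,
        )
    else:
        Lx, Ly = config.lattice_shape
        times, pos, borders = _kernels.run_torus(
            Lx, Ly, config.cp_positions(),
            config.bias_p, config.active_scent_time, config.jump_rate,
            n_sweeps, stride, config.n_rays, seed,
        )
    return TrajectoryRecord(config=config, times=times, positions=pos, borders=borders)


def run_replicates(config: SimConfig, n_replicates: int, seed: int) -> list[TrajectoryRecord]:
    """Run an ensemble of independent replicates with per-replicate seeds
    split from ``seed``."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_replicates)]
    return [run_simulation(config, seed=s) for s in seeds]
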