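import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from terriforage.config import SimConfig
from terriforage.lattice import (
    LatticeState,
    extract_borders_1d,
    extract_radius_profile_2d,
    init_state,
    move_probabilities_2d,
    run_replicates,
    run_simulation,
    step,
)


# ---------------------------------------------------------------------------
# initial state


def test_init_state_animals_at_cps_and_empty_scent():
    for cfg in (SimConfig(dimension=1, cp_sites=10),
                SimConfig(dimension=2, cp_sites=8)):
        s = init_state(cfg)
        assert np.array_equal(s.positions, s.cp_positions)
        assert np.all(s.scent_owner == -1)
        assert s.time == 0.0


# ---------------------------------------------------------------------------
# 2D move kernel


def test_move_probabilities_uniform_at_cp_and_neutral_bias():
    np.testing.assert_allclose(move_probabilities_2d((5, 5), (5, 5), 0.9), 0.25)
    np.testing.assert_allclose(move_probabilities_2d((2, 9), (17, 3), 0.5), 0.25)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    px=st.integers(-40, 40), py=st.integers(-40, 40),
    cx=st.integers(-40, 40), cy=st.integers(-40, 40),
    p=st.floats(0.5, 1.0),
)
def test_move_probabilities_sum_to_one_and_drift_toward_cp(px, py, cx, cy, p):
    pr = np.asarray(move_probabilities_2d((px, py), (cx, cy), p))
    assert np.all(pr >= 0)
    assert pr.sum() == pytest.approx(1.0, abs=1e-12)
    disp = np.array([pr[0] - pr[1], pr[2] - pr[3]])  # expected single step
    to_cp = np.array([cx - px, cy - py], dtype=float)
    if np.linalg.norm(to_cp) > 0 and p > 0.5:
        # expected displacement is parallel to the CP direction
        assert float(disp @ to_cp) >= 0
        cross = disp[0] * to_cp[1] - disp[1] * to_cp[0]
        assert abs(cross) < 1e-12 * max(1.0, np.linalg.norm(to_cp))


def test_move_probabilities_scale_invariant():
    a = move_probabilities_2d((0, 0), (3, 4), 0.8)
    b = move_probabilities_2d((0, 0), (30, 40), 0.8)
    np.testing.assert_allclose(a, b, atol=1e-14)


# ---------------------------------------------------------------------------
# exclusion and expiry rules (hand-built states)


def _tiny_1d_state(t_as=100.0):
    cfg = SimConfig(dimension=1, cp_sites=5, active_scent_time=t_as, bias_p=1.0)
    return cfg, init_state(cfg)


def test_blocked_by_active_foreign_scent_stays_put():
    cfg, s = _tiny_1d_state()
    # animal 0 at site 0 wants to move right (bias_p=1 toward CP is ambiguous
    # at the CP), so force the geometry: put animal 0 at site 4, CP at 0 ->
    # it always steps left to 3; mark site 3 with fresh foreign scent.
    s.positions[0] = 4
    s.scent_owner[3] = 1
    s.scent_time[3] = 0.0
    s.time = 10.0  # age 10 < T_AS
    step(s, seed=1)
    assert s.positions[0] == 4
    assert s.scent_owner[4] == 0  # re-marked its own site after the attempt


def test_expired_foreign_scent_does_not_block():
    cfg, s = _tiny_1d_state(t_as=5.0)
    s.positions[0] = 4
    s.scent_owner[3] = 1
    s.scent_time[3] = 0.0
    s.time = 10.0  # age 10 >= T_AS -> expired
    step(s, seed=1)
    assert s.positions[0] == 3
    assert s.scent_owner[3] == 0  # ownership transferred to the mover


# ---------------------------------------------------------------------------
# trajectory-level contracts


def test_run_simulation_deterministic_given_seed():
    cfg = SimConfig(dimension=1, cp_sites=10, t_max=500, record_every=5,
                    ).with_dimensionless(beta=2.0, Z=1.0)
    r1 = run_simulation(cfg, seed=5)
    r2 = run_simulation(cfg, seed=5)
    assert np.array_equal(r1.positions, r2.positions)
    assert np.array_equal(
        np.nan_to_num(r1.borders, nan=-1), np.nan_to_num(r2.borders, nan=-1)
    )
    r3 = run_simulation(cfg, seed=6)
    assert not np.array_equal(r1.positions, r3.positions)


def test_borders_fluctuate_without_bias():
    cfg = SimConfig(dimension=1, cp_sites=10, bias_p=0.5, t_max=5000,
                    record_every=10).with_dimensionless(Z=1.0)
    rec = run_simulation(cfg, seed=9)
    b = rec.borders_unwrapped()
    track = b[np.isfinite(b[:, 0]), 0]
    assert np.std(track) > 0.5  # borders ebb and flow


def test_ownership_disjoint_and_animal_on_own_scent():
    cfg = SimConfig(dimension=2, cp_sites=8, t_max=600, record_every=600,
                    ).with_dimensionless(beta=2.0, Z=2.0)
    s = init_state(cfg)
    for sweep in range(500):
        step(s)
    active = s.active_mask()
    # ownership is single-valued by construction; every animal stands on a
    # site whose active scent, if any, is its own
    for i in range(cfg.n_animals):
        site = s.positions[i, 1] * cfg.lattice_shape[0] + s.positions[i, 0]
        assert active[site] in (-1, i)
    # at most one owner per site is structural; check the active counts add up
    owners, counts = np.unique(active[active >= 0], return_counts=True)
    assert counts.sum() == (active >= 0).sum()


def test_free_diffusion_matches_lattice_constant():
    """With T_AS=0 and no bias, the per-animal MSD is linear with slope
    2 d D t per the package's own diffusion constants."""
    # ~6000 independent walkers so the 5% band sits at ~3 ensemble sigmas
    cfg = SimConfig(dimension=1, cp_sites=1000, bias_p=0.5,
                    active_scent_time=0.0, t_max=1000, record_every=10)
    recs = run_replicates(cfg, 3000, seed=31)
    n = cfg.lattice_shape[0]
    msds = []
    for rec in recs:
        d = rec.positions - rec.positions[0]
        d = (d + n // 2) % n - n // 2
        msds.append((d.astype(float) ** 2).mean(axis=1))
    msd = np.mean(msds, axis=0)
    t = recs[0].times
    slope = np.polyfit(t[1:], msd[1:], 1)[0]
    assert slope == pytest.approx(2 * cfg.diffusion_constant, rel=0.05)


# ---------------------------------------------------------------------------
# border / radius observables


def test_extract_borders_midgap_definition():
    cfg = SimConfig(dimension=1, cp_sites=10, active_scent_time=1e6)
    s = init_state(cfg)
    s.time = 1.0
    # animal 0's arc covers sites 18..7 (wrapping), animal 1's sites 10..15:
    for site in list(range(0, 8)) + [18, 19]:
        s.scent_owner[site] = 0
        s.scent_time[site] = 1.0
    for site in range(10, 16):
        s.scent_owner[site] = 1
        s.scent_time[site] = 1.0
    b = extract_borders_1d(s)
    # gap between 7 and 10 -> border 8.5; gap between 15 and 18 -> 16.5
    assert sorted(b) == [8.5, 16.5]
    # juxtaposed blocks: extend animal 1 to sites 8..9 -> border at 7.5
    for site in (8, 9):
        s.scent_owner[site] = 1
        s.scent_time[site] = 1.0
    b2 = extract_borders_1d(s)
    assert 7.5 in b2.tolist()


def test_symmetric_initial_marks_give_borders_at_half_L():
    cfg = SimConfig(dimension=1, cp_sites=10, active_scent_time=1e6)
    s = init_state(cfg)
    s.time = 1.0
    for i, cp in enumerate(s.cp_positions):
        s.scent_owner[cp] = i
        s.scent_time[cp] = 1.0
    b = np.sort(extract_borders_1d(s))
    np.testing.assert_allclose(b, [5.0, 15.0])


def test_border_undefined_without_scent():
    cfg = SimConfig(dimension=1, cp_sites=10, active_scent_time=100.0)
    s = init_state(cfg)
    assert np.all(np.isnan(extract_borders_1d(s)))


def test_radius_profile_on_exact_disc():
    cfg = SimConfig(dimension=2, cp_sites=16, active_scent_time=1e6, n_rays=8)
    s = init_state(cfg)
    s.time = 1.0
    Lx, Ly = cfg.lattice_shape
    cx, cy = s.cp_positions[0]
    for x in range(Lx):
        for y in range(Ly):
            dx = (x - cx + Lx // 2) % Lx - Lx // 2
            dy = (y - cy + Ly // 2) % Ly - Ly // 2
            if dx * dx + dy * dy <= 25:
                s.scent_owner[y * Lx + x] = 0
                s.scent_time[y * Lx + x] = 1.0
    r = extract_radius_profile_2d(s, 0)
    assert np.all(np.abs(r - 5.0) <= 1.0)
    # shared bearings agree between n_rays=4 and n_rays=8
    r4 = extract_radius_profile_2d(s, 0, n_rays=4)
    r8 = extract_radius_profile_2d(s, 0, n_rays=8)
    np.testing.assert_allclose(r4, r8[::2])
    # mean over rays ~ sqrt(area/pi) for this convex territory
    area = (s.active_mask() == 0).sum()
    assert np.mean(r8) == pytest.approx(np.sqrt(area / np.pi), rel=0.15)


def test_radius_profile_empty_territory_flags_zero():
    cfg = SimConfig(dimension=2, cp_sites=8, active_scent_time=10.0)
    s = init_state(cfg)
    assert np.all(extract_radius_profile_2d(s, 0) == 0.0)


def test_2d_territories_disjoint_every_sample():
    cfg = SimConfig(dimension=2, cp_sites=8, t_max=2000, record_every=100,
                    ).with_dimensionless(beta=4.0, Z=4.0)
    rec = run_simulation(cfg, seed=3)
    assert rec.positions.shape[1] == 30
    # exclusion implies pairwise disjoint site ownership, which the scent
    # field enforces structurally; verify via a fresh state replay
    s = init_state(cfg)
    for _ in range(300):
        step(s)
    active = s.active_mask()
    assert (active >= 0).sum() == sum((active == i).sum() for i in range(30))
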