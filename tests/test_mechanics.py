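import numpy as np
import pytest

from cryptsim import CellType, make_fixture
from cryptsim.mechanics import (FORWARD, RETROGRADE, contact_matrix,
                                motion_direction, neighbours, place_daughters,
                                pressure, relax)


def brute_force_neighbours(world, cell_id):
    """All-pairs oracle for contact detection."""
    idx = world.live()
    i = world.index_of[cell_id]
    radii = world.radii(idx)
    out = []
    cf = world.config.geometry.contact_factor
    for row, j in enumerate(idx):
        if j == i:
            continue
        d = np.linalg.norm(world.pos[j] - world.pos[i])
        ri = radii[int(np.flatnonzero(idx == i)[0])]
        if d < (radii[row] + ri) * cf:
            out.append(int(world.cell_id[j]))
    return sorted(out)


def test_neighbour_detection_matches_all_pairs_oracle(mini_world):
    w = mini_world
    for cid in list(w.index_of)[::3]:
        assert sorted(neighbours(w, cid)) == brute_force_neighbours(w, cid)


def test_cell_is_not_its_own_neighbour(mini_world):
    w = mini_world
    cid = next(iter(w.index_of))
    assert cid not in neighbours(w, cid)


def test_distant_cells_are_not_neighbours(overlap_pair):
    w = overlap_pair
    ids = list(w.index_of)
    i = w.index_of[ids[0]]
    w.pos[i, 2] += 3.5   # move one cell far up the crypt
    w.pos[i] = w.surface.project(w.pos[i])
    assert ids[1] not in neighbours(w, ids[0])


def test_symmetric_pair_displaces_equally_and_oppositely(overlap_pair):
    w = overlap_pair
    ids = list(w.index_of)
    i, j = (w.index_of[c] for c in ids)
    p0 = w.pos[[i, j]].copy()
    relax(w, 0.02, jitter=False)
    d_i = w.pos[i] - p0[0]
    d_j = w.pos[j] - p0[1]
    assert np.linalg.norm(d_i) > 1e-6
    # mirror symmetry about the plane between them (x components oppose)
    assert d_i[0] == pytest.approx(-d_j[0], abs=1e-9)


def test_isolated_cell_does_not_move(overlap_pair):
    w = overlap_pair
    ids = list(w.index_of)
    w.remove_cell(ids[1])
    i = w.index_of[ids[0]]
    p0 = w.pos[i].copy()
    relax(w, 0.02, jitter=False)
    assert np.linalg.norm(w.pos[i] - p0) < 1e-12


def test_isolated_cell_has_zero_pressure(overlap_pair):
    w = overlap_pair
    ids = list(w.index_of)
    w.remove_cell(ids[1])
    assert pressure(w, ids[0]) == 0.0


def test_pressure_increases_with_overlap(overlap_pair):
    w = overlap_pair
    ids = list(w.index_of)
    p1 = pressure(w, ids[0])
    i = w.index_of[ids[1]]
    # push the neighbour closer (deeper overlap)
    w.pos[i] = w.surface.project(w.pos[i] * [0.5, 1.0, 1.0]
                                 + w.pos[w.index_of[ids[0]]] * [0.5, 0.0, 0.0])
    p2 = pressure(w, ids[0])
    assert p2 > p1 > 0


def test_paneth_displaces_less_than_stem_under_equal_force(overlap_pair):
    w = overlap_pair
    ids = list(w.index_of)
    i, j = (w.index_of[c] for c in ids)
    w.ctype[i] = int(CellType.PANETH)
    w.ctype[j] = int(CellType.STEM)
    cfg = w.config.mechanics
    cfg.paneth_anchor = 0.0     # isolate the drag effect
    p0 = w.pos[[i, j]].copy()
    relax(w, 0.02, jitter=False)
    disp_paneth = np.linalg.norm(w.pos[i] - p0[0])
    disp_stem = np.linalg.norm(w.pos[j] - p0[1])
    assert disp_paneth < disp_stem


def test_niche_pressure_exceeds_transit_pressure(homeostasis_runs):
    w = homeostasis_runs[0]["world"]
    idx = w.live()
    niche = w.surface.in_niche(w.pos[idx])
    ta = (~niche) & (w.ctype[idx] == CellType.ABSORPTIVE_PROGENITOR)
    assert w.pressure[idx[niche]].mean() > w.pressure[idx[ta]].mean()


def test_division_splits_mass_wnt_and_label_in_half(mini_world):
    w = mini_world
    idx = w.live()
    cyclers = idx[w.has_cycle[idx]]
    i = int(cyclers[0])
    cid = int(w.cell_id[i])
    w.mass[i] = 2.0
    w.wnt[i] = 8.0
    w.brdu[i] = 1.0
    da, db = place_daughters(w, cid)
    ia, ib = w.index_of[da], w.index_of[db]
    assert w.mass[ia] == w.mass[ib] == pytest.approx(1.0)
    assert w.wnt[ia] + w.wnt[ib] == pytest.approx(8.0)   # exact conservation
    assert w.brdu[ia] == w.brdu[ib] == pytest.approx(0.5)
    assert cid not in w.index_of                          # mother id retired


def test_motion_direction_classification():
    t = np.linspace(0, 4, 9)
    up = 5.0 + 0.2 * t
    down = 5.0 - 0.2 * t
    flat = np.full_like(t, 5.0)
    theta = np.full_like(t, np.pi / 2)
    assert motion_direction(up, theta, in_niche=False) == FORWARD
    assert motion_direction(down, theta, in_niche=False) == RETROGRADE
    # tie-break: zero velocity counts as forward
    assert motion_direction(flat, theta, in_niche=False) == FORWARD
    # inside the niche the polar angle decides, even at the crypt base
    z_base = np.full_like(t, 0.4)
    th_down = np.pi / 4 - 0.05 * t
    assert motion_direction(z_base, th_down, in_niche=True) == RETROGRADE
    with pytest.raises(ValueError):
        motion_direction([1.0], [0.5], in_niche=False)


def test_surface_constraint_holds_after_relaxation(mini_world):
    w = mini_world
    for _ in range(20):
        relax(w, 0.02)
    assert w.surface.residual(w.pos[w.live()]).max() < 1e-9
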