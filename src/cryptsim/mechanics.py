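"""Off-lattice cell-centre mechanics on the crypt surface.

Cells interact through linear (Hookean) overlap springs with type-dependent
stiffness; motion is overdamped and constrained to the surface by projection
after every step. Paneth cells are stiffer and their drag scales with
stiffness, so they displace less under equal force. Pressure on a cell is the
stiffness-weighted sum of positive overlaps with its neighbours, the input to
contact inhibition of proliferation.
"""
from __future__ import annotations

import numpy as np

from .state import World

FORWARD = "FORWARD"
RETROGRADE = "RETROGRADE"


class MechanicsInstability(RuntimeError):
    pass


def _pairwise(world: World, idx: np.ndarray):
    """Distance matrix, summed radii and contact mask for live cells."""
    pos = world.pos[idx]
    radii = world.radii(idx)
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    rsum = radii[:, None] + radii[None, :]
    np.fill_diagonal(dist, np.inf)
    return diff, dist, rsum


def neighbours(world: World, cell_id: int) -> list[int]:
    """Cells whose centre distance is below the contact cutoff (symmetric)."""
    idx = world.live()
    i = world.index_of[cell_id]
    pos = world.pos[idx]
    radii = world.radii(idx)
    self_row = int(np.flatnonzero(idx == i)[0])
    d = np.linalg.norm(pos - world.pos[i], axis=1)
    cutoff = (radii + radii[self_row]) * world.config.geometry.contact_factor
    mask = d < cutoff
    mask[self_row] = False
    return [int(c) for c in world.cell_id[idx[mask]]]


def contact_matrix(world: World, idx: np.ndarray) -> np.ndarray:
    """Boolean contact matrix for the given live indices (brute force)."""
    _, dist, rsum = _pairwise(world, idx)
    return dist < rsum * world.config.geometry.contact_factor


def pressure(world: World, cell_id: int) -> float:
    """Stiffness-weighted sum of positive overlaps (A.U., >= 0)."""
    idx = world.live()
    i = world.index_of[cell_id]
    row = int(np.flatnonzero(idx == i)[0])
    _, dist, rsum = _pairwise(world, idx)
    k = world.stiffness(idx)
    kref = world.config.mechanics.spring_stiffness
    kij = 2.0 * k[row] * k / (k[row] + k) / kref
    overlap = np.maximum(0.0, rsum[row] - dist[row])
    return float(np.sum(overlap * kij))


def relax(world: World, dt: float, jitter: bool = True) -> None:
    """One overdamped relaxation step; updates cached pressures and Delta
    contact counts as side effects. Contact detection uses a k-d tree over
    cell centres (equivalent to the all-pairs scan; see tests)."""
    from scipy.spatial import cKDTree

    idx = world.live()
    n = len(idx)
    if n == 0:
        return
    mech = world.config.mechanics
    cf = world.config.geometry.contact_factor
    pos = world.pos[idx]
    radii = world.radii(idx)
    k = world.stiffness(idx)

    rmax = 2.0 * radii.max() * cf
    pairs = cKDTree(pos).query_pairs(rmax, output_type="ndarray")
    force = np.zeros((n, 3))
    press = np.zeros(n)
    dcount = np.zeros(n)
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        d = pos[i] - pos[j]
        dist = np.linalg.norm(d, axis=1)
        rsum = radii[i] + radii[j]
        overlap = np.maximum(0.0, rsum - dist)
        kij = 2.0 * k[i] * k[j] / (k[i] + k[j])   # springs in series (forces)
        fvec = (kij * overlap / np.maximum(dist, 1e-9))[:, None] * d
        np.add.at(force, i, fvec)
        np.add.at(force, j, -fvec)
        pr = overlap * kij / mech.spring_stiffness
        np.add.at(press, i, pr)
        np.add.at(press, j, pr)
        from .state import DELTA_STRENGTH
        presenter = np.zeros(n)
        for ct, wgt in DELTA_STRENGTH.items():
            presenter[world.ctype[idx] == ct] = wgt
        contact = (dist < rsum * cf).astype(float)
        np.add.at(dcount, i, contact * presenter[j])
        np.add.at(dcount, j, contact * presenter[i])

    # Paneth cells are anchored toward the crypt base (niche retention)
    if mech.paneth_anchor > 0:
        from .state import CellType
        pan = np.flatnonzero(world.ctype[idx] == CellType.PANETH)
        if len(pan):
            pp = pos[pan]
            R = world.surface.R
            on_cap = pp[:, 2] < R
            direc = np.zeros((len(pan), 3))
            direc[~on_cap] = (0.0, 0.0, -1.0)
            if np.any(on_cap):
                theta = np.arccos(np.clip((R - pp[on_cap, 2]) / R, -1, 1))
                phi = np.arctan2(pp[on_cap, 1], pp[on_cap, 0])
                # anchoring fades toward the pole (sin theta), where the
                # meridian direction degenerates
                direc[on_cap] = -np.sin(theta)[:, None] * np.column_stack([
                    np.cos(theta) * np.cos(phi),
                    np.cos(theta) * np.sin(phi),
                    np.sin(theta)])
            force[pan] += mech.paneth_anchor * direc

    drag = mech.drag * (k / mech.spring_stiffness)
    from .state import CellType
    drag[world.ctype[idx] == CellType.PANETH] = \
        mech.drag * mech.paneth_drag_factor
    disp = force / drag[:, None] * dt
    norms = np.linalg.norm(disp, axis=1)
    maxd = norms.max() if n else 0.0
    if maxd > 2.0 * mech.max_step_displacement:
        raise MechanicsInstability(
            f"mechanical step displacement {maxd:.3f} CD exceeds "
            f"{2 * mech.max_step_displacement} CD; reduce dt or stiffness")
    # velocity saturation: transient deep overlaps (e.g. just after division
    # in a crowded cap) relax over a few steps instead of overshooting
    over = norms > 0.3
    if np.any(over):
        disp[over] *= (0.3 / norms[over])[:, None]
    newpos = pos + disp
    if jitter and mech.jitter > 0:
        newpos += mech.jitter * np.sqrt(dt) * world.rng.standard_normal(newpos.shape)
    world.pos[idx] = world.surface.project(newpos)
    world.pressure[idx] = press
    # smoothed pressure feeds contact inhibition (filters fast fluctuations)
    tau = world.config.cycle.pressure_tau
    a = min(1.0, dt / tau)
    world.pressure_ema[idx] += a * (press - world.pressure_ema[idx])
    world._delta_contacts[idx] = dcount


def place_daughters(world: World, mother_id: int):
    """Replace a divided mother by two daughters at +/- epsilon along a random
    tangent. Mass, tethered Wnt and BrdU label are split in half; the
    division counter advances for committed progenitors."""
    from .state import CellType
    i = world.index_of[mother_id]
    sep = world.config.mechanics.division_separation
    tangent = world.surface.random_tangent(world.pos[i], world.rng)
    ctype = CellType(int(world.ctype[i]))

    base = dict(
        mass=world.mass[i] / 2.0, wnt=world.wnt[i] / 2.0,
        brdu=world.brdu[i] / 2.0, notch=world.notch[i],
        dna=world.dna_damage[i], rna=world.rna_damage[i], p21=world.p21[i],
        k27=world.k27[i], mu=world.mu[i], pema=world.pressure_ema[i],
        divisions=world.divisions[i] + (1 if ctype != CellType.STEM else 0),
        cyc=world.cyc[i].copy(),
        left_niche=world.left_niche[i], type_changed=world.type_changed[i],
        stem_since=world.stem_since[i],
    )
    mother_pos = world.pos[i].copy()
    world.remove_cell(mother_id)

    out = []
    for sgn in (+1.0, -1.0):
        p = world.surface.project(mother_pos + sgn * sep * tangent)
        cid = world.new_cell(ctype, p, mass=base["mass"])
        j = world.index_of[cid]
        world.wnt[j] = base["wnt"]
        world.brdu[j] = base["brdu"]
        world.notch[j] = base["notch"]
        world.dna_damage[j] = base["dna"]
        world.rna_damage[j] = base["rna"]
        world.p21[j] = base["p21"]
        world.k27[j] = base["k27"]
        world.mu[j] = base["mu"]
        world.pressure_ema[j] = base["pema"]
        world.divisions[j] = base["divisions"]
        world.cyc[j] = base["cyc"]
        world.has_cycle[j] = True
        world.phase[j] = 0              # daughters re-enter the cycle in G1
        world.b_m_entry[j] = 0.0
        world.cycle_start_time[j] = world.time
        world.stem_since[j] = base["stem_since"]
        # residency/type flags restart at birth (used for cycle-duration stats)
        world.type_changed[j] = False
        world.left_niche[j] = False
        world.entered_niche[j] = False
        out.append(cid)
    return tuple(out)


def motion_direction(zs: np.ndarray, thetas: np.ndarray, in_niche: bool) -> str:
    """Classify a recorded track as FORWARD or RETROGRADE.

    Outside the niche the sign of the mean dz/dt decides; inside the
    hemispherical niche the sign of the mean polar-angle rate decides, so a
    cell at the crypt base can still move retrogradely. Zero net motion
    counts as FORWARD (retrograde is a strict event).
    """
    zs = np.asarray(zs, dtype=float)
    if len(zs) < 2:
        raise ValueError("need at least two recorded positions")
    if in_niche:
        rate = np.mean(np.diff(np.asarray(thetas, dtype=float)))
    else:
        rate = np.mean(np.diff(zs))
    return RETROGRADE if rate < 0.0 else FORWARD
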