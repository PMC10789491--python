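"""World initialization and the per-tick update loop.

Update order within one tick: pharmacokinetics and drug schedules ->
signalling fields -> per-cell cycle network -> divisions -> fate decisions ->
interventions (ablation, BrdU) -> apoptotic clearance -> mechanics
relaxation -> villus transfer/shedding -> observers. Time advances by dt at
the end of the tick. A single seeded RNG stream with fixed draw order makes
runs bit-reproducible.
"""
from __future__ import annotations

import warnings

import numpy as np

from . import cycle as cyc
from .config import ConfigurationError, SimulationConfig
from .cycle import (APC_TRIGGER, THETA_A, THETA_DIV, THETA_E, THETA_W,
                    k27_for_pressure, period_from_k27, rk4_step)
from .fate import AblationSchedule, ablate_stem, apply_fate_decisions, \
    mark_apoptotic
from .geometry import CryptSurface
from .mechanics import place_daughters, relax
from .observers import brdu_pulse
from .pharmacology import (APOPTOSIS, CDK1Schedule, PKState,
                           checkpoint_decision, integrate_pk)
from .signalling import mesenchymal_ring, update_notch, update_wnt
from .state import (CYC_A, CYC_B, CYC_E, CYC_P, CYC_W, CellType, G1, G2, M,
                    S, World)
from .villus import VillusCompartment, transfer_and_shed

_REF_TRAJ_CACHE: dict[float, tuple[np.ndarray, np.ndarray]] = {}


def _reference_trajectory(k27: float = 0.6, dt: float = 0.05):
    """One period of the free-running cycle, used to seed desynchronized
    initial protein states."""
    key = round(k27, 3)
    if key in _REF_TRAJ_CACHE:
        return _REF_TRAJ_CACHE[key]
    y = cyc.Y_G1.copy()[None, :]
    m = np.array([1.8])
    states, divs = [], []
    for i in range(int(400 / dt)):
        yp = y.copy()
        y = rk4_step(y, m, k27, dt)
        if yp[0, CYC_B] >= THETA_DIV > y[0, CYC_B] and y[0, CYC_P] > 0.3:
            divs.append(i)
        states.append(y[0].copy())
        if len(divs) >= 4:
            break
    states = np.array(states)
    seg = states[divs[-2]:divs[-1]]
    phases = np.array([_phase_of_traj(seg, j) for j in range(len(seg))])
    _REF_TRAJ_CACHE[key] = (seg, phases)
    return _REF_TRAJ_CACHE[key]


def _phase_of_traj(seg, j):
    """Phase along a stored one-period trajectory starting at division."""
    y = seg[j]
    if y[CYC_E] < THETA_E and y[CYC_A] < THETA_A:
        return G1
    if y[CYC_W] >= THETA_W:
        return S
    if y[CYC_A] >= THETA_A:
        return G2
    return M


def initialize_world(config: SimulationConfig) -> World:
    """Seed a crypt with an intermingled (checkerboard-like) stem/Paneth
    niche, progenitors above it, mature cells near the mouth, and a
    pre-filled villus. Deterministic given the config seed."""
    config.validate()
    g = config.geometry
    if g.niche_radius <= 0 or g.crypt_height <= 0:
        raise ConfigurationError("invalid geometry")
    world = World(config)
    surface = CryptSurface(g.niche_radius, g.crypt_height)
    world.surface = surface
    world.mesenchyme = mesenchymal_ring(surface, config.signalling.n_mesenchymal_sources)
    world.villus = VillusCompartment(config.villus,
                                     rng=np.random.default_rng(config.run.seed + 1),
                                     prefill_time=0.0)
    world.pk = PKState(config.pharmacology)
    rng = world.rng
    ic = config.init

    seg, seg_phases = _reference_trajectory()

    def seed_cycle(i, k27):
        j = rng.integers(len(seg))
        world.cyc[i] = seg[j]
        world.phase[i] = seg_phases[j]
        world.has_cycle[i] = True
        world.k27[i] = k27
        world.mu[i] = np.log(2.0) / period_from_k27(k27)
        world.mass[i] = rng.uniform(1.35, 2.3)
        world.cycle_start_time[i] = 0.0

    # hemispherical niche: alternating stem / Paneth
    cap = surface.cap_points(ic.n_niche)
    for k, p in enumerate(cap):
        ctype = CellType.STEM if k % 2 == 0 else CellType.PANETH
        cid = world.new_cell(ctype, p, mass=1.6)
        i = world.index_of[cid]
        world.wnt[i] = 35.0
        world.notch[i] = 2.0 if ctype == CellType.STEM else 0.2
        if ctype == CellType.STEM:
            seed_cycle(i, cyc.K27_SLOW)
        else:
            world.mass[i] = 1.8

    # cylinder rings: progenitors low, mature cells high
    z = surface.R + ic.ring_spacing / 2
    ring = 0
    while z < surface.mouth_z:
        offset = (ring % 2) * np.pi / ic.cells_per_ring
        for k in range(ic.cells_per_ring):
            phi = 2 * np.pi * k / ic.cells_per_ring + offset
            p = [surface.R * np.cos(phi), surface.R * np.sin(phi), z]
            u = rng.random()
            if z < ic.init_diff_boundary:
                if u < ic.init_secretory_fraction:
                    ctype = CellType.SECRETORY_PROGENITOR
                else:
                    ctype = CellType.ABSORPTIVE_PROGENITOR
            else:
                ctype = CellType.GOBLET if u < 0.10 else CellType.ENTEROCYTE
            cid = world.new_cell(ctype, p, mass=1.6)
            i = world.index_of[cid]
            world.wnt[i] = 22.0 * 2.0 ** (-(z - surface.R) / 1.0)
            world.notch[i] = 1.3 if ctype == CellType.ABSORPTIVE_PROGENITOR else 0.3
            if ctype == CellType.ABSORPTIVE_PROGENITOR:
                seed_cycle(i, cyc.K27_FAST)
                world.divisions[i] = int(np.clip((z - surface.R) / 1.5, 0, 4))
            elif ctype == CellType.SECRETORY_PROGENITOR:
                seed_cycle(i, config.fate.sp_k27)
        z += ic.ring_spacing
        ring += 1

    relax(world, config.run.dt, jitter=False)   # populate pressure/contact caches
    idx = world.live()
    for i in idx:
        world.events.append(0.0, "birth", int(world.cell_id[i]),
                            int(world.ctype[i]), float(world.pos[i, 2]),
                            detail="initial")
    return world


def step_cycles(world: World, dt: float, recorders=()):
    """Advance every active cycle network one tick; handle phase
    transitions, checkpoints, divisions and drug outcomes."""
    cfg = world.config
    cycfg = cfg.cycle
    ph = cfg.pharmacology
    idx = world.live()
    act = idx[world.has_cycle[idx] & ~world.arrested[idx] & ~world.apoptotic[idx]]
    if len(act) == 0:
        return []

    # contact inhibition: continuous pressure -> p27 production
    k27 = k27_for_pressure(world.pressure_ema[act], cycfg.k27_max,
                           cycfg.pressure_half, cycfg.pressure_exponent,
                           clamp=cycfg.k27_clamp, k27_min=cycfg.k27_min)
    sp = world.ctype[act] == CellType.SECRETORY_PROGENITOR
    k27[sp] = np.maximum(k27[sp], cfg.fate.sp_k27)
    world.k27[act] = k27

    rho = 1.0 / (1.0 + ph.rna_slowdown * world.rna_damage[act])
    p21 = world.p21[act]
    # mass doubles per *effective* expected period: p21 lengthens G1 exactly
    # like p27 (same inhibition term), and RNA damage slows global synthesis
    from .cycle import P27_SCALE
    k27_eff = k27 + p21 / P27_SCALE
    world.mu[act] = rho * np.log(2.0) / period_from_k27(k27_eff)

    # damage-induced arrest (and release once repaired); lethally damaged
    # cells are not frozen — they proceed to die at the next checkpoint
    to_arrest = (rho < ph.arrest_rho) | \
        ((p21 > ph.arrest_p21)
         & (world.dna_damage[act] < ph.theta_apopt_dna))
    for i in act[to_arrest]:
        world.arrested[i] = True
        world.arrest_time[i] = world.time
        world.events.append(world.time, "arrest", int(world.cell_id[i]),
                            int(world.ctype[i]), float(world.pos[i, 2]))
    arr = idx[world.arrested[idx] & ~world.giant[idx] & ~world.apoptotic[idx]]
    if len(arr):
        rho_a = 1.0 / (1.0 + ph.rna_slowdown * world.rna_damage[arr])
        release = (rho_a > ph.arrest_rho + 0.15) & (world.p21[arr] < 0.5)
        for i in arr[release]:
            world.arrested[i] = False
            world.post_arrest_g1[i] = True
            world.events.append(world.time, "arrest_release",
                                int(world.cell_id[i]), int(world.ctype[i]),
                                float(world.pos[i, 2]))

    act = act[~to_arrest]
    if len(act) == 0:
        return []
    k27 = world.k27[act]
    rho = 1.0 / (1.0 + ph.rna_slowdown * world.rna_damage[act])
    p21 = world.p21[act]
    f = 1.0 - world.cdk1_strength if world.cdk1_active else 1.0

    Yp = world.cyc[act].copy()
    Yn = rk4_step(Yp, world.mass[act], k27, dt, rho, f, p21)
    if not np.all(np.isfinite(Yn)):
        bad = ~np.all(np.isfinite(Yn), axis=1)
        warnings.warn(f"cycle integration failure for {bad.sum()} cell(s); "
                      "state frozen")
        Yn[bad] = Yp[bad]
    world.cyc[act] = Yn

    grow = world.mass[act] < cycfg.mass_saturation
    world.mass[act[grow]] *= np.exp(world.mu[act[grow]] * dt)

    phase = world.phase[act]
    divisions = []

    # G1 -> S (with damage checkpoint)
    s_try = (phase == G1) & (Yp[:, CYC_E] < THETA_E) & (Yn[:, CYC_E] >= THETA_E)
    for r in np.flatnonzero(s_try):
        i = act[r]
        cp = checkpoint_decision(world.dna_damage[i], world.rna_damage[i], ph)
        if cp == APOPTOSIS:
            mark_apoptotic(world, int(i), cause="apoptosis")
        else:
            world.phase[i] = S
            world.post_arrest_g1[i] = False

    # S -> G2
    g2 = (phase == S) & (Yp[:, CYC_W] >= THETA_W) & (Yn[:, CYC_W] < THETA_W)
    world.phase[act[g2]] = G2

    # G2 -> M (damage checkpoint) or drug-induced premature G1 restart
    a_fall = (phase == G2) & (Yp[:, CYC_A] >= THETA_A) & (Yn[:, CYC_A] < THETA_A)
    for r in np.flatnonzero(a_fall):
        i = act[r]
        if Yn[r, CYC_B] > THETA_DIV:
            cp = checkpoint_decision(world.dna_damage[i], world.rna_damage[i], ph)
            if cp == APOPTOSIS:
                mark_apoptotic(world, int(i), cause="apoptosis")
            else:
                world.phase[i] = M
                world.b_m_entry[i] = Yn[r, CYC_B]
        elif world.cdk1_active:
            world.phase[i] = G1
            world.restarted[i] = True
            world.cycle_start_time[i] = world.time
            world.events.append(world.time, "premature_restart",
                                int(world.cell_id[i]), int(world.ctype[i]),
                                float(world.pos[i, 2]))

    phase = world.phase[act]
    if world.cdk1_active:
        dying = (phase == M) & ~world.apoptotic[act] & \
            (Yn[:, CYC_B] < cycfg.mitotic_death_fraction
             * np.maximum(world.b_m_entry[act], 1e-6))
        for i in act[dying]:
            mark_apoptotic(world, int(i), cause="mitotic_death")
    else:
        div = (phase == M) & ~world.apoptotic[act] & \
            (Yp[:, CYC_B] >= THETA_DIV) & (Yn[:, CYC_B] < THETA_DIV) & \
            (Yn[:, CYC_P] > 0.3)
        divisions = [int(i) for i in act[div]]

    # oversized cells arrest as giants (cap relative to newborn mass).
    # The giant phenotype belongs to the CDK1-disruption path: cells that
    # restarted without dividing or that outgrew the cap while inhibited.
    # M-phase cells under active inhibition are on the mitotic-death path.
    phase = world.phase[act]
    giant = (world.mass[act] >= cycfg.giant_mass_cap) & ~world.giant[act] \
        & (world.restarted[act] | world.cdk1_active) \
        & ~((phase == M) & world.cdk1_active)
    for i in act[giant]:
        world.giant[i] = True
        world.arrested[i] = True
        world.arrest_time[i] = world.time
        world.events.append(world.time, "giant_arrest", int(world.cell_id[i]),
                            int(world.ctype[i]), float(world.pos[i, 2]))

    # Ki-67 memory: active cycling outside G1
    mem = ~world.apoptotic[act] & ~world.arrested[act] & (world.phase[act] != G1)
    world.ki67_memory[act[mem]] = world.time
    return divisions


def step(world: World, dt: float, *, doses=(), cdk1: CDK1Schedule | None = None,
         ablation: AblationSchedule | None = None, brdu_window=None,
         recorders=()) -> World:
    """Advance the world by one tick of dt hours."""
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    t = world.time

    # pharmacology first: drug fields seen by this tick's biology
    integrate_pk(world.pk, doses, t, dt)
    if cdk1 is not None:
        s = cdk1.strength_at(t)
        world.cdk1_active = s > 0
        world.cdk1_strength = s
    else:
        world.cdk1_active = False
        world.cdk1_strength = 0.0
    from .pharmacology import accumulate_damage
    accumulate_damage(world, dt)

    update_wnt(world, dt)
    update_notch(world, dt)

    divisions = step_cycles(world, dt, recorders)
    for i in divisions:
        for rec in recorders:
            if hasattr(rec, "record_division"):
                rec.record_division(world, i)
        cid = int(world.cell_id[i])
        world.events.append(t, "division", cid, int(world.ctype[i]),
                            float(world.pos[i, 2]))
        da, db = place_daughters(world, cid)
        for d in (da, db):
            world.events.append(t, "birth", d,
                                int(world.ctype[world.index_of[d]]),
                                float(world.pos[world.index_of[d], 2]))

    apply_fate_decisions(world, dt)

    if ablation is not None:
        ablate_stem(world, ablation, dt)
    if brdu_window is not None:
        brdu_pulse(world, brdu_window[0] <= t < brdu_window[1])

    # clear apoptotic corpses after the configured delay
    idx = world.live()
    gone = idx[world.apoptotic[idx] & (t >= world.apopt_clear_time[idx])]
    for i in gone:
        world.remove_cell(int(world.cell_id[i]))

    relax(world, dt)

    idx = world.live()
    niche = world.surface.in_niche(world.pos[idx])
    world.left_niche[idx[~niche]] = True
    world.entered_niche[idx[niche]] = True

    transfer_and_shed(world, dt)

    world.time = t + dt
    for rec in recorders:
        if hasattr(rec, "maybe_record"):
            rec.maybe_record(world)
    return world
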