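"""Cell-fate rules, terminal differentiation, dedifferentiation and targeted
stem-cell ablation.

Fate is re-evaluated every tick from tethered Wnt and accumulated Notch, so
all decisions are reversible by construction. A short dwell requirement
(config ``fate.dwell_time``) filters threshold chatter. Existing stem cells
keep stemness down to ``wnt_low`` (hysteresis band), while acquiring stemness
requires the full ``wnt_high`` + Notch-on condition — that acquisition from a
Paneth cell, absorptive progenitor or secretory progenitor is
dedifferentiation and is logged with its cell of origin.
"""
from __future__ import annotations

import numpy as np

from .cycle import Y_G1, G1, period_from_k27
from .state import CellType, PLASTIC_TYPES, World

_NO_TARGET = -1


def fate_targets(world: World, idx: np.ndarray) -> np.ndarray:
    """Target lineage for each cell under the instantaneous signal rules.

    Returns -1 where no change is indicated. Mature goblet, enteroendocrine
    and enterocyte cells are outside the plastic set and never retarget.
    """
    fc = world.config.fate
    ctype = world.ctype[idx]
    wnt = world.wnt[idx]
    notch = world.notch[idx]
    z = world.pos[idx, 2]
    target = np.full(len(idx), _NO_TARGET, dtype=np.int8)

    # secretory lineages (Paneth, secretory progenitors) revert to stem under
    # milder lateral-inhibition exposure than absorptive progenitors
    notch_need = np.where(
        (ctype == CellType.PANETH) | (ctype == CellType.SECRETORY_PROGENITOR),
        fc.notch_on_secretory, fc.notch_on)
    stem_ok = (wnt >= fc.wnt_high) & (notch >= notch_need)

    # stem cells: demote only when leaving the hysteresis band; high-Wnt
    # demotions (Notch lost in the niche) yield Paneth cells, low-Wnt ones
    # commit to progenitors split by the lateral-inhibition threshold
    is_stem = ctype == CellType.STEM
    demote = is_stem & ((wnt < fc.wnt_low) | (notch < fc.notch_off))
    target[demote & (wnt >= fc.wnt_high)] = CellType.PANETH
    target[demote & (wnt < fc.wnt_high) & (notch >= fc.notch_split)] = \
        CellType.ABSORPTIVE_PROGENITOR
    target[demote & (wnt < fc.wnt_high) & (notch < fc.notch_split)] = \
        CellType.SECRETORY_PROGENITOR

    # already-stem cells keep stemness inside the hysteresis band
    target[is_stem & ~demote] = _NO_TARGET

    # dedifferentiation into stem for the plastic set
    plastic = np.isin(ctype, PLASTIC_TYPES)
    target[plastic & stem_ok] = CellType.STEM

    # absorptive progenitors: terminal differentiation against the BMP field
    is_ap = ctype == CellType.ABSORPTIVE_PROGENITOR
    if np.any(is_ap):
        from .signalling import evaluate_bmp
        bmp = evaluate_bmp(world, z[is_ap])
        divs = world.divisions[idx[is_ap]]
        # differentiation when BMP beats residual Wnt after enough divisions,
        # or when tethered Wnt is diluted away entirely (exhausted lineage)
        terminal = ((bmp > fc.bmp_alpha * wnt[is_ap] + fc.bmp_beta)
                    & (divs >= fc.min_divisions)) \
            | (wnt[is_ap] < fc.wnt_floor) \
            | ((divs >= fc.max_divisions) & (bmp > fc.bmp_floor))
        sub = np.flatnonzero(is_ap)
        t_ap = target[sub]
        t_ap[(t_ap == _NO_TARGET) & terminal] = CellType.ENTEROCYTE
        # lateral-inhibition flip when Notch support is lost (hysteresis)
        t_ap[(t_ap == _NO_TARGET) & ~terminal
             & (notch[is_ap] < 0.7 * fc.notch_split)] = \
            CellType.SECRETORY_PROGENITOR
        target[sub] = t_ap

    # secretory progenitors regaining Notch become absorptive (hysteresis)
    is_sp = ctype == CellType.SECRETORY_PROGENITOR
    target[is_sp & ~stem_ok & (notch >= 1.3 * fc.notch_split)] = \
        CellType.ABSORPTIVE_PROGENITOR

    target[target == ctype] = _NO_TARGET
    return target


def decide_fate(world: World, cell_id: int) -> CellType:
    """Lineage the rules indicate for one cell right now."""
    i = world.index_of[cell_id]
    t = fate_targets(world, np.array([i]))[0]
    return CellType(int(world.ctype[i])) if t == _NO_TARGET else CellType(int(t))


def dedifferentiate(world: World, cell_id: int) -> CellType:
    """Revert a plastic cell to STEM if it regained stem-level Wnt and Notch."""
    i = world.index_of[cell_id]
    fc = world.config.fate
    ctype = CellType(int(world.ctype[i]))
    need = fc.notch_on_secretory if ctype in (
        CellType.PANETH, CellType.SECRETORY_PROGENITOR) else fc.notch_on
    if ctype in PLASTIC_TYPES and world.wnt[i] >= fc.wnt_high \
            and world.notch[i] >= need:
        _switch_type(world, i, CellType.STEM, log_event="dedifferentiation")
        return CellType.STEM
    return ctype


def _switch_type(world: World, i: int, new_type: CellType, log_event="fate_change"):
    old = CellType(int(world.ctype[i]))
    cid = int(world.cell_id[i])
    z = float(world.pos[i, 2])
    if new_type == CellType.STEM and old in PLASTIC_TYPES:
        log_event = "dedifferentiation"
    world.events.append(world.time, log_event, cid, int(old), z,
                        detail=f"{old.name}->{new_type.name}")
    world.ctype[i] = int(new_type)
    world.type_changed[i] = True
    world.differentiation_time[i] = world.time
    world.pending_type[i] = _NO_TARGET

    if new_type == CellType.ENTEROCYTE and old == CellType.ABSORPTIVE_PROGENITOR:
        world.terminal_divisions.append((world.time, int(world.divisions[i])))
    from .state import CYCLING_TYPES
    if new_type == CellType.STEM:
        world.stem_since[i] = world.time
        world.divisions[i] = 0
    if new_type == CellType.ABSORPTIVE_PROGENITOR and old == CellType.STEM:
        world.divisions[i] = 0  # commitment: divisions counted from here
    if new_type in CYCLING_TYPES:
        if not world.has_cycle[i]:
            world.has_cycle[i] = True
            world.cyc[i] = Y_G1
            world.phase[i] = G1
            world.cycle_start_time[i] = world.time
            world.mu[i] = np.log(2.0) / period_from_k27(world.k27[i])
            world.restarted[i] = False
            # a reverted cell re-enters the cycle at a regular size
            world.mass[i] = min(world.mass[i], 1.4)
    else:
        if world.has_cycle[i]:
            world.ki67_memory[i] = world.time if world.phase[i] != G1 \
                else world.ki67_memory[i]
        world.has_cycle[i] = False
        world.phase[i] = -1
        world.arrested[i] = False


def apply_fate_decisions(world: World, dt: float) -> None:
    """Vectorized per-tick fate update with the dwell-time filter plus the
    stochastic maturation of secretory progenitors above the niche."""
    fc = world.config.fate
    idx = world.live()
    if len(idx) == 0:
        return
    # giants are terminally arrested oversized cells and take no decisions
    ok = ~world.apoptotic[idx] & ~world.giant[idx]
    idx = idx[ok]
    target = fate_targets(world, idx)

    # dwell bookkeeping
    tgt_changed = target != world.pending_type[idx]
    world.pending_type[idx[tgt_changed]] = target[tgt_changed]
    world.pending_since[idx[tgt_changed]] = world.time
    # reversion to stemness requires a long reprogramming dwell; all other
    # switches use the short anti-chatter dwell
    dwell = np.where(target == CellType.STEM, fc.dediff_dwell, fc.dwell_time)
    ready = (target != _NO_TARGET) & \
        (world.time - world.pending_since[idx] >= dwell)
    for j in idx[ready]:
        _switch_type(world, int(j), CellType(int(world.pending_type[j])))

    # secretory progenitor maturation outside the niche (goblet-biased split)
    idx = world.live()
    sp = idx[(world.ctype[idx] == CellType.SECRETORY_PROGENITOR)
             & ~world.apoptotic[idx]
             & (world.pos[idx, 2] > world.surface.R
                + world.config.signalling.bmp_antagonist_zone)]
    if len(sp):
        mature = world.rng.random(len(sp)) < fc.sp_maturation_rate * dt
        for j in sp[mature]:
            new = CellType.GOBLET if world.rng.random() < fc.goblet_fraction \
                else CellType.ENTEROENDOCRINE
            _switch_type(world, int(j), new)


class AblationSchedule:
    """Diphtheria-toxin-style targeted stem ablation: all stem cells present
    during the first day are killed within 24 h; for the remaining days any
    cell acquiring the stem state is killed after a short lag."""

    def __init__(self, start: float, duration_days: float = 4.0,
                 lag: float = 0.2, first_day_rate: float = 0.25,
                 washout: float = 8.0):
        self.start = start
        self.end = start + duration_days * 24.0
        self.lag = lag
        self.first_day_rate = first_day_rate
        self.washout = washout   # toxin persistence past the last induction

    def active(self, t: float) -> bool:
        return self.start <= t < self.end + self.washout


def ablate_stem(world: World, schedule: AblationSchedule, dt: float) -> None:
    t = world.time
    if not schedule.active(t):
        return
    idx = world.live()
    stems = idx[(world.ctype[idx] == CellType.STEM) & ~world.apoptotic[idx]]
    if len(stems) == 0:
        return
    if t < schedule.start + 24.0:
        # per-tick hazard; guaranteed completion at the end of day 1
        kill = world.rng.random(len(stems)) < schedule.first_day_rate * dt
        if t + dt >= schedule.start + 24.0:
            kill[:] = True
        targets = stems[kill]
    else:
        targets = stems[t - world.stem_since[stems] >= schedule.lag]
    for j in targets:
        mark_apoptotic(world, int(j), cause="ablation")


def mark_apoptotic(world: World, i: int, cause: str = "apoptosis") -> None:
    """Flag a cell for death; it is cleared after the configured delay."""
    if world.apoptotic[i]:
        return
    world.apoptotic[i] = True
    world.has_cycle[i] = False
    world.phase[i] = -1
    world.apopt_clear_time[i] = world.time + \
        world.config.pharmacology.apoptosis_clearance
    world.apopt_cause[i] = {"apoptosis": 0, "mitotic_death": 1,
                            "ablation": 2}.get(cause, 0)
    world.events.append(world.time, cause, int(world.cell_id[i]),
                        int(world.ctype[i]), float(world.pos[i, 2]))
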