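"""5-FU pharmacokinetics, metabolite-driven DNA/RNA damage, checkpoint
decisions and the CDK1-inhibitor schedule.

The PK model is a linear 1-compartment parent (bolus dosing, first-order
elimination) feeding three first-order metabolite compartments (FUTP, FdUMP,
FdUTP). Updates use the exact two-exponential (Bateman) step, so the system
is deterministic and exactly linear in dose. FdUMP is tracked but has no
downstream effect (thymidylate-synthase inhibition is deliberately not
modelled). FUTP damages the RNA of proliferative cells; FdUTP damages DNA
during S-phase only; both are repaired at first order.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ConfigurationError, PharmacologyConfig
from .state import G1, G2, M, S, World

CONTINUE, SLOW, APOPTOSIS = "CONTINUE", "SLOW", "APOPTOSIS"
SPECIES = ("5-FU", "FUTP", "FdUMP", "FdUTP")


@dataclass
class Dose:
    time: float          # h
    amount: float        # mg/kg
    compound: str = "5-FU"


@dataclass
class PKState:
    config: PharmacologyConfig
    fu: float = 0.0
    futp: float = 0.0
    fdump: float = 0.0
    fdutp: float = 0.0
    dose_log: list = field(default_factory=list)

    def concentrations(self) -> dict[str, float]:
        return {"5-FU": self.fu, "FUTP": self.futp,
                "FdUMP": self.fdump, "FdUTP": self.fdutp}

    def epithelium(self) -> dict[str, float]:
        f = self.config.epithelium_factor
        return {k: v * f for k, v in self.concentrations().items()}


def _bateman_step(parent0, met0, kf, ke_parent, ke_met, dt):
    """Exact step of dM/dt = kf*C - ke_met*M with C = parent0*exp(-ke_parent t)."""
    if abs(ke_met - ke_parent) < 1e-9:
        ke_met = ke_parent + 1e-9
    ep = np.exp(-ke_parent * dt)
    em = np.exp(-ke_met * dt)
    return met0 * em + parent0 * kf * (ep - em) / (ke_met - ke_parent)


def integrate_pk(pk: PKState, doses, t0: float, dt: float) -> PKState:
    """Advance the PK state from t0 to t0+dt, applying any bolus doses whose
    time falls in (t0, t0+dt]."""
    cfg = pk.config
    for d in doses:
        if d.amount < 0:
            raise ConfigurationError("negative dose")
        if t0 <= d.time < t0 + dt:
            pk.fu += d.amount * cfg.dose_to_conc
            pk.dose_log.append((d.time, d.compound, d.amount))
    ke = cfg.fu_elimination
    pk.futp = _bateman_step(pk.fu, pk.futp, cfg.futp.formation, ke,
                            cfg.futp.elimination, dt)
    pk.fdump = _bateman_step(pk.fu, pk.fdump, cfg.fdump.formation, ke,
                             cfg.fdump.elimination, dt)
    pk.fdutp = _bateman_step(pk.fu, pk.fdutp, cfg.fdutp.formation, ke,
                             cfg.fdutp.elimination, dt)
    pk.fu *= np.exp(-ke * dt)
    return pk


def q12h_schedule(dose_mg_kg: float, days: float = 4.0,
                  start: float = 0.0) -> list[Dose]:
    """Dose every 12 h for the given number of days (e.g. 50 mg/kg x 4 d)."""
    n = int(round(days * 2))
    return [Dose(start + 12.0 * k, dose_mg_kg) for k in range(n)]


def accumulate_damage(world: World, dt: float) -> None:
    """FUTP -> RNA damage of proliferative cells; FdUTP -> DNA damage during
    S-phase; first-order repair of both."""
    cfg = world.config.pharmacology
    idx = world.live()
    if len(idx) == 0:
        return
    conc = world.pk.epithelium() if world.pk is not None else None
    prolif = world.has_cycle[idx] & ~world.apoptotic[idx]
    if conc is not None and conc["FUTP"] > 0:
        world.rna_damage[idx[prolif]] += cfg.k_rna * conc["FUTP"] * dt
    in_s = prolif & (world.phase[idx] == S) & ~world.arrested[idx]
    if conc is not None and conc["FdUTP"] > 0:
        world.dna_damage[idx[in_s]] += cfg.k_dna * conc["FdUTP"] * dt
    world.rna_damage[idx] *= np.exp(-cfg.repair_rna * dt)
    world.dna_damage[idx] *= np.exp(-cfg.repair_dna * dt)
    # p21 induction by sub-lethal DNA damage
    drive = np.maximum(0.0, world.dna_damage[idx] - cfg.theta_p21)
    world.p21[idx] += (cfg.p21_rate * drive - cfg.p21_decay * world.p21[idx]) * dt


def checkpoint_decision(dna_damage: float, rna_damage: float,
                        cfg: PharmacologyConfig) -> str:
    """Damage decision taken at the G1/S and G2/M phase boundaries."""
    if dna_damage >= cfg.theta_apopt_dna or rna_damage >= cfg.theta_apopt_rna:
        return APOPTOSIS
    if dna_damage >= cfg.theta_p21:
        return SLOW
    return CONTINUE


@dataclass
class CDK1Schedule:
    """CDK1 inhibition for ``on_hours`` every ``every_hours`` for
    ``days`` consecutive days."""
    start: float = 0.0
    on_hours: float = 6.0
    every_hours: float = 12.0
    days: float = 4.0
    strength: float = 0.9

    def strength_at(self, t: float) -> float:
        rel = t - self.start
        if rel < 0 or rel >= self.days * 24.0:
            return 0.0
        return self.strength if (rel % self.every_hours) < self.on_hours else 0.0


def cdk1_schedule(schedule: CDK1Schedule, t: float) -> float:
    return schedule.strength_at(t)
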