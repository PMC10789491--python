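"""Per-cell division-cycle protein network.

A compact cyclin/CDK relaxation oscillator drives each proliferative cell:

  * CycE rises during G1 against inhibition by p27 (and drug-induced p21);
    its rise through ``THETA_E`` marks S entry. p27 production is set
    continuously from the mechanical pressure on the cell, which is how
    contact inhibition of proliferation lengthens G1.
  * CycA is switched on by high CycE, self-sustains, and its accumulation
    drives Wee1 down; the Wee1 fall through ``THETA_W`` ends S.
  * CycB is switched on by high CycA. When CycB crosses ``APC_TRIGGER`` the
    APC/C fires as a spike that degrades CycA first (the CycA fall through
    ``THETA_A`` marks M entry) and then CycB; the CycB fall through
    ``THETA_DIV`` completes mitosis and the cell divides.
  * The APC spike also resets CycE, re-arming G1.

Mass grows exponentially at a rate chosen so it doubles per expected period
(from the frozen pressure->period calibration); a sharp size checkpoint gates
CycE synthesis so newborn cells below the critical size wait in G1.

Drug couplings: CDK1 inhibition scales down CycA/CycB production; RNA damage
scales down all protein production (factor rho); DNA damage above a threshold
induces p21 which adds to p27's inhibition of CycE.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .state import (CYC_A, CYC_B, CYC_E, CYC_P, CYC_W, G1, G2, M, NO_PHASE,
                    PHASE_NAMES, S)

# -- network constants (A.U., 1/h) -----------------------------------------
PAR = dict(
    kE=1.0, Ki=1.0, dE0=0.06, dEP=8.0, m_crit=1.3,
    kA=0.8, KA=1.5, KA2=1.2, dA0=0.2, dAP=8.0,
    kW=0.6, dW0=0.6, dWA=4.0, KW=2.4,
    kB=1.0, KB=1.8, dB0=0.2, dBP=1.2,
    ki=1.5, KPd=0.5,
)
APC_TRIGGER = 1.8        # CycB level firing the APC/C spike
THETA_E = 1.5            # S entry: CycE rises through this
THETA_W = 0.5            # G2 entry: Wee1 falls through this
THETA_A = 1.0            # M entry: CycA falls through this (with CycB high)
THETA_DIV = 1.0          # division: CycB falls through this
P27_SCALE = 2.0          # steady-state p27 = P27_SCALE * k27

#: reference post-division G1 state [CycE, CycA, CycB, Wee1, APC]
Y_G1 = np.array([0.05, 0.02, 0.05, 1.0, 0.6])

# frozen calibration: p27 production rate -> free-running network period (h),
# measured with the size checkpoint unbound. Strictly increasing.
K27_GRID = np.array([
    0.0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5, 0.55, 0.6,
    0.65, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95, 1.0, 1.05, 1.1, 1.15, 1.2, 1.25,
    1.3, 1.35])
PERIOD_GRID = np.array([
    7.31, 7.32, 7.38, 7.48, 7.62, 7.8, 8.0, 8.26, 8.56, 8.9, 9.28, 9.7,
    10.169, 10.686, 11.26, 11.88, 12.56, 13.32, 14.14, 15.02, 16.0, 17.072,
    18.24, 19.56, 21.0, 22.62, 24.44, 26.5])

#: p27 rates reproducing the two calibrated cycle-duration anchors
K27_FAST = float(np.interp(10.0, PERIOD_GRID, K27_GRID))    # ~10 h transit cycle
K27_SLOW = float(np.interp(21.5, PERIOD_GRID, K27_GRID))    # ~21.5 h niche cycle


def period_from_k27(k27):
    """Expected free-running period (h) for a p27 production rate."""
    return np.interp(k27, K27_GRID, PERIOD_GRID)


def k27_from_period(period):
    return np.interp(period, PERIOD_GRID, K27_GRID)


def _hill(x, K, n):
    x = np.maximum(x, 0.0)
    xn = x ** n
    return xn / (K ** n + xn)


def rhs(Y, mass, k27, rho=1.0, cdk1_factor=1.0, p21=0.0):
    """Time derivative of the protein state. Vectorized over rows of Y."""
    Y = np.atleast_2d(Y)
    E, A, B, W, P = (Y[:, j] for j in range(5))
    p27 = P27_SCALE * np.asarray(k27, dtype=float)
    inh = 1.0 + ((p27 + p21) / PAR["Ki"]) ** 2
    apc = _hill(P, PAR["KPd"], 4)
    trigA = np.minimum(1.0, _hill(E, PAR["KA"], 8) + _hill(A, PAR["KA2"], 6))
    size_ok = _hill(np.asarray(mass, dtype=float), PAR["m_crit"], 8)
    dE = rho * PAR["kE"] * size_ok / inh - E * (PAR["dE0"] + PAR["dEP"] * apc)
    dA = rho * cdk1_factor * PAR["kA"] * trigA - A * (PAR["dA0"] + PAR["dAP"] * apc)
    dB = rho * cdk1_factor * PAR["kB"] * _hill(A, PAR["KB"], 4) \
        - B * (PAR["dB0"] + PAR["dBP"] * apc)
    dW = rho * PAR["kW"] - W * (PAR["dW0"] + PAR["dWA"] * _hill(A, PAR["KW"], 4))
    dP = -PAR["ki"] * P
    return np.stack([dE, dA, dB, dW, dP], axis=1)


def rk4_step(Y, mass, k27, dt, rho=1.0, cdk1_factor=1.0, p21=0.0):
    k1 = rhs(Y, mass, k27, rho, cdk1_factor, p21)
    k2 = rhs(Y + 0.5 * dt * k1, mass, k27, rho, cdk1_factor, p21)
    k3 = rhs(Y + 0.5 * dt * k2, mass, k27, rho, cdk1_factor, p21)
    k4 = rhs(Y + dt * k3, mass, k27, rho, cdk1_factor, p21)
    out = np.atleast_2d(Y) + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    # APC/C fires as a spike when CycB crosses its trigger
    fired = (np.atleast_2d(Y)[:, CYC_B] < APC_TRIGGER) & (out[:, CYC_B] >= APC_TRIGGER)
    out[fired, CYC_P] = 1.0
    return out


def classify_phase(y) -> int:
    """Phase inferred from the marker pattern of a single protein state."""
    E, A, B, W, P = y
    if A >= THETA_A and W < THETA_W:
        return M if (B >= THETA_DIV and P > 0.3) else G2
    if A >= THETA_A or (E >= THETA_E and W >= THETA_W):
        return S if W >= THETA_W else G2
    if B >= THETA_DIV and P > 0.3:
        return M
    return G1


@dataclass
class CycleState:
    """Single-cell view of the protein network state."""
    proteins: np.ndarray = field(default_factory=lambda: Y_G1.copy())
    mass: float = 1.3
    p27_production_rate: float = 0.0
    p21: float = 0.0
    phase: int = G1
    cycle_start_time: float = 0.0
    cdk1_strength: float = 0.0
    cdk1_active: bool = False
    rho: float = 1.0

    # marker accessors
    @property
    def CycE(self):
        return float(self.proteins[CYC_E])

    @property
    def CycA(self):
        return float(self.proteins[CYC_A])

    @property
    def CycB(self):
        return float(self.proteins[CYC_B])

    @property
    def Wee1(self):
        return float(self.proteins[CYC_W])

    @property
    def p27(self):
        return P27_SCALE * self.p27_production_rate

    @property
    def phase_name(self):
        return PHASE_NAMES[self.phase]

    @classmethod
    def from_world(cls, world, i):
        return cls(proteins=world.cyc[i].copy(), mass=float(world.mass[i]),
                   p27_production_rate=float(world.k27[i]),
                   p21=float(world.p21[i]), phase=int(world.phase[i]),
                   cycle_start_time=float(world.cycle_start_time[i]))

    def copy(self):
        return CycleState(self.proteins.copy(), self.mass,
                          self.p27_production_rate, self.p21, self.phase,
                          self.cycle_start_time, self.cdk1_strength,
                          self.cdk1_active, self.rho)


def integrate_cycle(state: CycleState, dt: float, perturbations=None,
                    step: float = 0.02, mass_doubling_period=None,
                    collect=None):
    """Advance a single cell's network by ``dt`` hours.

    ``perturbations`` may carry 'cdk1_strength', 'cdk1_active', 'rho' and
    'p21'. Returns (state, events) where events is a list of
    (time_offset, name) for phase transitions and divisions. Division events
    halve the mass in place (the caller owns daughter bookkeeping).
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    st = state.copy()
    if perturbations:
        st.cdk1_strength = perturbations.get("cdk1_strength", st.cdk1_strength)
        st.cdk1_active = perturbations.get("cdk1_active", st.cdk1_active)
        st.rho = perturbations.get("rho", st.rho)
        st.p21 = perturbations.get("p21", st.p21)
    if mass_doubling_period is None:
        mass_doubling_period = float(period_from_k27(st.p27_production_rate))
    mu = np.log(2.0) / mass_doubling_period
    n = max(1, int(round(dt / step))) if dt > 0 else 0
    h = dt / n if n else 0.0
    events = []
    b_m_entry = getattr(st, "_b_m_entry", APC_TRIGGER)
    for k in range(n):
        f = 1.0 - st.cdk1_strength if st.cdk1_active else 1.0
        yp = st.proteins.copy()
        st.proteins = rk4_step(yp, st.mass, st.p27_production_rate, h,
                               st.rho, f, st.p21)[0]
        y = st.proteins
        t_off = (k + 1) * h
        if st.phase == G1 and yp[CYC_E] < THETA_E <= y[CYC_E]:
            st.phase = S
            events.append((t_off, "s_entry"))
        elif st.phase == S and yp[CYC_W] >= THETA_W > y[CYC_W]:
            st.phase = G2
            events.append((t_off, "g2_entry"))
        elif st.phase == G2 and yp[CYC_A] >= THETA_A > y[CYC_A]:
            if y[CYC_B] > THETA_DIV:
                st.phase = M
                b_m_entry = y[CYC_B]
                events.append((t_off, "m_entry"))
            elif st.cdk1_active:
                st.phase = G1
                st.cycle_start_time += t_off
                events.append((t_off, "premature_restart"))
        if st.phase == M and st.cdk1_active and \
                y[CYC_B] < 0.45 * b_m_entry:
            events.append((t_off, "mitotic_death"))
            st.phase = NO_PHASE
            break
        if yp[CYC_B] >= THETA_DIV > y[CYC_B] and y[CYC_P] > 0.3 \
                and not st.cdk1_active and st.phase == M:
            st.mass /= 2.0
            st.phase = G1
            events.append((t_off, "division"))
        if st.mass < PAR_MASS_SAT:
            st.mass *= np.exp(mu * h)
        if collect is not None:
            collect.append((t_off, y.copy(), st.mass, st.phase))
    if not np.all(np.isfinite(st.proteins)):
        raise FloatingPointError("cycle integration produced non-finite state")
    st._b_m_entry = b_m_entry
    return st, events


PAR_MASS_SAT = 4.8


def annotate_phase(state: CycleState) -> str:
    """Phase name from marker levels (G1 low cyclins/high Wee1, etc.)."""
    return PHASE_NAMES[classify_phase(state.proteins)]


def couple_pressure(state: CycleState, pressure: float, *, k27_max: float,
                    pressure_half: float, exponent: float = 2.0) -> CycleState:
    """Set the p27 production rate from mechanical pressure (Hill map)."""
    if pressure < 0:
        raise ValueError("pressure must be >= 0")
    st = state.copy()
    st.p27_production_rate = float(k27_for_pressure(
        pressure, k27_max, pressure_half, exponent))
    return st


def k27_for_pressure(pressure, k27_max, pressure_half, exponent=2.0,
                     clamp=None, k27_min=0.0):
    p = np.maximum(np.asarray(pressure, dtype=float), 0.0)
    pn = p ** exponent
    k = k27_min + (k27_max - k27_min) * pn / (pressure_half ** exponent + pn)
    if clamp is not None:
        k = np.minimum(k, clamp)
    return k


def apply_cdk1_inhibition(state: CycleState, strength: float,
                          active: bool) -> CycleState:
    """Scale CycA/CycB production down by ``strength`` while active."""
    if strength < 0:
        raise ValueError("strength must be >= 0")
    st = state.copy()
    st.cdk1_strength = strength
    st.cdk1_active = bool(active)
    return st


def apply_damage_coupling(state: CycleState, dna_damage: float,
                          rna_damage: float, pharm) -> CycleState:
    """Couple DNA damage (p21 induction) and RNA damage (global slowdown)."""
    if dna_damage < 0 or rna_damage < 0:
        raise ValueError("damage levels must be >= 0")
    st = state.copy()
    st.p21 = (pharm.p21_rate / pharm.p21_decay) * \
        max(0.0, dna_damage - pharm.theta_p21)
    st.rho = 1.0 / (1.0 + pharm.rna_slowdown * rna_damage)
    return st
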