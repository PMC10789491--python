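"""Unit tests for the cell-cycle protein network: oscillation, phase
annotation, contact-inhibition coupling and drug perturbations."""
import numpy as np
import pytest

from cryptsim.cycle import (CycleState, K27_FAST, K27_SLOW, Y_G1,
                            annotate_phase, apply_cdk1_inhibition,
                            apply_damage_coupling, couple_pressure,
                            integrate_cycle, k27_for_pressure,
                            period_from_k27)
from cryptsim.config import CycleConfig, PharmacologyConfig
from cryptsim.state import G1


def run_cycles(k27, hours=200.0, state=None, perturbations=None, mass=2.0):
    """Integrate one cell and return (state, list of (t, event))."""
    st = state or CycleState(mass=mass, p27_production_rate=k27)
    events = []
    t = 0.0
    chunk = 1.0
    while t < hours:
        st, ev = integrate_cycle(st, chunk, perturbations=perturbations)
        events += [(t + off, name) for off, name in ev]
        t += chunk
    return st, events


def division_times(events):
    return np.array([t for t, name in events if name == "division"])


def test_unperturbed_cycle_visits_all_phases_in_order():
    st, events = run_cycles(K27_FAST, hours=40.0)
    names = [n for _, n in events]
    first = names[:4]
    assert first == ["s_entry", "g2_entry", "m_entry", "division"]


def test_zero_dt_leaves_state_unchanged():
    st = CycleState(mass=2.0, p27_production_rate=0.5)
    before = st.proteins.copy()
    out, ev = integrate_cycle(st, 0.0)
    assert np.allclose(out.proteins, before)
    assert ev == []


def test_high_p27_rate_gives_longer_period_than_low():
    _, ev_fast = run_cycles(K27_FAST, hours=120.0)
    _, ev_slow = run_cycles(K27_SLOW, hours=200.0)
    t_fast = np.diff(division_times(ev_fast)).mean()
    t_slow = np.diff(division_times(ev_slow)).mean()
    assert t_slow > 1.5 * t_fast


def test_calibrated_anchors_hit_reference_durations():
    # the frozen k27 anchors reproduce the two calibrated cycle lengths
    _, ev_fast = run_cycles(K27_FAST, hours=150.0)
    _, ev_slow = run_cycles(K27_SLOW, hours=300.0)
    assert np.diff(division_times(ev_fast)).mean() == pytest.approx(10.0, rel=0.08)
    assert np.diff(division_times(ev_slow)).mean() == pytest.approx(21.5, rel=0.08)


def test_pressure_to_period_monotone_over_sweep():
    cfg = CycleConfig()
    pressures = np.linspace(0.0, 2.5, 10)
    k = k27_for_pressure(pressures, cfg.k27_max, cfg.pressure_half,
                         cfg.pressure_exponent, clamp=cfg.k27_clamp,
                         k27_min=cfg.k27_min)
    periods = period_from_k27(k)
    assert np.all(np.diff(periods) >= -1e-9)
    assert periods[0] < periods[-1]


def test_couple_pressure_zero_gives_shortest_cycle():
    cfg = CycleConfig()
    st = couple_pressure(CycleState(), 0.0, k27_max=cfg.k27_max,
                         pressure_half=cfg.pressure_half,
                         exponent=cfg.pressure_exponent)
    assert st.p27_production_rate == pytest.approx(0.0, abs=1e-9)


def test_phase_durations_partition_the_period():
    st, events = run_cycles(K27_FAST, hours=120.0)
    divs = division_times(events)
    # events between two consecutive divisions partition the cycle
    t0, t1 = divs[-2], divs[-1]
    marks = [(t, n) for t, n in events if t0 < t <= t1]
    names = [n for _, n in marks]
    assert names == ["s_entry", "g2_entry", "m_entry", "division"]
    durations = np.diff([t0] + [t for t, _ in marks])
    assert durations.sum() == pytest.approx(t1 - t0, abs=1e-6)
    assert np.all(durations > 0)


def test_limit_cycle_attracts_perturbed_initial_conditions():
    rng = np.random.default_rng(0)
    periods = []
    for _ in range(5):
        y0 = Y_G1 * rng.uniform(0.3, 2.0, size=5)
        st = CycleState(proteins=y0, mass=rng.uniform(1.4, 2.4),
                        p27_production_rate=K27_FAST)
        _, events = run_cycles(K27_FAST, hours=120.0, state=st)
        d = division_times(events)
        # period over the last cycles, after at most 3 transient cycles
        periods.append(np.diff(d[3:]).mean())
    assert np.ptp(periods) < 0.1 * np.mean(periods)


def test_p27_lengthens_g1_much_more_than_s():
    def phase_lengths(k27):
        _, events = run_cycles(k27, hours=350.0)
        divs = division_times(events)
        t0, t1 = divs[-2], divs[-1]
        marks = {n: t for t, n in events if t0 < t <= t1}
        g1 = marks["s_entry"] - t0
        return g1, t1 - t0
    g1_f, per_f = phase_lengths(K27_FAST)
    g1_s, per_s = phase_lengths(K27_SLOW)
    assert (g1_s - g1_f) / (per_s - per_f) > 0.6


def test_annotate_phase_from_marker_pattern():
    st = CycleState(proteins=np.array([0.1, 0.05, 0.05, 1.0, 0.0]))
    assert annotate_phase(st) == "G1"   # low cyclins, high Wee1
    st = CycleState(proteins=np.array([2.5, 0.4, 0.1, 0.9, 0.0]))
    assert annotate_phase(st) == "S"    # CycE risen, Wee1 still high
    st = CycleState(proteins=np.array([0.5, 3.0, 1.2, 0.1, 0.0]))
    assert annotate_phase(st) == "G2"   # Wee1 fallen, CycA high
    st = CycleState(proteins=np.array([0.2, 0.5, 1.5, 0.1, 1.0]))
    assert annotate_phase(st) == "M"    # CycA fallen, CycB high, APC active


# -- CDK1 inhibition --------------------------------------------------------

def _advance_to(target, k27=K27_FAST):
    st = CycleState(mass=1.6, p27_production_rate=k27)
    t = 0.0
    for _ in range(5000):
        st, ev = integrate_cycle(st, 0.1)
        t += 0.1
        if any(n == target for _, n in ev):
            return st, t
    raise AssertionError(f"never reached {target}")


def test_cdk1_pulse_in_early_g1_barely_shifts_division():
    baseline, _ = run_cycles(K27_SLOW, hours=70.0)
    _, ev0 = run_cycles(K27_SLOW, hours=70.0)
    t_div0 = division_times(ev0)[0]

    st = CycleState(mass=1.6, p27_production_rate=K27_SLOW)
    st, ev1 = integrate_cycle(st, 6.0, perturbations={
        "cdk1_active": True, "cdk1_strength": 0.9})
    events = [(off, n) for off, n in ev1]
    t = 6.0
    while t < 70.0:
        st, ev = integrate_cycle(st, 1.0,
                                 perturbations={"cdk1_active": False})
        events += [(t + off, n) for off, n in ev]
        t += 1.0
    t_div1 = division_times(events)[0]
    period = np.diff(division_times(ev0)).mean() if len(ev0) > 2 else 21.5
    assert abs(t_div1 - t_div0) < 0.1 * period


def test_cdk1_in_late_g2_restarts_without_division_and_doubles_mass():
    st, _ = _advance_to("g2_entry")
    mass_at_g2 = st.mass
    st2, ev = integrate_cycle(st, 14.0, perturbations={
        "cdk1_active": True, "cdk1_strength": 0.9})
    names = [n for _, n in ev]
    assert "premature_restart" in names
    assert "division" not in names
    # the division-less cycle leaves the cell with roughly twice the mass a
    # divided daughter would carry
    assert st2.mass > 1.6 * mass_at_g2


def test_cdk1_in_m_phase_causes_mitotic_death():
    st, _ = _advance_to("m_entry")
    _, ev = integrate_cycle(st, 8.0, perturbations={
        "cdk1_active": True, "cdk1_strength": 0.9})
    names = [n for _, n in ev]
    assert "mitotic_death" in names
    assert "division" not in names


# -- damage coupling --------------------------------------------------------

def test_zero_damage_is_identity_for_dynamics():
    pharm = PharmacologyConfig()
    st = CycleState(mass=2.0, p27_production_rate=K27_FAST)
    st_d = apply_damage_coupling(st, 0.0, 0.0, pharm)
    assert st_d.p21 == 0.0 and st_d.rho == 1.0
    a, _ = integrate_cycle(st, 5.0)
    b, _ = integrate_cycle(st_d, 5.0)
    assert np.allclose(a.proteins, b.proteins)


def test_dna_damage_above_p21_threshold_lengthens_cycle():
    pharm = PharmacologyConfig()
    base, ev0 = run_cycles(K27_FAST, hours=100.0)
    t_base = np.diff(division_times(ev0)).mean()
    st = apply_damage_coupling(CycleState(mass=2.0,
                                          p27_production_rate=K27_FAST),
                               pharm.theta_p21 + 0.3, 0.0, pharm)
    _, ev1 = run_cycles(K27_FAST, hours=150.0, state=st,
                        perturbations={"p21": st.p21})
    t_slow = np.diff(division_times(ev1)).mean()
    assert t_slow > 1.05 * t_base


def test_arrest_level_damage_stops_phase_transitions():
    pharm = PharmacologyConfig()
    # RNA damage heavy enough to push the global slowdown below the arrest cap
    rna = (1.0 / pharm.arrest_rho - 1.0) / pharm.rna_slowdown + 1.0
    st = apply_damage_coupling(CycleState(mass=2.0,
                                          p27_production_rate=K27_FAST),
                               2.0, rna, pharm)
    assert st.rho < pharm.arrest_rho
    _, ev = run_cycles(K27_FAST, hours=60.0, state=st,
                       perturbations={"p21": st.p21, "rho": st.rho})
    assert division_times(ev).size == 0


def test_cdk1_op_validates_and_sets_strength():
    st = apply_cdk1_inhibition(CycleState(), 0.9, True)
    assert st.cdk1_active and st.cdk1_strength == 0.9
    with pytest.raises(ValueError):
        apply_cdk1_inhibition(CycleState(), -1.0, True)
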