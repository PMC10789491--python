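import numpy as np
import pytest

from cryptsim.config import PharmacologyConfig, ConfigurationError
from cryptsim.pharmacology import (APOPTOSIS, CONTINUE, SLOW, CDK1Schedule,
                                   Dose, PKState, cdk1_schedule,
                                   checkpoint_decision, integrate_pk,
                                   q12h_schedule)


def simulate_pk(doses, hours, dt=0.05):
    pk = PKState(PharmacologyConfig())
    trace = []
    t = 0.0
    for _ in range(int(hours / dt)):
        integrate_pk(pk, doses, t, dt)
        t += dt
        trace.append((t, pk.fu, pk.futp, pk.fdump, pk.fdutp))
    return pk, np.array(trace)


def test_zero_doses_keep_all_concentrations_zero():
    pk, trace = simulate_pk([], 24.0)
    assert np.all(trace[:, 1:] == 0.0)


def test_pk_is_linear_in_dose():
    _, t1 = simulate_pk([Dose(1.0, 50.0)], 12.0)
    _, t2 = simulate_pk([Dose(1.0, 100.0)], 12.0)
    assert np.allclose(t2[:, 1:], 2.0 * t1[:, 1:], rtol=1e-9, atol=1e-9)


def test_q12h_schedule_peaks_and_washout():
    doses = q12h_schedule(50.0, days=4.0)
    assert len(doses) == 8
    _, trace = simulate_pk(doses, 96.0)
    t = trace[:, 0]
    fu = trace[:, 1]
    # a peak shortly after every dose, near-complete washout before the next
    for k in range(8):
        window = (t > 12 * k) & (t <= 12 * k + 1.0)
        pre_next = (t > 12 * k + 10.0) & (t <= 12 * k + 12.0)
        assert fu[window].max() > 1e4
        assert fu[pre_next].max() < 1e-3 * fu[window].max()


def test_negative_dose_rejected():
    pk = PKState(PharmacologyConfig())
    with pytest.raises(ConfigurationError):
        integrate_pk(pk, [Dose(0.5, -1.0)], 0.0, 1.0)


def test_checkpoint_decision_thresholds():
    cfg = PharmacologyConfig()
    assert checkpoint_decision(0.0, 0.0, cfg) == CONTINUE
    assert checkpoint_decision(cfg.theta_p21 + 0.05, 0.0, cfg) == SLOW
    assert checkpoint_decision(cfg.theta_apopt_dna + 0.1, 0.0, cfg) == APOPTOSIS
    assert checkpoint_decision(0.0, cfg.theta_apopt_rna + 0.1, cfg) == APOPTOSIS


def test_cdk1_schedule_windows():
    sched = CDK1Schedule(start=0.0, strength=0.9)
    assert cdk1_schedule(sched, 3.0) == 0.9          # within first on-window
    assert cdk1_schedule(sched, 9.0) == 0.0          # off part of the cycle
    assert cdk1_schedule(sched, 26.0) == 0.9         # day 2 on-window
    assert cdk1_schedule(sched, 24.0 * 4 + 1.0) == 0.0   # after treatment
    assert cdk1_schedule(sched, -1.0) == 0.0


def test_damage_accrual_rules(mini_world):
    from cryptsim.pharmacology import accumulate_damage
    from cryptsim.state import G1, S, CellType
    w = mini_world
    w.pk.futp = 1000.0
    w.pk.fdutp = 1000.0
    idx = w.live()
    ent = idx[w.ctype[idx] == CellType.ENTEROCYTE]
    cyc = idx[w.has_cycle[idx]]
    g1 = cyc[w.phase[cyc] == G1]
    s_cells = cyc[w.phase[cyc] == S]
    accumulate_damage(w, 1.0)
    # non-proliferative cells accumulate nothing
    assert np.all(w.rna_damage[ent] == 0.0)
    assert np.all(w.dna_damage[ent] == 0.0)
    # proliferative cells take RNA damage; DNA damage is S-phase only
    assert np.all(w.rna_damage[cyc] > 0.0)
    if len(g1):
        assert np.all(w.dna_damage[g1] == 0.0)
    if len(s_cells):
        assert np.all(w.dna_damage[s_cells] > 0.0)


def test_damage_repairs_exponentially_after_washout(mini_world):
    from cryptsim.pharmacology import accumulate_damage
    w = mini_world
    idx = w.live()
    cyc = idx[w.has_cycle[idx]]
    w.rna_damage[cyc] = 1.0
    cfg = w.config.pharmacology
    accumulate_damage(w, 1.0)     # no drug present: repair only
    assert np.allclose(w.rna_damage[cyc], np.exp(-cfg.repair_rna),
                       rtol=1e-6)
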