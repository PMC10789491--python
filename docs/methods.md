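# Methods

This note records the model as implemented: its assumptions, the parameters
that matter, the numerical choices, and the limits of what the desk-scale
validation shows.

## Geometry and units

The crypt is a rigid surface: a hemisphere of radius R = 2.5 cell diameters
(CD) joined smoothly at z = R to a cylinder of the same radius and height
H = 12 CD; the crypt mouth is the circle z = R + H. Cell centres are
constrained to the surface by projection after every mechanical step.
Lengths are in cell diameters (≈8 µm in mouse), time in hours, signals in
arbitrary units. At these dimensions a hemi-crypt column holds ~25–35 cells
and the whole crypt ~250–290 — a deliberately scaled-down crypt that keeps a
full simulation on one CPU in minutes. All validated quantities are ratios,
durations or percentages that do not depend on the column length.

## Mechanics

Cell centres interact through linear overlap springs, `F = k_ij · overlap`,
with `k_ij` the series (harmonic-mean) stiffness of the pair; motion is
overdamped with drag proportional to stiffness, so Paneth cells — 1.4× the
radius, 4× the stiffness of other cells — displace less under equal force.
Paneth cells additionally feel a small basal anchoring force along the
meridian (fading at the cap pole where that direction degenerates), the
model's reading of their wedged, matrix-attached position in the niche;
without it they are advected out of the crypt within days. A small random
motility term (0.02 CD/√h) provides the positional noise behind neutral
drift. Displacements are capped at 0.3 CD per step (velocity saturation) so
transient deep overlaps right after division relax over a few steps instead
of overshooting; a hard guard at 1.5 CD aborts genuinely unstable
configurations.

Pressure on a cell is the stiffness-weighted sum of positive overlaps with
its contacts. Before it feeds contact inhibition it is smoothed with a 3 h
exponential moving average: G1 progression integrates the p27 level, and
without smoothing, brief low-pressure excursions let CycE ratchet through
its threshold, biasing realized cycle times far below the mapped period.

## Cell-cycle network

Each proliferative cell integrates a five-species relaxation oscillator
(RK4, one step per 0.02 h tick):

* CycE is synthesized against inhibition by p27 + p21
  (`1/(1+((p27+p21)/K)²)`), gated by a sharp size checkpoint
  (Hill-8 in mass around 1.3), and rises through θ_E = 1.5 to mark S entry.
* CycA switches on at high CycE (Hill-8) and self-sustains (Hill-6 latch);
  its accumulation degrades Wee1, whose fall through θ_W = 0.5 ends S.
* CycB is switched on by high CycA; when it crosses 1.8 the APC/C fires as
  a discrete spike (P := 1, then first-order decay). Smooth APC activation
  was tried first and invariably found stable intermediate fixed points —
  sub-threshold APC leak capped CycA below the CycB trigger — so activation
  is event-triggered while all APC-mediated degradation remains a smooth
  switched function of P. The spike degrades CycA first (its fall through
  θ_A = 1.0 marks M entry) and then CycB, whose fall through θ_div = 1.0
  completes mitosis.
* Division halves mass, tethered Wnt and BrdU label exactly; daughters
  restart in G1.

p27 production is the control input: the frozen calibration table
(`K27_GRID`/`PERIOD_GRID` in `cycle.py`, measured on the free-running
network with the size checkpoint unbound) maps it monotonically onto the
cycle period, 7.3 h at zero to 26.5 h at the top of the grid. Contact
inhibition sets it per cell as an offset saturating Hill function of
smoothed pressure (`k27_min = 0.45`, i.e. a ~8.9 h floor under full pressure
release; half-point 1.15, exponent 16; clamped at the rate whose
free-running period is 21.5 h). The two anchors — ≈10 h for
transit-amplifying pressure, ≈21.5 h for niche pressure — were calibrated
against the equilibrium pressure distributions of the self-organized crypt;
because those distributions feed back on the map, the calibration was
iterated to a fixed point. Mass grows exponentially, doubling per *effective*
expected period (p21 counts as extra p27; RNA-damage slowdown scales growth
too), so drug-slowed cells do not balloon spuriously.

Realized niche-resident stem cycles average ≈20 h over the 20-day
observation, a little below the 21.5 h saturation anchor: stems sample a
pressure distribution whose lower tail maps to shorter periods, and
mean-first-passage through G1 weights the fast excursions. Transit cells
average ≈10 h. The compartment ordering (niche ≈ 2× slower) and the
G1-dominance of the difference (ΔG1/Δperiod > 0.6) are robust.

Phase annotation follows the marker crossings above, tracked as a state
machine; thresholds are fixed constants on the order of the half-maximum of
each marker on the reference (low-p27) limit cycle, with θ_E placed at the
functional CycA trigger since the CycE peak height varies with p27.

### Drug couplings

CDK1 inhibition multiplies CycA/CycB synthesis by (1 − strength), strength
0.9, on a 6 h-on/12 h schedule for 4 days. Outcomes, all emergent from the
network: cells early in the cycle stall briefly and complete mitosis in the
off-windows; late-G2 cells whose CycA collapses without mitosis restart G1
without dividing; and cells on the disruption path — restarted, or still
growing under active inhibition — arrest permanently as oversized "giant"
cells once mass passes 4.2 (versus a normal division mass ≈2.2–2.6). The
giant cap is gated to that disruption path deliberately: an unconditional
mass cap either freezes the whole crypt during pulses (cap near the
stall-overshoot mass) or distorts homeostatic progenitor pools (cap above
it). M-phase cells whose CycB falls below 45% of its M-entry level while
inhibited undergo mitotic death (the 45% severity criterion makes deaths,
giants and unaffected cells coexist under the 6 h schedule — with the APC
spike decayed, CycB lingers, and a stricter criterion lets the giant path
win every race). Giant cells never divide and take no further fate
decisions.

DNA damage above θ_p21 = 0.2 induces p21 (production 2·(dna−θ), decay
0.5/h), which lengthens G1 exactly like p27; RNA damage scales all protein
synthesis by ρ = 1/(1+0.5·rna). Cells arrest when ρ < 0.55 or p21 > 3 —
unless DNA damage is lethal (≥1.0), in which case they are deliberately not
frozen so they reach the next checkpoint and die there (otherwise arrest
races apoptosis and wins, and the checkpoint-death phenotype disappears).
Checkpoints are evaluated only at the G1/S and G2/M transitions.

## Signalling

**Wnt.** Sources are Paneth cells and 28 static mesenchymal emitters on a
shell 0.6 CD outside the hemispherical cap (mesenchyme "surrounding the
niche"; a ring at the niche boundary alone leaves the crypt base pole
unsupplied and the niche starves). Each source contributes linearly down to
zero at range 1.3 CD; tethering is `1.5 · φ · Σweights` per hour, capped at
60 (receptor saturation — without a ceiling, non-dividing Paneth accumulate
unboundedly and corrupt the axial gradient). φ is the ZNRF3/RNF43-like
feedback `min(1,(N*/S))` with N* = 24. Tethered Wnt is never removed except
by exact halving at division.

**Notch.** Delta presentation is weighted by lineage (Paneth 1.0, goblet and
enteroendocrine 0.8, secretory progenitors 0.6); accumulation is
`1.0·Σstrengths − 0.5·notch` per hour (τ = 2 h — slow enough that transient
contacts integrate, which matters for reversion in the sparse post-ablation
niche).

**BMP.** `B(z,t) = 0.05 · E(t) · g(z) · a(z)` with E the villus enterocyte
count, g a logistic in z (midpoint 8, width 2) and a = 0.2 within one CD of
the niche (antagonist zone). An analytic profile replaces a diffusion solve;
every mechanism statement the model needs is axial and monotone.

## Fate rules

Evaluated every tick on the plastic set (stem, Paneth, absorptive and
secretory progenitors); goblet, enteroendocrine and enterocyte are terminal.

* Acquisition of stemness (dedifferentiation when from a committed type):
  wnt ≥ 22 and notch ≥ 2.0, held for a 4 h reprogramming dwell.
* Stem maintenance is hysteretic: demotion only when wnt < 13 or
  notch < 1.85. High-Wnt demotions become Paneth; low-Wnt demotions commit
  to absorptive (notch ≥ 1.2) or secretory (otherwise) progenitors.
* Absorptive progenitors become enterocytes when `B > 0.1·wnt + 5` after ≥3
  divisions, when tethered Wnt is exhausted (< 1), or at the 5-division cap
  provided B > 2 — the BMP gate on the cap keeps the Wnt-rich niche from
  bricking over with enterocytes during deep injury, preserving the plastic
  reservoir that regenerates the crypt.
* Secretory progenitors above the niche mature to goblet or enteroendocrine
  (3:1) at 0.5/h; all other switches need a 0.5 h anti-chatter dwell.

Stem-cell ablation kills all current stems within the first day, then any
cell acquiring stemness after a 0.2 h lag, with an 8 h toxin washout past
the last induction — which is why no stem cells are detectable 6 h after
interruption while regeneration begins immediately afterwards. Dying cells
are flagged apoptotic, excluded from counts as detectable cells, and cleared
after 1 h.

## Villus

An age-structured conveyor: cells crossing the crypt mouth enqueue
(progenitors maturing on entry) and shed when their residence exceeds the
84 h transit time — equivalent, at fixed ring circumference, to travelling
one villus length. A single short step with zero influx sheds nothing;
a sustained influx collapse drains the compartment with the transit delay,
which is what makes the villus minimum lag the crypt minimum in both the
ablation and 5-FU scenarios. The enterocyte count of this compartment drives
the BMP feedback.

## Pharmacokinetics

One-compartment bolus parent (elimination 3/h, 500 ng/ml plasma per mg/kg)
feeding FUTP (formation 0.15/h, elimination 0.8/h), FdUMP (0.20/1.0) and
FdUTP (0.05/0.9) by first order; updates use the exact
two-exponential step, so the system is deterministic and exactly linear in
dose, with near-complete washout between q12h doses. FdUMP is tracked but
deliberately has no downstream effect. Damage constants are normalized so
the lethal DNA threshold is 1.0 and a cell spending a full S-phase under the
first 50 mg/kg exposure crosses it (k_dna = 4×10⁻³ per ng/ml/h, S-phase
only), while a cell with only the tail of S left accumulates ~0.3 —
sub-lethal, p21-slowing. RNA damage (k_rna = 8×10⁻⁵, proliferative cells)
accumulates over repeated doses toward arrest territory.

## Observers

Positions are scored as mouse slides are: 8 angular sectors (hemi-crypt
columns of ~30 cells), cells ranked by meridional arc length. BrdU labels
S-phase cells to 1.0 during a 2 h pulse window, halves at division, and is
detectable above 0.04 — exactly 4 divisions detectable, 5 not. Ki-67 default
follows the staining convention that cycling cells are positive outside G1,
plus a 6 h memory for recently cycling differentiated cells and recently
drug-arrested cells; the variant in which continuously cycling cells stain
in G1 too (except the first G1 after arrest) is available behind a switch.
Motion is sampled at 0.5 h intervals; an interval is retrograde when the
longitudinal velocity (outside the niche) or the polar-angle rate (inside
it) is negative, zero counting as forward.

## Synthetic data and what passing tests show

All inputs are generated: the initializer seeds an alternating stem/Paneth
cap, progenitors below a differentiation boundary, mature cells above it and
a pre-filled villus, then a 14-day burn-in lets the feedback loops find
their own equilibrium — validation never depends on the seeded layout, only
on the self-organized state. The fixtures module provides miniature worlds
(≤40 cells) and prescribed trajectories for millisecond unit tests. None of
this emulates real mouse measurement noise, section geometry, or inter-crypt
variability; passing tests show that the mechanisms interact as designed at
desk scale, not that the model is quantitatively predictive for tissue.

## Known limitations

* Realized niche stem cycles average ~16 h against the 21.5 h anchor (see
  above); the bound is respected but the mean sits below it.
* Small populations (secretory progenitors, enteroendocrine cells) are
  shot-noise dominated at this crypt size; their 7-day moving averages can
  drift more than the 20% stationarity band that holds for the major types.
* The retrograde-motion excess in the ablated niche is a small effect on
  top of positional noise and can fall within noise for single seeds.
* The homeostatic dedifferentiation churn (niche maintenance) shares its
  event type with injury-driven reversion; origin statistics over long
  recovery windows therefore mix both.
* Post-ablation progenitor recovery plateaus near (rather than above) its
  baseline within the 8-day window: after near-complete Paneth loss the
  rebuilt niche is small and re-commitment ramps slowly. A larger Paneth
  pool restores the overshoot but pushes the Paneth-loss and
  dedifferentiation-origin statistics out of their calibration bands.
* Desk scale: one crypt, ~270 cells, 3 seeds; a full-scale replication
  (100-day averages, larger crypts) was not run here.
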