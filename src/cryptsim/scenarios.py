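"""Scenario definitions and runners: homeostasis, BrdU/Ki-67 virtual assays,
stem-cell ablation, CDK1 inhibition and 5-FU dosing.

Every scenario is reproducible from (name, seed) alone: a 14-day burn-in
establishes homeostasis, a 2-day pre-intervention window provides baselines,
then the intervention and recovery run with observers attached.
"""
from __future__ import annotations

import copy
import json
import pathlib

import numpy as np
import pandas as pd

from . import __version__ as _version
from .config import SimulationConfig
from .engine import initialize_world, step
from .fate import AblationSchedule
from .observers import (CountsRecorder, CycleDurationRecorder, MotionRecorder,
                        ki67_positive, positional_fraction)
from .pharmacology import CDK1Schedule, q12h_schedule
from .state import CellType, World

SCENARIOS = ("homeostasis", "brdu_chase", "ki67", "stem_ablation", "cdk1",
             "fu5_high", "fu5_low")


class PKRecorder:
    def __init__(self, cadence: float = 0.25):
        self.cadence = cadence
        self._next = 0.0
        self.rows = []

    def maybe_record(self, world):
        if world.time + 1e-9 < self._next:
            return
        self._next = world.time + self.cadence
        row = {"time": world.time}
        row.update(world.pk.concentrations())
        self.rows.append(row)

    def frame(self):
        return pd.DataFrame(self.rows)


class StainingRecorder:
    """Ki-67 (and optionally BrdU) positional fractions at sample times."""

    def __init__(self, sample_times, assays=("ki67",)):
        self.sample_times = sorted(sample_times)
        self.assays = assays
        self._taken = 0
        self.rows = []

    def maybe_record(self, world):
        from .observers import brdu_detectable
        while self._taken < len(self.sample_times) and \
                world.time + 1e-9 >= self.sample_times[self._taken]:
            t = self.sample_times[self._taken]
            self._taken += 1
            idx = world.live()
            for assay in self.assays:
                if assay == "ki67":
                    flags = ki67_positive(world)
                else:
                    flags = brdu_detectable(world.brdu[idx])
                tab = positional_fraction(world, flags)
                for _, r in tab.iterrows():
                    self.rows.append({"time": t, "assay": assay,
                                      "position": int(r["position"]),
                                      "fraction": r["fraction"],
                                      "n": int(r["n"])})

    def frame(self):
        return pd.DataFrame(self.rows)


def default_config(seed: int) -> SimulationConfig:
    cfg = SimulationConfig()
    cfg.run.seed = int(seed)
    return cfg


def run_burn_in(seed: int, days: float | None = None,
                config: SimulationConfig | None = None) -> World:
    """Initialize and run the burn-in with no observers attached."""
    cfg = config or default_config(seed)
    if days is None:
        days = cfg.run.burn_in_days
    world = initialize_world(cfg)
    dt = cfg.run.dt
    n = int(round(days * 24.0 / dt))
    for _ in range(n):
        step(world, dt)
    return world


def branch(world: World) -> World:
    """Deep copy for branching several scenarios off one burn-in."""
    return copy.deepcopy(world)


def _run(world, hours, recorders, **kw):
    dt = world.config.run.dt
    n = int(round(hours / dt))
    for _ in range(n):
        step(world, dt, recorders=recorders, **kw)


def run_homeostasis(seed: int, days: float = 20.0, world: World | None = None,
                    config: SimulationConfig | None = None) -> dict:
    world = world if world is not None else run_burn_in(seed, config=config)
    counts = CountsRecorder()
    motion = MotionRecorder()
    cycles = CycleDurationRecorder()
    recs = (counts, motion, cycles)
    _run(world, days * 24.0, recs)
    return {"world": world, "counts": counts.frame(), "motion": motion,
            "cycles": cycles, "events": world.events.to_frame()}


def run_brdu_chase(seed: int, world: World | None = None,
                   chase_hours: float = 84.0,
                   sample_offsets=(2.0, 24.0, 80.0)) -> dict:
    world = world if world is not None else run_burn_in(seed)
    t0 = world.time
    staining = StainingRecorder([t0 + o for o in sample_offsets],
                                assays=("brdu",))
    counts = CountsRecorder()
    _run(world, chase_hours, (staining, counts),
         brdu_window=(t0, t0 + 2.0))
    return {"world": world, "staining": staining.frame(),
            "counts": counts.frame()}


def run_ki67(seed: int, world: World | None = None) -> dict:
    world = world if world is not None else run_burn_in(seed)
    staining = StainingRecorder([world.time + 1.0])
    _run(world, 2.0, (staining,))
    return {"world": world, "staining": staining.frame()}


def run_stem_ablation(seed: int, world: World | None = None,
                      pre_days: float = 2.0, treat_days: float = 4.0,
                      recovery_days: float = 8.0) -> dict:
    """Four-day persistent stem ablation; analysis point 6 h after the last
    induction, plus a recovery window."""
    world = world if world is not None else run_burn_in(seed)
    counts = CountsRecorder()
    motion = MotionRecorder()           # homeostatic (pre-treatment) motion
    motion_treat = MotionRecorder()     # motion during the ablation days
    _run(world, pre_days * 24.0, (counts, motion))
    t_start = world.time
    ablation = AblationSchedule(start=t_start, duration_days=treat_days)
    _run(world, treat_days * 24.0, (counts, motion_treat), ablation=ablation)
    _run(world, 6.0, (counts,), ablation=ablation)
    analysis_time = world.time
    analysis = snapshot_counts(world)
    _run(world, recovery_days * 24.0 - 6.0, (counts,), ablation=ablation)
    return {"world": world, "counts": counts.frame(), "motion": motion,
            "motion_treatment": motion_treat,
            "events": world.events.to_frame(), "t_start": t_start,
            "analysis_time": analysis_time, "analysis_counts": analysis}


def run_cdk1(seed: int, world: World | None = None, pre_days: float = 2.0,
             treat_days: float = 4.0, recovery_days: float = 3.0) -> dict:
    world = world if world is not None else run_burn_in(seed)
    counts = CountsRecorder()
    _run(world, pre_days * 24.0, (counts,))
    t_start = world.time
    cdk1 = CDK1Schedule(start=t_start, days=treat_days,
                        strength=world.config.cycle.cdk1_strength)
    _run(world, (treat_days + recovery_days) * 24.0, (counts,), cdk1=cdk1)
    return {"world": world, "counts": counts.frame(),
            "events": world.events.to_frame(), "t_start": t_start}


def run_fu5(seed: int, dose: float, world: World | None = None,
            pre_days: float = 2.0, treat_days: float = 4.0,
            recovery_days: float = 4.0) -> dict:
    world = world if world is not None else run_burn_in(seed)
    counts = CountsRecorder()
    pk = PKRecorder()
    _run(world, pre_days * 24.0 - 2.0, (counts, pk))
    t0 = world.time + 2.0              # first dose time
    sample_times = [t0 - 1.0, t0 + 6.0] + \
        [t0 + 24.0 * d for d in (1, 2, 3, 4, 5, 5.5, 6, 6.5, 7)]
    staining = StainingRecorder(sample_times)
    _run(world, 2.0, (counts, pk, staining))
    doses = q12h_schedule(dose, days=treat_days, start=t0 + 1e-9)
    t_start = world.time
    _run(world, (treat_days + recovery_days) * 24.0,
         (counts, pk, staining), doses=doses)
    return {"world": world, "counts": counts.frame(), "pk": pk.frame(),
            "staining": staining.frame(), "events": world.events.to_frame(),
            "t_start": t_start}


def snapshot_counts(world: World) -> dict:
    out = {k.lower(): v for k, v in world.counts_by_type().items()}
    out["villus"] = world.villus.count
    out["villus_enterocytes"] = world.villus.enterocytes
    return out


def dedifferentiation_origins(events: pd.DataFrame, t_from: float = -np.inf,
                              t_to: float = np.inf) -> dict[str, float]:
    """Percentage of dedifferentiation events by originating lineage."""
    ev = events[(events["event"] == "dedifferentiation")
                & (events["time"] >= t_from) & (events["time"] <= t_to)]
    if len(ev) == 0:
        return {}
    frac = ev["cell_type"].value_counts(normalize=True) * 100.0
    return frac.to_dict()


_RUNNERS = {
    "homeostasis": lambda seed, world=None: run_homeostasis(seed, world=world),
    "brdu_chase": lambda seed, world=None: run_brdu_chase(seed, world=world),
    "ki67": lambda seed, world=None: run_ki67(seed, world=world),
    "stem_ablation": lambda seed, world=None: run_stem_ablation(seed, world=world),
    "cdk1": lambda seed, world=None: run_cdk1(seed, world=world),
    "fu5_high": lambda seed, world=None: run_fu5(seed, 50.0, world=world),
    "fu5_low": lambda seed, world=None: run_fu5(seed, 20.0, world=world),
}


def run_scenario(name: str, seed: int, out_dir=None, world: World | None = None) -> dict:
    """Execute a named scenario; optionally write the output bundle."""
    if name not in _RUNNERS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    result = _RUNNERS[name](seed, world=world)
    if out_dir is not None:
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for key in ("counts", "staining", "pk", "events"):
            if key in result and isinstance(result[key], pd.DataFrame):
                result[key].to_csv(out / f"{key}.csv", index=False)
        if "motion" in result:
            result["motion"].frame().to_csv(out / "motion.csv", index=False)
        w = result["world"]
        w.config.to_yaml(out / "config.yaml")
        manifest = {"scenario": name, "seed": int(seed),
                    "cryptsim_version": _version,
                    "final_time_h": float(w.time),
                    "final_counts": snapshot_counts(w)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
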