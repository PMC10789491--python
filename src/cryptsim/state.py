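"""Shared data model: cell types, the structure-of-arrays world state, and the
append-only event log.

Cells are stored column-wise in numpy arrays for speed; ``CellView`` provides
a per-cell object interface over the same storage. Cell ids are unique within
a run and never reused.
"""
from __future__ import annotations

from enum import IntEnum

import numpy as np
import pandas as pd

from .config import SimulationConfig


class CellType(IntEnum):
    STEM = 0
    PANETH = 1
    ABSORPTIVE_PROGENITOR = 2
    SECRETORY_PROGENITOR = 3
    GOBLET = 4
    ENTEROENDOCRINE = 5
    ENTEROCYTE = 6


#: lineages that present Delta ligands (drive Notch in their neighbours),
#: with relative presentation strengths (Paneth express the most ligand)
SECRETORY_TYPES = (CellType.PANETH, CellType.SECRETORY_PROGENITOR,
                   CellType.GOBLET, CellType.ENTEROENDOCRINE)
DELTA_STRENGTH = {CellType.PANETH: 1.0, CellType.SECRETORY_PROGENITOR: 0.6,
                  CellType.GOBLET: 0.8, CellType.ENTEROENDOCRINE: 0.8}
#: lineages that may carry an active division cycle
CYCLING_TYPES = (CellType.STEM, CellType.ABSORPTIVE_PROGENITOR,
                 CellType.SECRETORY_PROGENITOR)
#: lineages able to dedifferentiate back into stem cells
PLASTIC_TYPES = (CellType.PANETH, CellType.ABSORPTIVE_PROGENITOR,
                 CellType.SECRETORY_PROGENITOR)

NO_PHASE = -1
G1, S, G2, M = 0, 1, 2, 3
PHASE_NAMES = {NO_PHASE: "-", G1: "G1", S: "S", G2: "G2", M: "M"}

# columns of the per-cell protein state (cycle ODE)
CYC_E, CYC_A, CYC_B, CYC_W, CYC_P = range(5)


class EventLog:
    """Append-only record of births, deaths, fate changes and drug events."""

    COLUMNS = ("time", "event", "cell_id", "cell_type", "z", "detail")

    def __init__(self):
        self._rows: list[tuple] = []
        self._last_time = -np.inf

    def append(self, time, event, cell_id, cell_type, z=np.nan, detail=""):
        if time < self._last_time - 1e-9:
            raise ValueError("event log timestamps must be non-decreasing")
        self._last_time = max(self._last_time, time)
        self._rows.append((float(time), event, int(cell_id),
                           CellType(int(cell_type)).name if cell_type >= 0 else "-",
                           float(z), detail))

    def __len__(self):
        return len(self._rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows, columns=self.COLUMNS)

    def counts(self, event: str) -> int:
        return sum(1 for r in self._rows if r[1] == event)


class World:
    """All simulation state: the crypt cell population (structure of arrays),
    the villus compartment, pharmacokinetics, clock and seeded RNG."""

    _FLOATS = ("mass", "wnt", "notch", "brdu", "dna_damage", "rna_damage",
               "p21", "k27", "mu", "pressure", "pressure_ema", "b_m_entry",
               "birth_time", "last_division_time", "differentiation_time",
               "arrest_time", "ki67_memory", "cycle_start_time",
               "apopt_clear_time", "pending_since", "stem_since")
    _BOOLS = ("alive", "has_cycle", "arrested", "apoptotic", "giant",
              "restarted", "post_arrest_g1", "type_changed", "left_niche",
              "entered_niche")
    _INTS = ("cell_id", "divisions")
    _BYTES = ("ctype", "phase", "pending_type", "apopt_cause")

    def __init__(self, config: SimulationConfig, capacity: int = 512):
        config.validate()
        self.config = config
        self.time = 0.0
        self.rng = np.random.default_rng(config.run.seed)
        self.events = EventLog()
        self._next_id = 0
        self._n = 0
        self._cap = capacity
        self._free: list[int] = []
        self.index_of: dict[int, int] = {}

        self.pos = np.zeros((capacity, 3))
        self.cyc = np.zeros((capacity, 5))
        for name in self._FLOATS:
            setattr(self, name, np.zeros(capacity))
        for name in self._BOOLS:
            setattr(self, name, np.zeros(capacity, dtype=bool))
        for name in self._INTS:
            setattr(self, name, np.zeros(capacity, dtype=np.int64))
        for name in self._BYTES:
            setattr(self, name, np.full(capacity, -1, dtype=np.int8))

        self.villus = None      # set by villus.VillusCompartment
        self.pk = None          # set by pharmacology.PKState
        self.surface = None     # set by engine.initialize_world
        self.mesenchyme = None  # fixed Wnt-emitter ring positions
        self.cdk1_active = False
        self.cdk1_strength = 0.0
        self.terminal_divisions: list[tuple[float, int]] = []
        self._delta_contacts = np.zeros(capacity)   # cached presenter contacts

    # -- storage management -------------------------------------------------
    def _grow(self):
        old = self._cap
        new = old * 2
        self.pos = np.vstack([self.pos, np.zeros((old, 3))])
        self.cyc = np.vstack([self.cyc, np.zeros((old, 5))])
        for name in self._FLOATS:
            setattr(self, name, np.concatenate([getattr(self, name), np.zeros(old)]))
        for name in self._BOOLS:
            setattr(self, name, np.concatenate([getattr(self, name),
                                                np.zeros(old, dtype=bool)]))
        for name in self._INTS:
            setattr(self, name, np.concatenate([getattr(self, name),
                                                np.zeros(old, dtype=np.int64)]))
        for name in self._BYTES:
            setattr(self, name, np.concatenate([getattr(self, name),
                                                np.full(old, -1, dtype=np.int8)]))
        self._delta_contacts = np.concatenate([self._delta_contacts, np.zeros(old)])
        self._cap = new

    def new_cell(self, ctype: CellType, position, mass: float = 1.3) -> int:
        if self._free:
            i = self._free.pop()
        else:
            if self._n >= self._cap:
                self._grow()
            i = self._n
            self._n += 1
        cid = self._next_id
        self._next_id += 1

        self.pos[i] = position
        self.cyc[i] = 0.0
        for name in self._FLOATS:
            getattr(self, name)[i] = 0.0
        for name in self._BOOLS:
            getattr(self, name)[i] = False
        self.alive[i] = True
        self.cell_id[i] = cid
        self.divisions[i] = 0
        self.ctype[i] = int(ctype)
        self.phase[i] = NO_PHASE
        self.pending_type[i] = -1
        self.apopt_cause[i] = -1
        self.mass[i] = mass
        self.birth_time[i] = self.time
        self.last_division_time[i] = self.time
        self.differentiation_time[i] = self.time
        self.ki67_memory[i] = -np.inf
        self.arrest_time[i] = -np.inf
        self.stem_since[i] = self.time if ctype == CellType.STEM else -np.inf
        self._delta_contacts[i] = 0.0
        self.index_of[cid] = i
        return cid

    def remove_cell(self, cid: int):
        i = self.index_of.pop(cid)
        self.alive[i] = False
        self._free.append(i)

    # -- views --------------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.index_of)

    def live(self) -> np.ndarray:
        """Indices of live cells, in ascending storage order (deterministic)."""
        return np.flatnonzero(self.alive[: self._n])

    def radii(self, idx=None) -> np.ndarray:
        if idx is None:
            idx = self.live()
        g = self.config.geometry
        r = g.cell_radius * np.cbrt(np.maximum(self.mass[idx], 0.1))
        r[self.ctype[idx] == CellType.PANETH] *= g.paneth_radius_factor
        return r

    def stiffness(self, idx=None) -> np.ndarray:
        if idx is None:
            idx = self.live()
        m = self.config.mechanics
        k = np.full(len(idx), m.spring_stiffness)
        k[self.ctype[idx] == CellType.PANETH] *= m.paneth_stiffness_factor
        return k

    def counts_by_type(self) -> dict[str, int]:
        """Counts of detectable (non-apoptotic) cells per lineage; corpses
        awaiting clearance are tallied separately."""
        idx = self.live()
        ok = ~self.apoptotic[idx]
        out = {t.name: int(np.sum(self.ctype[idx[ok]] == t)) for t in CellType}
        out["TOTAL"] = int(ok.sum())
        out["APOPTOTIC"] = int((~ok).sum())
        return out

    def cell(self, cid: int) -> "CellView":
        return CellView(self, self.index_of[cid])


class CellView:
    """Object-style view of one cell, backed by the world's arrays."""

    _ATTRS = set(World._FLOATS) | set(World._BOOLS) | set(World._INTS)

    def __init__(self, world: World, index: int):
        object.__setattr__(self, "_w", world)
        object.__setattr__(self, "_i", index)

    def __getattr__(self, name):
        w, i = self._w, self._i
        if name == "type":
            return CellType(int(w.ctype[i]))
        if name == "position":
            return w.pos[i]
        if name == "radius":
            return float(w.radii(np.array([i]))[0])
        if name == "cycle":
            from .cycle import CycleState
            if not w.has_cycle[i]:
                return None
            return CycleState.from_world(w, i)
        if name == "phase":
            return PHASE_NAMES[int(w.phase[i])]
        if name in self._ATTRS:
            return getattr(w, name)[i]
        raise AttributeError(name)

    def __setattr__(self, name, value):
        w, i = self._w, self._i
        if name == "position":
            w.pos[i] = value
        elif name in self._ATTRS:
            getattr(w, name)[i] = value
        else:
            raise AttributeError(name)
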