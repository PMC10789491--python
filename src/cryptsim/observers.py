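"""Virtual experiments: BrdU pulse-chase, Ki-67 staining, positional
histograms, per-type counts, and retrograde-motion frequencies.

Positions are scored the way mouse slides are: cells are assigned to angular
sectors (hemi-crypt columns, default 2 per crypt) and ranked by arc length
from the crypt base, giving an integer cell position per column.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .state import CellType, G1, S, World

BRDU_THETA = 0.04        # detection threshold: between 1/32 and 1/16
KI67_MEMORY_H = 6.0      # recently-cycling / recently-arrested window


def position_index(world: World, n_sectors: int = 8):
    """(live index, sector, position) triples; positions are a gapless
    permutation 1..n within each sector, ordered by arc length."""
    idx = world.live()
    if len(idx) == 0:
        return idx, np.array([], dtype=int), np.array([], dtype=int)
    pos = world.pos[idx]
    phi = np.mod(np.arctan2(pos[:, 1], pos[:, 0]), 2 * np.pi)
    sector = np.minimum((phi / (2 * np.pi) * n_sectors).astype(int),
                        n_sectors - 1)
    s = world.surface.arc_length(pos)
    rank = np.zeros(len(idx), dtype=int)
    for sec in range(n_sectors):
        sel = np.flatnonzero(sector == sec)
        order = sel[np.argsort(s[sel], kind="stable")]
        rank[order] = np.arange(1, len(order) + 1)
    return idx, sector, rank


def brdu_pulse(world: World, active: bool) -> None:
    """While the pulse window is active, any S-phase cell labels fully."""
    if not active:
        return
    idx = world.live()
    in_s = (world.phase[idx] == S) & world.has_cycle[idx] & ~world.arrested[idx]
    world.brdu[idx[in_s]] = 1.0


def brdu_detectable(level) -> np.ndarray:
    return np.asarray(level) > BRDU_THETA


def ki67_positive(world: World, idx=None, variant: str = "figure") -> np.ndarray:
    """Ki-67 staining flags.

    variant='figure': cycling cells stain in all phases except G1 (plus the
    6 h memory of recently cycling differentiated cells and recently
    drug-arrested cells). variant='text': continuously cycling cells stain in
    G1 as well, except the first G1 after an arrest.
    """
    if idx is None:
        idx = world.live()
    t = world.time
    cycling = world.has_cycle[idx] & ~world.arrested[idx] & ~world.apoptotic[idx]
    if variant == "figure":
        pos = cycling & (world.phase[idx] != G1)
    elif variant == "text":
        pos = cycling & ~((world.phase[idx] == G1) & world.post_arrest_g1[idx])
    else:
        raise ValueError(f"unknown Ki-67 variant {variant!r}")
    recently_cycling = (t - world.ki67_memory[idx]) <= KI67_MEMORY_H
    recently_arrested = world.arrested[idx] & \
        ((t - world.arrest_time[idx]) <= KI67_MEMORY_H)
    return pos | (~cycling & recently_cycling) | recently_arrested


def positional_fraction(world: World, flags: np.ndarray,
                        n_sectors: int = 8) -> pd.DataFrame:
    """Per-position fraction of hemi-crypt columns whose cell satisfies the
    predicate encoded in ``flags`` (aligned with world.live())."""
    idx, sector, rank = position_index(world, n_sectors)
    if len(idx) == 0:
        return pd.DataFrame(columns=["position", "fraction", "n"])
    df = pd.DataFrame({"position": rank, "flag": np.asarray(flags, dtype=float)})
    g = df.groupby("position")["flag"]
    return pd.DataFrame({"position": g.mean().index,
                         "fraction": g.mean().to_numpy(),
                         "n": g.size().to_numpy()})


class CountsRecorder:
    """Periodic per-type counts for crypt and villus."""

    def __init__(self, cadence: float = 1.0):
        self.cadence = cadence
        self._next = 0.0
        self.rows = []

    def maybe_record(self, world: World):
        if world.time + 1e-9 < self._next:
            return
        self._next = world.time + self.cadence
        row = {"time": world.time}
        row.update({k.lower(): v for k, v in world.counts_by_type().items()})
        row["villus"] = world.villus.count if world.villus else 0
        row["villus_enterocytes"] = world.villus.enterocytes if world.villus else 0
        self.rows.append(row)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


class MotionRecorder:
    """Samples positions on a fixed cadence and tabulates forward/retrograde
    motion per cell position, using dz/dt outside the niche and the polar
    angle rate inside it (zero motion counts as forward)."""

    def __init__(self, cadence: float = 0.5, max_position: int = 40):
        self.cadence = cadence
        self._next = 0.0
        self._prev = None
        self.forward = np.zeros(max_position + 1)
        self.retro = np.zeros(max_position + 1)
        self.niche_forward = 0
        self.niche_retro = 0

    def maybe_record(self, world: World):
        if world.time + 1e-9 < self._next:
            return
        self._next = world.time + self.cadence
        idx, sector, rank = position_index(world)
        z, theta = world.surface.z_theta(world.pos[idx])
        in_niche = world.surface.in_niche(world.pos[idx])
        cur = {int(world.cell_id[i]): (zz, th, nn, rk)
               for i, zz, th, nn, rk in zip(idx, z, theta, in_niche, rank)}
        if self._prev is not None:
            for cid, (zz, th, nn, rk) in cur.items():
                if cid not in self._prev:
                    continue
                z0, th0, nn0, _ = self._prev[cid]
                rate = (th - th0) if nn else (zz - z0)
                p = min(rk, len(self.forward) - 1)
                if rate < 0:
                    self.retro[p] += 1
                    if nn0:
                        self.niche_retro += 1
                else:
                    self.forward[p] += 1
                    if nn0:
                        self.niche_forward += 1
        self._prev = cur

    def frame(self) -> pd.DataFrame:
        total = self.forward + self.retro
        with np.errstate(invalid="ignore", divide="ignore"):
            fr = np.where(total > 0, self.retro / total, np.nan)
        rows = [{"position": p, "forward_fraction": 1.0 - fr[p],
                 "retrograde_fraction": fr[p], "n": int(total[p])}
                for p in range(1, len(total)) if total[p] > 0]
        return pd.DataFrame(rows)

    def retro_fraction(self, positions=None) -> float:
        """Retrograde fraction; with no positions given, over movement
        intervals of cells resident in the hemispherical niche."""
        if positions is None:
            f, r = self.niche_forward, self.niche_retro
        else:
            f = self.forward[positions].sum()
            r = self.retro[positions].sum()
        return r / (f + r) if (f + r) > 0 else np.nan


def retrograde_frequency(recorder: MotionRecorder) -> pd.DataFrame:
    return recorder.frame()


class CycleDurationRecorder:
    """Birth-to-division intervals, stratified into niche-resident stem cells
    and transit-amplifying absorptive progenitors that never entered the
    niche. Fed from division events by the engine."""

    def __init__(self):
        self.stem_niche: list[float] = []
        self.ta: list[float] = []
        self.ap_terminal_divisions: list[int] = []

    def record_division(self, world: World, i: int):
        dur = world.time - world.last_division_time[i]
        if world.type_changed[i] or dur <= 0:
            return
        ct = int(world.ctype[i])
        if ct == CellType.STEM and not world.left_niche[i]:
            self.stem_niche.append(float(dur))
        elif ct == CellType.ABSORPTIVE_PROGENITOR and not world.entered_niche[i]:
            self.ta.append(float(dur))
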