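"""The villus compartment: an ordered conveyor of cells fed by the crypt
mouth and drained by shedding at the tip.

The conveyor is age-structured: a cell entering the villus base is shed when
its residence time exceeds the configured transit time, which at a fixed ring
circumference is equivalent to travelling one villus length. The compartment
supplies the enterocyte count that drives the BMP feedback. Progenitors
crossing the crypt mouth mature on entry (absorptive -> enterocyte,
secretory -> goblet/enteroendocrine).
"""
from __future__ import annotations

from collections import deque

import numpy as np

from .state import CellType, World


class VillusCompartment:
    def __init__(self, config, rng=None, prefill_time: float = 0.0):
        self.config = config
        self.queue: deque[tuple[float, int]] = deque()  # (entry_time, type)
        self._counts = {t: 0 for t in CellType}
        if config.initial_count > 0:
            # steady-state age structure: uniform entry times over one transit
            n = config.initial_count
            times = prefill_time - config.transit_time * (1.0 - (np.arange(n) + 0.5) / n)
            rng = rng or np.random.default_rng(0)
            for t in times:
                u = rng.random()
                ct = CellType.ENTEROCYTE if u < 0.90 else (
                    CellType.GOBLET if u < 0.98 else CellType.ENTEROENDOCRINE)
                self.queue.append((float(t), int(ct)))
                self._counts[CellType(int(ct))] += 1

    @property
    def count(self) -> int:
        return len(self.queue)

    @property
    def enterocytes(self) -> int:
        return self._counts[CellType.ENTEROCYTE]

    def enqueue(self, entry_time: float, ctype: CellType):
        self.queue.append((entry_time, int(ctype)))
        self._counts[CellType(int(ctype))] += 1

    def shed(self, now: float):
        """Remove (and return) all cells older than the transit time."""
        out = []
        tau = self.config.transit_time
        while self.queue and now - self.queue[0][0] > tau:
            t, ct = self.queue.popleft()
            self._counts[CellType(int(ct))] -= 1
            out.append((t, CellType(int(ct))))
        return out

    def position_of_age(self, age: float) -> float:
        """Axial position index proxy: fraction of the villus traversed."""
        return age / self.config.transit_time


def transfer_and_shed(world: World, dt: float) -> None:
    """Move cells beyond the crypt mouth onto the villus, then shed from the
    tip by residence age. Both flows are logged."""
    surface = world.surface
    idx = world.live()
    over = idx[world.pos[idx, 2] > surface.mouth_z]
    for j in over:
        ct = CellType(int(world.ctype[j]))
        if ct in (CellType.STEM, CellType.ABSORPTIVE_PROGENITOR):
            new_ct = CellType.ENTEROCYTE
        elif ct == CellType.SECRETORY_PROGENITOR:
            new_ct = CellType.GOBLET if world.rng.random() < \
                world.config.fate.goblet_fraction else CellType.ENTEROENDOCRINE
        else:
            new_ct = ct
        world.events.append(world.time, "transfer", int(world.cell_id[j]),
                            int(ct), float(world.pos[j, 2]))
        world.villus.enqueue(world.time, new_ct)
        world.remove_cell(int(world.cell_id[j]))
    for _, ct in world.villus.shed(world.time):
        world.events.append(world.time, "shed", -1, int(ct),
                            surface.mouth_z + 1.0)
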