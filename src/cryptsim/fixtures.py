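"""Deterministic miniature worlds and synthetic trajectories for fast tests
and demos. Every generator is a pure function of (name, seed)."""
from __future__ import annotations

import numpy as np

from .config import SimulationConfig
from .engine import initialize_world
from .geometry import CryptSurface
from .pharmacology import PKState
from .signalling import mesenchymal_ring
from .state import CellType, World
from .villus import VillusCompartment

FIXTURES = ("mini_crypt", "checkerboard_niche", "overlap_pair",
            "staining_columns", "conveyor_villus", "prescribed_trajectories")


def mini_config(seed: int = 0) -> SimulationConfig:
    """A miniature crypt configuration (<= 40 cells) for millisecond tests."""
    cfg = SimulationConfig()
    cfg.geometry.niche_radius = 1.8
    cfg.geometry.crypt_height = 3.0
    cfg.init.n_niche = 12
    cfg.init.cells_per_ring = 9
    cfg.init.ring_spacing = 0.9
    cfg.init.init_diff_boundary = 3.2
    cfg.villus.initial_count = 60
    cfg.signalling.znrf3_nstar = 6
    cfg.run.seed = seed
    return cfg


def _bare_world(seed, niche_radius=2.5, crypt_height=10.0) -> World:
    cfg = SimulationConfig()
    cfg.geometry.niche_radius = niche_radius
    cfg.geometry.crypt_height = crypt_height
    cfg.villus.initial_count = 0
    cfg.run.seed = seed
    world = World(cfg)
    world.surface = CryptSurface(niche_radius, crypt_height)
    world.mesenchyme = mesenchymal_ring(world.surface,
                                        cfg.signalling.n_mesenchymal_sources)
    world.villus = VillusCompartment(cfg.villus)
    world.pk = PKState(cfg.pharmacology)
    return world


def make_fixture(name: str, seed: int = 0):
    """Return the named fixture world (or trajectory set)."""
    if name == "mini_crypt":
        return initialize_world(mini_config(seed))

    if name == "checkerboard_niche":
        world = _bare_world(seed)
        cap = world.surface.cap_points(36)
        for k, p in enumerate(cap):
            ct = CellType.STEM if k % 2 == 0 else CellType.PANETH
            cid = world.new_cell(ct, p, mass=1.9)
            i = world.index_of[cid]
            world.wnt[i] = 30.0
        from .mechanics import relax
        relax(world, world.config.run.dt, jitter=False)
        return world

    if name == "overlap_pair":
        # two unit-mass cells with 20% radius overlap along x
        world = _bare_world(seed, niche_radius=2.0, crypt_height=4.0)
        r = world.config.geometry.cell_radius
        gap = 2 * r * 0.8
        z = 3.0
        R = world.surface.R
        for x in (-gap / 2, gap / 2):
            world.new_cell(CellType.ABSORPTIVE_PROGENITOR,
                           world.surface.project([x, -np.sqrt(max(R**2 - x**2, 0)), z]),
                           mass=1.0)
        return world

    if name == "staining_columns":
        # 2 columns x 10 positions; a known subset is "positive" via brdu=1
        world = _bare_world(seed, niche_radius=1.5, crypt_height=10.0)
        R = world.surface.R
        positive = {(0, 3), (0, 4), (1, 4), (1, 7)}   # (sector, position-1)
        for sec, phi in enumerate((0.5, np.pi + 0.5)):
            for k in range(10):
                z = R + 0.2 + k * 0.95
                p = [R * np.cos(phi), R * np.sin(phi), z]
                cid = world.new_cell(CellType.ENTEROCYTE, p, mass=1.0)
                if (sec, k) in positive:
                    world.brdu[world.index_of[cid]] = 1.0
        return world

    if name == "conveyor_villus":
        cfg = SimulationConfig()
        cfg.villus.transit_time = 10.0
        cfg.villus.initial_count = 50
        return VillusCompartment(cfg.villus, rng=np.random.default_rng(seed))

    if name == "prescribed_trajectories":
        # synthetic tracks: one rising, one descending, one flat
        t = np.linspace(0.0, 5.0, 11)
        return {
            "up": {"z": 5.0 + 0.3 * t, "theta": np.full_like(t, np.pi / 2)},
            "down": {"z": 5.0 - 0.3 * t, "theta": np.full_like(t, np.pi / 2)},
            "flat": {"z": np.full_like(t, 5.0), "theta": np.full_like(t, np.pi / 2)},
        }

    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURES}")
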