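"""Simulation configuration.

All lengths are in cell-diameter units (CD) internally; one CD corresponds to
roughly 8 µm in the mouse small intestine. Time is in hours throughout.
Signal levels (Wnt, Notch, BMP) and protein concentrations are in arbitrary
units (A.U.).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml


class ConfigurationError(ValueError):
    """Raised for invalid scenario/geometry configuration."""


@dataclass
class GeometryConfig:
    """Crypt surface: hemispherical niche of radius ``niche_radius`` smoothly
    joined to a cylinder of the same radius and height ``crypt_height``.
    The crypt mouth sits at z = niche_radius + crypt_height."""
    niche_radius: float = 2.5
    crypt_height: float = 12.0
    cell_radius: float = 0.42          # radius at unit mass; r = cell_radius * mass^(1/3)
    paneth_radius_factor: float = 1.4
    contact_factor: float = 1.1        # neighbour cutoff multiplier on sum of radii


@dataclass
class MechanicsConfig:
    spring_stiffness: float = 20.0     # Hookean overlap spring (force / CD overlap)
    paneth_stiffness_factor: float = 4.0
    drag: float = 1.0                  # overdamped drag; velocity = force / drag
    paneth_anchor: float = 5.0         # basal anchoring force on Paneth cells
    paneth_drag_factor: float = 4.0   # Paneth are quasi-immobile (niche retention)
    division_separation: float = 0.2   # daughter offset along a random tangent (CD)
    jitter: float = 0.02               # random-motility amplitude, CD / sqrt(h)
    max_step_displacement: float = 0.75  # instability guard (~1 cell radius per step)


@dataclass
class SignallingConfig:
    wnt_range: float = 1.3             # emission range of Paneth/mesenchymal sources (CD)
    wnt_max: float = 60.0              # receptor saturation: tethered-Wnt ceiling
    wnt_tether_rate: float = 1.5       # A.U./h per unit source weight
    znrf3_nstar: int = 24              # homeostatic stem-cell count N*
    znrf3_exponent: float = 1.0        # feedback phi = min(1, (N*/S)^h)
    n_mesenchymal_sources: int = 28    # virtual emitter shell around the niche
    notch_rate: float = 1.0            # A.U./h per Delta-presenting contact
    notch_decay: float = 0.5           # 1/h
    bmp_scale: float = 0.05            # per enterocyte
    bmp_z0: float = 8.0                # logistic midpoint of g(z)
    bmp_width: float = 2.0
    bmp_antagonist_zone: float = 1.0   # CD above the niche still protected
    bmp_antagonist_factor: float = 0.2


@dataclass
class FateConfig:
    wnt_high: float = 22.0             # stemness requires wnt >= wnt_high (with notch)
    wnt_low: float = 13.0              # stem cells demote below this (hysteresis band)
    notch_on: float = 2.0              # Notch for absorptive cells to gain stemness
    notch_on_secretory: float = 2.0    # Paneth/secretory progenitors revert easier
    notch_off: float = 1.85             # stem cells demote below this
    notch_split: float = 1.2           # absorptive (>=) vs secretory (<) decision
    bmp_alpha: float = 0.1             # terminal differentiation when B > alpha*wnt + beta
    bmp_beta: float = 5.0
    min_divisions: int = 3
    max_divisions: int = 5
    wnt_floor: float = 1.0             # proliferative capacity exhausted below
                                       # this tethered-Wnt level (differentiate)
    bmp_floor: float = 2.0             # forced differentiation at the division
                                       # cap needs at least this much BMP
    dwell_time: float = 0.5            # h a fate decision must persist before switching
    dediff_dwell: float = 4.0          # h of sustained stem-level signals before a
                                       # committed cell reverts (reprogramming time)
    goblet_fraction: float = 0.75      # goblet : enteroendocrine split for maturing SP
    sp_maturation_rate: float = 0.5    # 1/h once above the niche
    sp_k27: float = 1.28               # slow cycle for secretory progenitors


@dataclass
class CycleConfig:
    # pressure -> p27 production map:
    # k27(p) = k27_min + (k27_max - k27_min) * p^n / (p_half^n + p^n),
    # clamped at k27_clamp (the calibrated niche anchor) so the densest niche
    # moments saturate at the long-cycle anchor; k27_min sets the shortest
    # configured cycle under full pressure release
    k27_min: float = 0.45
    pressure_tau: float = 3.0          # h; EMA smoothing of pressure before the map
    k27_max: float = 1.30
    pressure_half: float = 1.15
    pressure_exponent: float = 16.0
    k27_clamp: float = 1.21
    giant_mass_cap: float = 4.2        # mass (x newborn) beyond which a cell arrests as giant
    mass_saturation: float = 4.8
    cdk1_strength: float = 0.9         # fractional cut of CycA/CycB production while inhibited
    mitotic_death_fraction: float = 0.45 # CycB below this fraction of M-entry level -> death


@dataclass
class MetaboliteConfig:
    formation: float                   # 1/h from parent
    elimination: float                 # 1/h


@dataclass
class PharmacologyConfig:
    fu_elimination: float = 3.0        # parent 5-FU, 1/h (t1/2 ~ 14 min)
    futp: MetaboliteConfig = field(default_factory=lambda: MetaboliteConfig(0.15, 0.8))
    fdump: MetaboliteConfig = field(default_factory=lambda: MetaboliteConfig(0.20, 1.0))
    fdutp: MetaboliteConfig = field(default_factory=lambda: MetaboliteConfig(0.05, 0.9))
    dose_to_conc: float = 500.0        # ng/ml plasma per mg/kg bolus
    epithelium_factor: float = 1.0     # epithelium concentration / plasma
    k_rna: float = 8e-5                # RNA damage per ng/ml FUTP per h (proliferative)
    k_dna: float = 4.0e-3                # DNA damage per ng/ml FdUTP per h (S-phase only)
    repair_rna: float = 0.05           # 1/h
    repair_dna: float = 0.05
    theta_p21: float = 0.2             # DNA damage triggering p21 induction
    theta_apopt_dna: float = 1.0       # checkpoint apoptosis thresholds
    theta_apopt_rna: float = 1.2
    p21_rate: float = 2.0
    p21_decay: float = 0.5
    rna_slowdown: float = 0.5          # rho = 1/(1 + rna_slowdown * rna)
    arrest_rho: float = 0.55           # global slowdown below which the cycle arrests
    arrest_p21: float = 3.0
    apoptosis_clearance: float = 1.0   # h between decision and removal


@dataclass
class VillusConfig:
    transit_time: float = 84.0         # h from villus base to shedding at the tip
    initial_count: int = 650
    include_crypt_enterocytes: bool = False


@dataclass
class InitConfig:
    n_niche: int = 44                  # cells seeded on the hemispherical cap
    ring_spacing: float = 0.85         # CD between seeded rings on the cylinder
    cells_per_ring: int = 15
    init_diff_boundary: float = 8.5    # z above which initial cells are mature
    init_secretory_fraction: float = 0.12


@dataclass
class RunConfig:
    dt: float = 0.02                   # h
    seed: int = 0
    burn_in_days: float = 14.0
    counts_cadence: float = 1.0        # h between count frames
    motion_cadence: float = 0.5        # h between trajectory samples


@dataclass
class SimulationConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    mechanics: MechanicsConfig = field(default_factory=MechanicsConfig)
    signalling: SignallingConfig = field(default_factory=SignallingConfig)
    fate: FateConfig = field(default_factory=FateConfig)
    cycle: CycleConfig = field(default_factory=CycleConfig)
    pharmacology: PharmacologyConfig = field(default_factory=PharmacologyConfig)
    villus: VillusConfig = field(default_factory=VillusConfig)
    init: InitConfig = field(default_factory=InitConfig)
    run: RunConfig = field(default_factory=RunConfig)

    def validate(self) -> None:
        g = self.geometry
        if g.niche_radius <= 0 or g.crypt_height <= 0 or g.cell_radius <= 0:
            raise ConfigurationError("geometry radii/height must be positive")
        if self.run.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if not (self.fate.wnt_high > self.fate.wnt_low > 0):
            raise ConfigurationError("need wnt_high > wnt_low > 0")
        for name in ("wnt_tether_rate", "notch_rate", "notch_decay", "bmp_scale"):
            if getattr(self.signalling, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        def build(tp, val):
            if dataclasses.is_dataclass(tp) and isinstance(val, dict):
                kwargs = {}
                for f in dataclasses.fields(tp):
                    if f.name in val:
                        ftype = f.type if not isinstance(f.type, str) else _TYPES.get(f.name, None)
                        kwargs[f.name] = build(ftype, val[f.name]) if ftype else val[f.name]
                return tp(**kwargs)
            return val

        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                kwargs[f.name] = build(_TYPES[f.name], d[f.name])
        return cls(**kwargs)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "SimulationConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, ValueError):
                data = yaml.safe_load(source)
        cfg = cls.from_dict(data)
        cfg.validate()
        return cfg


_TYPES: dict[str, Any] = {
    "geometry": GeometryConfig, "mechanics": MechanicsConfig,
    "signalling": SignallingConfig, "fate": FateConfig, "cycle": CycleConfig,
    "pharmacology": PharmacologyConfig, "villus": VillusConfig,
    "init": InitConfig, "run": RunConfig,
    "futp": MetaboliteConfig, "fdump": MetaboliteConfig, "fdutp": MetaboliteConfig,
}
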