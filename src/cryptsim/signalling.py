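"""Wnt tethering with ZNRF3/RNF43-like feedback, Notch lateral inhibition and
the enterocyte-coupled BMP gradient.

Wnt is emitted by Paneth cells and by a fixed ring of mesenchymal sources at
the niche boundary; cells within range tether Wnt at a rate attenuated by a
negative feedback from the current stem-cell count (the ZNRF3/RNF43 proxy).
Tethered Wnt is never removed except by halving at division.

Notch is a continuous accumulated level fed by Delta-presenting (secretory)
contacts with first-order decay.

BMP is an analytic axial profile proportional to the current enterocyte
count (the hedgehog relay), increasing in z and suppressed in an antagonist
zone around the niche.
"""
from __future__ import annotations

import numpy as np

from .state import CellType, World


def mesenchymal_ring(surface, n: int) -> np.ndarray:
    """Static shell of virtual Wnt emitters surrounding the hemispherical
    niche (just outside the epithelium), closing with a ring at the niche
    boundary. Mesenchyme is not an agent; these sources never move."""
    R = surface.R + 0.6
    k = np.arange(n) + 0.5
    cz = -k / n                      # lower hemisphere, pole included
    theta = np.arccos(cz)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * np.arange(n)
    x = R * np.sin(theta) * np.cos(phi)
    y = R * np.sin(theta) * np.sin(phi)
    z = surface.R + R * cz
    return np.column_stack([x, y, z])


def znrf3_feedback(stem_count: int, nstar: int, exponent: float) -> float:
    """phi = min(1, (N*/S)^h); full tethering at or below the homeostatic
    stem number, attenuated above it."""
    if stem_count <= nstar:
        return 1.0
    return float(min(1.0, (nstar / stem_count) ** exponent))


def update_wnt(world: World, dt: float) -> None:
    sig = world.config.signalling
    idx = world.live()
    if len(idx) == 0:
        return
    stems = int(np.sum(world.ctype[idx] == CellType.STEM))
    phi = znrf3_feedback(stems, sig.znrf3_nstar, sig.znrf3_exponent)

    paneth = idx[world.ctype[idx] == CellType.PANETH]
    sources = world.pos[paneth]
    if world.mesenchyme is not None:
        sources = np.vstack([sources, world.mesenchyme]) if len(sources) \
            else world.mesenchyme
    if len(sources) == 0:
        return
    pos = world.pos[idx]
    d = np.sqrt(np.sum((pos[:, None, :] - sources[None, :, :]) ** 2, axis=2))
    # graded short-range field: each source contributes linearly down to zero
    # at its emission range, so cells deep in the niche tether fastest
    weight = np.sum(np.maximum(0.0, 1.0 - d / sig.wnt_range), axis=1)
    wnt = world.wnt[idx] + sig.wnt_tether_rate * phi * weight * dt
    world.wnt[idx] = np.minimum(wnt, sig.wnt_max)   # receptor saturation


def update_notch(world: World, dt: float) -> None:
    sig = world.config.signalling
    idx = world.live()
    if len(idx) == 0:
        return
    n_delta = world._delta_contacts[idx]
    notch = world.notch[idx]
    world.notch[idx] = notch + (sig.notch_rate * n_delta
                                - sig.notch_decay * notch) * dt


def notch_steady_state(n_presenters: float, config) -> float:
    """Closed-form steady state k*n/lambda for a fixed presenter count."""
    return config.signalling.notch_rate * n_presenters / config.signalling.notch_decay


def enterocyte_count(world: World) -> int:
    count = world.villus.enterocytes if world.villus is not None else 0
    if world.config.villus.include_crypt_enterocytes:
        idx = world.live()
        count += int(np.sum(world.ctype[idx] == CellType.ENTEROCYTE))
    return count


def evaluate_bmp(world: World, z, e_count=None):
    """B(z, t) = scale * E(t) * g(z) * a(z).

    g is a normalized logistic in z (increasing toward the villus) and a(z)
    is the antagonist suppression near the niche.
    """
    sig = world.config.signalling
    if e_count is None:
        e_count = enterocyte_count(world)
    z = np.asarray(z, dtype=float)
    g = 1.0 / (1.0 + np.exp(-(z - sig.bmp_z0) / sig.bmp_width))
    zone = world.surface.R + sig.bmp_antagonist_zone
    a = np.where(z < zone, sig.bmp_antagonist_factor, 1.0)
    return sig.bmp_scale * e_count * g * a
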