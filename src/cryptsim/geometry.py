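"""Crypt surface geometry.

The crypt is a hemisphere of radius R (the stem-cell niche, pole at z = 0)
smoothly joined at z = R to a cylinder of radius R and height H. The crypt
mouth is the circle z = R + H; cells crossing it transfer to the villus.

Parametrization per cell:
  * z      -- height above the crypt base pole,
  * theta  -- polar angle from the downward axis (cap only), in [0, pi/2],
  * s      -- arc length from the base pole along a meridian
              (s = R*theta on the cap, s = R*pi/2 + (z - R) on the cylinder).
"""
from __future__ import annotations

import numpy as np


class CryptSurface:
    def __init__(self, niche_radius: float, crypt_height: float):
        if niche_radius <= 0 or crypt_height <= 0:
            raise ValueError("surface radii must be positive")
        self.R = float(niche_radius)
        self.H = float(crypt_height)

    @property
    def mouth_z(self) -> float:
        return self.R + self.H

    def project(self, points: np.ndarray) -> np.ndarray:
        """Project points onto the surface. Idempotent to numerical precision."""
        p = np.atleast_2d(np.asarray(points, dtype=float)).copy()
        R = self.R
        centre = np.array([0.0, 0.0, R])
        d = p - centre
        # points whose direction from the sphere centre aims below the junction
        # plane belong to the cap; others to the cylinder
        on_cap = d[:, 2] < 0.0
        if np.any(on_cap):
            dc = d[on_cap]
            norm = np.linalg.norm(dc, axis=1, keepdims=True)
            # a point exactly at the centre has no direction; nudge to the pole
            bad = norm[:, 0] < 1e-12
            if np.any(bad):
                dc[bad] = (0.0, 0.0, -1.0)
                norm[bad] = 1.0
            p[on_cap] = centre + R * dc / norm
        cyl = ~on_cap
        if np.any(cyl):
            xy = p[cyl, :2]
            rho = np.linalg.norm(xy, axis=1, keepdims=True)
            bad = rho[:, 0] < 1e-12
            if np.any(bad):
                xy[bad] = (1.0, 0.0)
                rho[bad] = 1.0
            p[cyl, :2] = R * xy / rho
            p[cyl, 2] = np.maximum(p[cyl, 2], R)
        return p if np.asarray(points).ndim > 1 else p[0]

    def residual(self, points: np.ndarray) -> np.ndarray:
        """Distance from each point to its surface projection."""
        p = np.atleast_2d(points)
        return np.linalg.norm(p - self.project(p), axis=1)

    def z_theta(self, points: np.ndarray):
        """Longitudinal coordinate z and (cap) polar angle theta.

        theta increases from 0 at the base pole to pi/2 at the cap-cylinder
        junction, so increasing theta points toward the villus. On the
        cylinder theta is pinned at pi/2.
        """
        p = np.atleast_2d(points)
        z = p[:, 2]
        theta = np.where(z < self.R,
                         np.arccos(np.clip((self.R - z) / self.R, -1.0, 1.0)),
                         np.pi / 2)
        return z, theta

    def arc_length(self, points: np.ndarray) -> np.ndarray:
        """Meridional arc length from the crypt base pole (continuous in z)."""
        z, theta = self.z_theta(points)
        s_cap = self.R * theta
        s_cyl = self.R * np.pi / 2 + (z - self.R)
        return np.where(z < self.R, s_cap, s_cyl)

    def in_niche(self, points: np.ndarray) -> np.ndarray:
        """True for positions on the hemispherical cap."""
        return np.atleast_2d(points)[:, 2] < self.R

    def random_tangent(self, point: np.ndarray, rng) -> np.ndarray:
        """Unit tangent to the surface at ``point`` in a seeded random direction."""
        n = self.normal(point)
        v = rng.standard_normal(3)
        v -= v.dot(n) * n
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            v = np.cross(n, [0.0, 0.0, 1.0])
            nv = np.linalg.norm(v)
            if nv < 1e-12:
                v = np.cross(n, [1.0, 0.0, 0.0])
                nv = np.linalg.norm(v)
        return v / nv

    def normal(self, point: np.ndarray) -> np.ndarray:
        p = np.asarray(point, dtype=float)
        if p[2] < self.R:
            d = p - np.array([0.0, 0.0, self.R])
            n = np.linalg.norm(d)
            return d / n if n > 1e-12 else np.array([0.0, 0.0, -1.0])
        rho = np.hypot(p[0], p[1])
        if rho < 1e-12:
            return np.array([1.0, 0.0, 0.0])
        return np.array([p[0] / rho, p[1] / rho, 0.0])

    def cap_points(self, n: int, rng=None) -> np.ndarray:
        """Deterministic, roughly uniform Fibonacci layout of n points on the cap."""
        k = np.arange(n) + 0.5
        # cos(theta_polar) uniform on [-1, 0]: lower hemisphere of the sphere
        cz = -k / n
        theta = np.arccos(cz)
        golden = np.pi * (3.0 - np.sqrt(5.0))
        phi = golden * np.arange(n)
        R = self.R
        x = R * np.sin(theta) * np.cos(phi)
        y = R * np.sin(theta) * np.sin(phi)
        z = R + R * cz
        return np.column_stack([x, y, z])
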