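"""Arena (tank) geometry models used for confined pair statistics.

The observation tank is bowl-shaped: its wall is the paraboloid
``z = c * (x^2 + y^2)`` (c in 1/mm) capped above by a flat water surface
at ``z = water_level``.  The radial distribution function of a confined
group must be normalised against uniform configurations drawn in the same
region, so every arena provides membership tests and uniform sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class Arena:
    """Interface: a bounded 3D region with membership test and uniform sampling."""

    def contains(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError


@dataclass
class ParaboloidArena(Arena):
    """Bowl-shaped tank: z >= coeff * r^2, 0 <= z <= water_level.

    Defaults model the observation tank (coeff = 0.734 / mm with lengths
    in mm; the water level sets the overall size).
    """

    coeff: float = 0.734e-3  # 1/mm; z and r in mm (0.734 with r, z in m)
    water_level: float = 150.0  # mm
    tol: float = 1e-9

    @property
    def max_radius(self) -> float:
        return float(np.sqrt(self.water_level / self.coeff))

    def contains(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        r2 = points[:, 0] ** 2 + points[:, 1] ** 2
        z = points[:, 2]
        return (z >= self.coeff * r2 - self.tol) & (z <= self.water_level + self.tol)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform points in the bowl via rejection from the bounding cylinder.

        The bowl fills exactly half of the cylinder, so the loop converges
        geometrically.
        """
        out = np.empty((0, 3))
        rmax = self.max_radius
        while len(out) < n:
            m = max(2 * (n - len(out)), 16)
            xy = rng.uniform(-rmax, rmax, size=(m, 2))
            z = rng.uniform(0.0, self.water_level, size=m)
            cand = np.column_stack([xy, z])
            inside = (xy[:, 0] ** 2 + xy[:, 1] ** 2 <= rmax**2) & self.contains(cand)
            out = np.vstack([out, cand[inside]])
        return out[:n]

    def volume(self) -> float:
        # integral of pi r^2(z) dz with r^2 = z / coeff
        return float(np.pi * self.water_level**2 / (2 * self.coeff))


@dataclass
class BoxArena(Arena):
    """Axis-aligned box [lo, hi]^3 (or per-axis bounds); mainly for tests."""

    lo: tuple[float, float, float] = (0.0, 0.0, 0.0)
    hi: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def contains(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        lo = np.asarray(self.lo)
        hi = np.asarray(self.hi)
        return np.all((points >= lo) & (points <= hi), axis=1)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.lo, self.hi, size=(n, 3))
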