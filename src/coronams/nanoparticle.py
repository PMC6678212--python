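"""Rigid citrate-capped gold nanoparticle bead model.

The nanoparticle is a hollow sphere of beads placed on a deterministic
Fibonacci lattice.  A uniform negative charge per bead stands in for a
monolayer of adsorbed citrate; dividing the total surface charge by the
charge of one citrate ion gives the implied citrate count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GoldNP", "build_gold_np", "estimate_citrate_count", "scale_np"]


@dataclass
class GoldNP:
    """Hollow sphere of equally charged beads.

    Attributes
    ----------
    diameter : float, Å
    coords : (n, 3) float array, Å — bead positions on the sphere surface
    bead_charge : float, e — identical for every bead
    center : (3,) float array, Å
    """

    diameter: float
    coords: np.ndarray
    bead_charge: float
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    @property
    def total_charge(self) -> float:
        return self.n_beads * self.bead_charge

    @property
    def charges(self) -> np.ndarray:
        return np.full(self.n_beads, self.bead_charge)

    def surface_distance(self, points: np.ndarray) -> np.ndarray:
        """Distance from point(s) to the sphere surface (negative inside)."""
        pts = np.atleast_2d(points)
        d = np.linalg.norm(pts - self.center, axis=-1) - self.radius
        return d if np.ndim(points) > 1 else float(d[0])


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere lattice (golden-angle spiral), n ≥ 1."""
    i = np.arange(n, dtype=float)
    # offset 0.5 avoids clustering at the poles
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def build_gold_np(diameter: float, n_beads: int = 5160,
                  bead_charge: float = -0.5,
                  center=(0.0, 0.0, 0.0)) -> GoldNP:
    """Build the nanoparticle bead sphere.

    Defaults correspond to a 15 nm particle built from 5160 beads of
    −0.5 e each (pass ``diameter=150.0`` for 15 nm).
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if n_beads < 12:
        raise ValueError("need at least 12 beads for a sphere shell")
    center = np.asarray(center, dtype=float)
    coords = center + (diameter / 2.0) * _fibonacci_sphere(n_beads)
    return GoldNP(diameter=float(diameter), coords=coords,
                  bead_charge=float(bead_charge), center=center)


def estimate_citrate_count(nano: GoldNP, citrate_charge: float = -3.0) -> int:
    """Number of citrate ions implied by the total surface charge.

    The default −3 e corresponds to fully deprotonated citrate.
    """
    if citrate_charge >= 0:
        raise ValueError("citrate charge must be negative")
    return int(round(nano.total_charge / citrate_charge))


def scale_np(nano: GoldNP, new_diameter: float) -> GoldNP:
    """Rescale the particle, preserving surface bead density and per-bead
    charge (bead count grows with the surface area ratio)."""
    if new_diameter <= 0:
        raise ValueError("diameter must be positive")
    if new_diameter == nano.diameter:
        return build_gold_np(nano.diameter, nano.n_beads, nano.bead_charge,
                             nano.center)
    n_new = int(round(nano.n_beads * (new_diameter / nano.diameter) ** 2))
    return build_gold_np(new_diameter, max(n_new, 12), nano.bead_charge,
                         nano.center)
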