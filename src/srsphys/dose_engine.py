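"""Point-dose verification formula, grid superposition, and inverse MU.

The point dose of one beam is

    D(x) = MU * C * OCR(coll, deff, OAD) * TMR(coll, deff) * OF(coll) * (450/SAD_x)^2

with C the absolute calibration (cGy/MU at dmax, SAD 450 mm, reference
collimator), ``deff`` the water-equivalent depth along the central axis to the
projection of ``x`` on the axis, ``OAD`` the perpendicular distance from ``x``
to the axis scaled to the isocenter plane, and ``SAD_x`` the source-to-
projection distance.  Phantoms are water-equivalent spheres (density-scaled);
beams that miss the phantom contribute zero (no air dose is modelled).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .beam_model import SAD_REF, BeamDataSet, lookup_ocr, lookup_tmr

__all__ = ["BeamSpec", "Phantom", "DoseGrid", "point_dose", "dose_at_points",
           "compute_mu", "superpose"]


@dataclass
class BeamSpec:
    """One therapeutic beam: collimator, monitor units, and geometry."""

    coll: float
    mu: float
    source_position: np.ndarray
    axis_direction: np.ndarray
    sad: float = SAD_REF

    def __post_init__(self) -> None:
        self.source_position = np.asarray(self.source_position, dtype=float)
        self.axis_direction = np.asarray(self.axis_direction, dtype=float)
        if self.mu < 0:
            raise ValueError("monitor units must be non-negative")
        if self.sad <= 0:
            raise ValueError("SAD must be positive")
        norm = float(np.linalg.norm(self.axis_direction))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("axis_direction must be a unit vector")

    @classmethod
    def isocentric(cls, coll: float, mu: float, direction,
                   sad: float = SAD_REF, isocenter=(0.0, 0.0, 0.0)) -> "BeamSpec":
        """Beam pointing along ``direction`` through ``isocenter`` at ``sad``."""
        direction = np.asarray(direction, dtype=float)
        direction = direction / np.linalg.norm(direction)
        source = np.asarray(isocenter, dtype=float) - sad * direction
        return cls(coll=coll, mu=mu, source_position=source,
                   axis_direction=direction, sad=sad)


@dataclass
class Phantom:
    """Water-equivalent sphere (the reference geometry is a 200 mm head)."""

    center: np.ndarray
    diameter: float = 200.0
    density: float = 1.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.diameter <= 0 or self.density <= 0:
            raise ValueError("diameter and density must be positive")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    def ray_entry(self, origin, direction):
        """Distance along the ray to the sphere entry point, or ``None``."""
        origin = np.asarray(origin, dtype=float)
        direction = np.asarray(direction, dtype=float)
        oc = origin - self.center
        b = float(np.dot(oc, direction))
        disc = b * b - (float(np.dot(oc, oc)) - self.radius**2)
        if disc < 0:
            return None
        t0 = -b - np.sqrt(disc)
        return float(t0)


@dataclass
class DoseGrid:
    """Regular 3-D grid of absolute dose (cGy)."""

    origin: np.ndarray
    spacing: np.ndarray
    dims: tuple
    dose: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.dims = tuple(int(n) for n in self.dims)
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive")
        if self.dose is None:
            self.dose = np.zeros(self.dims)
        else:
            self.dose = np.asarray(self.dose, dtype=float)
            if self.dose.shape != self.dims:
                raise ValueError("dose array shape must equal dims")

    @classmethod
    def centered(cls, half_extent: float, spacing: float = 1.0,
                 center=(0.0, 0.0, 0.0)) -> "DoseGrid":
        """Cubic grid of +/- ``half_extent`` mm about ``center``."""
        n = int(round(2 * half_extent / spacing)) + 1
        center = np.asarray(center, dtype=float)
        origin = center - half_extent
        return cls(origin=origin, spacing=np.full(3, float(spacing)),
                   dims=(n, n, n))

    def points(self) -> np.ndarray:
        """Voxel-center coordinates, shape ``(prod(dims), 3)``, C order."""
        axes = [self.origin[k] + self.spacing[k] * np.arange(self.dims[k])
                for k in range(3)]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=-1)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


def dose_at_points(data: BeamDataSet, beam: BeamSpec, phantom: Phantom,
                   points) -> np.ndarray:
    """Vectorised single-beam dose at an ``(n, 3)`` array of points, cGy."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    u = beam.axis_direction
    t0 = phantom.ray_entry(beam.source_position, u)
    if t0 is None:
        warnings.warn("beam central axis misses the phantom; dose is 0",
                      stacklevel=2)
        return np.zeros(len(pts))
    v = pts - beam.source_position
    sad_x = v @ u                              # source-to-projection distance
    downstream = sad_x > 0
    sad_safe = np.where(downstream, sad_x, 1.0)
    proj = beam.source_position + sad_safe[:, None] * u
    perp = np.linalg.norm(pts - proj, axis=1)
    oad = perp * (SAD_REF / sad_safe)          # scaled to the isocenter plane
    deff = (sad_safe - t0) * phantom.density   # water-equivalent central depth
    in_phantom = downstream & (deff >= 0)
    deff = np.clip(deff, 0.0, None)
    ocr = np.asarray(lookup_ocr(data, beam.coll, deff, oad))
    tmr = np.asarray(lookup_tmr(data, beam.coll, deff))
    of = data.output_factor(beam.coll)
    dose = (beam.mu * data.calibration * ocr * tmr * of
            * (SAD_REF / sad_safe) ** 2)
    return np.where(in_phantom, dose, 0.0)


def point_dose(data: BeamDataSet, beam: BeamSpec, phantom: Phantom, x) -> float:
    """Single-beam dose at one point, cGy (0 if the beam misses the phantom)."""
    return float(dose_at_points(data, beam, phantom, np.asarray(x))[0])


def compute_mu(prescription_dose: float, prescription_isodose: float,
               tmr: float, of: float, sad: float = SAD_REF,
               calibration: float = 1.0) -> float:
    """Monitor units delivering ``prescription_dose`` to the isodose surface.

    MU = D / (isodose * TMR * OF * C * (450/SAD)^2).  The prescription isodose
    is a fraction of the axis maximum (0.8 for a typical 80% prescription).
    """
    if not 0 < prescription_isodose <= 1:
        raise ValueError("prescription isodose must lie in (0, 1]")
    if tmr <= 0 or of <= 0 or calibration <= 0 or sad <= 0:
        raise ValueError("TMR, OF, calibration and SAD must be positive")
    return prescription_dose / (
        prescription_isodose * tmr * of * calibration * (SAD_REF / sad) ** 2
    )


def superpose(data: BeamDataSet, beams, phantom: Phantom,
              grid: DoseGrid) -> DoseGrid:
    """Voxelwise sum of per-beam point doses over the grid (linear in MU)."""
    beams = list(beams)
    if not beams:
        raise ValueError("at least one beam is required")
    pts = grid.points()
    total = np.zeros(len(pts))
    for beam in beams:
        total += dose_at_points(data, beam, phantom, pts)
    return DoseGrid(origin=grid.origin.copy(), spacing=grid.spacing.copy(),
                    dims=grid.dims, dose=total.reshape(grid.dims))
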