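"""Beam-profile metrics: field size, 80–20% penumbra, symmetry, focal spot.

The reference level for the 50/80/20% thresholds is the central-axis reading,
estimated as the mean of the three samples nearest the field centre (robust to
single-sample noise spikes); all crossings are located by linear interpolation
between samples, so each estimator resolves to about one sample spacing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = ["ProfileShapeError", "ScanProfile", "FocalSpotCamera",
           "FocalSpotResult", "field_size", "penumbra", "symmetry",
           "focal_spot_size"]


class ProfileShapeError(ValueError):
    """The profile lacks the edges/crossings a metric requires."""


@dataclass
class ScanProfile:
    """A 1-D scanned dose profile (relative readings vs lateral position)."""

    positions: np.ndarray
    readings: np.ndarray
    depth: float = 0.0
    coll: float = 0.0
    plane: str = "wheel-plane"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.readings = np.asarray(self.readings, dtype=float)
        if self.positions.shape != self.readings.shape or self.positions.ndim != 1:
            raise ProfileShapeError("positions and readings must be equal-length 1-D")
        if self.positions.size < 10:
            raise ProfileShapeError("profile needs at least 10 samples")
        if np.any(np.diff(self.positions) <= 0):
            raise ProfileShapeError("positions must be strictly increasing")
        if np.max(self.readings) <= 0:
            raise ProfileShapeError("profile must contain positive readings")

    def smoothed(self, window: int = 3) -> "ScanProfile":
        """Optional moving-average copy (no smoothing is applied by default)."""
        kernel = np.ones(window) / window
        pad = window // 2
        padded = np.pad(self.readings, pad, mode="edge")
        return ScanProfile(self.positions, np.convolve(padded, kernel, "valid"),
                           self.depth, self.coll, self.plane)


@dataclass(frozen=True)
class FocalSpotCamera:
    """Stacked-leaf slit camera: alternating absorber leaves and spacers."""

    leaf_thickness: float = 0.1
    spacer_thickness: float = 0.1
    n_leaves: int = 100
    ssd_camera: float = 228.0

    def __post_init__(self) -> None:
        if self.leaf_thickness <= 0 or self.spacer_thickness <= 0:
            raise ValueError("leaf and spacer thickness must be positive")

    @property
    def pitch(self) -> float:
        """One line pair = one leaf + one spacer, mm."""
        return self.leaf_thickness + self.spacer_thickness


class FocalSpotResult(NamedTuple):
    size_mm: float
    uncertainty_mm: float


def _central_reading(profile: ScanProfile) -> tuple[float, float]:
    """(reference level, field centre): two-pass centre-then-reference."""
    x, y = profile.positions, profile.readings
    crude = _crossings(x, y, 0.5 * float(np.max(y)))
    center = 0.5 * (crude[0] + crude[1])
    nearest = np.argsort(np.abs(x - center))[:3]
    ref = float(np.mean(y[nearest]))
    if ref <= 0:
        raise ProfileShapeError("central reading must be positive")
    left, right = _crossings(x, y, 0.5 * ref)
    return ref, 0.5 * (left + right)


def _crossings(x: np.ndarray, y: np.ndarray, level: float) -> tuple[float, float]:
    """Outermost rising/falling crossings of ``level``, linearly interpolated."""
    above = y >= level
    if not above.any() or above[0] or above[-1]:
        raise ProfileShapeError(
            f"profile does not cross level {level:g} on both sides"
        )
    i = int(np.argmax(above))                 # first sample at/above level
    j = len(y) - 1 - int(np.argmax(above[::-1]))  # last sample at/above level
    left = x[i - 1] + (level - y[i - 1]) / (y[i] - y[i - 1]) * (x[i] - x[i - 1])
    right = x[j] + (level - y[j]) / (y[j + 1] - y[j]) * (x[j + 1] - x[j])
    return float(left), float(right)


def field_size(profile: ScanProfile) -> float:
    """Distance between the 50%-of-central-reading crossings, mm."""
    ref, _ = _central_reading(profile)
    left, right = _crossings(profile.positions, profile.readings, 0.5 * ref)
    return right - left


def penumbra(profile: ScanProfile) -> tuple[float, float]:
    """Per-side 80%→20% distances ``(left, right)``, mm."""
    ref, _ = _central_reading(profile)
    x, y = profile.positions, profile.readings
    l80, r80 = _crossings(x, y, 0.8 * ref)
    l20, r20 = _crossings(x, y, 0.2 * ref)
    left, right = l80 - l20, r20 - r80
    if left < 0 or right < 0:
        raise ProfileShapeError("profile edge is not monotone (80% inside 20%)")
    return float(left), float(right)


def symmetry(profile: ScanProfile, fraction_of_radius: float = 0.8,
             n_eval: int = 201) -> float:
    """Max point-difference symmetry, percent of the central reading.

    max over |x| <= ``fraction_of_radius`` x field radius of
    |D(c+x) − D(c−x)| / D(c) × 100, with readings linearly interpolated about
    the field centre c (midpoint of the 50% crossings).
    """
    ref, center = _central_reading(profile)
    fs = field_size(profile)
    r = fraction_of_radius * fs / 2.0
    offsets = np.linspace(0.0, r, n_eval)
    right = np.interp(center + offsets, profile.positions, profile.readings)
    left = np.interp(center - offsets, profile.positions, profile.readings)
    d0 = float(np.interp(center, profile.positions, profile.readings))
    return float(np.max(np.abs(right - left)) / d0 * 100.0)


def focal_spot_size(camera: FocalSpotCamera,
                    resolved_line_pairs: int) -> FocalSpotResult:
    """Focal spot size from the number of resolved camera line pairs.

    Size = pairs × pitch (one leaf + one spacer); the quoted uncertainty is one
    line-pair pitch.  No magnification correction is applied — the camera is
    read directly in its own plane.
    """
    if resolved_line_pairs < 1:
        raise ValueError("at least one resolved line pair is required")
    size = resolved_line_pairs * camera.pitch
    return FocalSpotResult(size_mm=float(size), uncertainty_mm=camera.pitch)
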