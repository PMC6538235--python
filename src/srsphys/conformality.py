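"""Isodose-volume extraction and conformality indices.

The conformality index used here is a pure volume ratio: the volume enclosed
by an isodose level divided by the volume enclosed by the reference level
(the 80% prescription isodose in the canonical workflow).  Paddick/RTOG-style
target-weighted indices are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose_engine import DoseGrid

__all__ = ["ConformalityResult", "isodose_volume", "conformality_indices"]


@dataclass
class ConformalityResult:
    """Volumes (cm^3) and indices per isodose level (% of prescription)."""

    isodose_levels: list
    volumes: dict
    reference_level: float
    indices: dict

    def to_frame(self) -> pd.DataFrame:
        """Presentation table, volumes and indices rounded to 2 decimals."""
        return pd.DataFrame({
            "isodose_level_pct": self.isodose_levels,
            "volume_cm3": [round(self.volumes[l], 2) for l in self.isodose_levels],
            "conformality_index": [round(self.indices[l], 2)
                                   for l in self.isodose_levels],
        })


def isodose_volume(grid: DoseGrid, level: float, reference_dose: float) -> float:
    """Volume (cm^3) receiving at least ``level`` % of ``reference_dose``.

    Voxel-center classification with an inclusive (>=) threshold; no
    partial-volume weighting.
    """
    if reference_dose <= 0:
        raise ValueError("reference dose must be positive")
    if grid.dose.size == 0:
        raise ValueError("dose grid is empty")
    threshold = level / 100.0 * reference_dose
    n = int(np.count_nonzero(grid.dose >= threshold))
    return n * grid.voxel_volume_mm3 / 1000.0


def conformality_indices(volumes: dict, reference_level: float) -> ConformalityResult:
    """Index(level) = volume(level) / volume(reference_level) for each level."""
    if reference_level not in volumes:
        raise ValueError("reference level missing from the volume table")
    ref_volume = volumes[reference_level]
    if ref_volume <= 0:
        raise ValueError("reference volume must be positive")
    levels = sorted(volumes, reverse=True)
    indices = {l: volumes[l] / ref_volume for l in levels}
    return ConformalityResult(isodose_levels=levels, volumes=dict(volumes),
                              reference_level=reference_level, indices=indices)
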