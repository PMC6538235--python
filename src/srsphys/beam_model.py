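"""Machine dosimetric beam data: validated tables, lookup, and PDD↔TMR conversion.

A :class:`BeamDataSet` bundles, per circular collimator, the percent-depth-dose
curve (fixed SSD), the tissue-maximum ratio curve (fixed source-to-point
distance), a radial off-center-ratio table, and the relative output factor,
together with the absolute calibration (cGy/MU at ``dmax``, reference
collimator, SAD 450 mm).  All lengths are millimetres, dose is cGy.

Lookups interpolate linearly along every table axis (depth, off-axis distance,
collimator size).  Depth queries beyond the tabulated range are clamped to the
table edge with a :class:`TableEdgeWarning`; off-axis queries beyond the table
support return 0 (no dose is extrapolated outside the measured field).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "BeamDataError",
    "TableEdgeWarning",
    "Curve",
    "OCRTable",
    "CollimatorSet",
    "BeamDataSet",
    "lookup_tmr",
    "lookup_ocr",
    "pdd_to_tmr",
    "tmr_to_pdd",
    "validate",
    "fold_profile",
    "save_beam_dataset",
    "load_beam_dataset",
]

#: default SSD/SAD reference of the platform, mm
SAD_REF = 450.0


class BeamDataError(ValueError):
    """Raised for invalid, missing or out-of-range beam data."""


class TableEdgeWarning(UserWarning):
    """A lookup was clamped to the edge of a tabulated range."""


@dataclass
class Curve:
    """A 1-D table ``x -> y`` with strictly increasing ``x``."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise BeamDataError("curve axes must be 1-D and equal length")
        if self.x.size < 2 or np.any(np.diff(self.x) <= 0):
            raise BeamDataError("curve abscissa must be strictly increasing")

    def __call__(self, x, *, clamp: bool = True, label: str = "curve"):
        x = np.asarray(x, dtype=float)
        if clamp and (np.any(x < self.x[0]) or np.any(x > self.x[-1])):
            warnings.warn(
                f"{label}: query outside tabulated range "
                f"[{self.x[0]:g}, {self.x[-1]:g}] mm clamped to edge",
                TableEdgeWarning,
                stacklevel=2,
            )
        return np.interp(x, self.x, self.y)


@dataclass
class OCRTable:
    """Radial off-center-ratio table over (depth, off-axis distance).

    ``values[i, j]`` is the OCR at ``depth[i]``, ``oad[j]``; OAD is one-sided
    (radial symmetry), expressed in the isocenter plane.
    """

    depth: np.ndarray
    oad: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.oad = np.asarray(self.oad, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.depth.size, self.oad.size):
            raise BeamDataError("OCR table shape must be (n_depth, n_oad)")
        if np.any(np.diff(self.depth) <= 0) or np.any(np.diff(self.oad) <= 0):
            raise BeamDataError("OCR axes must be strictly increasing")
        if self.oad[0] != 0.0:
            raise BeamDataError("OCR table must include the central axis (oad=0)")
        self._interp = RegularGridInterpolator(
            (self.depth, self.oad), self.values, method="linear",
            bounds_error=False, fill_value=None,
        )

    def __call__(self, depth, oad):
        depth = np.asarray(depth, dtype=float)
        oad = np.asarray(oad, dtype=float)
        d = np.clip(depth, self.depth[0], self.depth[-1])
        inside = oad <= self.oad[-1]
        r = np.clip(oad, 0.0, self.oad[-1])
        out = self._interp(np.stack(np.broadcast_arrays(d, r), axis=-1))
        return np.where(inside, out, 0.0)


@dataclass(frozen=True)
class CollimatorSet:
    """The platform's circular collimators (nominal diameters at isocenter)."""

    sizes: tuple = (4.0, 5.0, 7.5, 10.0, 12.5, 15.0, 20.0, 25.0)
    reference_size: float = 25.0

    def __post_init__(self) -> None:
        if self.reference_size not in self.sizes:
            raise BeamDataError("reference collimator must be one of the sizes")
        if any(s <= 0 for s in self.sizes) or list(self.sizes) != sorted(self.sizes):
            raise BeamDataError("collimator sizes must be positive and ascending")


@dataclass
class BeamDataSet:
    """All dosimetric tables of one machine.

    Parameters
    ----------
    collimator_sizes
        Nominal field diameters at isocenter, mm, ascending.
    pdd
        Per-collimator percent-depth-dose curve, depth mm -> %, at SSD 450 mm.
    tmr
        Per-collimator tissue-maximum-ratio curve, depth mm -> ratio.
    ocr
        Per-collimator :class:`OCRTable`.
    output_factors
        Per-collimator relative output (1.0 for the reference collimator).
    calibration
        Absolute calibration, cGy per MU at reference conditions.
    sad_ref
        Reference source-axis distance, mm.
    dmax
        Depth of dose maximum, mm.
    """

    collimator_sizes: list
    pdd: dict
    tmr: dict
    ocr: dict
    output_factors: dict
    calibration: float = 1.0
    sad_ref: float = SAD_REF
    dmax: float = 7.0
    reference_collimator: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.collimator_sizes = [float(c) for c in self.collimator_sizes]
        if self.reference_collimator is None:
            self.reference_collimator = max(self.collimator_sizes)

    # -- convenience wrappers -------------------------------------------------
    def lookup_tmr(self, coll, depth):
        return lookup_tmr(self, coll, depth)

    def lookup_ocr(self, coll, depth, oad):
        return lookup_ocr(self, coll, depth, oad)

    def output_factor(self, coll):
        return _interp_scalar_by_coll(self, self.output_factors, coll)

    def validate(self):
        return validate(self)


def _bracket_coll(data: BeamDataSet, coll: float):
    """Bracketing collimator sizes and interpolation weight for ``coll``."""
    sizes = data.collimator_sizes
    if not sizes:
        raise BeamDataError("dataset has no collimators")
    if coll < sizes[0] or coll > sizes[-1]:
        raise BeamDataError(
            f"collimator {coll} mm outside tabulated range [{sizes[0]}, {sizes[-1]}] mm"
        )
    hi = int(np.searchsorted(sizes, coll))
    if hi < len(sizes) and sizes[hi] == coll:
        return sizes[hi], sizes[hi], 0.0
    lo, hi = sizes[hi - 1], sizes[hi]
    return lo, hi, (coll - lo) / (hi - lo)


def _interp_scalar_by_coll(data: BeamDataSet, table: dict, coll: float) -> float:
    lo, hi, w = _bracket_coll(data, float(coll))
    if w == 0.0:
        return float(table[lo])
    return float((1.0 - w) * table[lo] + w * table[hi])


def lookup_tmr(data: BeamDataSet, coll: float, depth):
    """Tissue-maximum ratio, linear in depth and in collimator size.

    Depth beyond the table is clamped (with :class:`TableEdgeWarning`);
    negative depth raises.
    """
    depth = np.asarray(depth, dtype=float)
    if np.any(depth < 0):
        raise BeamDataError("depth must be non-negative")
    lo, hi, w = _bracket_coll(data, float(coll))
    v = data.tmr[lo](depth, label=f"TMR coll {lo:g} mm")
    if w > 0.0:
        v = (1.0 - w) * v + w * data.tmr[hi](depth, label=f"TMR coll {hi:g} mm")
    return v if v.ndim else float(v)


def lookup_ocr(data: BeamDataSet, coll: float, depth, oad):
    """Off-center ratio, bilinear in (depth, oad), linear in collimator size.

    OAD is radial (>= 0) in the isocenter plane; beyond the tabulated OAD
    support the OCR is 0.
    """
    depth = np.asarray(depth, dtype=float)
    oad = np.asarray(oad, dtype=float)
    if np.any(depth < 0):
        raise BeamDataError("depth must be non-negative")
    if np.any(oad < 0):
        raise BeamDataError("off-axis distance must be non-negative (radial table)")
    lo, hi, w = _bracket_coll(data, float(coll))
    v = data.ocr[lo](depth, oad)
    if w > 0.0:
        v = (1.0 - w) * v + w * data.ocr[hi](depth, oad)
    if depth.ndim == 0 and oad.ndim == 0:
        return float(np.squeeze(v))
    return v


def pdd_to_tmr(data: BeamDataSet, coll: float, ssd: float | None = None) -> Curve:
    """Convert a stored PDD curve to a TMR curve.

    TMR(d) = [PDD(d)/PDD(dmax)] * ((SSD+d)/(SSD+dmax))^2, phantom-scatter
    ratio taken as 1 — an approximation acceptable for the <= 25 mm fields of
    this platform.  The result is normalised to 1.0 at ``dmax``.
    """
    ssd = data.sad_ref if ssd is None else float(ssd)
    lo, hi, w = _bracket_coll(data, float(coll))
    if w != 0.0:
        raise BeamDataError("pdd_to_tmr requires a tabulated collimator size")
    curve = data.pdd[lo]
    pdd_dmax = float(curve(data.dmax, clamp=False))
    if pdd_dmax <= 0:
        raise BeamDataError("PDD at dmax must be positive")
    tmr = (curve.y / pdd_dmax) * ((ssd + curve.x) / (ssd + data.dmax)) ** 2
    return Curve(curve.x.copy(), tmr)


def tmr_to_pdd(tmr: Curve, dmax: float, ssd: float = SAD_REF,
               pdd_dmax: float = 100.0) -> Curve:
    """Inverse of :func:`pdd_to_tmr` under the same scatter-free approximation."""
    pdd = tmr.y * pdd_dmax * ((ssd + dmax) / (ssd + tmr.x)) ** 2
    return Curve(tmr.x.copy(), pdd)


def validate(data: BeamDataSet) -> list:
    """Check every dataset invariant; return a list of violation messages.

    An empty list means the dataset is internally consistent: sizes ascending,
    on-axis OCR normalised to 1, reference output factor 1, PDD in (0, 100]
    and non-increasing beyond ``dmax``, TMR equal to 1 at ``dmax``.
    """
    v: list[str] = []
    sizes = data.collimator_sizes
    if any(s <= 0 for s in sizes):
        v.append("collimator_sizes: all sizes must be positive")
    if sizes != sorted(sizes):
        v.append("collimator_sizes: not sorted ascending")
    for table_name in ("pdd", "tmr", "ocr", "output_factors"):
        missing = [c for c in sizes if c not in getattr(data, table_name)]
        if missing:
            v.append(f"{table_name}: missing collimators {missing}")
    ref = data.reference_collimator
    of_ref = data.output_factors.get(ref)
    if of_ref is not None and abs(of_ref - 1.0) > 1e-9:
        v.append(f"output_factors: reference collimator {ref:g} mm has OF "
                 f"{of_ref:g}, expected 1.0")
    for c in sizes:
        curve = data.pdd.get(c)
        if curve is not None:
            if np.any(curve.y <= 0) or np.any(curve.y > 100 + 1e-9):
                v.append(f"pdd[{c:g}]: values must lie in (0, 100]")
            past = curve.x >= data.dmax
            if np.any(np.diff(curve.y[past]) > 1e-9):
                v.append(f"pdd[{c:g}]: increases beyond dmax")
        tcurve = data.tmr.get(c)
        if tcurve is not None:
            t_dmax = float(tcurve(data.dmax, clamp=False))
            if abs(t_dmax - 1.0) > 1e-6:
                v.append(f"tmr[{c:g}]: TMR(dmax) = {t_dmax:.6f}, expected 1.0")
        table = data.ocr.get(c)
        if table is not None:
            axis = table.values[:, 0]
            if np.any(np.abs(axis - 1.0) > 1e-9):
                v.append(f"ocr[{c:g}]: on-axis values deviate from 1.0")
    if data.calibration <= 0:
        v.append("calibration: must be positive")
    return v


def fold_profile(positions, readings):
    """Fold a two-sided measured profile into a one-sided radial curve.

    Left and right half-profiles (about position 0) are averaged on the radial
    grid of the right half; the maximum left/right asymmetry relative to the
    central reading is returned so the fold's information loss is quantified.

    Returns ``(oad, folded, max_asymmetry_fraction)``.
    """
    positions = np.asarray(positions, dtype=float)
    readings = np.asarray(readings, dtype=float)
    r = positions[positions >= 0]
    right = readings[positions >= 0]
    left = np.interp(-r, positions, readings)
    center = np.interp(0.0, positions, readings)
    if center <= 0:
        raise BeamDataError("central reading must be positive to fold a profile")
    folded = 0.5 * (left + right)
    max_asym = float(np.max(np.abs(left - right)) / center)
    return r, folded, max_asym


# -- on-disk format -----------------------------------------------------------
# One JSON manifest plus one CSV per table, with units in the column headers.

_PDD_COLS = ["depth_mm", "pdd_percent"]
_TMR_COLS = ["depth_mm", "tmr"]
_OCR_COLS = ["depth_mm", "oad_mm", "ocr"]
_OF_COLS = ["collimator_mm", "output_factor"]


def _coll_tag(coll: float) -> str:
    return f"{coll:g}".replace(".", "p")


def save_beam_dataset(data: BeamDataSet, directory) -> Path:
    """Write a dataset as ``manifest.json`` + per-table CSVs; return the dir."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format": "srsphys-beamdata-v1",
        "collimator_sizes_mm": data.collimator_sizes,
        "reference_collimator_mm": data.reference_collimator,
        "calibration_cgy_per_mu": data.calibration,
        "sad_ref_mm": data.sad_ref,
        "dmax_mm": data.dmax,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for c in data.collimator_sizes:
        tag = _coll_tag(c)
        pd.DataFrame({"depth_mm": data.pdd[c].x, "pdd_percent": data.pdd[c].y}
                     ).to_csv(directory / f"pdd_{tag}.csv", index=False)
        pd.DataFrame({"depth_mm": data.tmr[c].x, "tmr": data.tmr[c].y}
                     ).to_csv(directory / f"tmr_{tag}.csv", index=False)
        t = data.ocr[c]
        dd, rr = np.meshgrid(t.depth, t.oad, indexing="ij")
        pd.DataFrame({"depth_mm": dd.ravel(), "oad_mm": rr.ravel(),
                      "ocr": t.values.ravel()}
                     ).to_csv(directory / f"ocr_{tag}.csv", index=False)
    pd.DataFrame({"collimator_mm": data.collimator_sizes,
                  "output_factor": [data.output_factors[c]
                                    for c in data.collimator_sizes]}
                 ).to_csv(directory / "output_factors.csv", index=False)
    return directory


def _read_csv_strict(path: Path, columns: list) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != columns:
        raise BeamDataError(
            f"{path.name}: expected columns {columns}, found {list(df.columns)}"
        )
    return df


def load_beam_dataset(directory) -> BeamDataSet:
    """Load a dataset written by :func:`save_beam_dataset` (headers validated)."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    if manifest.get("format") != "srsphys-beamdata-v1":
        raise BeamDataError("unrecognised beam-data manifest format")
    sizes = [float(c) for c in manifest["collimator_sizes_mm"]]
    pdd, tmr, ocr = {}, {}, {}
    for c in sizes:
        tag = _coll_tag(c)
        df = _read_csv_strict(directory / f"pdd_{tag}.csv", _PDD_COLS)
        pdd[c] = Curve(df["depth_mm"].to_numpy(), df["pdd_percent"].to_numpy())
        df = _read_csv_strict(directory / f"tmr_{tag}.csv", _TMR_COLS)
        tmr[c] = Curve(df["depth_mm"].to_numpy(), df["tmr"].to_numpy())
        df = _read_csv_strict(directory / f"ocr_{tag}.csv", _OCR_COLS)
        depths = np.unique(df["depth_mm"].to_numpy())
        oads = np.unique(df["oad_mm"].to_numpy())
        vals = (df.pivot(index="depth_mm", columns="oad_mm", values="ocr")
                .loc[depths, oads].to_numpy())
        ocr[c] = OCRTable(depths, oads, vals)
    df = _read_csv_strict(directory / "output_factors.csv", _OF_COLS)
    of = dict(zip(df["collimator_mm"].astype(float), df["output_factor"]))
    return BeamDataSet(
        collimator_sizes=sizes, pdd=pdd, tmr=tmr, ocr=ocr, output_factors=of,
        calibration=float(manifest["calibration_cgy_per_mu"]),
        sad_ref=float(manifest["sad_ref_mm"]),
        dmax=float(manifest["dmax_mm"]),
        reference_collimator=float(manifest["reference_collimator_mm"]),
    )
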