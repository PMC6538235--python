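"""Synthetic beam data, profiles, monitor series and survey tables.

Every generator is built around a closed-form ground truth so downstream
estimators can be checked against known answers:

* depth curves — linear build-up to ``dmax`` then exponential decay, with the
  decay constants calibrated to the platform anchors PDD(100 mm) = 40.29 %
  (at 450 mm SSD) and TMR(100 mm) = 0.5;
* lateral edges — an ideal circular field convolved with a Gaussian source
  (error-function edges, consistent with a ~2 mm focal spot), with per-
  collimator edge widths on the scale of the measured 80–20 penumbrae
  (1.77–2.27 mm at 5 cm depth) and purely geometric growth with depth;
* monitor series — proportional response with a controllable maximum
  nonlinearity and seeded relative noise.

All randomness is driven by an explicit seed; identical seeds give identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log, sqrt

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf
from scipy.stats import norm

from .beam_model import SAD_REF, BeamDataSet, Curve, OCRTable
from .profile_metrics import ScanProfile
from .qa_program import MonitorSeries
from .shielding_survey import SurveyRecord

__all__ = ["SyntheticBeamParams", "make_beam_dataset", "make_profile",
           "analytic_edge", "analytic_penumbra", "analytic_field_size",
           "make_monitor_series", "make_survey_table", "ERF_8020"]

#: 80–20 quantile spacing of a unit-σ Gaussian edge: Φ⁻¹(0.8) − Φ⁻¹(0.2)
ERF_8020 = float(norm.ppf(0.8) - norm.ppf(0.2))

#: measured-scale 80–20 penumbra (mm) at 5 cm depth per collimator, used to
#: set the default edge widths of the synthetic beam
_PENUMBRA_5CM = {4.0: 1.77, 5.0: 1.88, 7.5: 1.94, 10.0: 2.00,
                 12.5: 2.06, 15.0: 2.11, 20.0: 2.19, 25.0: 2.27}

#: relative output factors vs collimator (small-field output drop)
_DEFAULT_OF = {4.0: 0.68, 5.0: 0.78, 7.5: 0.88, 10.0: 0.93,
               12.5: 0.95, 15.0: 0.97, 20.0: 0.99, 25.0: 1.0}


def _edge_8020_width(coll: float, sigma: float) -> float:
    """80–20 width of the axis-normalised edge in the isocenter plane, mm.

    For wide fields this is ERF_8020·σ; for the smallest collimators the two
    erf edges overlap and the width must be solved numerically.
    """
    axis = analytic_edge(0.0, coll, sigma)
    hi = coll / 2.0 + 12.0 * sigma
    r80 = brentq(lambda r: analytic_edge(r, coll, sigma) - 0.8 * axis, 0.0, hi)
    r20 = brentq(lambda r: analytic_edge(r, coll, sigma) - 0.2 * axis, 0.0, hi)
    return r20 - r80


def _default_sigma() -> dict:
    """Isocenter-plane Gaussian edge σ per collimator, calibrated so the
    projected 80–20 width at 5 cm depth equals the measured penumbra."""
    m5 = (SAD_REF + 50.0) / SAD_REF
    out = {}
    for c, p in _PENUMBRA_5CM.items():
        guess = p / (ERF_8020 * m5)
        out[c] = brentq(
            lambda s: _edge_8020_width(c, s) * m5 - p, 0.2 * guess, 5.0 * guess)
    return out


@dataclass
class SyntheticBeamParams:
    """Ground-truth parameters of the synthetic 3 MV beam."""

    collimators: tuple = (4.0, 5.0, 7.5, 10.0, 12.5, 15.0, 20.0, 25.0)
    dmax: float = 7.0                       # mm
    pdd_surface: float = 50.0               # % at depth 0
    pdd_100: float = 40.29                  # % target at 100 mm depth
    tmr_100: float = 0.5                    # target at 100 mm depth
    penumbra_sigma: dict = field(default_factory=_default_sigma)  # mm, per coll
    of_curve: dict = field(default_factory=lambda: dict(_DEFAULT_OF))
    noise_sd: float = 0.0                   # relative, applied by make_profile
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.pdd_100 < 100:
            raise ValueError("target PDD(100) must lie in (0, 100) %")
        if any(s <= 0 for s in self.penumbra_sigma.values()):
            raise ValueError("penumbra sigma must be positive")

    @property
    def mu_pdd(self) -> float:
        """Effective PDD attenuation per mm beyond dmax."""
        return log(100.0 / self.pdd_100) / (100.0 - self.dmax)

    @property
    def mu_tmr(self) -> float:
        """Effective TMR attenuation per mm beyond dmax."""
        return log(1.0 / self.tmr_100) / (100.0 - self.dmax)


def analytic_edge(r, coll: float, sigma: float):
    """Axis-normalised radial edge model in the isocenter plane.

    ½[erf((R+r)/σ√2) + erf((R−r)/σ√2)] / erf(R/σ√2), R the nominal field
    radius.  For wide fields this is a pure erf edge crossing 50 % at R.
    """
    r = np.asarray(r, dtype=float)
    a = sigma * sqrt(2.0)
    R = coll / 2.0
    return 0.5 * (erf((R + r) / a) + erf((R - r) / a)) / erf(R / a)


def _magnification(depth: float) -> float:
    """Divergence scale of the measurement plane at ``depth`` (SSD 450 mm)."""
    return (SAD_REF + depth) / SAD_REF


def analytic_field_size(params: SyntheticBeamParams, coll: float,
                        depth: float) -> float:
    """Exact 50 %-of-axis field width of the synthetic beam at ``depth``, mm."""
    sigma = params.penumbra_sigma[coll]
    target = 0.5 * analytic_edge(0.0, coll, sigma)
    hi = coll / 2.0 + 12.0 * sigma
    r50 = brentq(lambda r: analytic_edge(r, coll, sigma) - target, 0.0, hi)
    return 2.0 * r50 * _magnification(depth)


def analytic_penumbra(params: SyntheticBeamParams, coll: float,
                      depth: float) -> float:
    """Exact 80–20 edge width of the synthetic beam at ``depth``, mm."""
    sigma = params.penumbra_sigma[coll]
    return _edge_8020_width(coll, sigma) * _magnification(depth)


def _depth_curves(params: SyntheticBeamParams):
    """(depths, PDD %, TMR) on a 1 mm grid to 250 mm."""
    d = np.arange(0.0, 251.0, 1.0)
    build = params.pdd_surface + (100.0 - params.pdd_surface) * d / params.dmax
    pdd = np.where(d < params.dmax, build,
                   100.0 * np.exp(-params.mu_pdd * (d - params.dmax)))
    tbuild = build / 100.0
    tmr = np.where(d < params.dmax, tbuild,
                   np.exp(-params.mu_tmr * (d - params.dmax)))
    return d, pdd, tmr


def make_beam_dataset(params: SyntheticBeamParams | None = None) -> BeamDataSet:
    """Generate a complete, internally consistent :class:`BeamDataSet`.

    The OCR tables are stored radially in isocenter-plane coordinates, so the
    edge position and width are depth-independent in the table; the measured
    penumbra growth with depth arises purely from beam divergence when a
    profile is projected to a measurement plane (see :func:`make_profile`).
    """
    params = params or SyntheticBeamParams()
    d, pdd_y, tmr_y = _depth_curves(params)
    ocr_depths = np.array([0.0, params.dmax, 25.0, 50.0, 100.0, 150.0,
                           200.0, 250.0])
    oad = np.arange(0.0, 50.25, 0.25)
    pdd, tmr, ocr = {}, {}, {}
    for c in params.collimators:
        pdd[c] = Curve(d.copy(), pdd_y.copy())
        tmr[c] = Curve(d.copy(), tmr_y.copy())
        row = analytic_edge(oad, c, params.penumbra_sigma[c])
        ocr[c] = OCRTable(ocr_depths.copy(), oad.copy(),
                          np.tile(row, (ocr_depths.size, 1)))
    return BeamDataSet(
        collimator_sizes=list(params.collimators),
        pdd=pdd, tmr=tmr, ocr=ocr,
        output_factors=dict(params.of_curve),
        calibration=1.0, sad_ref=SAD_REF, dmax=params.dmax,
        reference_collimator=max(params.collimators),
    )


def make_profile(params: SyntheticBeamParams, coll: float, depth: float,
                 n: int = 201, noise_sd: float | None = None,
                 seed: int | None = None) -> ScanProfile:
    """Synthetic lateral scan at ``depth`` (positions in the scan plane, mm).

    Readings are the analytic edge model projected to the measurement plane
    plus seeded Gaussian relative noise (``noise_sd`` defaults to the params'
    value).
    """
    if n < 50:
        raise ValueError("a scan profile needs at least 50 samples")
    sigma = params.penumbra_sigma[coll]
    m = _magnification(depth)
    half = m * (coll / 2.0 + 10.0 * sigma)
    positions = np.linspace(-half, half, n)
    readings = analytic_edge(np.abs(positions) / m, coll, sigma)
    noise_sd = params.noise_sd if noise_sd is None else noise_sd
    if noise_sd > 0:
        rng = np.random.default_rng(params.seed if seed is None else seed)
        readings = readings * (1.0 + rng.normal(0.0, noise_sd, n))
    return ScanProfile(positions=positions, readings=readings,
                       depth=depth, coll=coll, plane="wheel-plane")


_MONITOR_MU_GRID = (2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0, 500.0, 1000.0)


def make_monitor_series(k: float = 1.0, nonlinearity_pct: float = 0.0,
                        noise_sd: float = 0.0, seed: int = 0,
                        n_repeats: int = 5) -> MonitorSeries:
    """Monitor check data on the 2–1,000 MU grid with known nonlinearity.

    dose = k·MU·(1 + bias(MU))·(1 + ε); the bias ramps log-linearly from its
    maximum ``nonlinearity_pct`` at 2 MU to zero at 1,000 MU, so the fitted
    slope stays anchored by the high-MU points.
    """
    if k <= 0:
        raise ValueError("response slope k must be positive")
    rng = np.random.default_rng(seed)
    mu = np.array(_MONITOR_MU_GRID)
    bias = nonlinearity_pct / 100.0 * np.log(mu[-1] / mu) / np.log(mu[-1] / mu[0])
    clean = k * mu * (1.0 + bias)
    eps = rng.normal(0.0, noise_sd, mu.size) if noise_sd > 0 else np.zeros(mu.size)
    measured = clean * (1.0 + eps)
    repeats = {}
    for m, c in zip(mu, clean):
        reps = rng.normal(0.0, noise_sd, n_repeats) if noise_sd > 0 \
            else np.zeros(n_repeats)
        repeats[float(m)] = c * (1.0 + reps)
    return MonitorSeries(set_mu=mu, measured_dose=measured, repeats=repeats)


def make_survey_table(rate_scale: float = 1.0, jitter_sd: float = 0.0,
                      seed: int = 0) -> list:
    """The canonical 15-station survey fixture, optionally perturbed.

    With defaults the packaged survey table is returned verbatim; a
    ``rate_scale`` and/or seeded lognormal ``jitter_sd`` produce randomized
    variants for property tests.
    """
    from .datasets import load_survey_table   # local import: avoid cycle

    records = load_survey_table()
    if rate_scale == 1.0 and jitter_sd == 0.0:
        return records
    rng = np.random.default_rng(seed)
    out = []
    for r in records:
        factor = rate_scale
        if jitter_sd > 0:
            factor *= float(rng.lognormal(0.0, jitter_sd))
        out.append(SurveyRecord(
            station_id=r.station_id, description=r.description,
            beam_position=r.beam_position, rate=r.rate * factor,
            use_factor=r.use_factor, duty_cycle=r.duty_cycle))
    return out
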