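"""Workload, utilization, survey annual-dose and analytic TVL shielding math.

Conventions: exposure rates in mR/hr, annual dose in mSv with the fixed
equivalence 100 mR = 1 mSv, a 2,000-hour work year (overridable), thicknesses
in mm.  The tenth-value-layer (TVL) solver is purely analytic: thickness =
-log10(attenuation) x TVL, maximised over the active radiation sources
(target scatter, patient scatter, collimator leakage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["WorkloadModel", "SurveyRecord", "ShieldingSource", "ShieldingSpec",
           "SurveyReport", "annual_mu", "utilization", "allowable_rate",
           "annual_dose", "survey_report", "leakage_fraction",
           "weekly_workload", "annual_beam_hours", "required_thickness",
           "thickness_profile", "MR_PER_MSV"]

#: fixed exposure/dose equivalence used throughout: 100 mR = 1 mSv
MR_PER_MSV = 100.0


@dataclass
class WorkloadModel:
    """Operating conditions driving shielding and utilization arithmetic.

    ``np_patients`` is the annual census (single-fraction treatments/year);
    weekly quantities for the workload formula W = Np*T + Tqc are derived from
    it via ``weeks_Nw``.
    """

    np_patients: float = 2250.0            # patients per year
    mu_per_treatment: float = 6250.0       # MU
    dose_rate: float = 1500.0              # MU/min at isocenter
    treatment_time_T: float = 25.0         # min/patient (beam-on + handling)
    qual_time_Tqc: float = 2.0             # QA/calibration hours per week
    use_factor_U: float = 1.0              # fraction of beam time toward a point
    safety_factor_SF: float = 1.0
    weeks_Nw: float = 50.0                 # operating weeks per year
    work_hours_per_year: float = 2000.0
    max_dose_rate_D: float = 1500.0        # MU/min, worst case

    def __post_init__(self) -> None:
        positive = ("np_patients", "mu_per_treatment", "dose_rate",
                    "treatment_time_T", "qual_time_Tqc", "safety_factor_SF",
                    "weeks_Nw", "work_hours_per_year", "max_dose_rate_D")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.use_factor_U <= 1:
            raise ValueError("use_factor_U must lie in (0, 1]")


@dataclass(frozen=True)
class SurveyRecord:
    """One survey station: measured rate plus occupancy/beam-on factors."""

    station_id: int
    description: str
    beam_position: str
    rate: float          # mR/hr, instantaneous with beam on
    use_factor: float
    duty_cycle: float

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        for name in ("use_factor", "duty_cycle"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


def annual_mu(model: WorkloadModel) -> float:
    """Total MU delivered per year: annual census x MU per treatment."""
    return model.np_patients * model.mu_per_treatment


def utilization(model: WorkloadModel) -> float:
    """Fraction of the work year the beam is on.

    Beam-on ("rad-on") hours = annual MU / (dose rate x 60); utilization is
    that divided by the work year.
    """
    if model.dose_rate <= 0:
        raise ValueError("dose rate must be positive")
    rad_on_hours = annual_mu(model) / (model.dose_rate * 60.0)
    return rad_on_hours / model.work_hours_per_year


def rad_on_hours(model: WorkloadModel) -> float:
    """Annual beam-on time, hours."""
    return annual_mu(model) / (model.dose_rate * 60.0)


def allowable_rate(annual_limit: float, model: WorkloadModel) -> float:
    """Allowable instantaneous rate (same unit as ``annual_limit`` per hour).

    (annual limit / work hours) / utilization — the hourly budget inflated by
    the fraction of time the beam is actually on.  Satisfies
    utilization x allowable_rate x work_hours = annual_limit exactly.
    """
    u = utilization(model)
    if u <= 0:
        raise ValueError("utilization must be positive")
    return (annual_limit / model.work_hours_per_year) / u


def annual_dose(record: SurveyRecord, work_hours: float = 2000.0) -> float:
    """Projected annual dose at a station, mSv/year.

    rate x use factor x duty cycle x work hours, converted at 100 mR = 1 mSv.
    """
    return (record.rate * record.use_factor * record.duty_cycle * work_hours
            / MR_PER_MSV)


@dataclass
class SurveyReport:
    """Per-station annual doses and verdicts against both limits."""

    table: pd.DataFrame
    limit_msv: float
    rate_limit: float
    work_hours: float

    @property
    def max_rate(self) -> float:
        return float(self.table["rate_mr_per_hr"].max())

    @property
    def max_rate_station(self) -> int:
        return int(self.table.loc[self.table["rate_mr_per_hr"].idxmax(),
                                  "station"])

    @property
    def all_pass(self) -> bool:
        return bool((self.table["dose_pass"] & self.table["rate_pass"]).all())


def survey_report(records, limit_msv: float = 1.0, rate_limit: float = 3.2,
                  work_hours: float = 2000.0) -> SurveyReport:
    """Evaluate survey stations against annual-dose and instantaneous limits.

    Pass/fail is computed on unrounded values; the tabulated annual dose is
    rounded to 3 decimals for presentation.
    """
    records = list(records)
    if not records:
        raise ValueError("at least one survey record is required")
    rows = []
    for r in records:
        dose = annual_dose(r, work_hours)
        rows.append({
            "station": r.station_id,
            "description": r.description,
            "beam_position": r.beam_position,
            "rate_mr_per_hr": r.rate,
            "use_factor": r.use_factor,
            "duty_cycle": r.duty_cycle,
            "annual_dose_msv": round(dose, 3),
            "dose_pass": dose < limit_msv,
            "rate_pass": r.rate <= rate_limit,
        })
    return SurveyReport(table=pd.DataFrame(rows), limit_msv=limit_msv,
                        rate_limit=rate_limit, work_hours=work_hours)


def leakage_fraction(leakage_reading_mr: float, mu_delivered: float,
                     cax_exposure_per_mu: float = 1.0) -> float:
    """Leakage as percent of the central-axis primary beam.

    ``leakage_reading_mr`` in mR; the primary exposure is
    MU x ``cax_exposure_per_mu`` (R/MU, 1.0 under the platform calibration).
    """
    if mu_delivered <= 0 or cax_exposure_per_mu <= 0:
        raise ValueError("MU delivered and R/MU must be positive")
    leakage_r = leakage_reading_mr / 1000.0
    return leakage_r / (mu_delivered * cax_exposure_per_mu) * 100.0


def weekly_workload(model: WorkloadModel) -> float:
    """W = Np x T + Tqc, hours per week (Np = weekly census, T in minutes)."""
    np_week = model.np_patients / model.weeks_Nw
    return np_week * model.treatment_time_T / 60.0 + model.qual_time_Tqc


def annual_beam_hours(model: WorkloadModel) -> float:
    """Equivalent radiation-on time per year: U x W x SF x Nw, hours."""
    return (model.use_factor_U * weekly_workload(model)
            * model.safety_factor_SF * model.weeks_Nw)


@dataclass(frozen=True)
class ShieldingSource:
    """One radiation source with TVLs per material, optionally angle-dependent.

    ``tvl`` maps material name to either a scalar TVL (mm, equilibrium) or an
    ``(angles_deg, tvl_mm)`` pair interpolated linearly in angle.
    """

    kind: str                      # target-scatter | patient-scatter | leakage
    tvl: dict

    def tvl_at(self, material: str, angle: float) -> float:
        try:
            entry = self.tvl[material]
        except KeyError:
            raise KeyError(f"source {self.kind!r} has no TVL for {material!r}")
        if np.isscalar(entry):
            t = float(entry)
        else:
            angles, tvls = (np.asarray(a, dtype=float) for a in entry)
            t = float(np.interp(angle, angles, tvls))
        if t <= 0:
            raise ValueError("TVL must be positive")
        return t


@dataclass
class ShieldingSpec:
    """Shielding design inputs: sources, materials and attenuation target."""

    sources: list
    required_attenuation: float
    boundary_radius: float = 3000.0
    materials: tuple = ("tungsten", "lead", "iron")

    def __post_init__(self) -> None:
        if not self.sources:
            raise ValueError("at least one shielding source is required")
        if not 0 < self.required_attenuation <= 1:
            raise ValueError("required attenuation must lie in (0, 1]")


def required_thickness(spec: ShieldingSpec, angle: float, material: str) -> float:
    """Shield thickness (mm) at ``angle`` from the beam axis for ``material``.

    n_TVL = -log10(required attenuation); the thickness is n_TVL x TVL, taken
    as the maximum over the active sources.  An attenuation of 1 needs 0 mm.
    """
    if not 0 <= angle <= 180:
        raise ValueError("angle must lie in [0, 180] degrees (axisymmetric)")
    n_tvl = -np.log10(spec.required_attenuation)
    return float(max(n_tvl * s.tvl_at(material, angle) for s in spec.sources))


def thickness_profile(spec: ShieldingSpec, material: str,
                      angles=None) -> pd.DataFrame:
    """Per-angle maximal thickness, revolved symmetrically about the beam axis."""
    if angles is None:
        angles = np.arange(0.0, 181.0, 5.0)
    rows = [{"angle_deg": float(a),
             "thickness_mm": required_thickness(spec, float(a), material)}
            for a in np.asarray(angles, dtype=float)]
    return pd.DataFrame(rows)
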