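"""Dose-monitor statistics and the acceptance-test tolerance engine.

``linearity`` and ``reproducibility`` implement the two dose-monitor checks
(±3% linearity over 2–1,000 MU, ±2% reproducibility); ``run_acceptance``
evaluates a measured-results table against a versioned rule set.  The default
rule set ships as YAML package data (see :func:`srsphys.datasets.load_acceptance_rules`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ToleranceRule", "MonitorSeries", "AcceptanceReport",
           "linearity", "reproducibility", "run_acceptance"]

_RULE_KINDS = {"within_abs", "within_pct", "max_abs_or_pct", "le", "ge", "info"}


@dataclass(frozen=True)
class ToleranceRule:
    """One acceptance criterion.

    kind:
        ``within_abs``      |x - nominal| <= tolerance
        ``within_pct``      |x - nominal| <= tolerance% of nominal
        ``max_abs_or_pct``  |x - nominal| <= max(tolerance, tolerance_pct% of nominal)
        ``le`` / ``ge``     x <= nominal / x >= nominal
        ``info``            metadata only, never evaluated
    """

    metric_id: str
    nominal: float = 0.0
    tolerance: float = 0.0
    kind: str = "within_abs"
    units: str = ""
    tolerance_pct: float = 0.0
    description: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _RULE_KINDS:
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.kind.startswith("within") and self.tolerance <= 0:
            raise ValueError("within-type rules need a positive tolerance")

    def allowed_deviation(self) -> float:
        if self.kind == "within_abs":
            return self.tolerance
        if self.kind == "within_pct":
            return abs(self.nominal) * self.tolerance / 100.0
        if self.kind == "max_abs_or_pct":
            return max(self.tolerance, abs(self.nominal) * self.tolerance_pct / 100.0)
        raise ValueError(f"rule kind {self.kind!r} has no deviation band")

    def evaluate(self, value: float) -> tuple[bool, float]:
        """(passed, margin); margin > 0 means inside tolerance by that much."""
        if self.kind == "info":
            return True, np.nan
        if self.kind == "le":
            margin = self.nominal - value
        elif self.kind == "ge":
            margin = value - self.nominal
        else:
            margin = self.allowed_deviation() - abs(value - self.nominal)
        return margin >= 0, float(margin)


@dataclass
class MonitorSeries:
    """Dose-monitor check data: set MU vs measured dose, plus replicates."""

    set_mu: np.ndarray
    measured_dose: np.ndarray
    repeats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.set_mu = np.asarray(self.set_mu, dtype=float)
        self.measured_dose = np.asarray(self.measured_dose, dtype=float)
        if self.set_mu.shape != self.measured_dose.shape:
            raise ValueError("set_mu and measured_dose must be paired")
        if np.any(self.set_mu <= 0):
            raise ValueError("MU settings must be positive")


def linearity(series: MonitorSeries) -> float:
    """Maximum percent deviation from proportionality (line through origin).

    A least-squares line dose = k x MU with no intercept is fitted (the
    calibration forces 1 cGy/MU, so a free intercept would hide a zero
    offset); the statistic is max |measured − k·MU| / (k·MU) x 100.  Requires
    at least 3 distinct MU settings spanning a decade.
    """
    mu, dose = series.set_mu, series.measured_dose
    distinct = np.unique(mu)
    if distinct.size < 3:
        raise ValueError("linearity needs at least 3 distinct MU settings")
    if distinct.max() / distinct.min() < 10:
        raise ValueError("MU settings must span at least one decade")
    k = float(np.sum(mu * dose) / np.sum(mu * mu))
    if k <= 0:
        raise ValueError("fitted response slope must be positive")
    return float(np.max(np.abs(dose - k * mu) / (k * mu)) * 100.0)


def reproducibility(readings) -> float:
    """Maximum percent deviation of replicate readings from their mean."""
    readings = np.asarray(readings, dtype=float)
    if readings.size < 2:
        raise ValueError("reproducibility needs at least 2 replicates")
    mean = float(np.mean(readings))
    if mean <= 0:
        raise ValueError("mean reading must be positive")
    return float(np.max(np.abs(readings - mean)) / mean * 100.0)


@dataclass
class AcceptanceReport:
    """Per-rule verdicts with margins, and the overall AND verdict."""

    table: pd.DataFrame
    overall_pass: bool

    def __str__(self) -> str:
        verdict = "PASS" if self.overall_pass else "FAIL"
        return f"{self.table.to_string(index=False)}\nOverall: {verdict}"


def run_acceptance(results: dict, rules, skip=()) -> AcceptanceReport:
    """Evaluate measured ``results`` (metric_id -> value) against ``rules``.

    Every non-informational rule must have a result or be listed in ``skip``;
    verdicts are independent of rule order and of repeated evaluation.
    """
    skip = set(skip)
    rows = []
    verdicts = []
    for rule in sorted(rules, key=lambda r: r.metric_id):
        if rule.kind == "info" or rule.metric_id in skip:
            rows.append({"metric": rule.metric_id, "value": np.nan,
                         "nominal": rule.nominal, "units": rule.units,
                         "margin": np.nan,
                         "verdict": "info" if rule.kind == "info" else "skipped"})
            continue
        if rule.metric_id not in results:
            raise KeyError(f"no measured result for metric {rule.metric_id!r} "
                           "(add it or list it in skip)")
        value = float(results[rule.metric_id])
        passed, margin = rule.evaluate(value)
        verdicts.append(passed)
        rows.append({"metric": rule.metric_id, "value": value,
                     "nominal": rule.nominal, "units": rule.units,
                     "margin": margin, "verdict": "pass" if passed else "fail"})
    if not verdicts:
        raise ValueError("no evaluable rules (all informational or skipped)")
    return AcceptanceReport(table=pd.DataFrame(rows),
                            overall_pass=all(verdicts))
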