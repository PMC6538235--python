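"""Loaders for the small reference tables shipped with the package."""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml

from .qa_program import ToleranceRule
from .shielding_survey import SurveyRecord

__all__ = ["load_survey_table", "load_penumbra_reference",
           "load_conformality_volumes", "load_acceptance_rules"]


def _data_path(name: str):
    return resources.files("srsphys.data").joinpath(name)


def load_survey_table() -> list:
    """The canonical 15-station radiation survey as :class:`SurveyRecord`\\ s."""
    with _data_path("radiation_survey.csv").open() as fh:
        df = pd.read_csv(fh)
    return [
        SurveyRecord(station_id=int(r.station), description=r.description,
                     beam_position=r.beam_position, rate=float(r.rate_mr_per_hr),
                     use_factor=float(r.use_factor),
                     duty_cycle=float(r.duty_cycle))
        for r in df.itertuples()
    ]


def load_penumbra_reference() -> pd.DataFrame:
    """Measured 80–20 penumbra per collimator/depth/side (tidy table, mm)."""
    with _data_path("penumbra_reference.csv").open() as fh:
        return pd.read_csv(fh)


def load_conformality_volumes() -> dict:
    """Reference isodose volumes (cm^3) keyed by isodose level (percent)."""
    with _data_path("conformality_volumes.csv").open() as fh:
        df = pd.read_csv(fh)
    return dict(zip(df["isodose_level_pct"].astype(float),
                    df["volume_cm3"].astype(float)))


def load_acceptance_rules() -> list:
    """The versioned default acceptance rule set as :class:`ToleranceRule`\\ s."""
    with _data_path("acceptance_rules.yaml").open() as fh:
        doc = yaml.safe_load(fh)
    rules = []
    for entry in doc["rules"]:
        rules.append(ToleranceRule(
            metric_id=entry["metric"],
            nominal=float(entry.get("nominal", 0.0)),
            tolerance=float(entry.get("tolerance", 0.0)),
            kind=entry.get("kind", "within_abs"),
            units=entry.get("units", ""),
            tolerance_pct=float(entry.get("tolerance_pct", 0.0)),
            description=entry.get("description", ""),
        ))
    return rules
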