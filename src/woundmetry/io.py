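"""CSV loaders for the tabular pipeline inputs.

Three schemas:

* observations: ``patient_id,location,day,area_cm2`` — one row per scan
  of one wound; grouped into :class:`~woundmetry.metrics.WoundSeries`.
* patients: ``patient_id,sex,age,height_cm,weight_kg``.
* annotations: ``patient_id,mechanism,degree,surgery_flag`` — clinical
  annotations applied at the patient level (burn depth is charted per
  patient in this cohort, not per wound).
"""
from __future__ import annotations

import pandas as pd

from .exceptions import SchemaError
from .metrics import PatientRecord, WoundObservation, WoundSeries

OBSERVATION_COLUMNS = ["patient_id", "location", "day", "area_cm2"]
PATIENT_COLUMNS = ["patient_id", "sex", "age", "height_cm", "weight_kg"]
ANNOTATION_COLUMNS = ["patient_id", "mechanism", "degree", "surgery_flag"]


def _require_columns(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} CSV is missing column(s): {', '.join(missing)}")


def load_observations(path) -> list[WoundSeries]:
    """Read an observations CSV into one WoundSeries per (patient, location).

    Series keep the file's first-appearance order; observations within a
    series are sorted by day.
    """
    df = pd.read_csv(path)
    _require_columns(df, OBSERVATION_COLUMNS, "observations")
    if df.empty:
        raise SchemaError("observations CSV has no rows")
    series = []
    for (pid, loc), grp in df.groupby(["patient_id", "location"], sort=False):
        grp = grp.sort_values("day")
        try:
            obs = [
                WoundObservation(str(pid), str(loc), int(r.day), float(r.area_cm2))
                for r in grp.itertuples()
            ]
            series.append(WoundSeries(tuple(obs)))
        except ValueError as exc:
            raise SchemaError(f"invalid observation rows for {pid}/{loc}: {exc}") from exc
    return series


def load_patients(path) -> list[PatientRecord]:
    df = pd.read_csv(path)
    _require_columns(df, PATIENT_COLUMNS, "patients")
    return [
        PatientRecord(
            patient_id=str(r.patient_id),
            sex=str(r.sex),
            age=float(r.age),
            height_cm=float(r.height_cm),
            weight_kg=float(r.weight_kg),
        )
        for r in df.itertuples()
    ]


def load_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ANNOTATION_COLUMNS, "annotations")
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    return df
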