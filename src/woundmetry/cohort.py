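"""Cohort-level aggregation of wound and patient metrics.

Builds the wound-level table (one row per wound, carrying the per-wound
reductions and the owning patient's dTBSA%), the cohort ranges that
summarize healing across all wounds, and grouped tabulations by burn
mechanism or degree. Only descriptive statistics are produced — counts,
medians and extrema — mirroring a pilot-study analysis with no
hypothesis testing.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .exceptions import AnnotationError, DomainError, SchemaError
from .metrics import WoundSeries, patient_summary, wound_metrics

GROUP_KEYS = ("mechanism", "degree")

TABLE_COLUMNS = [
    "patient_id", "location", "mechanism", "degree", "surgery_flag",
    "baseline_area_cm2", "last_area_cm2", "delta_a_cm2",
    "percent_reduction", "early_phase_reduction_pct",
    "overall_rate_cm2_per_day", "bsa_m2", "tbsa_baseline_pct",
    "delta_tbsa_pct",
]


@dataclass(frozen=True)
class CohortTable:
    """One row per wound plus cohort metadata.

    ``rows`` is a DataFrame in :data:`TABLE_COLUMNS` order; a patient's
    ``delta_tbsa_pct`` (a patient-level quantity) repeats on each of that
    patient's rows.
    """

    rows: pd.DataFrame
    n_patients: int
    n_wounds: int


@dataclass(frozen=True)
class CohortRanges:
    """Cohort extrema and medians over wound rows (dTBSA over patients)."""

    baseline_area_min_cm2: float
    baseline_area_max_cm2: float
    baseline_area_median_cm2: float
    percent_reduction_min: float
    percent_reduction_max: float
    percent_reduction_median: float
    delta_tbsa_min_pct: float
    delta_tbsa_max_pct: float


def build_cohort_table(patients, series_list, annotations: pd.DataFrame) -> CohortTable:
    """Assemble the wound-level cohort table.

    Every series must reference a known patient; annotations are joined
    per patient. Row order follows the series order, so the table is a
    pure function of its inputs.
    """
    records = {p.patient_id: p for p in patients}
    annot = annotations.set_index("patient_id")
    series_by_patient: dict[str, list[WoundSeries]] = {}
    for s in series_list:
        if s.patient_id not in records:
            raise SchemaError(f"series {s.patient_id}/{s.location} has no patient record")
        series_by_patient.setdefault(s.patient_id, []).append(s)

    summaries = {
        pid: patient_summary(records[pid], sl) for pid, sl in series_by_patient.items()
    }

    rows = []
    for s in series_list:
        wm = wound_metrics(s)
        ps = summaries[s.patient_id]
        if s.patient_id in annot.index:
            a = annot.loc[s.patient_id]
            mech, deg, surg = a["mechanism"], a["degree"], int(a["surgery_flag"])
        else:
            mech = deg = ""
            surg = 0
        rows.append({
            "patient_id": s.patient_id,
            "location": s.location,
            "mechanism": mech,
            "degree": deg,
            "surgery_flag": surg,
            "baseline_area_cm2": wm.baseline_area_cm2,
            "last_area_cm2": wm.last_area_cm2,
            "delta_a_cm2": wm.delta_a_cm2,
            "percent_reduction": wm.percent_reduction,
            "early_phase_reduction_pct": wm.early_phase_reduction_pct,
            "overall_rate_cm2_per_day": wm.overall_rate_cm2_per_day,
            "bsa_m2": ps.bsa_m2,
            "tbsa_baseline_pct": ps.tbsa_baseline_pct,
            "delta_tbsa_pct": ps.delta_tbsa_pct,
        })
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return CohortTable(rows=df, n_patients=len(series_by_patient), n_wounds=len(df))


def cohort_ranges(table: CohortTable) -> CohortRanges:
    """Extrema/medians over wound rows; dTBSA extrema over patients.

    Medians use the midpoint-of-two-central-values convention for even
    counts (pandas' default interpolation).
    """
    df = table.rows
    if df.empty:
        raise DomainError("cohort table is empty")
    per_patient = df.drop_duplicates("patient_id")["delta_tbsa_pct"]
    return CohortRanges(
        baseline_area_min_cm2=float(df["baseline_area_cm2"].min()),
        baseline_area_max_cm2=float(df["baseline_area_cm2"].max()),
        baseline_area_median_cm2=float(df["baseline_area_cm2"].median()),
        percent_reduction_min=float(df["percent_reduction"].min()),
        percent_reduction_max=float(df["percent_reduction"].max()),
        percent_reduction_median=float(df["percent_reduction"].median()),
        delta_tbsa_min_pct=float(per_patient.min()),
        delta_tbsa_max_pct=float(per_patient.max()),
    )


def group_summary(table: CohortTable, by: str = "mechanism") -> pd.DataFrame:
    """Per-group descriptive summary (stand-in for swarm-plot figures).

    Groups wound rows by the patient-level annotation ``by`` and reports
    patient/wound counts plus count-median-min-max of the wound percent
    reductions and of the patients' baseline TBSA%.
    """
    if by not in GROUP_KEYS:
        raise AnnotationError(f"can only group by one of {GROUP_KEYS}")
    df = table.rows
    if (df[by] == "").any():
        raise AnnotationError(f"some rows have no {by} annotation")
    out = []
    for label, grp in df.groupby(by, sort=True):
        patients = grp.drop_duplicates("patient_id")
        out.append({
            by: label,
            "n_patients": len(patients),
            "n_wounds": len(grp),
            "percent_reduction_median": float(grp["percent_reduction"].median()),
            "percent_reduction_min": float(grp["percent_reduction"].min()),
            "percent_reduction_max": float(grp["percent_reduction"].max()),
            "tbsa_baseline_median_pct": float(patients["tbsa_baseline_pct"].median()),
            "tbsa_baseline_min_pct": float(patients["tbsa_baseline_pct"].min()),
            "tbsa_baseline_max_pct": float(patients["tbsa_baseline_pct"].max()),
        })
    return pd.DataFrame(out)
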