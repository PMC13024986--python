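"""The bundled pilot burn cohort: 18 patients, 43 wounds.

These tables transcribe the published per-scan wound areas (cm²),
anthropometrics, and clinical annotations of a structured-light
3D-scanning pilot study of acute thermal burns. Every downstream number
in this package is recomputed from the raw areas and heights/weights;
the ``pilot_reference_*`` tables additionally carry the values as
printed in the source tables, for cross-checking.

The printed source tables contain a handful of internal inconsistencies
(a row-shifted block around P05-P07, three BSA values that disagree with
the Du Bois formula applied to the same row's height and weight, and a
few percent values printed from unrounded upstream areas). These rows
are *kept* in the data but flagged in the reference tables' ``flag``
column so that comparisons against printed values can exclude them
explicitly rather than silently:

* ``printed_bsa_inconsistent`` — printed BSA disagrees with Du Bois on
  the row's own height/weight by > 0.01 m² (P05, P07, P17).
* ``printed_delta_tbsa_inconsistent`` — printed dTBSA% disagrees with
  recomputation by > 0.005 (P05, P06).
* ``delta_a_inconsistent`` / ``percent_inconsistent`` — printed wound
  metric disagrees with the row's own area series beyond rounding
  (P06 LUL, P07 LUL, P04 LUL percent).
* ``percent_rounding`` — printed percent differs by 0.01-0.03 because it
  was computed upstream from unrounded areas (four rows in P09/P10).

P05's mechanism is recorded as Fire: the cohort-level mechanism counts
stated in the source text (scald 7, explosion 6, fire 5) are consistent
with the annotation table only under that reading, and P05 sits inside
the row-shifted block.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .cohort import CohortTable, build_cohort_table
from .io import load_annotations, load_observations, load_patients
from .metrics import PatientRecord, WoundSeries


def _data_path(name: str):
    return resources.files("woundmetry.data").joinpath(name)


def load_pilot_patients() -> list[PatientRecord]:
    """Anthropometrics for the 18 pilot patients."""
    with resources.as_file(_data_path("pilot_patients.csv")) as p:
        return load_patients(p)


def load_pilot_series() -> list[WoundSeries]:
    """Per-scan area series for the 43 pilot wounds."""
    with resources.as_file(_data_path("pilot_observations.csv")) as p:
        return load_observations(p)


def load_pilot_annotations() -> pd.DataFrame:
    """Mechanism / burn-degree / surgery annotations per patient."""
    with resources.as_file(_data_path("pilot_annotations.csv")) as p:
        return load_annotations(p)


def load_pilot_reference_patients() -> pd.DataFrame:
    """Patient-level values as printed in the source tables, with flags."""
    with resources.as_file(_data_path("pilot_reference_patients.csv")) as p:
        df = pd.read_csv(p, keep_default_na=False)
    df["patient_id"] = df["patient_id"].astype(str)
    return df


def load_pilot_reference_wounds() -> pd.DataFrame:
    """Wound-level dA / percent-reduction as printed, with flags."""
    with resources.as_file(_data_path("pilot_reference_wounds.csv")) as p:
        df = pd.read_csv(p, keep_default_na=False)
    df["patient_id"] = df["patient_id"].astype(str)
    return df


def pilot_cohort() -> CohortTable:
    """The full pilot cohort table, recomputed from raw areas."""
    return build_cohort_table(
        load_pilot_patients(), load_pilot_series(), load_pilot_annotations()
    )
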