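"""Healing metrics on the bundled pilot burn cohort (18 patients, 43 wounds).

Recomputes every area-based metric from the raw per-scan areas and
anthropometrics, then prints the cohort's headline numbers: baseline
area range, percent-reduction range, and the per-patient drop in burned
body fraction (dTBSA%).
"""
from woundmetry import cohort_ranges, datasets, group_summary

table = datasets.pilot_cohort()
r = cohort_ranges(table)

print(f"cohort: {table.n_patients} patients, {table.n_wounds} wounds")
print(f"baseline area    : {r.baseline_area_min_cm2:.2f} - "
      f"{r.baseline_area_max_cm2:.2f} cm2 (median {r.baseline_area_median_cm2:.2f})")
print(f"percent reduction: {r.percent_reduction_min:.2f} - "
      f"{r.percent_reduction_max:.2f} % (median {r.percent_reduction_median:.2f})")
print(f"dTBSA            : {r.delta_tbsa_min_pct:.3f} - {r.delta_tbsa_max_pct:.3f} %")

print("\nby mechanism of injury:")
print(group_summary(table, "mechanism").to_string(index=False, float_format="%.2f"))

print("\nlargest per-patient burden reductions:")
per_patient = (table.rows.drop_duplicates("patient_id")
               .nlargest(4, "delta_tbsa_pct"))
for row in per_patient.itertuples():
    print(f"  {row.patient_id}: dTBSA {row.delta_tbsa_pct:6.3f} %  "
          f"(BSA {row.bsa_m2:.2f} m2)")

# dTBSA% is a global-burden measure: a patient with several large wounds
# (P09) dominates it even when smaller wounds elsewhere heal by >80%.
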