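#!/usr/bin/env bash
# The same pipeline from the shell: generate a synthetic scan series,
# measure one scan from its files alone, and build the pilot cohort
# tables. Run from the repository root after `pip install -e .`.
set -euo pipefail

out=$(mktemp -d)
data=src/woundmetry/data

# 1. synthetic scan series (PLY + label sidecar + manifest per day)
woundmetry synth --anatomy sphere_torso --radius 80 --resolution 2.0 \
    --a0 60 --rate 0.1 --days 1,5,9 --noise-sigma 0.1 --seed 4 \
    --out "$out/series"

# 2. measure the day-5 scan from files alone
woundmetry measure --mesh "$out/series/scan_day005.ply" \
    --labels "$out/series/scan_day005.labels.csv" --out "$out/measure"
python -m json.tool "$out/measure/measure.json" | head -12

# 3. cohort tables from the bundled pilot CSVs
woundmetry cohort --observations $data/pilot_observations.csv \
    --patients $data/pilot_patients.csv \
    --annotations $data/pilot_annotations.csv --out "$out/cohort"
python -m json.tool "$out/cohort/summary.json"

rm -rf "$out"
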