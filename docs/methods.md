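# Methods

## Surface planimetry on triangulated scans

The primary measurement is the area of a wound region on an open
triangulated surface: the sum over selected faces of half the
cross-product magnitude of two edge vectors. Vertices are in
millimeters (scanner-native); the single mm²→cm² conversion happens at
the `surface_area` boundary, so the reported cm² value times 100 equals
the mm² face-area sum along the identical float path. Area is additive
over disjoint face sets and invariant under rigid motion to float
precision; both are asserted as properties in the test suite.

Scan meshes are treated as open surfaces — wound scans cover only the
affected region and are never watertight — and geometry is measured as
given: no smoothing, hole filling, or remeshing anywhere. Validation
(`validate_mesh`) only removes numerically collapsed faces (area ≤
1e-8 mm², far below the ~0.2 mm point spacing of a clinical
structured-light scanner, so only degenerate slivers can be affected)
and unreferenced vertices, re-indexing the color/label channels
consistently.

## Segmentation model

A wound delineation arrives as one of three equivalent inputs: a
per-vertex integer label channel (sidecar CSV, since PLY/OBJ/STL do not
standardize integer attributes), a color rule (score = w·RGB
thresholded, default weights (1, −1, −1) separating red wound tissue
from skin tones), or a boundary vertex loop (flood-filled to labels).
All three reduce to a vertex predicate; faces are then selected by the
`all_vertices` rule (all three corners wound-positive) by default.
This choice is deliberately conservative: it never charges a boundary
triangle containing any skin to the wound, so reported areas are lower
bounds at the triangle scale. The `majority` rule (≥ 2 of 3) is
available where an unbiased boundary split is preferred. Connected
components use shared-edge adjacency — shared-vertex adjacency would
merge patches touching at a single point — ordered by descending area
with ties broken by smallest face index for determinism.

## Healing metrics

Elapsed time is `day_t − day_baseline` with the baseline scan at day 1,
matching the follow-up-period convention of the bundled cohort. The
final scan per wound defines `A_last`; wounds are never truncated to a
common day, because follow-up in routine care is irregular by nature.
The daily healing rate is `(A₀ − Aₜ) / elapsed days` in cm²/day with no
additional scale factor: a percentage-style ×100 on this quantity would
be dimensionally inconsistent with its unit (clinically observed rates
for small partial-thickness wounds are single to low double digits of
cm²/day, which the plain quotient reproduces). Du Bois BSA is always
recomputed from height and weight, never read from a summary column.

## The bundled pilot cohort

`woundmetry/data/` transcribes an 18-patient / 43-wound pilot cohort of
acute thermal burns scanned serially with a structured-light scanner:
per-scan wound areas (cm²), patient anthropometrics, and
mechanism/degree/surgery annotations. The as-published summary columns
are preserved separately in `pilot_reference_*.csv` with a `flag`
column marking internal inconsistencies found by recomputation (a
row-shifted table block around P05–P07, three printed BSA values that
contradict the Du Bois formula on their own row's height and weight,
and four percent values printed from unrounded upstream areas). Flags
make exclusions explicit and auditable; the raw per-scan areas — the
actual inputs — are used everywhere, and all headline cohort numbers
(area extrema, reduction extrema, ΔTBSA extrema, mechanism counts)
reproduce from them. Cohort summaries are purely descriptive (counts,
medians, extrema; even-count medians are midpoints of the two central
values); no hypothesis testing is performed or implied at this sample
size.

## Synthetic scenes and their oracles

The generator replaces the scanner for development and testing.
Anatomies are parametric surfaces — plane, open cylinder (limb), sphere
(torso) — triangulated on a parameter grid at a target edge length
(default 1.0 mm, five times a clinical scanner's nominal point spacing;
a full limb is then ~10⁵ faces and every pipeline stage runs in well
under a second).

Wound patches have closed-form areas fixed *before* any mesh exists:
spherical cap `2πR²(1−cos θ)`, cylinder patch `R·Δφ·L`, plane disc
`πr²`. For the cap and cylinder patch the boundary runs along parameter
lines, so the generator snaps grid lines exactly onto it: the labeled
face set tiles the patch exactly and the only measurement error is
chordal flattening, O((edge/R)²) ≈ 1e-5 at the defaults, decreasing
monotonically under refinement. A disc boundary cannot be snapped into
a rectangular grid, so disc ROIs additionally carry a one-boundary-ring
bias of order perimeter × edge length under the conservative inclusion
rule; accuracy claims are therefore stated on cap and cylinder scenes.

Longitudinal series shrink the patch parameter (θ, Δφ and L jointly, or
r) in closed form to match the prescribed trajectory area
`A(t) = A₀e^(−k(t−t₀))` (exponential, emulating fast early healing that
plateaus) or `A₀ − rate·(t−t₀)` (linear) exactly at every scan day — an
exact oracle at each time point, rather than mesh morphing with an
approximate one. A day reaching area 0 yields an unlabeled (healed)
mesh; a positive target smaller than one mesh cell raises a
resolution error rather than silently under-representing the wound.

Scanner depth noise is modeled as a smooth random field — a sum of
eight random plane waves with 15–40 mm wavelengths, rescaled to the
requested RMS (default 0.1 mm, a typical structured-light accuracy) and
applied along vertex normals after labeling. Per-vertex white noise was
rejected deliberately: at 0.1 mm RMS on 1 mm triangles it tilts every
face independently and inflates total area by ~2%, an artifact real
correlated scanner noise does not show; the smooth field perturbs
geometry while changing extracted areas by < 0.1%. All generation is
deterministic: a scene seed (plus the scan day, via a seed sequence)
fixes the noise field bit-for-bit.

## Numerical and interface choices

- Writes are ASCII (PLY/OBJ/STL) for diffability; reads accept binary
  dialects too. Colors round-trip through 8-bit channels (quantization
  1/255, far below any threshold the color rule uses).
- The empty ROI is a warning-plus-zero in `surface_area` (a healed
  wound is a legitimate zero) but an error in selection operations,
  where it signals a misconfigured rule.
- CLI outputs: fixed 2-decimal CSVs for human comparison plus
  full-precision JSON twins; exit codes 0 / 2 (input or configuration)
  / 3 (empty selection); identical inputs produce byte-identical
  outputs.

## Limitations

The synthetic scenes validate the measurement pipeline, not clinical
segmentation: they have sharp, linearly separable wound boundaries and
no occlusion, registration artifacts, specular highlights, or
inter-operator delineation variability, so passing tests bound only
geometric and algorithmic error, not the accuracy of delineating a real
burn. Burn depth is carried as an annotation and never inferred from
geometry. TBSA% here quantifies scanned local wounds against computed
BSA; it is not a whole-body TBSA assessment of the kind used for acute
resuscitation decisions.
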