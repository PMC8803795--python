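# Methods

## Problem setting

DLBCL response assessment relies on FDG-PET at interim (I-PET) and end of
treatment (EoT-PET), read on the Deauville 5-point scale (DS) with DS1–3
counted as negative (complete metabolic response) and DS4–5 as positive.
The package quantifies this pipeline end to end — lesion delineation,
scoring, longitudinal change, cohort statistics — so that the response
behaviour of molecular subgroups (here *MYC*-rearranged vs *MYC*-negative
DLBCL) can be compared reproducibly.

## Segmentation

A lesion delineation is the connected component, under 26-neighborhood
connectivity (configurable to 6), of the voxels at or above a threshold
that contains the seed (fixed thresholds) or the lesion maximum (relative
thresholds). Thresholds are inclusive: SUV exactly equal to the threshold
belongs to the lesion, consistent with "SUV4.0" naming the floor of the
lesion. The six methods:

| method | threshold |
|---|---|
| SUV4.0 / SUV2.5 | fixed 4.0 / 2.5 |
| PC41MAX | 0.41 × lesion-local SUVmax |
| PC50PEAK | 0.50 × SUVpeak of the provisional SUV4.0 component |
| MV2 / MV3 | voxels kept by ≥ 2 / ≥ 3 of the four base methods |

Decisions taken where the field's conventions vary:

* **SUVpeak** is the maximum over placements of a 1-mL sphere (radius
  ≈ 6.2 mm) centered at a lesion voxel of the mean SUV of all in-grid
  voxels whose centers fall inside the sphere — the PERCIST-style
  convention. Voxels coarser than 1 mL are rejected.
* **PC41MAX reference maximum** is lesion-local (the maximum of the
  provisional SUV4.0 component at the seed), not the scan-global maximum;
  when the lesion maximum is below 4.0 the reference comes from a
  plateau-aware hill climb from the seed. A completely flat neighbourhood
  (no local maximum anywhere reachable) makes the relative threshold
  undefined and raises an error; PC50PEAK requires a non-empty provisional
  SUV4.0 component outright.
* **Method selection.** The trial protocol's "most complete segmentation
  without oversegmentation" is a physician's judgment; `select_mask` makes
  it an explicit configuration with default MV2, plus an optional automatic
  heuristic (smallest mask fully covering the SUV4.0 core).
* Grid indices are 0-based; voxel centers sit at `origin + index · spacing`
  (mm). MTV is exactly `voxel count × voxel volume / 1000` mL.

## Scoring

Quantitative DS per lesion: DS5 if the lesion is new or SUVmax ≥ 3 × the
hepatic reference; DS4 above liver; DS3 above mediastinal blood pool; DS2
for residual uptake at or below mediastinum; DS1 when no residual uptake
remains. The patient DS is the worst (maximum) lesion DS — the standard
worst-lesion convention. The hepatic reference is SUVmax by default with a
switch to SUVmean (`patient_ds(..., liver_reference=)`), since either
reading of the DS4 boundary is defensible. The DS1/DS2 distinction relies
on a no-residual-uptake indicator (missing or zero lesion SUV); it affects
no cut-off used in the analyses.

QC: a scan fails on out-of-range plasma glucose; passes when the liver
SUVmean is within range; and otherwise passes "by activity" when the total
image activity is 50–80% of the injected activity. The default ranges
(liver SUVmean 1.3–3.0, glucose ≤ 11 mmol/L) are explicit configuration —
guideline-style plausibility bounds, not constants baked into the logic.

Longitudinal change uses smallest-detectable-change semantics, so a change
exactly at the cutoff counts as detected: ΔSUVmax ≥ max(0.30 · ref, 1.3)
(the absolute floor governs up to ref = 1.3/0.30 ≈ 4.33) and MTV ≥ 1.30 ×
ref. Comparisons are tolerance-aware (1e-9 relative) so decimal inputs sit
on the intended side of the boundary. The percent-reduction interim
criterion (`delta_suv_response`) is parameterized by its reduction
threshold (default 0.66) rather than hard-coded, as published variants
differ.

Sites form a fixed two-category ontology (12 nodal, 8 extranodal buckets);
free-text localizations map to the matching "other" bucket with the text
preserved as an annotation that participates in identity, so two distinct
free-text sites remain distinct. New-site detection is a set difference of
involved sites against a reference scan (baseline or I-PET).

## Cohort statistics

The Pearson χ² uses no continuity correction by default (a flag restores
Yates), matching how 2 × k response-pattern tables are conventionally
tested; cell-wise post-hoc read-outs are adjusted standardized residuals
(O − E)/√(E(1 − r/n)(1 − c/n)), approximately standard normal under
independence. Diagnostic measures carry Wilson-score 95% CIs (well-behaved
at the small counts involved; Clopper–Pearson available), and measures with
zero denominators are reported missing, never 0. Kaplan–Meier and log-rank
computations are delegated to lifelines behind the module's interface, with
events-first tie handling; `os_at` reads the step function and flags
extrapolation past the last follow-up. Missing scans are excluded pairwise
per analysis — a patient without an EoT scan leaves the EoT-rate
denominator but not the I-PET one — which is what yields the denominators
80/126/121/56/91 on the packaged tallies. Case-control matching is greedy
1:k exact-stratum without replacement in a seeded random order: the
procedure is deliberately explicit and reproducible rather than optimal.
Display rounding (one decimal, half-up) happens only in the reporting
layer.

## Synthetic data

**Phantoms** place disjoint spheres (lesions, liver, mediastinum) on a
uniform background; a voxel belongs to a sphere iff its center lies inside
it, so ground truth is exact and all six segmentation methods must recover
it exactly in the noiseless case. Optional noise is independent Gaussian
truncated at zero — adequate for validating operators, with no claim to
scanner realism (no point-spread blur, reconstruction artefacts, or
anatomical texture; phantom-passing therefore validates the operators'
logic, not their behaviour on clinical images).

**Cohorts** draw each patient independently: MYC group (P(MYC+) = 81/210),
then one of six scan patterns (four complete I × EoT patterns plus
missing-I and missing-EoT, with the observed per-group frequencies as
default probabilities), then lesion-trajectory increase flags and new-site
events for PET-positive scans, then survival. Survival is exponential per
(MYC group, EoT positivity), calibrated so S(2 y) equals the configured
2-year OS (92.5/37.8% for MYC+ EoT−/EoT+; 94.1/66.7% for MYC−), with
administrative censoring at a 5-year horizon. The published survival is
stratified by each scan separately, not jointly by pattern, so the
generator conditions on EoT status only; patients lacking an EoT scan use
the EoT-negative group's survival (the majority, neutral choice). Joint
calibration remains available through `os2y_by_group`.

The three pairwise increase flags per measure are not free: increases on
baseline→I-PET and I-PET→EoT arithmetically entail one on baseline→EoT, so
the generator draws the first two and forces the third only in the
entailed case; `trajectory_from_pattern` rejects the impossible
combination. Emitted SUVmax/MTV triplets are constructed so that
re-applying the change rules reproduces the drawn flags exactly
(round-trip property, tested). Index-lesion baseline values are drawn
uniformly (SUVmax 8–20, MTV 50–300 mL), typical magnitudes for bulky
aggressive lymphoma. Scan-level DS values are built to be consistent with
the drawn pattern (faint DS2 residual or DS1 for negative scans, DS4/5 for
positive ones, new lesions flagged and thus DS5), so re-scoring the cohort
reproduces every generated pattern label. The quantitative trajectory and
the visual DS may disagree for individual patients (as they can in real
data); only the pattern and flag contracts are guaranteed.

Generation is fully deterministic given (config, seed): identical seeds
give byte-identical cohort tables and voxel-identical phantoms.

## Packaged reference tallies

Three CSVs transcribe cohort-level tallies from a multicenter DLBCL PET
response study (81 MYC+, 129 MYC− patients, plus a 92-patient risk-matched
MYC− subset): the I-PET × EoT-PET pattern counts, the new-localization
patients, and the lesional SUV/MTV change counts. `expand_response_patterns`
turns the counts into individual records carrying representative DS values
(DS2/DS4), so the rates are produced by running the actual scoring and
cross-tabulation code, not by reading percentages from a file. The joint
"both SUV and MTV increased" rate equals the shared marginal when the two
increase counts coincide (as they do in the shipped tallies, where the same
21 of 26 patients increased on both); for reconfigured tallies the
inclusion-exclusion lower bound is reported instead.

## Problem sizes and tolerances

The test suite validates operators on small grids (6³–32³ voxels) against
brute-force oracles (exhaustive flood fill, per-voxel vote counts, direct
χ² and product-limit formulas), and recovers generator parameters on
10,000-patient cohorts within three binomial standard errors. The
acceptance script uses the same 10,000-patient size for Kaplan–Meier
recovery of the configured 2-year OS. Numerical comparisons against
oracles use 1e-10 absolute (χ²) or 1e-9 relative tolerances; threshold and
change-flag boundaries are inclusive as described above.

## Known limitations

* No registration or lesion correspondence between timepoints: lesion
  identity across scans is supplied by the caller.
* No partial-volume correction, scanner simulation, or harmonization
  modelling; phantom results do not transfer claims to clinical images.
* The matched subset ships as tallies only; the original matching
  assignments are not reconstructable, so `match_controls` is validated on
  synthetic cohorts instead.
* Survival in the generator is memoryless within group — adequate for
  recovering 2-year OS, not for shape-sensitive survival analyses.
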