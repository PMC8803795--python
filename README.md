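# petpatterns

Quantitative FDG-PET response-pattern analysis for diffuse large B-cell
lymphoma (DLBCL), aimed at imaging researchers studying how molecular
high-risk disease — in particular *MYC*-rearranged DLBCL — responds during
first-line therapy. The package covers the full quantitative pipeline from
SUV volumes to cohort statistics:

* **Lesion segmentation** on 3-D SUV grids with six delineation methods:
  fixed thresholds SUV ≥ 4.0 and SUV ≥ 2.5, relative thresholds at 41% of
  the lesion SUV<sub>max</sub> and 50% of the lesion SUV<sub>peak</sub>, and
  majority votes MV2/MV3 keeping voxels selected by ≥ 2 or ≥ 3 of the four
  base methods. Metrics per lesion: SUV<sub>max</sub>, SUV<sub>peak</sub>
  (best 1-mL-sphere mean), and metabolic tumor volume
  MTV = n<sub>voxels</sub> · v<sub>voxel</sub> (mL).
* **Response scoring**: quantitative Deauville 5-point scale (DS5 when
  lesion SUV<sub>max</sub> ≥ 3 × hepatic SUV<sub>max</sub> or a new lesion
  appears, DS4 above liver, DS3 above mediastinal blood pool), binary
  response at the DS1–3 vs 4–5 cut-off (with DS1–2 vs 3–5 and DS1–4 vs 5
  sensitivity cut-offs), scan QC with liver/glucose ranges and the 50–80%
  total-activity rescue, smallest-detectable-change flags
  (ΔSUV<sub>max</sub> ≥ max(0.30 · SUV<sub>ref</sub>, 1.3); ΔMTV ≥ 0.30 ·
  MTV<sub>ref</sub>), new-site detection against baseline, and the six-way
  interim × end-of-treatment (I-PET × EoT-PET) response pattern.
* **Cohort statistics**: Pearson χ² with cell-wise adjusted standardized
  residuals, sensitivity/specificity/PPV/NPV with Wilson 95% CIs,
  Kaplan–Meier 2-year overall survival, log-rank tests, and seeded greedy
  exact-stratum case-control matching on IPI, Ann Arbor stage and
  extranodal involvement.
* **Synthetic data**: spherical-lesion SUV phantoms with exact ground-truth
  masks, and patient cohorts whose pattern frequencies, lesion SUV/MTV
  trajectories, new-site events and survival are calibrated to a published
  two-trial DLBCL cohort (81 *MYC*+, 129 *MYC*− patients).

Reference tallies from that cohort ship with the package, so the headline
statistics can be reproduced without any imaging data.

## Worked example

Segment a noiseless phantom sphere (radius 12 mm, peak SUV 8.0, background
1.0, 3-mm voxels) with all six methods:

```python
import numpy as np, petpatterns as pp
from petpatterns.synthetic import PhantomConfig, SphereRegion, generate_phantom

cfg = PhantomConfig(
    lesions=[SphereRegion((46.0, 46.0, 46.0), 12.0, 8.0)],
    liver_region=SphereRegion((20.0, 70.0, 46.0), 10.0, 2.2),
    mediastinum_region=SphereRegion((70.0, 20.0, 46.0), 8.0, 1.5),
)
volume, masks, refs = generate_phantom(cfg)
seed = tuple(np.argwhere(masks["lesion_0"])[0])
for name, mask in pp.segment_all_methods(volume, seed).items():
    m = pp.compute_metrics(volume, mask)
    print(f"{name:9s} SUVmax={m.suv_max:.1f} SUVpeak={m.suv_peak:.2f} MTV={m.mtv_ml:.3f} mL")
```

```
SUV4.0    SUVmax=8.0 SUVpeak=8.00 MTV=7.398 mL
SUV2.5    SUVmax=8.0 SUVpeak=8.00 MTV=7.398 mL
PC41MAX   SUVmax=8.0 SUVpeak=8.00 MTV=7.398 mL
PC50PEAK  SUVmax=8.0 SUVpeak=8.00 MTV=7.398 mL
MV2       SUVmax=8.0 SUVpeak=8.00 MTV=7.398 mL
MV3       SUVmax=8.0 SUVpeak=8.00 MTV=7.398 mL
```

On a uniform sphere whose background sits below every threshold, all six
delineations return exactly the ground-truth voxel set: 274 voxels × 27 mm³
= 7.398 mL. A lesion with SUV<sub>max</sub> 8.0 against hepatic
SUV<sub>max</sub> 3.0 scores Deauville 4 (above liver, below 3 × liver) —
PET-positive at the main cut-off.

The same analysis runs from the shell. `analyze --fixtures` scores the
packaged cohort tallies and `report` renders the JSON:

```bash
petpatterns analyze --fixtures --out report.json
petpatterns report --report report.json
```

```
cutoff: DS1-3 vs 4-5
myc_positive:
  ipet_positivity:
    23/80 = 28.8%
  eot_positivity:
    26/80 = 32.5%
  conversion_ineg_to_epos:
    13/56 = 23.2%
myc_negative:
  ipet_positivity:
    30/126 = 23.8%
  eot_positivity:
    19/121 = 15.7%
  conversion_ineg_to_epos:
    2/91 = 2.2%
...
```

Reading: *MYC*+ patients are no more often PET-positive at the interim scan
than *MYC*− patients (28.8 vs 23.8%), but twice as often at end of
treatment (32.5 vs 15.7%), and conversion from interim-negative to
end-of-treatment-positive is ten times more frequent (23.2 vs 2.2%) — the
aberrant response pattern the pipeline is built to quantify (χ²[3, n=197] =
17.4 on the complete-pattern table).

Other subcommands: `simulate` (synthetic cohorts and phantom volumes with a
checksummed manifest), `segment` (NIfTI volumes + seed table → per-lesion
metrics CSV with QC gating), `score` (append pattern and binary-response
columns to a cohort table).

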