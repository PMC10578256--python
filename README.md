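# orbitq

Quantitative MRI analysis of the extra-ocular muscles (EOM) — the four
recti (lateral, medial, inferior and superior rectus, the latter merged
with the levator palpebrae superioris as *SR+LPS*) that are affected in
myasthenia gravis, chronic progressive external ophthalmoplegia (CPEO),
oculopharyngeal muscular dystrophy (OPMD) and Graves' orbitopathy (GO).
The package is aimed at muscle-MRI researchers who want a tested,
scriptable version of the full analysis chain: water–fat separation,
T2 relaxometry, volumetry, orthoptic scoring and cohort statistics —
together with synthetic orbital phantoms and simulated cohorts so every
stage can be validated without patient data.

## What it computes

**Water–fat separation (3-point Dixon / IDEAL).** Per voxel, the complex
gradient-echo signal is modelled as

    s(TEₙ) = (W + F·c(TEₙ)) · exp(i·2π·ψ·TEₙ)

with water and fat amplitudes W, F, the B0 field-map offset ψ (Hz) and
the fat phasor c(TE) = exp(i·2π·f_fat·TE) (single peak at −3.4 ppm of a
7 T field by default). IDEAL alternates a linear least-squares solve for
(W, F) with a linearised update of ψ, independently per voxel (no field
smoothing or region growing). The fat fraction FF = F/(W+F) is corrected
for T1 bias with the Ernst equation, S ∝ sin α(1−E1)/(1−E1 cos α) with
E1 = exp(−TR/T1), evaluated at an EOM-specific effective flip angle
(ROI-mean relative B1 × nominal 7°).

**T2water mapping (multi-echo spin-echo + EPG).** The 24-echo CPMG train
(ΔTE = 9 ms, last 3 echoes RF-disabled for noise estimation) is modelled
as a water + fat two-component sum of extended-phase-graph (EPG) echo
trains, including B1-scaled refocusing and a slice-profile correction.
A dictionary over T2water 10–60 ms × B1 0.50–1.00 (T2fat fixed after
calibration on subcutaneous neck fat, 120–200 ms) is searched
exhaustively with closed-form non-negative amplitudes per candidate.

**ROI metrics.** Seed-grown 26-connected segmentation on the water
image, per-slice erosion, volumes (voxel count × voxel volume) and ROI
means.

**Orthoptics.** Duction limitations against device caps (40° ab-/
adduction, 30° elevation/depression), the per-patient severity sum-score
(total limitation over 8 directions × 2 eyes, degrees) and per-muscle
affected/not-affected flags (any limitation, or Hess-chart deviation
> 5°, in the muscle's primary direction of action).

**Cohort statistics.** Group mean ± SD summary tables, two-way mixed
ANOVA with the repeated measure *laterality* (left/right eye), Dunnett's
many-to-one post-hoc test, Pearson correlations, volume normalisation to
the healthy per-muscle mean, and counts of muscles outside the healthy
mean ± 2 SD band.

**Synthetic data.** Orbital phantoms (ellipsoidal muscles in orbital
fat with known FF/T2/volume, smooth polynomial B0 and B1 fields) with
forward models for both acquisitions, and simulated cohorts drawn from
the published per-group per-muscle distributions with within-patient
left–right correlation and duction–volume coupling.

## Worked example

Simulate a noisy orbital phantom, run IDEAL, apply the Ernst correction
at the B1-derived effective flip angle, and read out per-muscle metrics:

```python
import numpy as np
from orbitq import (default_phantom_spec, make_orbit_phantom, simulate_dixon,
                    dixon_params_from_config, ideal_decompose, t1_corrected_ff,
                    effective_flip_angle, roi_mean_map, muscle_volume)

spec = default_phantom_spec(seed=7)
truth = make_orbit_phantom(spec)
acq = dixon_params_from_config()          # TEs 2.4/2.73/3.06 ms, TR 8 ms, 7 deg
img = simulate_dixon(truth, acq, noise_sd=0.0005, seed=7)
maps = ideal_decompose(img, acq)
alpha = effective_flip_angle(truth.b1, truth.labels > 0, acq.nominal_flip_deg)
ff = t1_corrected_ff(maps, acq, alpha)
vols = muscle_volume(truth.labels, 0.8)
means = roi_mean_map(ff, truth.labels)
```

which prints:

```
effective flip angle: 5.59 deg
LR      volume   935.9 mm^3   FF 0.131 (true 0.130)
MR      volume   935.9 mm^3   FF 0.118 (true 0.120)
IR      volume   935.9 mm^3   FF 0.172 (true 0.170)
SR+LPS  volume   935.9 mm^3   FF 0.139 (true 0.140)
```

The effective flip angle is the ROI-mean relative B1 (≈ 0.80 in the
phantom's orbit) times the nominal 7°; recovered fat fractions agree
with the phantom ground truth to ≈ 0.002 at this noise level, and the
identical volumes reflect the four identically sized ellipsoids of the
default phantom.

The same pipeline is available from the shell:

```sh
orbitq simulate phantom --out phantom/ --grid 64
orbitq dixon --in-prefix phantom/dixon_echo --out maps/
orbitq simulate cohort --out cohort.csv --seed 1
orbitq stats table2 --in cohort.csv --out table2.csv
orbitq stats anova --in cohort.csv --metric volume_mm3 --muscle LR
```

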