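# Methods

This note records the models, numerical choices and open design
decisions behind each stage of the pipeline, and what the synthetic
experiments do and do not demonstrate about real data.

## Signal models

### Dixon / IDEAL water–fat separation

Per voxel the 3-echo complex gradient-echo signal is
`s(TEₙ) = (W + F·c(TEₙ))·exp(i·2π·ψ·TEₙ)` with complex amplitudes W, F
and the field-map offset ψ in Hz. The fat phasor is single-peak by
default, `c(TE) = exp(i·2π·f_fat·TE)` with
`f_fat = fat_shift_ppm · γ(¹H) · B0` (−3.4 ppm at 7 T ⇒ ≈ −1013 Hz); a
multi-peak spectrum can be supplied as (amplitude, ppm) pairs and enters
as the amplitude-weighted phasor sum. With the protocol echo times
(2.4/2.73/3.06 ms) the fat phase advances ≈ −120° per echo — the classic
3-point spacing.

The solver alternates (a) the exact linear least squares for (W, F)
given ψ (the design matrix depends only on the echo times, so its
pseudo-inverse is computed once for all voxels) and (b) a linearised
real-valued least-squares update of (Δψ, ΔW, ΔF), iterating until
|Δψ| < 0.01 Hz (well below any field offset that could move a fat
fraction at this ΔTE) or 50 iterations. Each voxel is independent — no
field-map smoothing, region growing or T2* correction — so water–fat
swaps can occur when |ψ| exceeds roughly 1/(2ΔTE) ≈ 1.5 kHz of the
initialisation (ψ₀ = 0); this aliasing is documented behaviour, not
guarded against. A relative 1e−12 Tikhonov term keeps zero-signal
voxels solvable; such voxels are flagged undefined rather than zeroed.
Noise-free inversion is exact to ≲ 1e−10 relative for |ψ| ≤ 200 Hz
(verified against a brute-force ψ grid search).

### Ernst T1-bias correction

The spoiled gradient echo at TR 8 ms saturates water and fat
differently, biasing FF = F/(W+F). Correction divides each compartment
by its Ernst factor `sin α(1−E1)/(1−E1 cos α)`, `E1 = exp(−TR/T1)`, at
the *effective* flip angle: the ROI-mean relative B1 times the nominal
7°. T1 defaults are 1400 ms (muscle water) and 380 ms (fat) at 7 T,
config-exposed: the protocol literature prints no T1 values, so these
are the package's own choices from standard 7 T relaxometry. Equal T1s
cancel exactly; FF 0 and 1 are fixed points. Using a single scalar
flip angle across a ROI while the true B1 varies leaves a second-order
residual bias — on the default phantom it is below 0.002 in FF.

### EPG T2water mapping

CPMG echo trains are simulated with the extended-phase-graph formalism:
states (F⁺(k), F⁻(k), Z(k)) per dephasing order, mixed by the standard
RF rotation matrix, with T2 decay on transverse and T1
relaxation/recovery on longitudinal states over each half echo spacing
and one gradient shift per half interval. Excitation is about +y,
refocusing about +x (CPMG condition); the echo is the zeroth-order
transverse state. The implementation is vectorised over parameter sets
and retains 2·n_echoes+4 orders, enough that truncation is invisible at
machine precision: the engine matches an independent isochromat Bloch
simulation (2000 spins) to ~1e−16 and reduces exactly to
`exp(−n·ΔTE/T2)` for ideal refocusing with T1 = ∞.

**Slice profile.** The through-slice flip-angle profile is the
small-tip Fourier transform of a Hann-windowed sinc (time-bandwidth 4),
discretised in 51 equal-weight bins across twice the nominal slice
width; the refocusing profile is spatially narrower by the printed
slice-selection gradient ratio 3.15/3.78. The bin trains are summed
coherently before taking magnitudes. The profile is replaceable by a
measured table. The small-tip approximation is used for the refocusing
pulse too, a deliberate simplification; since the identical profile is
used in the forward simulation and the dictionary, recovery tests
validate the fitting machinery, not the realism of any one profile.

**Dictionary.** Water atoms over T2water 10–60 ms (step 0.5 ms) × B1
0.50–1.00 (step 0.01), fat atoms over T2fat 120–200 ms (step 5 ms) × the
same B1 grid; T1 during the train is fixed at 1400/365 ms (water/fat) —
nuisance parameters with second-order effect at 9 ms spacing. Steps were
chosen well below the reported between-subject SDs (~2–4 ms in T2water).
Atoms are unit-normalised over the 21 fitted echoes; the raw-train norms
are kept so fitted amplitudes can be referred back to magnetisation
units — the fat fraction is computed from those M0-referred amplitudes,
not from the unit-norm coefficients.

**Fitting.** The last 3 (RF-disabled, noise-only) echoes estimate the
Rician noise floor, σ = mean magnitude / √(π/2), which is
quadrature-subtracted from the fitted echoes (default on; a no-op on
noise-free data). T2fat is calibrated first on a pure-fat reference ROI
(single-component search, B1 free, ROI-mean train by default; per-voxel
median optional — per-subject calibration when a neck scan exists, else
a config constant). The two-component fit then scans (T2water, B1)
exhaustively with T2fat fixed, solving the 2×2 non-negative least
squares for the water/fat amplitudes in closed form per candidate; ties
resolve to the lowest T2water, then lowest B1, in C scan order. Fitting
is invariant to overall train scaling. Per-muscle T2water is the mean of
voxel fits inside labels eroded in-plane by one voxel; labels that
vanish under erosion are reported, not fatal.

Grid-aligned noise-free voxels are recovered exactly; off-grid truths
can land one or two cells away along the T2water/B1/FF trade-off ridge,
so the recovery suites sample truths on the grid and treat "within one
grid step" as the discreteness allowance. At SNR 50 (first-echo
amplitude / Gaussian channel SD) the T2water RMSE over 200 voxels is
≈ 3.4 ms with |bias| < 0.5 ms; the RMSE is regression-frozen in the
tests for a fixed seed.

## Segmentation and ROI metrics

Region growing is a 26-connected flood fill over an intensity band,
seeded per label; the default band `[μ_seed − 2σ_seed, ∞)` is estimated
from the seed's 3×3×3 neighbourhood (the manual thresholding step of
interactive tools is not printed anywhere, so k = 2 is a config-exposed
choice). Growth caps at `max_voxels` with a warning. Manual removal of
vessels/nerves is replaced by an optional largest-connected-component
filter — the only batch-reproducible analogue. Erosion is per-slice with
the full 3×3 structuring element. Volumes are voxel count × voxel
volume (0.8³ = 0.512 mm³ default); a 10×5×5 mm ellipsoid rasterised by
voxel-centre inclusion is within 0.5 % of 4/3·π·abc at 0.8 mm, and the
error bound halves at 0.4 mm. Coordinates are 0-based voxel indices;
world coordinates follow the NIfTI affine.

## Orthoptics

Limitation = max(0, cap − measured angle); caps are 40° (ab-/adduction),
30° (elevation/depression) and 35° for the four diagonals — the
midpoint of the two printed device ranges, since diagonal caps are not
printed. The severity sum-score adds limitations over all eight
directions *and both eyes* ("both angles" is read as both eyes: the
score is defined per patient and the synoptophore measures one eye at a
time). Affected flags use strictly-greater-than comparisons: a Hess
deviation of exactly 5° is not affected. Whether past ocular symptoms
should modulate the classification is left open in the source material;
the package classifies on the measured exam only.

## Cohort statistics

Group summaries pool both eyes (two observations per patient) by
default; eye-averaging first is a switch, since the published table does
not state its pooling. The mixed ANOVA (between: group; within:
laterality, 2 levels) is computed from explicit sums of squares: the
between part is a one-way ANOVA on patient eye-means (×2), the within
part an ANOVA on left−right differences (halved); with two within
levels this decomposition is exact, the five SS partition the total, and
the F statistics match pingouin's `mixed_anova` to 1e−14 on balanced
data. With unbalanced groups the weighted (Type I/II-style) sums are
used. Degenerate cases (left ≡ right) return F = 0, p = 1 rather than
0/0. Groups below 2 patients are excluded with a warning; missing eyes
are handled complete-case, mirroring the exclusion of patients without
reference scans.

Dunnett's many-to-one p-values come from `scipy.stats.dunnett`
(multivariate-t, seeded); the package's own critical-value routine
integrates `P(max|Tᵢ| ≤ c) = E[(Φ(z+√2cs)−Φ(z−√2cs))ᵏ]` over the
control variate and the scaled-chi error term with 160-point
Gauss-Legendre rules and Brent root-finding, and agrees with published
two-sided 5 % table values (k = 3: 2.76 at df 10, 2.54 at df 20) and
with R's `mvtnorm` to 4 decimals. The significance threshold is 0.05
throughout; no FDR layer is added beyond Dunnett. Volume normalisation
divides by the healthy per-muscle mean; 2-SD band counts default to 8
muscle observations per patient (4 muscles × 2 eyes, switchable to
eye-averaged) against the healthy mean ± 2 SD. Baseline age (one-way
ANOVA) and sex (chi-square) tests are standard conveniences.

## Synthetic data: what it emulates, and what it does not

Phantoms place four ellipsoidal recti (voxel-centre rasterisation) in
orbital fat (FF 0.95) with smooth quadratic B0 (±~50 Hz) and relative-B1
(~0.75–0.85, matching the low orbital B1 regime) fields. Dixon noise is
complex Gaussian per channel before magnitude; MSE noise is Rician
(complex Gaussian added before the magnitude); both reproducible under a
seed. SNR is defined against the first-echo (MSE) or peak (Dixon)
signal; the source protocol prints no noise levels, so SNR 50/100 are
the package's stated simulation conditions, config-exposed. Cohorts
draw per-muscle volume/FF/T2water from truncated-at-zero Gaussians at
the published per-group means and SDs (the healthy SR+LPS volume SD
follows the running text, 268.5 mm³, where the table prints an
inconsistent value), with left–right correlation 0.7 (laterality is a
repeated measure downstream, so within-patient correlation must exist;
the exact value is a design choice), and duction limitations coupled to
the primary muscle's volume through a Gaussian copula-style latent
(e.g. −0.8 in CPEO-like groups).

Not simulated: eye motion/blinking artefacts, coil sensitivities,
k-space sampling, chemically shifted fat slice displacement, partial
volume beyond rasterisation, and any 3+-component relaxation. Passing
recovery tests therefore shows the inversion machinery is correct under
its own forward model at stated noise levels — not that the models
capture every feature of in-vivo orbital data (the unexplained
between-subject T2water variation reported for EOM being a case in
point).

## Problem sizes

Default test/acceptance problem sizes — 64³ phantom voxels for the
Dixon chain, 200 voxels for dictionary recovery, 1000 replicates for
the ANOVA null simulation, 2000 isochromats for the Bloch oracle — were
chosen so every quoted tolerance is resolved by a comfortable margin
while the whole suite stays fast on a single CPU.
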