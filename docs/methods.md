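# Methods

## The analysis this package implements

The pipeline reproduces a voxel-wise "hub" functional-connectivity (FC)
analysis of resting-state fMRI in chronic low back pain (cLBP), together
with a long-axis volumetric subdivision of the primary somatosensory
cortex (S1). The study design it targets: 18 patients scanned twice — once
at lower endogenous pain (LP) and once after exercise-provoked pain (HP) —
and 18 matched controls scanned once (TR 3 s, 6-minute runs, 3 mm
acquisition analysed at 4 mm isotropic).

Per scan, after preprocessing, every in-mask voxel's Pearson correlation
with every other in-mask voxel is computed, and the voxel's *degree* is
the number of partners with r strictly above 0.25 (positive correlations
only, self excluded; ties at exactly 0.25 are excluded). Degree maps are
z-normalized across voxels within subject (sample SD), a monotone
transform that preserves topography while equating scales across
subjects. Group inference uses pooled two-sample t (HC vs LP, HC vs HP),
paired t (HP vs LP within patients), and a per-voxel regression of each
patient's FC change (HP − LP) on their pain-rating change (each scan's
rating is the mean of its pre- and post-scan 0–10 ratings). Statistic
maps are converted to z through equal-tail-mass quantile mapping,
thresholded at Z > 2.3 with a 10-contiguous-voxel candidate floor
(26-connectivity by default), and cluster-corrected at p < 0.05.

## Preprocessing chain

Applied in the stated order: drop the first 4 volumes; per-voxel linear
detrending (residuals exactly orthogonal to [1, t]); zero-phase low-pass
at 0.08 Hz (4th-order Butterworth run forward–backward; an FFT brick-wall
variant is available via `filter_kind="fft"` — note that the
forward–backward Butterworth is ~3 dB down at 0.9x the cutoff, so the
"within 1 dB" passband property holds only for the FFT variant);
regression of nine nuisance series (six motion, whole-brain, white-matter
and CSF means) plus an intercept — the source text lists these as
"extracted"; we regress them, the standard reading, since extraction
without use would be inert; 4 mm FWHM Gaussian smoothing; trilinear
resampling onto a 4 mm isotropic grid sharing the source origin
(block-mean is available for integral factors). Brain masks are taken
from the raw intensities (mean above 10% of the robust maximum, nonzero
temporal variance) before detrending removes the baseline. Slice timing,
motion correction and template registration are out of scope: inputs are
assumed aligned, and motion enters only as nuisance regressors.

## Cluster-level correction

The original analysis used a parametric (random-field) cluster
correction. Its smoothness estimation is under-specified at the level of
the source text, so this package substitutes a permutation max-cluster-
size correction, which is exact under exchangeability: group labels are
shuffled for two-sample designs; subject signs are flipped for paired
designs; for the regression, subjects are sign-flipped about the mean
difference map. Cluster-level p = (1 + #{permutation max cluster size ≥
observed size}) / (n_perm + 1); candidate clusters below 10 voxels are
discarded before correction. This is a deliberate methodological
substitution, validated by the null-calibration experiment below.

## The synthetic cohort generator

No data accession exists for the study, so the generator is a first-class
module that emulates the design with known ground truth.

**Noise.** Voxel noise is AR(1) in time (default coefficient 0.3) and
spatially smooth: white fields are convolved with a Gaussian of 10 mm
FWHM, the typical intrinsic smoothness of 3T EPI. The spatial component
is essential, not cosmetic: cluster-extent inference presupposes smooth
statistic fields — with spatially white noise, suprathreshold clusters
almost never reach the 10-voxel floor and the cluster correction's
false-positive rate would sit near zero instead of its nominal level.
Per-voxel linear drift (amplitude ±5 a.u. over the run) and nine mixed
nuisance series (written verbatim to the nuisance TSV, so regression can
remove exactly what was mixed in) make detrending and nuisance
regression consequential. In-brain baseline is 1000 a.u. with noise SD
10; outside the ellipsoidal brain stand-in, voxels are zero.

**The planted hub.** A hub region (20 × 20 × 8 mm — 50 voxels on the 4 mm
analysis grid — slightly superior of the grid centre) shares a latent
time series. The latent enters through a spatial weight field that is 1
on the hub core and decays as a Gaussian skirt (11 mm FWHM) outside it,
mixed into the *already-smoothed* noise with per-voxel variance
normalization: x = (n + a·w·s)/sqrt(1 + a²w²), a = sqrt(rho/(1 − rho)).
Two distant hub-core voxels therefore correlate at rho by construction.
The skirt matters: a hard-edged hub would sever the core's
smoothness-driven local correlations, and the degree *lost* to the
neighbourhood can cancel the degree gained inside the hub — with a smooth
skirt the planted effect is monotone in rho, as intended. The idealized
form (i.i.d. noise, w·s + e, expected pairwise correlation exactly
w²/(w²+1) = rho) is exposed as `plant_hub_signal` and verified against
its closed form. Default couplings: controls 0.45, patients 0.30 (LP)
and 0.50 (HP) — ordered so the emulated contrasts match the study's
findings (HC > LP; HP > LP; HC ≈ HP at S1).

**Subjects and ratings.** Per-condition couplings are drawn per subject
(SD 0.10, clipped to [0, 0.95]); each patient's rating change is
Δpain = 0.5 + 12·Δcoupling + ε, ε ~ N(0, 0.4), giving a mean increase of
~2.9 points (matching the reported 3.8 ± 2.5 → 6.7 ± 2.0 shift) and a
rating change genuinely *caused* by the coupling change, so the
regression stage has a recoverable ground truth. The subject-level
coupling spread and the small rating noise are design choices: together
they make the pain covariate informative (correlation with the true
coupling change ≈ 0.97) while keeping the paired contrast detectable; a
much smaller spread leaves the regression unidentifiable at n = 18, a
much larger one erodes paired power. Pre- and post-scan ratings are the
condition mean plus N(0, 0.3) jitter, clipped to [0, 10]; controls report
0. One patient can be flagged (`rest_subject_index`) to have rested
rather than exercised (coupling change forced to 0), as in the study.
Ages and genders (≈2/3 female) are generated for the covariate-adjusted
volume model.

**Structural labels.** Mirror-symmetric left/right ellipsoids on a
separate 1.2 mm grid (the structural resolution), long axis oblique to
the grid (default direction (0.5, 0.1, 0.86), length 36 mm, radii
9.9 mm), with per-subject size jitter (radii scaled by N(1, 0.08), so
bilateral-volume CV ≈ 0.14, comparable to the printed SDs). Patients'
top-third cross-section is inflated by the factor 1.13 — the published
group ratio 5416/4781.

Everything is driven by `numpy.random.SeedSequence(seed)` with
per-subject spawn keys; identical spec + seed yields byte-identical
files (uncompressed NIfTI, fixed-format TSV).

## ROI thirds

The long axis of a label is the first principal component of its voxels'
world coordinates (sign fixed superior); voxels are cut into three
equal-length intervals of the projection range ("equal-count" terciles
are available as an option), and "top" is the section with the highest
mean world z — matching the somatotopic lower-back representation near
the vertex. Volumes are voxel count × |det| of the affine's 3×3 block;
group comparisons use a pooled two-sample t, or OLS with age and gender
when adjusting. Degenerate labels (no unique long axis within a 5%
eigenvalue gap, e.g. a sphere) are rejected rather than silently split.

## Numerical choices

- Degree is computed in column blocks (memory O(n_voxels × block_size));
  the result is block-size independent and equals a brute-force per-pair
  oracle exactly. Degenerate (zero-variance) voxels get degree 0.
- t→z conversion goes through the survival function on the matching tail
  (finite and accurate for |t| in the hundreds); permutation thresholds
  compare t-maps against the t-equivalent of Z = 2.3, avoiding per-
  permutation conversions.
- Zero-variance voxels in group tests are set to t = z = 0 with a
  warning rather than propagating NaN.
- Z_max peak ties are broken by the lowest linear voxel index.
- Self-correlation is excluded from degree (inclusion would shift every
  voxel by +1, removed by z-normalization anyway).

## Validation experiments and the sizes they run at

`painhub.validation` re-measures the pipeline's statistical guarantees;
`scripts/acceptance.py` and the acceptance tests drive it.

- *Oracle equivalence*: blocked degree vs a naive O(n²) per-pair count on
  50 random instances (≤200 voxels × 116 frames), exact equality.
- *Null calibration*: 200 pure-noise cohorts (18 vs 18), one-sided
  two-sample contrast, n_perm = 99; the family-wise false-positive rate
  must sit inside the binomial 95% CI around 0.05. Observed: 0.045.
- *Planted recovery*: 50 cohorts with hub coupling 0.50 (HP) vs 0.30
  (LP); corrected-significant cluster overlapping the hub core in ≥80% of
  reps (observed 0.82–0.90 across seeds) and positive mean regression-
  slope t over the hub in ≥95% (observed 0.94–0.98).
- *Geometry*: exact partition (disjoint, exhaustive) of every generated
  label; principal-axis recovery within 5° (observed <1°) on rotated
  labels.

The calibration experiments generate scans directly on the 4 mm analysis
grid (18×18×14, the grid the 24×24×18 @ 3 mm field of view downsamples
to) and apply the temporal chain (detrend, 0.08 Hz low-pass) before
degree mapping; the spatial resampling is folded into generation, and
the null cohorts omit AR/drift/nuisance structure since those stages
only remove components that are absent under the null. This choice keeps
the 200-replicate calibration within minutes on one CPU while preserving
exactly the stages whose statistical behaviour is being measured; the
full chain (3 mm acquisition grid → smooth → downsample → common mask →
contrasts) is exercised end-to-end at the study's published size in the
test suite and in `analysis/`.

## What the synthetic data does and does not establish

Passing tests show the *implementation* is correct and the *inference
machinery* calibrated under the generator's assumptions: Gaussian AR(1)
noise with stationary spatial smoothness, a single planted hub with a
linear coupling→pain rule, aligned scans, and nuisance structure that
regression can remove exactly. Real BOLD data violate most of these in
degree (non-stationary smoothness, physiological noise, imperfect
alignment, many interacting networks, head motion correlated with
condition), so these results validate the method's behaviour, not any
clinical claim. The degree maps also carry a centre-weighted topography
from mask geometry (edge voxels have fewer nearby in-mask partners);
group contrasts cancel it, but raw single-subject maps should not be
interpreted as anatomy.

## Known limitations

- The permutation correction replaces the original random-field
  correction; cluster p-values are not numerically comparable to
  parametric ones, only calibration-comparable.
- Trilinear 3→4 mm resampling mildly dilutes the hub at its edges;
  planted couplings are realized slightly below nominal after the full
  chain.
- The generator's pain model is linear with homoscedastic noise and
  clips at the 0–10 scale boundaries; the convergence of mean Δpain to
  intercept + slope·Δcoupling holds where clipping is rare.
- Anatomical region names in cluster tables are free text supplied by
  the caller; no atlas lookup is performed.
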