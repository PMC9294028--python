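# Methods

`muscleqmri` re-creates, end to end, the quantitative thigh-MRI biomarker
workflow used in DMD therapeutic trials: tissue segmentation of
proton-density images, extraction of eight per-visit endpoints (volumes, MVI,
T2-map summaries, Dixon fat fractions), and the longitudinal statistics that
relate early imaging change to later function and loss of ambulation.
Because no patient imaging is publicly deposited for such trials, the package
ships a synthetic trial generator with known ground truth; every estimator is
validated against that truth or against brute-force oracles.

## The synthetic trial

**Disease model.** Each virtual participant carries a latent *infiltration*
fraction `f ∈ [0, 1]`: the share of the thigh muscle bundle replaced by
inter/intramuscular fat. Baseline infiltration follows a logistic curve in
age (plateau 0.60, midpoint 9.5 y, width 1.8 y, subject SD 0.05), reflecting
the accelerated progression observed around ages 8–10. Progression is linear
per week, `f_v = clip(f0 + r_i · week_v, 0, 1)`, with subject rate
`r_i = rate · m_arm · exp(b_i)`, `b_i ~ N(−σ²/2, σ²)` (mean-one lognormal,
σ = 0.4), `rate = 0.004/week`, and treatment multiplier `m = 0.5`. Because
the lognormal is mean-one, arm means obey `E[Δf] = rate · m · week` exactly —
the closed form the tests check. Visits follow the trial schedule
0/17/33/49/97 weeks; randomisation is 2:1 treatment:placebo; the
stratification covariate is an age band (6–8 / 8–11 / 11+), a stand-in since
the source trial's factor is not public.

**Imaging.** Each visit renders an axial stack (default 96×96×12 at
2×2×5 mm; 5 mm slices, 0 mm gap) of concentric ellipses with mild per-slice
jitter: subcutaneous fat ring, muscle bundle, central bone, plus a
copper-sulfate belt phantom in the image corner. A fraction `f` of bundle
voxels becomes inter/intramuscular fat by taking the top-k voxels of a fixed,
spatially smoothed per-subject Gaussian field (σ ≈ 2.5 voxels in plane), so
infiltrated regions are coherent blobs that grow monotonically across visits;
a one-voxel fascia margin keeps blobs off the subcutaneous ring, as the
fascia lata does anatomically. Signals: proton density per tissue
(lean 0.45, fat 1.0, bone 0.12, phantom 0.70 a.u.); multi-echo spin-echo
`S(TE) = S0·exp(−TE/T2)` with tissue T2 of 40 (lean), 150 (fat), 5 (bone)
and 90 ms (phantom) — lean below and fat above the 55 ms elevation
threshold — at echo times 20–100 ms; two-point magnitude Dixon pairs
`water = A(1−ff)`, `fat = A·ff`. Disease couples into lean tissue:
`T2_lean = 40·(1 + 0.5 f)` ms (edema/fat proxy) and
`ff_lean = 0.10 + 0.25 f`, so the lean-ROI endpoints progress as in
patients. The first echo is inflated by +8 % to emulate stimulated-echo
contamination, making first-echo exclusion consequential. Noise is Rician
(magnitude of complex Gaussian), σ = 0.02 a.u. (≈ SNR 22 in lean muscle).
A `t2_scale` hook multiplies all tissue T2 — a deliberate miscalibration used
to exercise phantom QC.

**Outcomes.** 4-stair-climb time is lognormal with log-mean
`log 5 s + 2.5·f`; NSAA is a rounded, [0, 34]-truncated Gaussian declining
by 25 points per unit infiltration and 1 point per year of baseline age.
Loss of ambulation follows a proportional-hazards model with piecewise
constant hazard between visits: log-hazard linear in carried-forward
infiltration (HR 2 per +0.25) plus 0.10 per year of age, baseline hazard
4.5e−5/day, administrative censoring at day 679 (week 97). These values give
event fractions (~15–20 %) and functional spreads comparable to an ambulant
DMD cohort; all are configurable.

**Tabular path.** For statistical calibration work the generator also maps
latent state directly to the eight endpoints plus measurement noise
(`simulate_biomarker_table`), bypassing rendering — the same latent truth at
a fraction of the cost. Bundle volume is 1.55e6 mm³ (≈ trial-scale thighs)
with 10 % between-subject lognormal spread and 1 % per-visit measurement
noise.

**What the generator does not emulate.** No B1/bias fields, motion, partial
volume (voxels are pure tissue), per-muscle anatomy, k-space effects, or
scanner-to-scanner differences beyond the phantom-T2 miscalibration hook.
Passing tests therefore demonstrate correctness of the measurement and
statistics chain under idealised geometry, not clinical segmentation
performance.

## Segmentation

Per-slice, two stages on the normalized (robust p1–p99) PD image:

1. Foreground by intensity threshold (0.08) and connected components: the
   largest component is the thigh, smaller distant components are belt
   phantoms. Fuzzy c-means (k = 3, fuzzifier m = 2) on in-thigh intensities;
   classes are assigned by centroid order plus geometry — bright components
   touching the thigh boundary shell form the subcutaneous ring, the most
   central compact dark component is bone. The bundle (thigh minus ring) is
   regularised by a morphological closing/opening with a radius-2 disk,
   largest-component selection and hole filling (a morphological-snake-style
   boundary step); a missing fat ring triggers a warning and an
   intensity-only fallback.
2. Two-class fuzzy clustering of bundle voxels into lean muscle (lower PD)
   vs inter/intramuscular fat (higher PD). If the two centroids are closer
   than 0.15 normalized units the bundle is declared homogeneous (all lean) —
   this prevents noise-splitting of an uninfiltrated bundle. Components
   smaller than 4 voxels merge into their surroundings. Bone is made
   3-D-consistent by keeping its largest 3-D component.

FCM centroids are initialized evenly spaced over the sample range
(positions (2i+1)/2k), which is deterministic and robust when cluster sizes
are very unequal (quantile or random initialization collapses when fat
dominates the thigh at high infiltration). Membership ties break toward the
lower-intensity class. The FCM implementation is checked against an
independent loop-based alternating-update oracle to 1e−6 in the objective.

## Biomarkers

* **T2 map** — per-voxel mono-exponential fit `S(TE) = S0·exp(−TE/T2)`,
  always excluding the first echo (stimulated-echo mitigation); with 5 echoes
  four points remain, and at least 3 are required. Initialization is a
  signal-weighted log-linear regression; refinement is a damped Gauss-Newton
  (Levenberg) iteration in `(S0, 1/T2)`, vectorized across voxels via
  closed-form 2×2 normal equations (50 iterations, accept-if-improved).
  `fit_ok` excludes voxels with non-positive signal at all kept echoes,
  non-positive S0, or T2 outside (1, 1000) ms; invalid voxels are excluded
  from every summary, numerator and denominator alike. The fit is validated
  against a brute-force grid search (T2 grid 1–300 ms, step 0.25, closed-form
  S0) at SNR 50.
* **Percent non-elevated** — share of valid voxels with T2 strictly below
  55 ms: a voxel at exactly 55 ms counts as elevated. The denominator is the
  mask handed in; the pipeline uses the muscle bundle (whether the original
  "percent of total voxels" included non-muscle voxels of the acquisition is
  an open interpretation — any mask can be supplied).
* **Fat fraction** — `fat / (water + fat)` per voxel from magnitude Dixon
  images (no phase unwrapping); voxels with zero denominator are invalid.
* **Volumes / MVI** — label count × voxel volume;
  `MVI = 100·muscle/(muscle + fat)`.
* **ROIs** — muscle bundle (lean ∪ inter/intramuscular fat) and lean muscle.
  T2 summaries are restricted to a proximal slice window (default the leading
  40 % of slices), mirroring the shorter coverage of the T2 acquisition;
  volumes and Dixon summaries use the whole stack.
* **Phantom QC** — pass iff the median belt-phantom T2 lies in
  (80, 100) ms; a timing miscalibration of ×1.3 moves a 90 ms phantom to
  ≈ 117 ms and fails. Failing scans are non-evaluable and excluded from the
  statistics input; the manifest records each exclusion and the overall
  evaluable fraction.

## Statistics

* **CFB bookkeeping** — baseline is the week-0 assessment; unscheduled and
  early-termination rows are excluded; change at each visit is attributed to
  the dose received at the previous visit; a zero baseline leaves %CFB
  missing with a warning. Volumes and MVI are analysed as %CFB, T2 /
  percent-non-elevated / fat-fraction endpoints as absolute CFB.
* **MMRM** — fixed effects: stratification factor, baseline value,
  treatment, visit (categorical) and treatment×visit; subjects are the
  repeated-measures unit. The default covariance is **unstructured across
  visits**, fitted by iterated feasible GLS (3 iterations) with a pooled
  pairwise-complete within-subject covariance; a random-intercept (compound
  symmetry) option uses statsmodels MixedLM. Unstructured is the default
  because progression rates vary across boys, which makes
  compound symmetry anticonservative for late-visit contrasts — simulation
  shows ≈ 6 % type-I error at week 49 for the unstructured fit vs ≈ 18 % for
  the random intercept under the generator's heterogeneous-slope null.
  Contrast df use a between-within approximation (subjects minus
  between-subject parameters); the baseline covariate is standardized
  internally for conditioning (contrasts unaffected); collinear design
  columns are dropped by a greedy rank check. P values are nominal — no
  multiplicity adjustment anywhere. Per-visit adjusted means are computed at
  observed stratum proportions and the mean baseline.
* **Week-49 vs week-97 regressions** — OLS on complete cases, arms pooled;
  4SC analysed as %CFB, NSAA as CFB.
* **Cutpoints** — exhaustive scan over midpoints between consecutive sorted
  distinct predictor values, minimizing pooled within-subgroup SSE of the
  outcome; ties break toward the smaller cutpoint. Inputs are canonically
  sorted, so results are invariant to record order. The `informative` flag
  comes from a seeded permutation test (199 permutations, α = 0.05) on the
  SSE reduction — the source analyses report a cutpoint but no significance
  rule, so the flag is this package's own guard against over-reading noise
  splits. The bivariate tree splits on muscle-volume %CFB first and re-splits
  only the low-volume branch on the quality endpoint, leaving the high-volume
  region terminal.
* **Survival** — lifelines Cox fits with Efron ties, always including
  baseline age. Median split: "below" is strictly less than the median, ties
  join the upper group, and the indicator is oriented so HR > 1 means the
  less favourable baseline group (direction per endpoint: higher is better
  for volume/MVI/percent-non-elevated, lower for fat volume/T2/fat
  fraction). Time-varying: counting-process intervals with the endpoint
  carried forward between visits; intervals must partition follow-up and the
  event may occur only in the final interval. With constant covariates the
  time-varying fit reduces to the time-fixed fit to solver precision.

## Pipeline and reproducibility

`run_pipeline` chains generate → segment → extract → analyze → report,
writing NIfTI volumes (optional), tidy CSV tables, PNG plots, a text report
and a JSON manifest (config echo, per-scan QC with reasons, stage status,
SHA-256 of every emitted file, evaluable fraction) — the manifest is written
even on failure. All randomness derives from one root seed through
`numpy.random.SeedSequence` key paths (subject-level streams for geometry and
infiltration fields, visit-level streams for acquisition noise), so identical
config + seed reproduce byte-identical outputs. Age plots pool arms, as the
descriptive age analysis does.

## Problem sizes used in validation

Unit tests run compact phantoms (48–64 px, 3–4 slices). The acceptance suite
uses: the default 96×96×12 phantom for segmentation recovery (10 seeded
noisy phantoms); 10,000 voxels at SNR 50 for T2; 500 simulated trials of
n = 120 (tabular path) for MMRM calibration and 200 for effect recovery;
100 seeds × n = 1000 for Cox recovery; and 20 full pipeline runs of n = 120
at a reduced 32×32×3 image size for the directionality check — the imaging
chain is identical, only the grid is smaller, which we verified leaves Dice
and QC behaviour intact at the 0.9 level.

## Known limitations

* The segmenter assumes the concentric topology the generator produces;
  real thighs (two bones at proximal slices, muscle-group boundaries,
  bias fields) would need atlas priors or learning-based methods, which are
  out of scope.
* The unstructured MMRM uses moment-based GLS rather than REML; for severely
  unbalanced missingness REML would be preferable.
* `fit_ok` screening does not correct Rician floor bias at very low SNR.
* The permutation-based `informative` flag is a pragmatic guard, not part of
  the original analyses.
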