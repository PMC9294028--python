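# muscleqmri

Quantitative thigh-MRI biomarkers for Duchenne muscular dystrophy (DMD)
trials: a reproducible "trial in a box" that generates a synthetic imaging
cohort with known ground truth, segments each scan, extracts the standard
muscle-MRI endpoints, and runs the longitudinal statistics that relate early
imaging change to later function and loss of ambulation.

It is aimed at imaging scientists and trial statisticians who need a tested,
end-to-end reference implementation of this analysis chain — every stage is
validated against generator ground truth or a brute-force oracle, because
patient-level imaging from such trials is not publicly deposited.

## What it computes

Per subject-visit, from a proton-density stack, a multi-echo spin-echo series
and a Dixon water/fat pair:

- **Segmentation** into bone, subcutaneous fat, lean muscle and
  inter/intramuscular fat by per-slice fuzzy c-means plus geometric rules and
  a morphological active-contour boundary refinement. The *muscle bundle* is
  the thigh cross-section excluding bone and subcutaneous fat.
- **Muscle volume index**: `MVI = 100 · muscle / (muscle + fat)` where `fat`
  is inter/intramuscular fat volume.
- **T2 map**: per-voxel mono-exponential fit `S(TE) = S0·exp(−TE/T2)`,
  excluding the first echo (stimulated-echo mitigation), summarized as the
  mean T2 of the bundle and of lean muscle, and as the **percent
  non-elevated voxels** — the share with T2 strictly below 55 ms. A
  copper-sulfate belt phantom in the field of view provides per-scan QC.
- **Dixon fat fraction**: `fat / (water + fat)` per voxel, summarized over
  the same two ROIs.

Cohort-level statistics: change / percent-change from baseline with dose
attribution; MMRM treatment contrasts by visit (unstructured covariance,
nominal p-values); simple regressions and single-cutpoint regression trees of
week-49 MRI change against week-97 function (4-stair-climb time, NSAA);
bivariate volume + quality trees; and Cox models of time to loss of
ambulation (median baseline split, and time-varying covariates), always
adjusted for age.

## Worked example

```python
import muscleqmri as mq

subs = mq.simulate_cohort(24, mq.CohortConfig(), seed=7)
vi = mq.render_visit(subs[0], visit_index=3, spec=mq.PhantomSpec(), seed=42)

seg   = mq.segment_thigh(mq.normalize_volume(vi.pd_volume), seed=0)
t2map = mq.fit_t2_map(vi.multi_echo, seg.data != mq.Tissue.BACKGROUND)
ffmap = mq.fat_fraction_map(vi.dixon_water, vi.dixon_fat)
bm    = mq.extract_visit_biomarkers(seg, t2map, ffmap, t2_slice_window=(0, 5))
print(bm.as_dict())
```

For this subject (true infiltration 0.492 at week 49) the endpoints are:

```
muscle_volume_mm3                   214040.00
intermuscular_fat_volume_mm3        223860.00
mvi_percent                             48.88
t2_bundle_ms                            99.71
t2_lean_ms                              53.53
pct_non_elevated                        33.08
ff_bundle_percent                       55.62
ff_lean_percent                         22.62
```

Roughly half the bundle is fat (MVI ≈ 49 %, consistent with the configured
infiltration), the bundle-mean T2 sits between the lean (≈ 50 ms) and fat
(150 ms) values, and the belt phantom reads 90.3 ms → QC pass. Fitting the
treatment model on a cohort of 24:

```python
tab = mq.simulate_biomarker_table(subs, seed=7)
cfb = mq.derive_cfb(tab, ["muscle_volume_mm3"], mode="percent")
base = tab[tab.week == 0].set_index("subject_id")["muscle_volume_mm3"]
cfb["bl"] = cfb["subject_id"].map(base)
print(mq.MMRM(cfb, "pcfb_muscle_volume_mm3", "bl", weeks=(17, 33, 49)).fit().summary())
```

```
MMRM: pcfb_muscle_volume_mm3   (covariance: unstructured, contrast df: 19)
 week  n_trt  n_pbo     adj mean trt (95% CI)     adj mean pbo (95% CI)      difference (95% CI)        P
   17     16      8   -5.20 (-6.81, -3.59)   -8.26 (-10.53, -5.98)    3.06 (0.27, 5.84)   0.0332
   33     16      8  -10.61 (-13.70, -7.53)  -16.02 (-20.38, -11.66)  5.41 (0.06, 10.75)  0.0476
   49     16      8  -15.65 (-20.20, -11.10) -23.69 (-30.13, -17.25)  8.04 (0.15, 15.92)  0.0462
```

Both arms lose muscle volume relative to baseline (disease progression), the
treated arm loses less, and the per-visit difference is the adjusted
treatment contrast with its nominal p-value.

The same chain runs from the shell:

```bash
muscleqmri run --out results/demo --seed 7 --subjects 12
muscleqmri segment --in pd.nii.gz --out labels.nii.gz
muscleqmri stats --table results/demo/tables/cohort.csv \
    --analysis mmrm --endpoint mvi_percent --out mvi_mmrm.csv
```

`run` writes NIfTI volumes, tidy CSV tables, plots (trajectories and
biomarker-vs-age scatters) and a JSON manifest with per-scan QC outcomes and
SHA-256 checksums; identical config + seed reproduce identical outputs.

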