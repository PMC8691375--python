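# aaamorph

Geometric morphometry and growth prediction for abdominal aortic
aneurysms (AAA).

Small AAAs are kept under imaging surveillance until repair is indicated,
and predicting which aneurysm will grow quickly is an open clinical
problem. From a binary 3D segmentation of the infra-renal aorta (the
region between the renal arteries and the iliac bifurcation), `aaamorph`
extracts three geometric predictors of future growth:

- **Maximal anteroposterior diameter (APD, mm)** — for every axial slice
  the anteroposterior extent of the segmented cross-section; the maximum
  over slices is the aneurysm "size" used in clinical practice.
- **Undulation index (UI, dimensionless)** — `UI = 1 − V / V_CH`, where
  `V` is the segmented volume and `V_CH` the volume of its convex hull.
  A convex shape has UI = 0; lobulated, bulging or bent sacs approach 1.
- **Minimum radius of curvature (min RC, mm)** — the vessel centerline is
  obtained by topology-preserving 3D thinning, smoothed with a b-spline
  and resampled to one point per axial slice; the circumradius
  `R = abc / 4A` of point triplets along the curve is scanned and the
  minimum marks the sharpest bend. A straight vessel has infinite RC.

Between two scans taken `d` days apart, growth is annualized as
`(APD_followup − APD_baseline) / (d / 365)` mm/yr and categorized as
*slow* (< 2.5), *some* (2.5–5.0) or *fast* (> 5.0 mm/yr). Two model
families predict growth from baseline geometry: a multinomial logistic
model for the category (evaluated by one-vs-rest AUROC for the slow and
fast classes) and a linear model for the rate (evaluated by RMSE,
correlation, and the fraction of predictions within a ±2 mm/yr margin,
the accepted technical variability of APD measurement on CT). Both are
tuned by 10-fold cross-validation over a small ridge-regularization grid
with fold-internal standardization.

Because no clinical images ship with the package, a synthetic-cohort
module generates voxel phantoms (bent, bulged and lobulated tubes;
dumbbells) with analytic ground truth, and serial-scan cohorts whose
growth follows a known linear law of the extracted features — so every
stage of the pipeline is testable end to end. See `docs/methods.md` for
the model details and design choices.

## Worked example

Simulate a 192-patient serial-scan cohort, fit all feature subsets, and
render the summary:

```sh
aaamorph simulate -o out/sim --seed 1
aaamorph extract -m out/sim/masks -o out/features
aaamorph fit-evaluate --cohort out/sim/cohort.csv -o out/fit --seed 1
aaamorph report --metrics out/fit/metrics.json -o out/report
```

which prints (seed 1):

```
Growth model evaluation (train n=100, test n=92)

features            AUROC slow  AUROC fast  RMSE mm/yr r (Pearson)  within 2mm
apd                      0.657       0.788       1.650       0.406       0.772
apd+ui+min_rc            0.864       0.850       1.401       0.605       0.870
min_rc                   0.824       0.652       1.535       0.493       0.826
ui                       0.683       0.707       1.725       0.293       0.750
```

Reading the table: the three-feature model separates both slow and fast
growers from the rest (AUROC 0.86 / 0.85) clearly better than aneurysm
diameter alone (0.66 / 0.79), its growth-rate predictions are on average
1.4 mm/yr off, and 87% of test patients are predicted within the 2 mm/yr
measurement margin. `out/fit/` also contains the ROC curves
(`roc_curves.csv`, `roc_panels.png`) and the predicted-vs-actual scatter
(`predicted_vs_actual.png`); every output directory carries a
`manifest.json` (config hash, seed, library versions) that reproduces
the run exactly.

The library surface mirrors the pipeline: `read_mask` /
`extract_all_features` for single scans, `filter_cohort` /
`annual_growth` for serial pairs, `fit_with_cv` / `roc_at_threshold` /
`evaluate_linear` for modelling, and `generate_phantom` /
`generate_cohort` for synthetic data.

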