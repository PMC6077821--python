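# adsev

Computational pipelines for staging Alzheimer's disease from imaging:
**(1)** automatic arterial-input-function (AIF) determination in
dynamic-susceptibility-contrast (DSC) perfusion MRI by K-means versus
fuzzy C-means clustering, with truncated-SVD deconvolution into
CBF/CBV/MTT hemodynamic maps and a seeded reproducibility comparison of
the two methods; **(2)** an MCI-to-AD conversion "aggregate biomarker"
that combines a semi-supervised MRI score with age and baseline cognitive
measures, evaluated by 10-fold cross-validated AUC.

Both arms run on data the package generates itself — a 4-D DSC phantom
with known ground truth, and a synthetic four-group cohort
(NC/sMCI/pMCI/AD) with an aging confound deliberately co-directional with
disease atrophy — so every result is reproducible from a single seed.
The intended users are methods researchers who want a controlled testbed
for AIF-selection and conversion-prediction pipelines rather than a
clinical tool.

## The models in brief

**Perfusion arm.**  The arterial bolus is a gamma variate
Ca(t) = a(t−t0)^r e^{−(t−t0)/b}; tissue curves follow the
indicator-dilution convolution Ct = F·(Ca ⊛ R) with residue function
R(t) = e^{−t/MTT} and the central-volume identity MTT = CBV/CBF.  Voxel
curves (converted from signal by C = −ln(S/S0)/(κ·TE)) are filtered,
normalized to unit area, and clustered; each cluster's mean curve is
scored by peak/(TTP·FWHM) and the winner is the AIF.  CBF comes from
truncated-SVD deconvolution of the Toeplitz system A·x = Ct
(CBF = 6000·max x), CBV from 100·∫Ct/∫Ca, MTT from the central-volume
identity.  K-means (Lloyd, k-means++ seeding, multi-restart) and fuzzy
C-means (membership exponent m = 2) are implemented from scratch with
asserted monotone objectives.

**Biomarker arm.**  Within each training fold: per-feature OLS on healthy
controls removes the normal-aging trend from all MRI features;
L1-logistic regression on AD vs NC (never MCI) selects features; a
low-density-separation scorer — logistic loss on AD/NC plus an annealed
entropy penalty H(p(x)) on unlabeled MCI subjects — yields the MRI score
p(AD-like | x); a random forest over [MRI score, age, cognition] of the
training MCI subjects yields the aggregate score.  Folds are stratified
over conversion labels; the pooled out-of-fold Mann-Whitney AUC is the
endpoint, and a built-in audit verifies held-out labels cannot touch any
fitted model.

See `docs/methods.md` for defaults, numerical choices and limitations.

## Worked example

```python
import numpy as np
from adsev import (CohortSpec, default_acquisition, default_grid,
                   default_phantom_spec, generate_cohort, generate_phantom,
                   method_comparison_report, perfusion_maps, run_cv_pipeline,
                   signal_to_concentration)

# Perfusion arm: 50-repeat K-means vs FCM comparison on a noisy phantom
phantom = generate_phantom(default_phantom_spec(),
                           default_acquisition(noise_sigma=2.0),
                           default_grid(), seed=7)
report = method_comparison_report(phantom, k=5, n_repeats=50, base_seed=100)
print(report["table"][["method", "mean_peak", "cv_peak", "mean_auc",
                       "mean_rmse"]].round(4).to_string(index=False))
print("flags:", report["flags"])

# Quantify the noiseless phantom against its true AIF
clean = generate_phantom(default_phantom_spec(), default_acquisition(0.0),
                         default_grid(), seed=1)
conc, _ = signal_to_concentration(clean.signal, clean.acq)
gray = clean.region_indices("gray")
maps = perfusion_maps(conc, clean.true_aif, gray, threshold_frac=0.01)
print(f"gray CBF {maps.cbf[gray].mean():.1f} (true 60.0)  "
      f"CBV {maps.cbv[gray].mean():.2f} (true 4.00)  "
      f"MTT {maps.mtt[gray].mean():.2f} s (true 4.00)")

# Biomarker arm: 10-fold CV on the default synthetic cohort
cohort = generate_cohort(CohortSpec(seed=0))
cv = run_cv_pipeline(cohort, n_folds=10, seed=0)
print(f"MRI-only AUC {cv.pooled_auc_mri:.3f}   "
      f"aggregate AUC {cv.pooled_auc_aggregate:.3f}")
```

Output:

```
method  mean_peak  cv_peak  mean_auc  mean_rmse
kmeans     3.1675   0.0084   22.3797     0.7978
   fcm     3.0779   0.0000   20.9400     0.8201
flags: {'higher_peak': 'kmeans', 'larger_auc': 'kmeans', 'lower_peak_cv': 'fcm', 'lower_rmse': 'kmeans'}
gray CBF 59.2 (true 60.0)  CBV 4.05 (true 4.00)  MTT 4.11 s (true 4.00)
MRI-only AUC 0.807   aggregate AUC 0.858
```

Reading it: partial-volume contamination drags both methods' selected AIF
peak below the true peak of 6, but K-means isolates a more arterial
cluster (higher peak, larger bolus area, lower RMSE against the known
true AIF) than fuzzy C-means, whose soft averaging mixes in tissue signal.
On the noiseless phantom the deconvolution recovers the gray-matter
ground truth to within a few percent.  In the biomarker arm, adding age
and baseline cognition to the MRI score lifts the cross-validated AUC for
discriminating converting from stable MCI — the aggregate-biomarker
effect the pipeline exists to demonstrate.

## Command line

Every pipeline stage is also a CLI command (all randomness from
`--seed`; each run writes a manifest with content digests):

```sh
adsev simulate-dsc    --config phantom.yaml --seed 7 --out dsc.nii.gz
adsev select-aif      --in dsc.nii.gz --method kmeans --k 5 --seed 3 --out aif.csv
adsev quantify        --in dsc.nii.gz --meta dsc.meta.json --aif aif.csv \
                      --mask dsc_mask.nii.gz --svd-thresh 0.01 --out-prefix maps_
adsev compare-methods --config phantom.yaml --repeats 50 --seed 1 --out report.csv
adsev simulate-cohort --config cohort.yaml --seed 5 --out cohort.csv
adsev biomarker       --cohort cohort.csv --folds 10 --seed 9 --out results.json
```

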