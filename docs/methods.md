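# Methods

`adsev` contains two independent analysis arms: a dynamic-susceptibility-
contrast (DSC) perfusion arm built around clustering-based arterial-input-
function (AIF) determination, and an MCI-to-AD conversion biomarker arm
built around semi-supervised scoring of synthetic MRI features.  Both arms
ship their own seeded data generators, because the corresponding clinical
data (a 42-subject perfusion cohort; ADNI) cannot be redistributed.  This
note records the models, the defaults and why, the numerical choices, and
what the synthetic experiments do and do not demonstrate.

## Perfusion arm

### Forward model

The phantom simulates bolus tracking with the standard indicator-dilution
chain.  The arterial concentration is a gamma variate

    Ca(t) = a (t − t0)^r exp(−(t − t0)/b),   t > t0,

with defaults t0 = 10 s, r = 3, b = 1.5 s, and `a` scaled so the peak is 6
(arbitrary mM-like units).  The gamma variate is the field-standard
parametric bolus shape; its mode sits at t0 + r·b = 14.5 s.  Tissue
concentration is the discrete rectangle-rule convolution

    Ct(t_i) = F_si · Σ_{j≤i} Ca(t_j − delay) · R(t_i − t_j) · dt,

where F_si = CBF/6000 converts mL/100g/min to 1/s at tissue density
1 g/mL, and R is the residue function (exponential `exp(−t/MTT)` by
default; a boxcar plug-flow variant is provided).  The central-volume
theorem MTT = (CBV/CBF)·60 is enforced at parameter construction, so truth
maps are internally consistent by design.  Signal follows the
gradient-echo DSC model S(t) = S0·exp(−κ·TE·C(t)) with TE = 30 ms,
S0 = 100, κ = 5 (mM·s)⁻¹ and 8 pre-bolus baseline samples; noise, when
enabled, is additive Gaussian on the signal (σ = 2, i.e. 2% of baseline,
for the default noisy condition).  Rician noise, bolus dispersion, T1
leakage and motion are out of scope.

### Time grid

The default grid is 60 s sampled at dt = 0.1 s (600 samples).  The
rectangle rule is first-order: its discrete sum over an exponential
residue overestimates ∫R by a factor x/(1 − e^(−x)) with x = dt/MTT,
about 13% at dt = 1 s and MTT = 4 s but only ~1.3% at dt = 0.1 s.  The
fine grid therefore keeps the quadrature bias of CBV (a ratio of
trapezoid integrals) and MTT safely below the 2%/5% recovery tolerances
the test suite asserts, without switching to a higher-order convolution
scheme that would complicate the exact Toeplitz forward/inverse pairing.

### Phantom geometry

32×32×4 voxels: a 2-voxel background frame, gray- and white-matter halves
(CBF/CBV/MTT = 60/4/4.0 and 25/2/4.8 in mL/100g/min, mL/100g, s), a 2×2
pure arterial column through all slices, and a one-voxel partial-volume
shell around it in which the measured curve is the linear concentration
mixture pv·Ca + (1−pv)·Ct with pv = 0.4.  Partial-volume mixing is applied
on concentration and then converted to signal (tracer mixing is linear in
concentration, not in log-signal).  Truth maps store the tissue
parameters of each region; for partial-volume voxels they describe the
tissue fraction, so deconvolving such voxels deliberately overestimates
flow — that bias is the phenomenon the AIF-selection comparison probes.

### AIF determination

The selection chain converts signal to concentration per voxel
(C = −ln(S/Ŝ0)/(κ·TE), Ŝ0 the per-voxel baseline mean; voxels with any
non-positive sample are invalidated), then filters candidates with three
conjunctive, order-independent rules: area under the curve at or above
the 90th percentile of valid voxels, time-to-peak within half the
acquisition window, and at most 20% "negative" samples.  A sample counts
as negative when it falls below −2σ̂ of a per-voxel robust noise scale
(σ̂ from the median absolute first difference); the floor is exactly zero
on noise-free data.  Without that floor, mean-zero noise marks ~half of
every pre-bolus and post-washout sample negative and the rule would
reject perfect arterial voxels.  Survivors are normalized to unit area so
clustering sees bolus *shape*, not amplitude.

The normalized curves are clustered into k = 5 groups by K-means or fuzzy
C-means (both written from scratch, see below).  Each cluster's mean
**raw** curve is scored by peak/(TTP·FWHM) — high, early and narrow is
arterial — and the winner's mean raw curve is the AIF.  Scoring metrics
are measured on a 1-s moving-average copy of the mean curve: on a raw
noisy mean, the width at half maximum of the single highest noise sample
can be arbitrarily small, which would let a flat tissue cluster outscore
a genuine bolus.  The returned AIF and its reported metrics (peak,
time-to-peak, trapezoid area, interpolated FWHM) are unsmoothed.  Clusters
that are empty, flat, or never cross half maximum score −∞ and cannot be
selected; ties break to the lower cluster index.

### Clustering

K-means is Lloyd's algorithm with squared-Euclidean distances,
distance-weighted (k-means++) seeding, 10 restarts by default keeping the
lowest final objective, and empty clusters re-seeded to the point
farthest from its center.  The multi-candidate "greedy k-means++" variant
was evaluated and rejected: it concentrates every restart on the same
seeding and measurably hurts the multi-restart scheme's chance of finding
the global optimum on small instances.  Fuzzy C-means starts from a
seeded Dirichlet membership matrix and iterates the standard coupled
updates with fuzziness m = 2; points coincident with a center get full
membership there (lowest index on ties).  Both objectives are
alternating-minimization monotone; the implementations assert
non-increase and (for FCM) row-stochastic memberships at every iteration
and expose the trajectories.  Multi-restart Lloyd remains a local method:
on roughly one in a hundred random 100-instance batches (n ≤ 8, k = 2),
20 restarts miss the exhaustive-partition optimum.

### Deconvolution

CBF is estimated by truncated-SVD inversion of the lower-triangular
Toeplitz AIF matrix A[i,j] = dt·Ca(t_{i−j}); singular values below
`threshold_frac`·σ_max are zeroed.  Defaults: 0.2 for noisy data, 0.01
for noiseless tests — field-typical values; the truncation is the only
regularization.  CBF = 6000·max(x) where x estimates F_si·R;
CBV = 100·∫Ct/∫Ca by trapezoid; MTT = (CBV/CBF)·60, reported as 0 where
the flow estimate is below 10⁻⁹ s⁻¹.  Delay-insensitive (block-circulant)
SVD is not implemented; phantom delays default to zero.  On the noiseless
default phantom this recovers gray/white CBF within ~1.4%, CBV within
~1.3% and MTT within ~2.7% of truth.

### Reproducibility experiment

"Same batch of data" is interpreted as one fixed phantom with only the
clustering initialization seed varying across 50 repeats per method.
Accuracy is RMSE/peak/area error against the known true AIF;
reproducibility is the per-metric coefficient of variation (sample
SD/mean).  Directional outcomes (which method has the higher peak, larger
area, lower CV, lower RMSE) are recorded as machine-readable flags and
frozen as a seeded regression test, not asserted as theorems.  On the
default noisy phantom K-means shows the higher peak, larger area and
lower RMSE — partial-volume contamination drags the fuzzy average down —
but FCM converges to an init-independent fixed point on this phantom, so
its dispersion is degenerate-zero and it takes the lower-CV flag.  A
reproducibility advantage of K-means, reported for clinical data
elsewhere, is therefore *not* reproduced by this synthetic setup; the
phantom's cluster structure is simply too clean to destabilize FCM.

## Biomarker arm

### Cohort generator

Subjects belong to four ordered stages NC → sMCI → pMCI → AD (100 per
group by default).  Of 50 Gaussian features, 10 are informative and carry
(i) a monotone disease effect −d[stage] with d = (0, 0.3, 0.7, 1.2) SD
(atrophy: volumes shrink with stage) and (ii) an aging slope of −0.02
SD/yr over ages Uniform(60, 85) — deliberately the *same sign* as the
disease effect, so normal aging mimics disease and confounds a naive
classifier.  Two cognitive scores decline monotonically with stage; their
effect sizes (0.5 and 1.0 SD) are parameterized as the pMCI-minus-sMCI
baseline contrast — the contrast that defines the conversion-prediction
task — with stage multipliers (0, 0.5, 1.5, 2.5): a mild deficit at
stable MCI, a drop of one full contrast at conversion, further decline at
AD.  Conversion labels exist only for MCI subjects (pMCI = 1, sMCI = 0).
The generator emulates the *structure* of an ADNI-like cohort, not its
field names, visit schedule, missingness, feature correlations or
non-Gaussian tails; passing tests show the pipeline behaves correctly
under this generative model, not that its AUCs transfer to real cohorts.

### Pipeline

Four stages, evaluated by stratified 10-fold cross-validation over the
MCI subjects with the Mann-Whitney AUC on pooled out-of-fold scores:

1. **Aging-effect removal.**  Per-feature OLS of feature on age over
   healthy controls only; all subjects are residualized against this
   model.  On the fitting controls the residual-on-age slope is zero to
   machine precision (OLS orthogonality), asserted at 1e-8.
2. **Feature selection.**  L1-penalized logistic regression on AD vs NC
   (MCI data never enter), nonzero coefficients selected; the penalty is
   chosen by internal stratified 5-fold CV over a log grid (1e-2 … 10),
   ties resolved toward the sparser model.  Features are standardized on
   the training statistics.
3. **MRI scorer — low-density separation.**  The published description of
   this stage names the low-density-separation principle without
   algorithmic detail, so the scorer is this package's own realization of
   that principle: a linear logistic separator minimizing

       Σ_labeled log-loss + λ_w‖w‖² + λ_u Σ_unlabeled H(σ(wᵀx + b)),

   where H is the binary entropy of the predicted probability of an
   unlabeled (MCI) point.  Penalizing entropy pushes the decision
   boundary away from regions where unlabeled data are dense — the
   defining idea of low-density separation — while keeping each solve
   smooth and desk-scale.  λ_u is annealed linearly from 0 to its target
   (default 1.0) over 5 warm-started L-BFGS solves, since early
   near-convex steps guide the boundary before the non-convex entropy
   term dominates.  With λ_u = 0 the objective is exactly ridge logistic
   regression (λ_w = 1 default), which the tests verify against an
   independent solver at 1e-4 relative.  This is an interpretation of
   low-density separation, not a reconstruction of the graph-based TSVM
   algorithm of the same name.
4. **Aggregate biomarker.**  A random forest (500 trees, unlimited depth,
   √d feature subsets, per-tree seeds derived from the run seed) over
   [MRI score, age, cognitive scores] of the training-fold MCI subjects;
   its class-probability output is the aggregate score.

Because stages 1–2 involve NC/AD subjects only — never an MCI subject —
they are identical in every outer training fold and are computed once;
stages 3–4 are refit per fold (the unlabeled set and the forest's
training labels change).  Standardization statistics always come from
training data.  Held-out labels touch nothing but the final AUC; the
`leakage_audit` helper refits each fold with that fold's held-out labels
permuted (fold assignment frozen) and verifies every fitted model is
byte-identical via SHA-256 digests of the model parameters.

Nesting everything (no selection or scaling on pooled data) makes the
synthetic AUCs conservative relative to a leaky protocol.  On the default
cohort at seed 0 the MRI-only biomarker reaches a pooled AUC of ~0.81 and
the aggregate ~0.86; on zero-effect cohorts both arms fall inside a
200-shuffle permutation band around 0.5.  AUC values reported on real
ADNI data are not reproduction targets — those data are unavailable and
the generator does not imitate their correlation structure — but the
qualitative ordering aggregate > MRI-only > chance is reproduced.

## Numerical choices and degenerate inputs

* Seeds: every entry point takes one integer seed; the CLI derives
  per-component seeds as SeedSequence([seed, crc32(tag)]) mod 2³¹, so a
  component's stream is stable under unrelated config edits.
* Clustering tolerances: tol 1e-6 on center shift (K-means) or maximum
  membership change (FCM), max 300 iterations, 10 restarts (K-means).
  Equidistant points assign to the lowest center index.
* Zero-distance FCM memberships are hard-assigned (lowest such center).
* Empty candidate sets, single-class label vectors, zero AIF integrals,
  zero age variance and mask/grid mismatches raise `ValueError` with the
  offending quantity named; per-voxel deconvolution failures become zeros
  and are counted in diagnostics.
* Gzipped NIfTI is written with a zeroed gzip mtime so identical runs are
  byte-identical.

## Known limitations

* The signal model omits Rician noise, dispersion, delay sensitivity and
  leakage; conclusions about K-means vs FCM hold for this phantom family
  only, and the FCM stability observed here (CV ≈ 0) shows the phantom
  does not reproduce the initialization sensitivity FCM can exhibit on
  clinical curves.
* The cohort generator's independence assumptions (features independent
  given stage and age) make feature selection easier than on correlated
  volumetric data; the planted-feature recall of 100% should be read in
  that light.
* The LDS scorer is linear; a low-density boundary that is non-linear in
  the selected features is out of reach by construction.
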