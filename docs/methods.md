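# Methods

`epicad` implements a voxelwise outlier-detection system for epileptogenic
lesions (focal cortical dysplasia, heterotopia) on T1-weighted brain MRI, and
a synthetic-phantom test bed for it.  This note documents the model, the
numerical choices, and what the phantom experiments do and do not show.

## Features

Two parametric maps are computed per subject from images assumed already
spatially normalized and intensity corrected:

* **Junction map** — the T1 volume is binarized to the interval
  `I = [T_low, T_high]` with `T_low = mean_GM + SD_GM/2` and
  `T_high = mean_WM − SD_WM/2` (per-class grey-level statistics of the
  subject's own GM/WM segmentation; population SD, i.e. divide by N), then
  smoothed with a 6 mm Gaussian kernel.  The binarization interval is closed
  on both ends.  High values mark voxels at, or resembling, the GM/WM
  interface; blurring of the junction changes them.
* **Extension map** — the GM probability map smoothed with the same kernel;
  it rises when grey matter extends abnormally into the white matter.

"Kernel width" is interpreted as FWHM (the convention of the neuroimaging
software ecosystem these maps come from); `sigma = FWHM / (2 sqrt(2 ln 2))`
per axis, in voxels, after dividing by the voxel size.  Smoothing uses
renormalized zero-padded convolution (the smoothed image divided by the
smoothed ones-volume), which reproduces constants exactly, keeps the
operation linear per voxel and preserves the `[0, 1]` range of the maps.

Each feature map is converted into a Z-score map against cohort **mean/SD
templates** (voxelwise mean and population SD over the control cohort).
Voxels whose SD template falls below a floor (default `1e-6` in map units) on
either feature are excluded from all downstream analysis rather than clamped,
avoiding infinite Z-scores at variance-free voxels.  The feature vector of a
voxel is the pair `(junction_z, extension_z)`, so p = 2.

## Per-voxel one-class SVM bank

Each valid voxel k gets its own one-class SVM trained on the n control
feature vectors at that voxel.  The primal is the Schölkopf formulation
(separate the training set from the origin of the RBF feature space with
maximum margin, slack controlled by ν); the dual solved here is

    min_α  1/2 Σ_ij α_i α_j K(x_i, x_j)
    s.t.   0 ≤ α_i ≤ 1/(νn),   Σ_i α_i = 1,

with `K(x, y) = exp(−‖x−y‖² / (2σ²))`.  This is feasible for any ν in
(0, 1] (the coordinate sum can always reach 1 because n/(νn) = 1/ν ≥ 1); the
solver accepts the full grid down to ν = 0.01.  The ν-property holds: the
fraction of training outliers is bounded by ν and the fraction of support
vectors is at least ν, up to 1/n finite-sample terms.

The solver is a deterministic maximal-violating-pair SMO written for these
tiny problems (n ≤ a few dozen) and batch-compiled with numba, so bank
training, leave-one-out calibration and hyperparameter search over hundreds
of thousands of voxel models stay inside desk-scale budgets.  Stopping
tolerance is a KKT gap of 1e-10; cross-checks against a generic QP solver
agree to better than 1e-6 in decision values.

* **ρ recovery**: mean of `Σ_j α_j K(x_j, x_i)` over margin support vectors
  (0 < α < 1/(νn) with a relative guard of 1e-7); if none exist, the midpoint
  of the KKT interval between the bound and zero sets.
* **Output**: the geometric signed distance `(Σ_i α_i K(x_i, x) − ρ)/‖w‖`
  with `‖w‖² = αᵀKα`, negative on the outlier side.  Geometric normalization
  makes thresholds comparable across voxels; it does not change any ranking
  within a voxel.
* **Training-outlier audits** count a point as an outlier when its distance
  is below −1e-8: margin support vectors sit at distance 0 up to solver
  tolerance and their sign there is numerical noise, not a modelling outcome.
* **Hyperparameters**: selected by minimizing the leave-one-out
  false-positive rate over voxels sampled uniformly without replacement
  (default 4000; the estimate stabilizes from about 1000).  The default grids
  are eight log10-equally-spaced ν values spanning [0.01, 0.56] and eight
  log2-equally-spaced σ values spanning [2⁻⁴, 2⁴], inclusive of both
  endpoints ("eight intervals" is read as eight values reproducing the
  printed endpoints).  Ties go to the least complex model: smallest mean
  support-vector count, then smallest σ.  The reference operating point used
  throughout the experiments is (ν = 0.03, σ = 4), the pair selected for the
  first control database in the source study.
* Bank training is chunked over voxel blocks (default 4096); chunking is an
  execution detail and the result is identical to sequential training.

## Normative calibration and cluster detection

Scores are converted to p-values against a normative distribution built by
leave-one-out: per voxel, train on n − 1 controls, score the held-out
control.  Two variants exist:

* `calibration.loo_normative_scores` holds the cohort templates fixed (the
  classic design with a single template set);
* `pipeline.loo_normative_scores_refit` — used by the calibrated pipeline and
  all experiments — also re-estimates the mean/SD templates from the n − 1
  retained subjects in each fold.  Keeping the held-out subject inside its
  own templates shrinks its Z-scores and inflates the type-I error of the
  resulting threshold roughly fourfold at p = 0.001, so the fully held-out
  variant is the default for inference.  A useful identity makes it cheap:
  pairwise feature differences cancel the fold mean, so only the fold SDs
  enter the per-voxel Gram matrix, which can therefore be assembled from
  pairwise squared differences computed once.

Per-subject histograms are computed on a shared bin grid (default 512 bins
spanning the pooled range ± 5%), density-normalized so cohort size does not
rescale the distribution, and averaged.  A Gaussian KDE with Silverman
bandwidth (`0.9 min(sd, IQR/1.34) N^{−1/5}`) over the pooled scores (equal
per-map weighting) provides the continuous density; its CDF and pdf are
evaluated exactly to double precision with a windowed scheme (kernel
contributions beyond eight bandwidths are 0 or 1).  The threshold for a
p-value is the left-tail KDE quantile — low scores are suspicious.

Thresholded maps (score ≤ threshold, inclusive) are decomposed into
26-connected components labelled in lexicographic scan order.  Clusters are
filtered by size — strictly larger than `min_size` voxels, default 82
(derived in the source study from the expected cluster size of its SPM
analysis on 1 mm³ real data; it is a data-derived constant, not universal) —
and ranked by their minimum (most pathological) score; ties go to the larger
cluster, then the lowest lexicographic seed voxel.

## Lesion simulators

* **Blurred junction** (FCD-like): inside a U-shaped ROI (a three-sided
  square band footprint replicated over 6 consecutive slices), the voxels
  whose original grey value lies in `I` are replaced by the in-plane
  disk-mean (radius 3 mm, lattice points with centre distance ≤ radius — 29
  points at 1 mm spacing; in-bounds renormalization at volume edges) of the
  original image.  Only those voxels change; the ground truth is exactly the
  altered set.  `pipeline.interface_u_roi` places the U base on the subject's
  own GM/WM interface, mirroring how the ROIs are drawn on each subject's
  image around a sulcus.
* **Heterotopion-like**: spheres (default radius 2 mm, world-mm distance to
  the voxel centre, inclusive) whose voxels are replaced by independent
  uniform draws from `I` — uniform because only "random sampling within the
  range" is specified.  The default design simulates 6 lesions at locations
  shared across 5 subjects (30 lesions total) plus one blurred-junction
  lesion per subject; shared locations are world-mm offsets from the volume
  centre on a deterministic Fibonacci sphere of radius 4.5 mm, which lies in
  deep WM of the default phantom.

## Evaluation

ROC analysis is pooled at the voxel level over test subjects with a full
sweep over unique scores.  Evaluation consumes *suspicion* values (higher =
more suspicious): negated signed distances for the one-class bank, t values
for the baseline.  TPR at fixed FPR (targets 0.01, 0.05, 0.1) uses
conservative step interpolation (largest achieved TPR with FPR ≤ target).
Confidence intervals are bias-corrected percentile bootstrap (z₀ correction,
no acceleration) with patient-level resampling, default 120 replicates; an
exhaustive mode enumerates all nⁿ resamples for small n.  The mass-univariate
baseline is a per-feature single-patient-vs-controls t-map,
`t = (x_p − mean_c)/(sd_c sqrt(1 + 1/n_c))` with sample SD and n_c − 1
degrees of freedom (the source study's four-group GLM df is specific to its
design matrix), and a minimum-statistic conjunction of the two feature
t-maps; zero-variance voxels are excluded (NaN) and dropped from pooling.

## Phantom generator

The phantom emulates a spatially normalized brain: a WM core wrapped by a GM
ribbon with sinusoidal folding, a CSF rim, empty background (normalized
interface radii 0.58 / 0.80 / 0.88 of the half grid).  Defaults: 32³ grid,
1 mm cubic voxels, class means CSF/GM/WM = 40/100/140 with within-class SDs
of 10 (so `I = [105, 135]` and in-range probability ≈ 0.31 for pure-class
voxels — a deliberately subtle junction signal), Gaussian noise (Rician
available; Gaussian default keeps moments exact for tests).

Between-subject variability has three components, chosen to mirror what
survives spatial normalization of real cohorts:

* a multiplicative intensity factor (SD 5%) acting as a receiver gain — it
  scales signal and noise together, since image units are arbitrary and
  within-subject SNR is set by the class SDs;
* per-voxel scanner noise;
* a smooth per-subject deformation of the tissue interfaces (unit-variance
  Gaussian random field smoothed over 3 voxels, amplitude 0.04 normalized
  radius units ≈ 0.6 voxel), standing in for residual anatomical and
  registration variability.  Without it, the per-voxel feature distributions
  are exactly Gaussian and a correctly-specified univariate t-test is
  provably near-optimal — an unrealistically favourable regime for the
  baseline.

Tissue probability maps are *derived from the noisy image* by a small EM on
a Gaussian mixture with fixed spatial priors (posterior-weighted moment
updates, 10 iterations), as a unified segmentation would produce them.  The
segmentation priors mix the geometric partial-volume weights with a flat
within-brain floor (weight 0.2), emulating probabilistic-atlas dispersion:
real tissue atlases keep every class possible everywhere in the brain, which
is what lets GM-like intensities deep in the WM (heterotopia) raise the GM
posterior.  Image synthesis itself uses the un-floored partial-volume
weights.  Subject streams derive from the root seed by the counter scheme
`default_rng([seed, subject_index, purpose])`, so cohorts extend without
reshuffling and every output is bitwise reproducible.

What the phantom does **not** model: real cortical geometry and atlases,
bias fields, partial-volume effects beyond the smoothed ribbon, multi-site
protocol differences, and true lesion biology.  Passing phantom tests shows
the pipeline's statistical machinery behaves as designed under controlled
conditions; it does not certify clinical performance.

## Study conditions of the experiments

`epicad.experiments` fixes the desk-scale conditions: ν-property audit on a
37-subject cohort (24³ grid, ≥1000 sampled voxels); type-I calibration on a
20-subject cohort (32³ grid, fully held-out LOO, 10 fresh test subjects,
>1e5 voxel decisions); method comparison and end-to-end detection on
37-control cohorts (32³) with 5 heterotopia test subjects or one
blurred-junction subject per replication.  Cohort sizes follow the source
study's first database where affordable; grid sizes are chosen so each
experiment regenerates everything from scratch in seconds to minutes.

Two caveats about desk scale, observed and deliberated rather than patched:

* **Spatial correlation vs binomial bands.**  6 mm FWHM features on a 32³
  grid leave on the order of only ~10² effectively independent decisions per
  subject; a p = 0.001 voxel threshold then admits false positives in rare
  ~100-voxel blobs, so the *measured* held-out FPR is an average of a few
  blob events and fluctuates far more than an independent-voxel binomial
  model predicts, even though its expectation sits at the nominal level.
* **Cluster size filters do not transfer across scales.**  The 82-voxel
  filter is ~1% of the whole phantom brain; at desk scale a suprathreshold
  lesion cluster of that size requires a large fraction of the simulated
  lesion to clear a 1-in-1000 threshold simultaneously.

## Known limitations

* The RBF signed distance saturates at `−ρ/‖w‖` for points far from all
  support vectors; extreme outliers are compressed toward a per-voxel floor,
  which limits dynamic range in the deep tail.
* Pooled voxel-level ROC mixes voxels with different per-voxel score scales;
  geometric normalization reduces, but does not remove, this heterogeneity.
* A subject-level global feature offset (e.g. a segmentation batch effect)
  can partially cancel a lesion's feature shift at the lesion voxels
  ("masking"), to which a direction-agnostic outlier score is more sensitive
  than a one-sided test.
* The simulators alter only voxels already inside `I`, so the junction
  feature change of a simulated blurred junction is bounded by the local
  density of in-range voxels.
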