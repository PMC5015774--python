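# epicad

Voxelwise outlier detection of epileptogenic lesions on T1-weighted brain
MRI, built around per-voxel one-class support vector machines, with a
synthetic brain-phantom test bed so the whole pipeline can be exercised and
validated without any patient data.

## The problem

Focal cortical dysplasias (FCD) and heterotopia are small, highly
epileptogenic malformations that are frequently invisible on routine reading
of T1 MRI.  Mass-univariate "lesion mapping" compares a patient to a healthy
cohort one voxel and one feature at a time; it cannot pool evidence across
features and its false positives are hard to control.  `epicad` instead
treats detection as *novelty detection*: at every brain voxel k, a one-class
SVM learns the healthy distribution of a two-component feature vector

    V_k = (junction_z, extension_z)

where the **junction map** is the smoothed binary image of grey values in
`I = [mean_GM + SD_GM/2, mean_WM − SD_WM/2]` (GM/WM interface blurring) and
the **extension map** is the smoothed GM probability map (grey matter
extending into white matter), each z-scored against cohort mean/SD
templates.  The model solves, per voxel, the Schölkopf one-class dual

    min_α 1/2 Σ_ij α_i α_j K(x_i, x_j)   s.t.  0 ≤ α_i ≤ 1/(νn),  Σ α_i = 1

with an RBF kernel `K(x, y) = exp(−‖x−y‖²/(2σ²))`, and outputs the signed
distance `(Σ_i α_i K(x_i, x) − ρ)/‖w‖` — negative means outlier, and ν
bounds the fraction of training outliers (the ν-property).  Signed-distance
maps are converted to p-values against a leave-one-out *normative
distribution* (averaged held-out score histograms + kernel density
estimate), thresholded (default p = 0.001), decomposed into 26-connected
clusters, size-filtered and ranked by their most pathological voxel.

The package also provides the two lesion simulators used to validate such
systems (blurred GM/WM junction in a U-shaped ROI; heterotopion-like spheres
with grey values drawn from `I`), ROC/AUC evaluation with TPR at fixed FPR
and bias-corrected percentile bootstrap CIs, a mass-univariate t-map +
conjunction baseline, and a phantom generator producing healthy-control
cohorts (folded GM ribbon over a WM core, per-subject gain, noise and shape
variability, segmentation-like tissue probability maps).

Audience: researchers building or benchmarking voxelwise normative-modelling
CAD pipelines, and anyone needing a self-contained, fully synthetic test bed
for one of them.

## Worked example

Train a bank on a synthetic cohort, calibrate it, and detect a simulated
heterotopion in a fresh subject:

```python
import numpy as np
from epicad import calibration, lesions, ocsvm, pipeline
from epicad.phantom import PhantomSpec, generate_phantom, tissue_posteriors
from epicad.volumes import Volume
from epicad.phantom import TissueProbMaps

spec = PhantomSpec(seed=7)                       # 32 mm cube, 1 mm voxels
cohort = pipeline.generate_phantom_cohort(spec, 20)
templates, fields, _ = pipeline.build_cohort_features(cohort)
bank = ocsvm.train_bank(fields, nu=0.03, sigma=4.0)

loo = pipeline.loo_normative_scores_refit(cohort, nu=0.03, sigma=4.0)
dist = calibration.normative_distribution(loo)

t1, probs, _ = generate_phantom(spec, 500)       # fresh test subject
stats = pipeline.subject_tissue_stats(t1, probs)
centre = (np.asarray(spec.shape) - 1) / 2.0
gt = lesions.simulate_heterotopia(
    t1, [centre + (4, 0, 0), centre + (0, -4, 0)], stats, seed=1)
post = tissue_posteriors(gt.modified_t1.data, spec, 500)
probs2 = TissueProbMaps(gm=Volume(post["gm"]), wm=Volume(post["wm"]),
                        csf=Volume(post["csf"]))
field = pipeline.features_for_subject(gt.modified_t1, probs2, templates)
smap = ocsvm.score_subject(bank, field)

threshold, labels, records = pipeline.detect_clusters(smap, dist,
                                                      p=0.001, min_size=10)
print(f"bank: {bank.n_models} voxel models")
print(f"p=0.001 threshold: {threshold:.3f}")
for r in records:
    overlap = (labels == r.label)[gt.lesion_mask].sum()
    print(f"cluster rank {r.rank}: size {r.size}, min score {r.min_score:.3f}, "
          f"lesion overlap {overlap} voxels")
```

Output:

```
bank: 10672 voxel models
p=0.001 threshold: -0.387
cluster rank 1: size 31, min score -0.624, lesion overlap 10 voxels
```

The bank holds one one-class SVM per valid brain voxel.  The threshold is
the score below which a healthy voxel would fall with probability 0.001
under the normative distribution; the reported cluster overlaps one of the
two inserted 2 mm lesions (the small `min_size` suits the 33-voxel lesions
of this small example — the clinical default of 82 voxels targets 1 mm³
whole-brain data).

The same workflow is available from the shell:

```bash
epicad phantom --n 20 --out cohort/
epicad model-train --cohort cohort/ --nu 0.03 --sigma 4 --out bank.npz
epicad calibrate --cohort cohort/ --nu 0.03 --sigma 4 --out dist.json
epicad model-score --bank bank.npz --t1 sub_T1.nii.gz --gm sub_gm.nii.gz \
    --wm sub_wm.nii.gz --csf sub_csf.nii.gz --out score.nii.gz
epicad detect --score score.nii.gz --dist dist.json --mask cohort/mask.nii.gz \
    --p 0.001 --out detections/
```

## Layout

| module | contents |
|---|---|
| `epicad.volumes` | `Volume`/`AnalysisMask`/`TissueStats`, NIfTI I/O, Gaussian smoothing |
| `epicad.phantom` | synthetic cohort generator + segmentation-like posteriors |
| `epicad.features` | junction/extension maps, templates, z-scores, feature fields |
| `epicad.lesions` | blurred-junction and heterotopion simulators, simulation design |
| `epicad.ocsvm` | per-voxel one-class SVM bank (SMO dual solver), LOO FPR, tuning |
| `epicad.calibration` | normative distribution, KDE thresholds, 26-connected clusters |
| `epicad.evaluation` | pooled ROC, TPR@FPR, BC bootstrap CIs, t-map/conjunction baseline |
| `epicad.pipeline` | glue: cohort → features → bank → calibrated detections |
| `epicad.experiments` | seeded end-to-end phantom experiments |
| `epicad.cli` | `epicad` command-line tool |

See `docs/methods.md` for the full model description, numerical choices and
limitations.
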