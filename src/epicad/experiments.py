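"""Reproducible phantom experiments exercising the whole CAD pipeline.

Each experiment regenerates its inputs from a seed, runs the pipeline and
returns summary metrics: the training ν-property audit, the held-out type-I
calibration of the normative threshold, the method comparison on simulated
heterotopia, and the end-to-end detection of a simulated blurred-junction
lesion.  The problem sizes (grid, cohort size, test-subject count) are the
package's desk-scale study conditions; see the methods note for rationale.
"""

from __future__ import annotations

import numpy as np

from . import calibration, evaluation, lesions, ocsvm, pipeline
from .features import FeatureVectorField
from .phantom import PhantomSpec, TissueProbMaps, generate_phantom, tissue_posteriors
from .volumes import Volume

__all__ = [
    "nu_property_audit",
    "type1_calibration",
    "heterotopia_method_comparison",
    "blurred_junction_detection",
]

NDB1_NU = 0.03
NDB1_SIGMA = 4.0
#: Index offset of test subjects so they never collide with a training cohort.
_TEST_OFFSET = 500


def _resegment(modified: Volume, spec: PhantomSpec, subject_index: int
               ) -> TissueProbMaps:
    post = tissue_posteriors(modified.data, spec, subject_index)
    return TissueProbMaps(gm=Volume(post["gm"], spacing=spec.spacing),
                          wm=Volume(post["wm"], spacing=spec.spacing),
                          csf=Volume(post["csf"], spacing=spec.spacing))


def nu_property_audit(seed: int, n_subjects: int = 37, n_voxels: int = 1500,
                      nu: float = NDB1_NU, sigma: float = NDB1_SIGMA,
                      shape=(24, 24, 24)) -> dict:
    """Mean training-outlier fraction of a per-voxel bank over sampled voxels.

    Trains one model per sampled valid voxel on an ``n_subjects`` phantom
    cohort and scores the training cohort itself; the ν-property bounds the
    fraction of training subjects with negative signed distance by ν.
    """
    spec = PhantomSpec(shape=tuple(shape), seed=int(seed))
    cohort = pipeline.generate_phantom_cohort(spec, n_subjects)
    templates, fields, _ = pipeline.build_cohort_features(cohort)
    rng = np.random.default_rng([int(seed), 101])
    n_voxels = min(int(n_voxels), fields[0].n_voxels)
    idx = np.sort(rng.choice(fields[0].n_voxels, size=n_voxels, replace=False))
    sub_mask = np.zeros(templates.valid_mask.data.shape, bool)
    sub_mask[tuple(np.argwhere(templates.valid_mask.data)[idx].T)] = True
    sub_fields = [FeatureVectorField(values=f.values[idx], mask=sub_mask)
                  for f in fields]
    bank = ocsvm.train_bank(sub_fields, nu=nu, sigma=sigma)
    frac = ocsvm.training_outlier_fraction(bank, sub_fields)
    return {"outlier_fraction": float(frac), "n_voxels": n_voxels,
            "nu": nu, "slack": 1.0 / n_subjects}


def type1_calibration(seed: int, p: float = 0.001, n_cohort: int = 20,
                      n_test: int = 10, nu: float = NDB1_NU,
                      sigma: float = NDB1_SIGMA, shape=(32, 32, 32)) -> dict:
    """Empirical held-out voxel FPR of the normative threshold at level ``p``.

    Runs the fully held-out leave-one-out normative procedure on an
    ``n_cohort`` phantom cohort, derives the KDE threshold at ``p``, then
    scores ``n_test`` freshly generated healthy subjects against the bank
    trained on the full cohort and counts the voxels below the threshold.
    """
    spec = PhantomSpec(shape=tuple(shape), seed=int(seed))
    cohort = pipeline.generate_phantom_cohort(spec, n_cohort)
    templates, fields, _ = pipeline.build_cohort_features(cohort)
    bank = ocsvm.train_bank(fields, nu=nu, sigma=sigma)
    loo = pipeline.loo_normative_scores_refit(cohort, nu, sigma)
    dist = calibration.normative_distribution(loo)
    threshold = calibration.threshold_for_pvalue(dist, p)
    decisions = []
    for i in range(n_test):
        t1, probs, _ = generate_phantom(spec, _TEST_OFFSET + 500 + i)
        field = pipeline.features_for_subject(t1, probs, templates)
        decisions.append(ocsvm.score_subject(bank, field).scores <= threshold)
    decisions = np.concatenate(decisions)
    return {"fpr": float(decisions.mean()), "n_decisions": int(decisions.size),
            "threshold": float(threshold), "p": p}


def _lesioned_heterotopia_subject(spec: PhantomSpec, subject_index: int,
                                  lesion_seed: int, n_locations: int = 6,
                                  radius_mm: float = 2.0):
    t1, probs, _ = generate_phantom(spec, subject_index)
    stats = pipeline.subject_tissue_stats(t1, probs)
    centre_mm = (np.asarray(spec.shape) - 1) / 2.0 * np.asarray(spec.spacing)
    centres = [centre_mm + np.asarray(s.center_offset_mm)
               for s in lesions.default_simulation_design(1, n_locations)
               if s.kind == "heterotopion"]
    gt = lesions.simulate_heterotopia(t1, centres, stats, radius_mm=radius_mm,
                                      seed=lesion_seed)
    return gt, _resegment(gt.modified_t1, spec, subject_index)


def heterotopia_method_comparison(seed: int, n_controls: int = 37,
                                  n_test_subjects: int = 5,
                                  nu: float = NDB1_NU, sigma: float = NDB1_SIGMA,
                                  shape=(32, 32, 32)) -> dict:
    """Pooled voxel AUCs of the one-class bank vs the mass-univariate baselines.

    Simulates the heterotopion design (6 shared locations per test subject)
    on ``n_test_subjects`` fresh subjects and evaluates the pooled ROC of the
    one-class SVM suspicion map against the per-feature t-maps and their
    minimum-statistic conjunction.
    """
    spec = PhantomSpec(shape=tuple(shape), seed=int(seed))
    cohort = pipeline.generate_phantom_cohort(spec, n_controls)
    templates, fields, maps = pipeline.build_cohort_features(cohort)
    bank = ocsvm.train_bank(fields, nu=nu, sigma=sigma)
    valid = templates.valid_mask
    control_junction = [m.junction for m in maps]
    control_extension = [m.extension for m in maps]
    susp = {"ocsvm": [], "t_junction": [], "t_extension": [], "conjunction": []}
    truths = []
    for i in range(n_test_subjects):
        sub = _TEST_OFFSET + i
        gt, probs = _lesioned_heterotopia_subject(spec, sub, int(seed) * 100 + i)
        field = pipeline.features_for_subject(gt.modified_t1, probs, templates)
        smap = ocsvm.score_subject(bank, field)
        susp["ocsvm"].append(Volume(evaluation.suspicion_from_scores(smap)))
        lesion_maps = pipeline.subject_feature_maps(gt.modified_t1, probs)
        tj = evaluation.univariate_tmap(lesion_maps.junction, control_junction, valid)
        te = evaluation.univariate_tmap(lesion_maps.extension, control_extension, valid)
        susp["t_junction"].append(tj)
        susp["t_extension"].append(te)
        susp["conjunction"].append(evaluation.conjunction_map(tj, te))
        truths.append(gt.lesion_mask)
    return {name: evaluation.roc_curve(vols, truths, valid).auc
            for name, vols in susp.items()}


def blurred_junction_detection(seed: int, n_controls: int = 37,
                               p: float = 0.001, min_size: int = 82,
                               nu: float = NDB1_NU, sigma: float = NDB1_SIGMA,
                               shape=(32, 32, 32)) -> dict:
    """End-to-end detection of one simulated blurred-junction lesion.

    Calibrates the normative threshold at ``p`` on an ``n_controls`` cohort,
    inserts a blurred-junction lesion in a fresh subject (U-shaped ROI drawn
    on the subject's own GM/WM interface), and reports whether a
    size-filtered detected cluster overlaps the ground-truth mask.
    """
    spec = PhantomSpec(shape=tuple(shape), seed=int(seed))
    cohort = pipeline.generate_phantom_cohort(spec, n_controls)
    templates, fields, _ = pipeline.build_cohort_features(cohort)
    bank = ocsvm.train_bank(fields, nu=nu, sigma=sigma)
    loo = pipeline.loo_normative_scores_refit(cohort, nu, sigma)
    dist = calibration.normative_distribution(loo)
    t1, probs, _ = generate_phantom(spec, _TEST_OFFSET)
    stats = pipeline.subject_tissue_stats(t1, probs)
    roi = pipeline.interface_u_roi(probs, spec.spacing)
    gt = lesions.simulate_blurred_junction(t1, roi, stats)
    probs2 = _resegment(gt.modified_t1, spec, _TEST_OFFSET)
    field = pipeline.features_for_subject(gt.modified_t1, probs2, templates)
    smap = ocsvm.score_subject(bank, field)
    threshold, labels, records = pipeline.detect_clusters(smap, dist, p=p,
                                                          min_size=min_size)
    hit = any((labels == r.label)[gt.lesion_mask].any() for r in records)
    return {"hit": bool(hit), "threshold": float(threshold),
            "n_clusters": len(records),
            "lesion_voxels": int(gt.lesion_mask.sum())}
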