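"""High-level glue: phantom cohorts -> features -> model bank -> detections.

These helpers wire the stage modules together the way the CAD system runs
end to end; the command-line interface and the evaluation experiments are
thin layers over them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import calibration, features, ocsvm
from .features import FeatureMaps, FeatureVectorField, Templates
from .lesions import make_u_shaped_roi
from .phantom import PhantomSpec, TissueProbMaps, generate_phantom
from .volumes import AnalysisMask, TissueStats, Volume, tissue_stats

__all__ = [
    "Cohort",
    "generate_phantom_cohort",
    "subject_tissue_stats",
    "subject_feature_maps",
    "build_cohort_features",
    "features_for_subject",
    "detect_clusters",
]


@dataclass
class Cohort:
    """A control cohort: T1 volumes, tissue maps and the shared analysis mask."""

    t1s: list[Volume]
    probs: list[TissueProbMaps]
    mask: AnalysisMask

    def __len__(self) -> int:
        return len(self.t1s)


def generate_phantom_cohort(spec: PhantomSpec, n: int,
                            start_index: int = 0) -> Cohort:
    """Generate ``n`` phantom subjects starting at ``start_index``.

    A non-zero ``start_index`` yields subjects independent of (and disjoint
    from) the cohort drawn at index 0, e.g. fresh healthy test subjects.
    """
    if n < 2 and start_index == 0:
        raise ValueError("a cohort needs at least 2 subjects")
    t1s, probs, mask = [], [], None
    for i in range(int(start_index), int(start_index) + int(n)):
        vol, pr, mask = generate_phantom(spec, i)
        t1s.append(vol)
        probs.append(pr)
    return Cohort(t1s=t1s, probs=probs, mask=mask)


def subject_tissue_stats(t1: Volume, probs: TissueProbMaps,
                         p_threshold: float = 0.5) -> TissueStats:
    """Grey-level statistics from the subject's own tissue probability maps."""
    gm = probs.gm.data > p_threshold
    wm = probs.wm.data > p_threshold
    return tissue_stats(t1, AnalysisMask(gm), AnalysisMask(wm))


def subject_feature_maps(t1: Volume, probs: TissueProbMaps,
                         fwhm_mm: float = features.DEFAULT_FWHM_MM) -> FeatureMaps:
    """Junction and extension maps of one subject (own tissue statistics)."""
    stats = subject_tissue_stats(t1, probs)
    return FeatureMaps(
        junction=features.junction_map(t1, stats, fwhm_mm),
        extension=features.extension_map(probs.gm, fwhm_mm),
    )


def build_cohort_features(cohort: Cohort,
                          fwhm_mm: float = features.DEFAULT_FWHM_MM,
                          sd_floor: float = features.DEFAULT_SD_FLOOR,
                          ) -> tuple[Templates, list[FeatureVectorField], list[FeatureMaps]]:
    """Feature maps, templates and per-subject Z-score feature fields of a cohort."""
    maps = [subject_feature_maps(t1, pr, fwhm_mm)
            for t1, pr in zip(cohort.t1s, cohort.probs)]
    templates = features.build_templates(maps, sd_floor=sd_floor, mask=cohort.mask)
    fields = [_field_from_maps(m, templates) for m in maps]
    return templates, fields, maps


def _field_from_maps(maps: FeatureMaps, templates: Templates) -> FeatureVectorField:
    valid = templates.valid_mask
    jz = features.zscore_map(maps.junction, templates.mean_junction,
                             templates.sd_junction, valid)
    ez = features.zscore_map(maps.extension, templates.mean_extension,
                             templates.sd_extension, valid)
    return features.assemble_features(jz, ez, valid)


def features_for_subject(t1: Volume, probs: TissueProbMaps, templates: Templates,
                         fwhm_mm: float = features.DEFAULT_FWHM_MM
                         ) -> FeatureVectorField:
    """Feature field of a (test) subject against existing cohort templates."""
    return _field_from_maps(subject_feature_maps(t1, probs, fwhm_mm), templates)


def loo_normative_scores_refit(cohort: Cohort, nu: float, sigma: float,
                               fwhm_mm: float = features.DEFAULT_FWHM_MM,
                               sd_floor: float = features.DEFAULT_SD_FLOOR,
                               ) -> list[ocsvm.ScoreMap]:
    """Fully held-out normative score maps: templates *and* bank refit per fold.

    For each subject, mean/SD templates are rebuilt from the other n - 1
    subjects before z-scoring and model training, so the held-out subject
    contributes nothing to its own normative score.  Keeping the templates
    fixed instead shrinks held-out z-scores and inflates the type-I error of
    the calibrated threshold severalfold.
    """
    maps = [subject_feature_maps(t1, pr, fwhm_mm)
            for t1, pr in zip(cohort.t1s, cohort.probs)]
    if len(maps) < 3:
        raise ValueError("leave-one-out needs at least 3 subjects")
    mask = cohort.mask.data
    X = np.stack([np.stack([m.junction.data[mask], m.extension.data[mask]], axis=-1)
                  for m in maps])  # (n, V, 2) raw feature maps
    scores = np.full(X.shape[:2], np.nan)
    for start in range(0, X.shape[1], 4096):
        sl = slice(start, min(start + 4096, X.shape[1]))
        scores[:, sl] = ocsvm._loo_refit_scores(
            np.ascontiguousarray(X[:, sl, :]), sd_floor, nu, sigma, 1e-10, 200_000)
    out = []
    for s in range(len(maps)):
        data = np.full(mask.shape, np.nan)
        data[mask] = scores[s]
        fold_mask = mask & np.isfinite(data)
        out.append(ocsvm.ScoreMap(data=data, mask=fold_mask))
    return out


def interface_u_roi(probs: TissueProbMaps, spacing, n_slices: int = 6,
                    arm_extent_mm: float = 16.0, arm_width_mm: float = 5.0,
                    ) -> np.ndarray:
    """U-shaped ROI whose base straddles the subject's own GM/WM interface.

    Mirrors drawing the ROI on the subject's image around the grey matter at
    the bottom of a sulcus: the interface position is located on the
    subject's WM probability map along the -y ray through the volume centre,
    and the U base is centred on it.
    """
    shape = probs.wm.shape
    cx, _, cz = (int(s) // 2 for s in shape)
    column = probs.wm.data[cx, :, cz]
    above = np.flatnonzero(column > 0.5)
    if above.size == 0:
        raise ValueError("no WM interface found along the -y ray")
    y_interface = int(above.min())
    half = arm_extent_mm / 2.0
    cy = int(round(y_interface + half - arm_width_mm / 2.0))
    return make_u_shaped_roi(shape, spacing, (cx, cy, cz), n_slices=n_slices,
                             arm_extent_mm=arm_extent_mm,
                             arm_width_mm=arm_width_mm)


def detect_clusters(score_map: ocsvm.ScoreMap,
                    dist: calibration.NormativeDistribution,
                    p: float = calibration.DEFAULT_P_VALUE,
                    min_size: int = calibration.DEFAULT_MIN_CLUSTER_SIZE,
                    ) -> tuple[float, np.ndarray, list[calibration.ClusterRecord]]:
    """Threshold a score map at the p-value, cluster and rank the detections."""
    threshold = calibration.threshold_for_pvalue(dist, p)
    labels = calibration.label_clusters(score_map, threshold)
    records = calibration.rank_clusters(labels, score_map, min_size=min_size)
    return threshold, labels, records
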