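"""Voxel-level ROC evaluation, bootstrap confidence intervals, and a
mass-univariate baseline.

Evaluation consumes *suspicion* values oriented so that higher means more
suspicious: negate one-class SVM signed distances
(:func:`suspicion_from_scores`) and use t statistics as-is for the baseline.
Confidence intervals use the bias-corrected (BC) percentile bootstrap with
patient-level resampling: each replicate redraws subjects with replacement
and concatenates their voxel scores into a global vector.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri
from sklearn import metrics as _skm

from .ocsvm import ScoreMap
from .volumes import AnalysisMask, Volume

__all__ = [
    "RocResult",
    "BootstrapCI",
    "suspicion_from_scores",
    "roc_curve",
    "tpr_at_fpr",
    "bootstrap_auc_ci",
    "bootstrap_auc_diff_ci",
    "univariate_tmap",
    "conjunction_map",
    "mip",
]


@dataclass
class RocResult:
    """Pooled voxel-level ROC curve with its AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


@dataclass
class BootstrapCI:
    """Bias-corrected percentile bootstrap interval."""

    point_estimate: float
    lower: float
    upper: float
    n_boot: int
    method: str = "bias-corrected percentile"
    seed: int | None = None


def _data(x) -> np.ndarray:
    if isinstance(x, Volume):
        return x.data
    if isinstance(x, ScoreMap):
        return x.data
    return np.asarray(x, dtype=np.float64)


def _bool(x) -> np.ndarray:
    if isinstance(x, AnalysisMask):
        return x.data
    if isinstance(x, Volume):
        return x.data.astype(bool)
    return np.asarray(x).astype(bool)


def suspicion_from_scores(score_map: ScoreMap) -> np.ndarray:
    """Negated signed distances: higher = more suspicious."""
    return -score_map.data


def _pool(suspicion_maps, truth_masks, valid) -> tuple[np.ndarray, np.ndarray]:
    if len(suspicion_maps) == 0 or len(suspicion_maps) != len(truth_masks):
        raise ValueError("need matched, non-empty suspicion and truth lists")
    vm = _bool(valid)
    ys, ss = [], []
    for smap, tmask in zip(suspicion_maps, truth_masks):
        s = _data(smap)
        t = _bool(tmask)
        if s.shape != vm.shape or t.shape != vm.shape:
            raise ValueError("suspicion/truth/valid shapes mismatch")
        sv = s[vm]
        tv = t[vm]
        finite = np.isfinite(sv)  # voxels excluded upstream carry non-finite values
        ys.append(tv[finite])
        ss.append(sv[finite])
    return np.concatenate(ys), np.concatenate(ss)


def _roc_from_vectors(y: np.ndarray, s: np.ndarray) -> RocResult:
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both positive and negative voxels")
    fpr, tpr, _ = _skm.roc_curve(y, s)
    return RocResult(fpr=fpr, tpr=tpr, auc=float(_skm.roc_auc_score(y, s)),
                     n_pos=n_pos, n_neg=n_neg)


def roc_curve(suspicion_maps, truth_masks, valid) -> RocResult:
    """Pooled voxel-level ROC over all subjects, full threshold sweep."""
    y, s = _pool(suspicion_maps, truth_masks, valid)
    return _roc_from_vectors(y, s)


def tpr_at_fpr(roc: RocResult, fpr_targets=(0.01, 0.05, 0.1)) -> list[float]:
    """TPR at fixed FPR targets (conservative step interpolation).

    Returns the largest achieved TPR among operating points with
    FPR <= target.
    """
    out = []
    for t in fpr_targets:
        if not 0.0 < t < 1.0:
            raise ValueError("FPR targets must lie in (0, 1)")
        ok = roc.fpr <= t
        out.append(float(roc.tpr[ok].max()) if ok.any() else 0.0)
    return out


def _auc_or_nan(y: np.ndarray, s: np.ndarray) -> float:
    if y.all() or not y.any():
        return np.nan
    return float(_skm.roc_auc_score(y, s))


def _resamples(n_subjects: int, n_boot: int, seed, exhaustive: bool):
    if exhaustive:
        return list(itertools.product(range(n_subjects), repeat=n_subjects))
    rng = np.random.default_rng(seed)
    return [tuple(rng.integers(0, n_subjects, size=n_subjects))
            for _ in range(int(n_boot))]


def _bc_interval(boot: np.ndarray, point: float, level: float = 0.95
                 ) -> tuple[float, float]:
    """Bias-corrected percentile interval (z0 correction, no acceleration)."""
    boot = boot[np.isfinite(boot)]
    if boot.size == 0:
        raise ValueError("no valid bootstrap replicates")
    if np.ptp(boot) < 1e-12:
        return point, point
    frac = np.mean(boot < point)
    frac = float(np.clip(frac, 0.5 / boot.size, 1.0 - 0.5 / boot.size))
    z0 = ndtri(frac)
    alpha = 1.0 - level
    lo_q = ndtr(2.0 * z0 + ndtri(alpha / 2.0))
    hi_q = ndtr(2.0 * z0 + ndtri(1.0 - alpha / 2.0))
    return float(np.quantile(boot, lo_q)), float(np.quantile(boot, hi_q))


def _check_paired(per_subject_scores, per_subject_truths):
    if len(per_subject_scores) != len(per_subject_truths):
        raise ValueError("scores/truths subject mismatch")
    if len(per_subject_scores) < 2:
        raise ValueError("bootstrap needs at least 2 subjects")
    scores = [np.asarray(s, dtype=np.float64).ravel() for s in per_subject_scores]
    truths = [np.asarray(t).astype(bool).ravel() for t in per_subject_truths]
    for s, t in zip(scores, truths):
        if s.shape != t.shape:
            raise ValueError("per-subject score/truth length mismatch")
    return scores, truths


def bootstrap_auc_ci(per_subject_scores, per_subject_truths, n_boot: int = 120,
                     seed: int = 0, exhaustive: bool = False) -> BootstrapCI:
    """Patient-level bootstrap CI (95%, bias-corrected percentile) of the pooled AUC.

    Replicates redraw subjects with replacement, concatenate the selected
    subjects' voxel suspicion vectors, and recompute the AUC.  With
    ``exhaustive=True`` all n^n resamples are enumerated instead of sampled.
    """
    scores, truths = _check_paired(per_subject_scores, per_subject_truths)
    n = len(scores)
    point = _auc_or_nan(np.concatenate(truths), np.concatenate(scores))
    boot = []
    for pick in _resamples(n, n_boot, seed, exhaustive):
        y = np.concatenate([truths[i] for i in pick])
        s = np.concatenate([scores[i] for i in pick])
        boot.append(_auc_or_nan(y, s))
    boot = np.asarray(boot)
    lo, hi = _bc_interval(boot, point)
    return BootstrapCI(point_estimate=point, lower=lo, upper=hi,
                       n_boot=len(boot), seed=seed)


def bootstrap_auc_diff_ci(scores_a, scores_b, truths, n_boot: int = 120,
                          seed: int = 0, exhaustive: bool = False) -> BootstrapCI:
    """BC percentile CI of AUC_a - AUC_b with paired patient-level resampling."""
    sa, ta = _check_paired(scores_a, truths)
    sb, tb = _check_paired(scores_b, truths)
    if len(sa) != len(sb):
        raise ValueError("the two methods must cover the same subjects")
    n = len(sa)
    y_all = np.concatenate(ta)
    point = _auc_or_nan(y_all, np.concatenate(sa)) - _auc_or_nan(y_all, np.concatenate(sb))
    boot = []
    for pick in _resamples(n, n_boot, seed, exhaustive):
        y = np.concatenate([ta[i] for i in pick])
        a = _auc_or_nan(y, np.concatenate([sa[i] for i in pick]))
        b = _auc_or_nan(y, np.concatenate([sb[i] for i in pick]))
        boot.append(a - b)
    boot = np.asarray(boot)
    lo, hi = _bc_interval(boot, point)
    return BootstrapCI(point_estimate=point, lower=lo, upper=hi,
                       n_boot=len(boot), seed=seed)


def univariate_tmap(patient_map: Volume, control_maps: list[Volume],
                    valid: AnalysisMask) -> Volume:
    """Per-voxel t statistic of one patient observation against the controls.

    ``t = (x_p - mean_c) / (sd_c * sqrt(1 + 1/n_c))`` with the sample SD
    (ddof = 1) of the controls; degrees of freedom are ``n_c - 1``.  Voxels
    with zero control variance, and voxels outside the valid mask, carry NaN
    and are excluded downstream.
    """
    if len(control_maps) < 3:
        raise ValueError("need at least 3 control maps")
    vm = _bool(valid)
    if patient_map.shape != vm.shape:
        raise ValueError("shape mismatch")
    stack = np.stack([_data(c) for c in control_maps])
    if stack.shape[1:] != vm.shape:
        raise ValueError("control map shape mismatch")
    n_c = stack.shape[0]
    mean_c = stack.mean(axis=0)[vm]
    sd_c = stack.std(axis=0, ddof=1)[vm]
    x_p = patient_map.data[vm]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (x_p - mean_c) / (sd_c * np.sqrt(1.0 + 1.0 / n_c))
    t[sd_c <= 0] = np.nan
    out = np.full(vm.shape, np.nan)
    out[vm] = t
    return patient_map.copy(data=out, id=f"{patient_map.id}|tmap")


def conjunction_map(tmap_junction: Volume, tmap_extension: Volume) -> Volume:
    """Minimum-statistic conjunction (global null) of two t maps."""
    if tmap_junction.shape != tmap_extension.shape:
        raise ValueError("shape mismatch")
    return tmap_junction.copy(
        data=np.minimum(tmap_junction.data, tmap_extension.data),
        id="conjunction")


def mip(vol: Volume, axis: int = 2) -> np.ndarray:
    """Maximum-intensity projection of a volume along one axis (display plumbing)."""
    data = np.where(np.isfinite(vol.data), vol.data, -np.inf)
    out = data.max(axis=axis)
    return np.where(np.isfinite(out), out, 0.0)
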