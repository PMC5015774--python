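"""Score calibration and cluster detection.

The normative distribution of one-class SVM scores in healthy tissue is built
by a leave-one-out procedure over the control cohort: per voxel, a model is
trained on n - 1 subjects and scores the held-out subject, yielding one score
map per subject.  Per-subject histograms on a shared bin grid are averaged,
and a Gaussian kernel density estimate over the pooled scores converts any
p-value into a score threshold (left tail: the more negative the score, the
more suspicious the voxel).  Thresholded maps are decomposed into
26-connected clusters, ranked by their minimum (most pathological) score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.special import ndtr

from .features import FeatureVectorField
from .ocsvm import ScoreMap, _check_hyper, _loo_stats, _stack_fields

__all__ = [
    "NormativeDistribution",
    "ClusterRecord",
    "loo_normative_scores",
    "normative_distribution",
    "threshold_for_pvalue",
    "label_clusters",
    "rank_clusters",
    "clusters_to_table",
]

DEFAULT_P_VALUE = 0.001
DEFAULT_MIN_CLUSTER_SIZE = 82
_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class NormativeDistribution:
    """Averaged LOO score histogram plus a KDE with quantile lookup."""

    bin_edges: np.ndarray
    mean_counts: np.ndarray   # averaged per-subject densities on the bin grid
    grid: np.ndarray          # evaluation grid of the KDE
    density: np.ndarray       # KDE density on the grid
    cdf: np.ndarray           # KDE CDF on the grid
    bandwidth: float
    n_scores: int = 0

    def quantile_fn(self, p: float) -> float:
        """Score threshold with left-tail KDE mass ``p`` (monotone in p)."""
        if not 0.0 < p < 1.0:
            raise ValueError("p must be in (0, 1)")
        # strictly increasing CDF for interpolation; tail plateaus get a
        # negligible ramp so the inverse stays well defined
        cdf = np.maximum.accumulate(self.cdf) + np.arange(self.cdf.size) * 1e-15
        return float(np.interp(p, cdf, self.grid))


def loo_normative_scores(cohort_features: list[FeatureVectorField], nu: float,
                         sigma: float) -> list[ScoreMap]:
    """One held-out score map per control subject (leave-one-out retraining)."""
    _check_hyper(nu, sigma)
    F, mask = _stack_fields(cohort_features)
    if F.shape[0] < 3:
        raise ValueError("leave-one-out needs at least 3 subjects")
    scores, _ = _loo_stats(F, nu, sigma)
    maps = []
    for s in range(F.shape[0]):
        data = np.full(mask.shape, np.nan)
        data[mask] = scores[s]
        maps.append(ScoreMap(data=data, mask=mask.copy()))
    return maps


def _silverman_bandwidth(x: np.ndarray) -> float:
    sd = x.std()
    q75, q25 = np.percentile(x, [75, 25])
    spread = min(sd, (q75 - q25) / 1.34) if q75 > q25 else sd
    h = 0.9 * spread * x.size ** (-0.2)
    if h <= 0:
        h = max(1e-3 * max(abs(float(x.mean())), 1.0), 1e-12)
    return float(h)


def _kde_on_grid(pooled: np.ndarray, weights: np.ndarray, grid: np.ndarray,
                 h: float) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-KDE pdf and CDF on a grid, exact to double precision.

    Kernel contributions beyond 8 bandwidths are 0 (left) or 1 (right) to
    machine accuracy, so only scores inside a +/- 8h window of each grid
    point need explicit evaluation; points left of the window contribute
    their total weight to the CDF via a prefix sum.
    """
    order = np.argsort(pooled)
    xs = pooled[order]
    ws = weights[order]
    wcum = np.concatenate([[0.0], np.cumsum(ws)])
    cut = 8.0 * h
    inv = 1.0 / h
    norm = inv / np.sqrt(2.0 * np.pi)
    lo_idx = np.searchsorted(xs, grid - cut, side="left")
    hi_idx = np.searchsorted(xs, grid + cut, side="right")
    pdf = np.empty(grid.size)
    cdf = np.empty(grid.size)
    for g in range(grid.size):
        i0, i1 = lo_idx[g], hi_idx[g]
        z = (grid[g] - xs[i0:i1]) * inv
        w = ws[i0:i1]
        pdf[g] = (np.exp(-0.5 * z**2) @ w) * norm
        cdf[g] = wcum[i0] + ndtr(z) @ w
    return pdf, cdf


def normative_distribution(score_maps: list[ScoreMap],
                           n_bins: int = 512) -> NormativeDistribution:
    """Averaged per-subject score histograms plus a Gaussian KDE.

    Histograms share one bin grid spanning the pooled score range with a 5%
    margin and are density-normalized before averaging (so cohort size does
    not rescale the distribution).  The KDE uses a Silverman bandwidth on the
    pooled scores with equal per-map weighting.
    """
    if len(score_maps) < 2:
        raise ValueError("need at least 2 score maps")
    per_map = [sm.scores for sm in score_maps]
    if any(s.size == 0 for s in per_map):
        raise ValueError("empty score map")
    pooled = np.concatenate(per_map)
    lo, hi = pooled.min(), pooled.max()
    pad = 0.05 * (hi - lo) if hi > lo else max(0.05 * abs(hi), 1e-6)
    edges = np.linspace(lo - pad, hi + pad, n_bins + 1)
    hists = [np.histogram(s, bins=edges, density=True)[0] for s in per_map]
    mean_counts = np.mean(hists, axis=0)

    weights = np.concatenate(
        [np.full(s.size, 1.0 / (len(per_map) * s.size)) for s in per_map])
    h = _silverman_bandwidth(pooled)
    grid = np.linspace(lo - 4.0 * h - pad, hi + 4.0 * h + pad, 2048)
    pdf, cdf = _kde_on_grid(pooled, weights, grid, h)
    return NormativeDistribution(
        bin_edges=edges, mean_counts=mean_counts, grid=grid, density=pdf,
        cdf=cdf, bandwidth=h, n_scores=pooled.size,
    )


def threshold_for_pvalue(dist: NormativeDistribution, p: float) -> float:
    """Score threshold whose left-tail mass under the KDE equals ``p``."""
    return dist.quantile_fn(p)


def label_clusters(score_map: ScoreMap, threshold: float) -> np.ndarray:
    """26-connected components of the suprathreshold set (score <= threshold).

    Labels are assigned in lexicographic (C-order scan) discovery order,
    starting at 1; 0 is background.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    binary = np.zeros(score_map.data.shape, dtype=bool)
    binary[score_map.mask] = score_map.data[score_map.mask] <= threshold
    raw, n = ndi.label(binary, structure=_CONNECTIVITY_26)
    if n == 0:
        return raw
    # enforce lexicographic discovery order of labels
    flat = raw.ravel()
    labels, first = np.unique(flat, return_index=True)
    keep = labels > 0
    order = np.argsort(first[keep])
    remap = np.zeros(n + 1, dtype=raw.dtype)
    remap[labels[keep][order]] = np.arange(1, keep.sum() + 1)
    return remap[raw]


@dataclass
class ClusterRecord:
    """One suprathreshold 26-connected component with its score statistics."""

    label: int
    size: int
    min_score: float
    max_score: float
    mean_score: float
    rank: int
    voxel_list: np.ndarray = field(repr=False, default=None)


def rank_clusters(labels: np.ndarray, score_map: ScoreMap,
                  min_size: int = DEFAULT_MIN_CLUSTER_SIZE) -> list[ClusterRecord]:
    """Filter clusters by size and rank them by minimum score.

    Clusters must be *strictly larger* than ``min_size`` voxels to survive.
    Survivors are ordered by ascending minimum score (most pathological
    first); ties go to the larger cluster, then to the lowest lexicographic
    seed voxel.
    """
    n = int(labels.max())
    entries = []
    for lab in range(1, n + 1):
        where = labels == lab
        size = int(where.sum())
        if size <= int(min_size):
            continue
        vals = score_map.data[where]
        seed = int(np.flatnonzero(where.ravel())[0])
        entries.append((float(vals.min()), -size, seed, lab, vals, where))
    entries.sort(key=lambda e: e[:3])
    records = []
    for rank, (mn, negsize, seed, lab, vals, where) in enumerate(entries, start=1):
        records.append(ClusterRecord(
            label=lab, size=-negsize, min_score=mn,
            max_score=float(vals.max()), mean_score=float(vals.mean()),
            rank=rank, voxel_list=np.argwhere(where),
        ))
    return records


def clusters_to_table(records: list[ClusterRecord],
                      spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
                      ) -> pd.DataFrame:
    """Cluster report: label, size, score statistics, rank and centroids."""
    rows = []
    for r in records:
        centroid = r.voxel_list.mean(axis=0)
        rows.append({
            "label": r.label, "size": r.size, "min_score": r.min_score,
            "max_score": r.max_score, "mean_score": r.mean_score,
            "rank": r.rank,
            "centroid_x": centroid[0], "centroid_y": centroid[1],
            "centroid_z": centroid[2],
            "centroid_x_mm": centroid[0] * spacing[0],
            "centroid_y_mm": centroid[1] * spacing[1],
            "centroid_z_mm": centroid[2] * spacing[2],
        })
    return pd.DataFrame(rows)
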