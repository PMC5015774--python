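"""Parametric feature maps: extension, junction, cohort templates and Z-scores.

Two maps describe each subject.  The *extension map* is the Gaussian-smoothed
GM probability map and highlights abnormal extension of grey matter into the
white matter.  The *junction map* is the smoothed binary indicator of voxels
whose grey value falls inside the GM/WM interface interval
``[t_low, t_high]`` and highlights blurring of the GM/WM junction.  Each map
is converted to a Z-score against cohort mean/SD templates, and the two
Z-scores at a voxel form its feature vector (p = 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import AnalysisMask, TissueStats, Volume, gaussian_smooth

__all__ = [
    "FeatureMaps",
    "Templates",
    "FeatureVectorField",
    "extension_map",
    "junction_map",
    "build_templates",
    "zscore_map",
    "assemble_features",
]

DEFAULT_FWHM_MM = 6.0
DEFAULT_SD_FLOOR = 1e-6


@dataclass
class FeatureMaps:
    """The two per-subject parametric maps, both valued in [0, 1]."""

    junction: Volume
    extension: Volume

    def __post_init__(self) -> None:
        if self.junction.shape != self.extension.shape:
            raise ValueError("junction/extension shape mismatch")
        for vol in (self.junction, self.extension):
            if vol.data.min() < -1e-6 or vol.data.max() > 1 + 1e-6:
                raise ValueError("feature map values outside [0, 1]")


@dataclass
class Templates:
    """Cohort mean/SD templates per feature and the valid-voxel mask.

    ``valid_mask`` excludes voxels whose SD template falls below the floor on
    either feature; those voxels are dropped from all downstream analysis
    (rather than clamped) to avoid infinite Z-scores.
    """

    mean_junction: Volume
    sd_junction: Volume
    mean_extension: Volume
    sd_extension: Volume
    valid_mask: AnalysisMask
    n_subjects: int = 0


@dataclass
class FeatureVectorField:
    """Per-voxel feature vectors (junction_z, extension_z) over the valid mask."""

    values: np.ndarray  # (n_valid, 2)
    mask: np.ndarray    # 3D bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2 or self.values.shape[1] != 2:
            raise ValueError("feature vectors must be (n_valid, 2)")
        if self.values.shape[0] != int(self.mask.sum()):
            raise ValueError("vector count does not match valid mask")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite feature values on the valid mask")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]


def extension_map(gm_prob: Volume, fwhm_mm: float = DEFAULT_FWHM_MM) -> Volume:
    """Smoothed GM probability map (extension of GM into WM)."""
    if gm_prob.data.min() < -1e-6 or gm_prob.data.max() > 1 + 1e-6:
        raise ValueError("GM probabilities outside [0, 1]")
    out = gaussian_smooth(gm_prob, fwhm_mm)
    out.id = f"{gm_prob.id}|extension"
    return out


def junction_map(t1: Volume, stats: TissueStats,
                 fwhm_mm: float = DEFAULT_FWHM_MM) -> Volume:
    """Smoothed binary indicator of grey values in ``[t_low, t_high]``.

    The binarization interval is closed on both ends.
    """
    binary = (t1.data >= stats.t_low) & (t1.data <= stats.t_high)
    vol = Volume(binary.astype(np.float64), spacing=t1.spacing,
                 affine=t1.affine, id=f"{t1.id}|junction-binary")
    out = gaussian_smooth(vol, fwhm_mm)
    out.id = f"{t1.id}|junction"
    return out


def _stack(maps: list[FeatureMaps], attr: str) -> np.ndarray:
    shapes = {getattr(m, attr).shape for m in maps}
    if len(shapes) != 1:
        raise ValueError("cohort maps have mismatching shapes")
    return np.stack([getattr(m, attr).data for m in maps])


def build_templates(cohort_maps: list[FeatureMaps],
                    sd_floor: float = DEFAULT_SD_FLOOR,
                    mask: AnalysisMask | None = None) -> Templates:
    """Voxelwise mean and population-SD templates over a control cohort.

    Voxels whose SD is below ``sd_floor`` on either feature (or outside the
    analysis ``mask``, when given) are excluded from ``valid_mask``.
    """
    if len(cohort_maps) < 2:
        raise ValueError("template building needs at least 2 subjects")
    ref = cohort_maps[0].junction
    junc = _stack(cohort_maps, "junction")
    ext = _stack(cohort_maps, "extension")
    mean_j, sd_j = junc.mean(axis=0), junc.std(axis=0)
    mean_e, sd_e = ext.mean(axis=0), ext.std(axis=0)
    valid = (sd_j >= sd_floor) & (sd_e >= sd_floor)
    if mask is not None:
        if mask.data.shape != ref.shape:
            raise ValueError("analysis mask shape mismatch")
        valid &= mask.data
    if not valid.any():
        raise ValueError("no valid voxels: SD template below floor everywhere")

    def _vol(data: np.ndarray, tag: str) -> Volume:
        return Volume(data, spacing=ref.spacing, affine=ref.affine, id=tag)

    return Templates(
        mean_junction=_vol(mean_j, "mean-junction"),
        sd_junction=_vol(sd_j, "sd-junction"),
        mean_extension=_vol(mean_e, "mean-extension"),
        sd_extension=_vol(sd_e, "sd-extension"),
        valid_mask=AnalysisMask(valid),
        n_subjects=len(cohort_maps),
    )


def zscore_map(subject_map: Volume, mean_t: Volume, sd_t: Volume,
               valid: AnalysisMask, background: float = 0.0) -> Volume:
    """Z-score of a subject map against the cohort templates.

    ``(subject - mean) / SD`` on valid voxels; excluded voxels carry the
    designated ``background`` value.
    """
    if not (subject_map.shape == mean_t.shape == sd_t.shape == valid.data.shape):
        raise ValueError("shape mismatch between map, templates and mask")
    out = np.full(subject_map.shape, float(background))
    m = valid.data
    out[m] = (subject_map.data[m] - mean_t.data[m]) / sd_t.data[m]
    return subject_map.copy(data=out, id=f"{subject_map.id}|z")


def assemble_features(junction_z: Volume, extension_z: Volume,
                      valid: AnalysisMask) -> FeatureVectorField:
    """Pack the two Z-score maps into per-voxel (junction_z, extension_z) vectors."""
    if junction_z.shape != extension_z.shape or junction_z.shape != valid.data.shape:
        raise ValueError("shape mismatch between z-maps and mask")
    m = valid.data
    values = np.column_stack([junction_z.data[m], extension_z.data[m]])
    return FeatureVectorField(values=values, mask=m.copy())
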