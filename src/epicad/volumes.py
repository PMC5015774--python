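"""Volume containers, NIfTI I/O, Gaussian smoothing and tissue grey-level statistics.

All images in the pipeline are 3D scalar grids assumed to live in a common
(spatially normalized) space.  A :class:`Volume` carries the voxel data, the
per-axis voxel size in mm and the voxel-to-world affine; an
:class:`AnalysisMask` restricts every cohort-level computation to brain
voxels; :class:`TissueStats` holds the grey-level statistics of the GM and WM
classes together with the derived junction interval
``[t_low, t_high] = [mean_GM + SD_GM/2, mean_WM - SD_WM/2]``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "FWHM_TO_SIGMA",
    "Volume",
    "AnalysisMask",
    "TissueStats",
    "read_volume",
    "write_volume",
    "gaussian_smooth",
    "mask_volume",
    "tissue_stats",
]

#: Conversion factor from full-width-at-half-maximum to standard deviation of
#: a Gaussian, 1 / (2 sqrt(2 ln 2)).
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing and voxel-to-world affine."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None
    id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("non-3D image")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be three positive lengths")
        if self.affine is None:
            self.affine = np.diag((*self.spacing, 1.0))
        else:
            self.affine = np.asarray(self.affine, dtype=np.float64)
            if self.affine.shape != (4, 4):
                raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self, data: np.ndarray | None = None, id: str | None = None) -> "Volume":
        return Volume(
            data=self.data.copy() if data is None else np.asarray(data),
            spacing=self.spacing,
            affine=self.affine.copy(),
            id=self.id if id is None else id,
        )

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """Map (k, 3) voxel indices to world mm coordinates via the affine."""
        idx = np.atleast_2d(np.asarray(indices, dtype=np.float64))
        hom = np.c_[idx, np.ones(len(idx))]
        return (hom @ self.affine.T)[:, :3]


@dataclass
class AnalysisMask:
    """Binary analysis mask restricting all voxelwise computations."""

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError("non-3D mask")
        if arr.dtype != bool:
            vals = np.unique(arr)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("mask is not strictly binary")
            arr = arr.astype(bool)
        if not arr.any():
            raise ValueError("mask is empty")
        self.data = arr

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class TissueStats:
    """Grey-level statistics of the GM and WM classes and junction thresholds.

    ``t_low = mean_gm + sd_gm / 2`` and ``t_high = mean_wm - sd_wm / 2`` bound
    the grey-value interval of voxels at the GM/WM interface.
    """

    mean_gm: float
    sd_gm: float
    mean_wm: float
    sd_wm: float
    t_low: float = field(init=False)
    t_high: float = field(init=False)

    def __post_init__(self) -> None:
        if self.sd_gm < 0 or self.sd_wm < 0:
            raise ValueError("standard deviations must be non-negative")
        if not self.mean_wm > self.mean_gm:
            raise ValueError("mean_wm must exceed mean_gm")
        self.t_low = float(self.mean_gm + self.sd_gm / 2.0)
        self.t_high = float(self.mean_wm - self.sd_wm / 2.0)
        if not self.t_low < self.t_high:
            raise ValueError(
                f"invalid junction range: t_low={self.t_low} >= t_high={self.t_high}"
            )


def read_volume(path: str | os.PathLike) -> Volume:
    """Read a NIfTI-1 (.nii / .nii.gz) file into a :class:`Volume`."""
    if not os.path.exists(path):
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError("non-3D image")
    data = np.asanyarray(img.dataobj).astype(np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data=data, spacing=spacing, affine=np.asarray(img.affine),
                  id=os.path.basename(str(path)))


def write_volume(vol: Volume, path: str | os.PathLike) -> None:
    """Write a :class:`Volume` as NIfTI-1 with spacing and affine in the header."""
    img = nib.Nifti1Image(vol.data.astype(np.float64), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def _mask_data(mask: AnalysisMask | np.ndarray) -> np.ndarray:
    if isinstance(mask, AnalysisMask):
        return mask.data
    return AnalysisMask(np.asarray(mask)).data


def gaussian_smooth(vol: Volume, fwhm_mm: float) -> Volume:
    """Separable Gaussian smoothing with kernel width given as FWHM in mm.

    The per-axis standard deviation in voxels is
    ``fwhm_mm * FWHM_TO_SIGMA / spacing``.  Boundaries are handled by
    renormalized zero-padded convolution (the zero-padded smoothed image
    divided by the zero-padded smoothed ones volume), so a constant volume is
    reproduced exactly and the operation stays linear per voxel.
    """
    if not fwhm_mm > 0:
        raise ValueError("fwhm_mm must be positive")
    if not np.isfinite(vol.data).all():
        raise ValueError("volume contains non-finite values")
    sigma = [fwhm_mm * FWHM_TO_SIGMA / s for s in vol.spacing]
    num = ndi.gaussian_filter(vol.data, sigma=sigma, mode="constant", cval=0.0)
    den = ndi.gaussian_filter(np.ones(vol.shape), sigma=sigma, mode="constant", cval=0.0)
    return vol.copy(data=num / den, id=f"{vol.id}|smooth{fwhm_mm}mm")


def mask_volume(vol: Volume, mask: AnalysisMask | np.ndarray,
                background: float = 0.0) -> Volume:
    """Set voxels outside ``mask`` to ``background``."""
    m = _mask_data(mask)
    if m.shape != vol.shape:
        raise ValueError("mask shape does not match volume shape")
    out = np.full(vol.shape, float(background))
    out[m] = vol.data[m]
    return vol.copy(data=out, id=f"{vol.id}|masked")


def tissue_stats(t1: Volume, gm_mask: AnalysisMask | np.ndarray,
                 wm_mask: AnalysisMask | np.ndarray) -> TissueStats:
    """Per-class grey-level mean and population SD, and junction thresholds.

    ``gm_mask``/``wm_mask`` must be non-empty, disjoint and match the volume
    shape.  The SD convention is the population SD (divide by N), used
    consistently across the package.
    """
    gm = _mask_data(gm_mask)
    wm = _mask_data(wm_mask)
    if gm.shape != t1.shape or wm.shape != t1.shape:
        raise ValueError("mask shape does not match volume shape")
    if (gm & wm).any():
        raise ValueError("GM and WM masks overlap")
    g = t1.data[gm]
    w = t1.data[wm]
    return TissueStats(
        mean_gm=float(g.mean()), sd_gm=float(g.std()),
        mean_wm=float(w.mean()), sd_wm=float(w.std()),
    )
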