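"""Realistic lesion simulators with voxel-level ground truth.

Two typical epileptogenic abnormalities are inserted into T1-like volumes:

* *blurred junction* (FCD-like): inside a U-shaped ROI at the GM/WM
  interface, voxels whose grey value lies in the junction interval
  ``[t_low, t_high]`` are replaced by the in-plane disk-mean of the original
  image, locally blurring the junction;
* *heterotopion-like*: small spheres deep in the WM whose voxels are replaced
  by independent draws from the junction interval, emulating grey matter
  nodules in the white matter.

Both emit a :class:`LesionGroundTruth` pairing the modified volume with the
binary mask of altered voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .volumes import TissueStats, Volume

__all__ = [
    "LesionGroundTruth",
    "SimLesionSpec",
    "make_u_shaped_roi",
    "simulate_blurred_junction",
    "simulate_heterotopia",
    "default_simulation_design",
]


@dataclass
class LesionGroundTruth:
    """A modified volume plus the binary mask of the altered voxels."""

    modified_t1: Volume
    lesion_mask: np.ndarray  # 3D bool
    lesion_type: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lesion_mask = np.asarray(self.lesion_mask, dtype=bool)
        if self.lesion_mask.shape != self.modified_t1.shape:
            raise ValueError("lesion mask shape mismatch")
        if not self.lesion_mask.any():
            raise ValueError("empty lesion mask")


@dataclass(frozen=True)
class SimLesionSpec:
    """One simulated lesion of the evaluation design.

    ``center_offset_mm`` is a world-mm offset from the volume centre (the
    phantom cohort shares one space, so locations are shared across subjects).
    """

    kind: str  # "heterotopion" | "blurred_junction"
    subject_index: int
    location_index: int
    center_offset_mm: tuple[float, float, float]
    radius_mm: float = 2.0


def _disk_footprint(radius_mm: float, spacing: tuple[float, float, float]) -> np.ndarray:
    """In-plane (x, y) disk of lattice points with centre distance <= radius."""
    nx = int(np.floor(radius_mm / spacing[0]))
    ny = int(np.floor(radius_mm / spacing[1]))
    dx = np.arange(-nx, nx + 1)[:, None] * spacing[0]
    dy = np.arange(-ny, ny + 1)[None, :] * spacing[1]
    return (dx**2 + dy**2) <= radius_mm**2 + 1e-12


def disk_mean_filter(vol: Volume, radius_mm: float = 3.0) -> Volume:
    """Slice-wise (in-plane) mean filter over a disk of the given radius.

    The mean at each voxel is over the in-bounds disk points only (boundary
    neighbourhoods are renormalized).
    """
    foot = _disk_footprint(radius_mm, vol.spacing)[:, :, None].astype(np.float64)
    num = ndi.convolve(vol.data, foot, mode="constant", cval=0.0)
    den = ndi.convolve(np.ones(vol.shape), foot, mode="constant", cval=0.0)
    return vol.copy(data=num / den, id=f"{vol.id}|diskmean{radius_mm}mm")


def make_u_shaped_roi(shape: tuple[int, int, int],
                      spacing: tuple[float, float, float],
                      center_voxel: tuple[int, int, int],
                      n_slices: int = 6,
                      arm_extent_mm: float = 8.0,
                      arm_width_mm: float = 3.0) -> np.ndarray:
    """U-shaped 2D footprint replicated over consecutive slices along z.

    The footprint is a square ring of half-extent ``arm_extent_mm / 2`` and
    band width ``arm_width_mm`` with one side removed (the opening of the U).
    """
    cx, cy, cz = (int(c) for c in center_voxel)
    half = arm_extent_mm / 2.0
    w = arm_width_mm
    x = (np.arange(shape[0]) - cx)[:, None] * spacing[0]
    y = (np.arange(shape[1]) - cy)[None, :] * spacing[1]
    outer = (np.abs(x) <= half) & (np.abs(y) <= half)
    inner = (np.abs(x) <= half - w) & (np.abs(y) <= half - w)
    footprint = outer & ~inner & ~(y >= half - w)  # remove +y side -> open U
    if not footprint.any():
        raise ValueError("degenerate U footprint (arm width/extent too small)")
    z0 = cz - n_slices // 2
    z1 = z0 + n_slices
    rx = half / spacing[0]
    ry = half / spacing[1]
    if (z0 < 0 or z1 > shape[2] or cx - rx < 0 or cx + rx > shape[0] - 1
            or cy - ry < 0 or cy + ry > shape[1] - 1):
        raise ValueError("ROI does not fit inside the grid")
    roi = np.zeros(shape, dtype=bool)
    roi[:, :, z0:z1] = footprint[:, :, None]
    return roi


def simulate_blurred_junction(t1: Volume, roi_mask: np.ndarray,
                              stats: TissueStats,
                              disk_radius_mm: float = 3.0) -> LesionGroundTruth:
    """Blur the GM/WM junction inside a ROI.

    Voxels are altered iff they lie inside ``roi_mask`` *and* their original
    grey value lies in ``[t_low, t_high]``; the new values are the in-plane
    disk-mean of the original image at those voxels.
    """
    roi = np.asarray(roi_mask, dtype=bool)
    if roi.shape != t1.shape:
        raise ValueError("ROI shape mismatch")
    if not roi.any():
        raise ValueError("empty ROI")
    in_range = (t1.data >= stats.t_low) & (t1.data <= stats.t_high)
    lesion = roi & in_range
    if not lesion.any():
        raise ValueError("no ROI voxels inside the junction interval; empty lesion")
    blurred = disk_mean_filter(t1, disk_radius_mm)
    modified = t1.data.copy()
    modified[lesion] = blurred.data[lesion]
    return LesionGroundTruth(
        modified_t1=t1.copy(data=modified, id=f"{t1.id}|blurred-junction"),
        lesion_mask=lesion,
        lesion_type="blurred_junction",
        provenance={"disk_radius_mm": disk_radius_mm,
                    "roi_voxels": int(roi.sum()),
                    "t_low": stats.t_low, "t_high": stats.t_high},
    )


def simulate_heterotopia(t1: Volume, centers_world_mm, stats: TissueStats,
                         radius_mm: float = 2.0, seed: int = 0) -> LesionGroundTruth:
    """Insert heterotopion-like spheres with grey values drawn from the junction interval.

    Sphere membership uses the world-mm distance from the voxel centre to the
    lesion centre (inclusive at the radius).  Voxel values inside the union of
    spheres are replaced by independent uniform draws from
    ``[t_low, t_high]``; the draw order is the flat C-order of the union mask,
    so the result is deterministic for a given ``seed``.
    """
    centers = np.atleast_2d(np.asarray(centers_world_mm, dtype=np.float64))
    if centers.shape[1] != 3:
        raise ValueError("centers must be (k, 3) world-mm coordinates")
    idx = np.indices(t1.shape).reshape(3, -1).T
    world = t1.world_coords(idx)
    union = np.zeros(t1.shape, dtype=bool)
    overlap = np.zeros(t1.shape, dtype=np.int32)
    inv = np.linalg.inv(t1.affine)
    for c in centers:
        vox = (inv @ np.r_[c, 1.0])[:3]
        if ((vox < -0.5) | (vox > np.asarray(t1.shape) - 0.5)).any():
            raise ValueError(f"lesion center {c} outside the grid")
        d2 = ((world - c) ** 2).sum(axis=1).reshape(t1.shape)
        sphere = d2 <= radius_mm**2 + 1e-12
        union |= sphere
        overlap += sphere
    overlapping = bool((overlap > 1).any())
    if overlapping:
        warnings.warn("heterotopion spheres overlap", stacklevel=2)
    rng = np.random.default_rng(int(seed))
    modified = t1.data.copy()
    modified[union] = rng.uniform(stats.t_low, stats.t_high, size=int(union.sum()))
    return LesionGroundTruth(
        modified_t1=t1.copy(data=modified, id=f"{t1.id}|heterotopia"),
        lesion_mask=union,
        lesion_type="heterotopion",
        provenance={"radius_mm": radius_mm, "seed": int(seed),
                    "n_centers": len(centers), "overlapping": overlapping,
                    "t_low": stats.t_low, "t_high": stats.t_high},
    )


def _fibonacci_directions(k: int) -> np.ndarray:
    """k roughly uniform unit vectors on the sphere (deterministic layout)."""
    i = np.arange(k) + 0.5
    phi = np.arccos(1 - 2 * i / k)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def default_simulation_design(n_subjects: int = 5, n_locations: int = 6,
                              ring_radius_mm: float = 4.5,
                              radius_mm: float = 2.0) -> list[SimLesionSpec]:
    """The evaluation design: shared heterotopion locations plus one junction lesion per subject.

    Each of ``n_subjects`` subjects receives ``n_locations`` heterotopion-like
    lesions at locations shared across subjects (world-mm offsets from the
    volume centre on a deterministic spherical layout of radius
    ``ring_radius_mm``, deep in the WM of the default phantom), and one
    blurred-junction lesion (offset at the GM ribbon).  Defaults yield
    ``5 x 6 = 30`` heterotopia and 5 junction lesions.
    """
    dirs = _fibonacci_directions(max(int(n_locations), 1))
    centers = [tuple(float(v) for v in ring_radius_mm * d) for d in dirs]
    specs: list[SimLesionSpec] = []
    for s in range(int(n_subjects)):
        for loc, c in enumerate(centers[: int(n_locations)]):
            specs.append(SimLesionSpec(kind="heterotopion", subject_index=s,
                                       location_index=loc, center_offset_mm=c,
                                       radius_mm=radius_mm))
        specs.append(SimLesionSpec(kind="blurred_junction", subject_index=s,
                                   location_index=0,
                                   center_offset_mm=(0.0, 0.0, 0.0),
                                   radius_mm=0.0))
    return specs
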