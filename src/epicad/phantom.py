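"""Synthetic healthy-control cohorts: T1-like phantoms with tissue probability maps.

The phantom emulates a spatially normalized brain: a white-matter core wrapped
by a folded grey-matter ribbon, a thin CSF rim, and empty background.  Subjects share
the nominal geometry (as spatially normalized data would) up to a small
per-subject smooth deformation of the tissue interfaces (residual anatomy /
registration variability); further between-subject variability enters through
a multiplicative intensity (gain) factor and per-voxel noise.  Tissue
probability maps are derived from the noisy image through a
segmentation-like posterior, as a real segmentation would produce them.  Phantom cohorts stand in for real healthy
control databases when exercising the feature extraction, model-bank and
calibration stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage as ndi

from .volumes import AnalysisMask, Volume

__all__ = [
    "PhantomSpec",
    "subject_priors",
    "TissueProbMaps",
    "analysis_mask",
    "tissue_posteriors",
    "generate_phantom",
    "generate_cohort",
]

# Normalized radii of the tissue interfaces (fraction of the half grid size).
_R_WM = 0.58
_R_GM = 0.80
_R_BRAIN = 0.88
# Smoothing (voxels) of the hard tissue indicators into prior probabilities,
# emulating partial volume at interfaces.
_PRIOR_SIGMA = 0.7
# Within-brain dispersion of the tissue priors (probabilistic-atlas floor):
# real tissue probability atlases keep every class possible everywhere in the
# brain, which lets image intensity move the posterior (e.g. grey matter
# appearing deep in the white matter).
_PRIOR_FLOOR = 0.2


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic cohort generator.

    Grey-level means/SDs are in arbitrary image units; ``subject_intensity_sd``
    is the SD of the per-subject multiplicative intensity factor;
    ``fold_frequency`` controls the spatial frequency of the sinusoidal
    folding of the GM/WM interface (sulci/gyri analogues).
    """

    shape: tuple[int, int, int] = (32, 32, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mean_gm: float = 100.0
    mean_wm: float = 140.0
    mean_csf: float = 40.0
    sd_gm: float = 10.0
    sd_wm: float = 10.0
    sd_csf: float = 10.0
    subject_intensity_sd: float = 0.05
    fold_frequency: float = 3.0
    fold_amplitude: float = 0.12
    shape_jitter: float = 0.04
    jitter_smooth_vox: float = 3.0
    noise_model: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 16 for s in self.shape):
            raise ValueError("shape components must be >= 16")
        if not self.mean_wm > self.mean_gm:
            raise ValueError("mean_wm must exceed mean_gm")
        if min(self.sd_gm, self.sd_wm, self.sd_csf) < 0 or self.subject_intensity_sd < 0:
            raise ValueError("SDs must be non-negative")
        if self.shape_jitter < 0:
            raise ValueError("shape_jitter must be non-negative")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")


@dataclass
class TissueProbMaps:
    """Per-voxel GM/WM/CSF class probabilities (simplex: sum <= 1)."""

    gm: Volume
    wm: Volume
    csf: Volume

    def __post_init__(self) -> None:
        total = self.gm.data + self.wm.data + self.csf.data
        for vol in (self.gm, self.wm, self.csf):
            if vol.data.min() < -1e-6 or vol.data.max() > 1 + 1e-6:
                raise ValueError("tissue probabilities outside [0, 1]")
        if total.max() > 1 + 1e-6:
            raise ValueError("tissue probabilities exceed the unit simplex")


@lru_cache(maxsize=8)
def _base_radius(shape: tuple[int, ...], fold_frequency: float,
                 fold_amplitude: float) -> np.ndarray:
    """Nominal folded radial coordinate of the tissue interfaces."""
    axes = [(np.arange(s) - (s - 1) / 2.0) / ((s - 1) / 2.0) for s in shape]
    ux, uy, uz = np.meshgrid(*axes, indexing="ij")
    rho = np.sqrt(ux**2 + uy**2 + uz**2)
    f = np.pi * fold_frequency
    fold = fold_amplitude * np.sin(f * ux) * np.sin(f * uy) * np.cos(f * uz)
    return rho + fold


def _priors_from_rr(rr: np.ndarray, floor: float) -> dict[str, np.ndarray]:
    wm = rr < _R_WM
    gm = (rr >= _R_WM) & (rr < _R_GM)
    csf = (rr >= _R_GM) & (rr < _R_BRAIN)
    bg = rr >= _R_BRAIN
    priors = [ndi.gaussian_filter(ind.astype(np.float64), _PRIOR_SIGMA)
              for ind in (gm, wm, csf, bg)]
    stack = np.stack(priors)
    stack /= stack.sum(axis=0, keepdims=True)
    if floor > 0:
        brain = 1.0 - stack[3]
        for c in range(3):  # mix each brain class with a flat within-brain prior
            stack[c] = (1.0 - floor) * stack[c] + floor * brain / 3.0
        stack[3] = 1.0 - stack[:3].sum(axis=0)
    return {"gm": stack[0], "wm": stack[1], "csf": stack[2], "bg": stack[3]}


def _subject_rr(spec: PhantomSpec, subject_index: int) -> np.ndarray:
    """Folded radial coordinate of one subject (nominal geometry + jitter).

    The jitter is a per-subject smooth Gaussian random field displacing the
    tissue interfaces (unit-variance field smoothed over
    ``jitter_smooth_vox`` voxels, scaled by ``shape_jitter`` in normalized
    radius units), emulating residual anatomical/registration variability
    after spatial normalization.  Drawn from a dedicated stream
    ``default_rng([seed, subject_index, 1])``.
    """
    rr = _base_radius(tuple(spec.shape), spec.fold_frequency, spec.fold_amplitude)
    if spec.shape_jitter > 0:
        rng = np.random.default_rng([int(spec.seed), int(subject_index), 1])
        g = ndi.gaussian_filter(rng.standard_normal(spec.shape),
                                spec.jitter_smooth_vox, mode="wrap")
        rr = rr + spec.shape_jitter * (g / g.std())
    return rr


@lru_cache(maxsize=64)
def _subject_pv(spec: PhantomSpec, subject_index: int) -> dict[str, np.ndarray]:
    """Partial-volume tissue weights used to synthesize intensities (no floor)."""
    return _priors_from_rr(_subject_rr(spec, subject_index), 0.0)


@lru_cache(maxsize=64)
def subject_priors(spec: PhantomSpec, subject_index: int) -> dict[str, np.ndarray]:
    """Segmentation priors of one subject (atlas-like within-brain floor)."""
    return _priors_from_rr(_subject_rr(spec, subject_index), _PRIOR_FLOOR)


def analysis_mask(spec: PhantomSpec) -> AnalysisMask:
    """Brain mask (nominal GM + WM + CSF region) shared by all subjects."""
    rr = _base_radius(tuple(spec.shape), spec.fold_frequency, spec.fold_amplitude)
    return AnalysisMask(rr < _R_BRAIN)


def tissue_posteriors(t1_data: np.ndarray, spec: PhantomSpec,
                      subject_index: int = 0, n_iter: int = 10) -> dict[str, np.ndarray]:
    """Segmentation-like class posteriors of a T1 volume given the phantom priors.

    A small EM on the Gaussian mixture with fixed spatial priors: class
    means/SDs are re-estimated from posterior-weighted image moments until
    (near) convergence, so the posteriors adapt to per-subject intensity
    scaling and to any inserted lesion, like a real unified segmentation.
    """
    priors = subject_priors(spec, int(subject_index))
    t1_data = np.asarray(t1_data, dtype=np.float64)
    names = list(priors)
    weights = {n: priors[n] for n in names}
    post = None
    for _ in range(max(int(n_iter), 1)):
        like = {}
        for n in names:
            w = weights[n]
            wsum = w.sum()
            if wsum <= 0:
                like[n] = np.zeros_like(t1_data)
                continue
            mu = float((w * t1_data).sum() / wsum)
            sd = float(np.sqrt((w * (t1_data - mu) ** 2).sum() / wsum))
            sd = max(sd, 1e-6)
            like[n] = np.exp(-0.5 * ((t1_data - mu) / sd) ** 2) / sd
        raw = {n: priors[n] * like[n] for n in names}
        denom = sum(raw.values())
        degenerate = denom < 1e-300
        safe = np.where(degenerate, 1.0, denom)
        post = {n: np.where(degenerate, priors[n], raw[n] / safe) for n in names}
        weights = post
    return {n: np.clip(post[n], 0.0, 1.0) for n in ("gm", "wm", "csf")}


def generate_phantom(spec: PhantomSpec, subject_index: int
                     ) -> tuple[Volume, TissueProbMaps, AnalysisMask]:
    """Generate one subject: T1-like volume, tissue probability maps, brain mask.

    Deterministic for a fixed ``(spec.seed, subject_index)`` pair: each subject
    draws from an independent stream derived from the root seed by the
    counter scheme ``default_rng([seed, subject_index])``.
    """
    priors = _subject_pv(spec, int(subject_index))
    mask = analysis_mask(spec).data
    rng = np.random.default_rng([int(spec.seed), int(subject_index), 0])
    scale = 1.0 + spec.subject_intensity_sd * rng.standard_normal()
    means = {"gm": spec.mean_gm, "wm": spec.mean_wm, "csf": spec.mean_csf, "bg": 0.0}
    sds = {"gm": spec.sd_gm, "wm": spec.sd_wm, "csf": spec.sd_csf, "bg": spec.sd_csf}
    noiseless = sum(means[c] * priors[c] for c in priors)
    sd_map = np.sqrt(sum(sds[c] ** 2 * priors[c] for c in priors))
    # the subject factor acts as a receiver gain: it scales signal and noise
    # together (image units are arbitrary; within-subject SNR is set by the
    # class SDs, not by the gain)
    if spec.noise_model == "gaussian":
        t1 = scale * (noiseless + sd_map * rng.standard_normal(spec.shape))
    else:  # rician: magnitude of a complex signal with Gaussian channel noise
        n1 = rng.standard_normal(spec.shape)
        n2 = rng.standard_normal(spec.shape)
        t1 = scale * np.sqrt((noiseless + sd_map * n1) ** 2 + (sd_map * n2) ** 2)
    sid = f"phantom-s{spec.seed}-{subject_index:03d}"
    vol = Volume(t1, spacing=spec.spacing, id=sid)
    post = tissue_posteriors(t1, spec, subject_index)
    probs = TissueProbMaps(
        gm=Volume(post["gm"], spacing=spec.spacing, id=sid + "-gm"),
        wm=Volume(post["wm"], spacing=spec.spacing, id=sid + "-wm"),
        csf=Volume(post["csf"], spacing=spec.spacing, id=sid + "-csf"),
    )
    return vol, probs, AnalysisMask(mask.copy())


def generate_cohort(spec: PhantomSpec, n: int) -> list[tuple[Volume, TissueProbMaps]]:
    """Generate ``n`` subjects sharing geometry up to per-subject variability."""
    if n < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    out = []
    for i in range(int(n)):
        vol, probs, _ = generate_phantom(spec, i)
        out.append((vol, probs))
    return out
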