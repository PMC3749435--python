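"""Spatial operations: Gaussian smoothing, brain masking, ventricle masking.

Ventricles are estimated from the temporal-mean image: CSF is bright on
T2*-weighted EPI, so thresholding the mean image followed by morphological
cleanup isolates the central bright connected component(s).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core_io import BoldSeries, MaskSet

__all__ = [
    "smooth_gaussian",
    "apply_brain_mask",
    "estimate_ventricles",
    "vm_stage",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def smooth_gaussian(bold: BoldSeries, fwhm_mm: float) -> BoldSeries:
    """Convolve each volume with an isotropic Gaussian of the given FWHM.

    The kernel standard deviation is ``fwhm_mm / (2 sqrt(2 ln 2))``,
    expressed in voxels per axis via the voxel size.  ``fwhm_mm = 0`` is
    the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return bold.with_data(bold.data.copy())
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / v for v in bold.voxel_size_mm]
    out = ndimage.gaussian_filter(bold.data, sigma=sigma_vox + [0.0],
                                  mode="constant", cval=0.0)
    return bold.with_data(out)


def apply_brain_mask(bold: BoldSeries, brain: np.ndarray) -> BoldSeries:
    """Zero all voxels outside the brain mask at every time point."""
    brain = np.asarray(brain, dtype=bool)
    if brain.shape != bold.spatial_shape:
        raise ValueError(
            f"mask shape {brain.shape} != spatial shape {bold.spatial_shape}")
    if not brain.any():
        raise ValueError("empty mask")
    out = bold.data * brain[..., None]
    return bold.with_data(out)


def estimate_ventricles(bold: BoldSeries, brain: np.ndarray,
                        threshold_k: float = 2.0,
                        min_size_voxels: int = 20) -> np.ndarray:
    """Segment the ventricles from the temporal-mean image.

    Steps: (1) threshold the mean image at ``mean + threshold_k * SD`` of
    the in-brain intensities; (2) one-voxel binary opening to remove
    speckles; (3) hole filling; (4) keep 6-connected components of at
    least ``min_size_voxels`` voxels whose centroid falls inside the
    central 50% bounding box of the brain mask (the ventricles are a
    central structure).  The union of surviving components is returned;
    an empty mask is a valid result (ventricle masking becomes a no-op).
    """
    brain = np.asarray(brain, dtype=bool)
    if brain.shape != bold.spatial_shape:
        raise ValueError("brain mask shape mismatch")
    if not brain.any():
        raise ValueError("empty brain mask")
    mean_vol = bold.data.mean(axis=3)
    vals = mean_vol[brain]
    thr = vals.mean() + threshold_k * vals.std()
    bright = (mean_vol > thr) & brain

    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    opened = ndimage.binary_opening(bright, structure=structure)
    filled = ndimage.binary_fill_holes(opened, structure=structure)

    labels, n = ndimage.label(filled, structure=structure)
    if n == 0:
        return np.zeros_like(brain)

    # central 50% bounding box of the brain mask
    idx = np.nonzero(brain)
    lo = np.array([a.min() for a in idx], dtype=float)
    hi = np.array([a.max() for a in idx], dtype=float)
    center = (lo + hi) / 2.0
    half = (hi - lo) / 4.0  # half of the 50% box

    out = np.zeros_like(brain)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    centroids = ndimage.center_of_mass(filled, labels, range(1, n + 1))
    for lab, size, com in zip(range(1, n + 1), sizes, centroids):
        if size < min_size_voxels:
            continue
        if np.all(np.abs(np.asarray(com) - center) <= half):
            out |= labels == lab
    return out


def vm_stage(bold: BoldSeries, masks: MaskSet) -> BoldSeries:
    """Zero ventricle voxels across time (ventricle masking).

    Callers must also exclude the ventricle voxels from any downstream
    parenchyma averaging; the pipeline handles this by shrinking the
    parenchyma mask.
    """
    vent = masks.ventricles
    if vent.shape != bold.spatial_shape:
        raise ValueError("ventricle mask shape mismatch")
    if not vent.any():
        return bold.with_data(bold.data.copy())
    out = bold.data * (~vent)[..., None]
    return bold.with_data(out)
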