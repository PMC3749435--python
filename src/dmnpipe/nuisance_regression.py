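"""Nuisance regression: motion parameters (MPR) and global signal (GSR).

Both stages project voxel time courses onto the orthogonal complement of a
design containing an intercept plus the nuisance regressors, keeping the
least-squares residual.  The intercept is always included: the pipeline
regresses raw intensity time courses, and omitting it would bias the
residuals.

Note that removing the global parenchymal mean can induce artifactual
anti-correlations between regions that were previously uncorrelated; this
is a documented (and tested) property of the operation, not a bug.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core_io import BoldSeries, MotionParams

__all__ = ["regress_out", "mpr_stage", "global_signal", "gsr_stage"]


def _build_design(n: int, regressors: np.ndarray) -> np.ndarray:
    """Intercept plus regressors; linearly dependent columns are dropped.

    Raises if no informative regressor column survives.
    """
    regressors = np.asarray(regressors, dtype=float)
    if regressors.ndim != 2 or regressors.shape[0] != n:
        raise ValueError(
            f"regressors must be {n} x K, got {regressors.shape}")
    if regressors.shape[1] + 1 >= n:
        raise ValueError("more regressors (plus intercept) than time points")
    design = np.ones((n, 1))
    dropped = []
    for k in range(regressors.shape[1]):
        cand = np.column_stack([design, regressors[:, k]])
        if np.linalg.matrix_rank(cand) > design.shape[1]:
            design = cand
        else:
            dropped.append(k)
    if dropped:
        warnings.warn(
            f"dropping rank-deficient regressor column(s) {dropped}",
            stacklevel=3)
    if design.shape[1] == 1:
        raise ValueError("design rank-deficient: no informative regressor left")
    return design


def regress_out(series_matrix: np.ndarray, regressors: np.ndarray) -> np.ndarray:
    """Replace each row by its residual against [intercept | regressors].

    Parameters
    ----------
    series_matrix : ndarray, shape (V, T)
        One time course per row.
    regressors : ndarray, shape (T, K)

    Returns
    -------
    ndarray, shape (V, T)
        Residuals, orthogonal to every retained regressor column.
    """
    x = np.asarray(series_matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("series_matrix must be V x T")
    design = _build_design(x.shape[1], regressors)
    q, _ = np.linalg.qr(design)
    return x - (x @ q) @ q.T


def mpr_stage(bold: BoldSeries, motion: MotionParams, mask: np.ndarray,
              include_derivatives: bool = False) -> BoldSeries:
    """Regress the six rigid-body motion parameters out of in-mask voxels.

    ``include_derivatives`` optionally adds the first temporal backward
    difference of each parameter to the design (off by default: the
    pipeline's regressors are the six absolute displacements only).
    """
    if motion.n_vols != bold.n_vols:
        raise ValueError(
            f"motion rows {motion.n_vols} != volumes {bold.n_vols}")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != bold.spatial_shape:
        raise ValueError("mask shape mismatch")
    regs = motion.table
    if include_derivatives:
        deriv = np.vstack([np.zeros((1, 6)), np.diff(regs, axis=0)])
        regs = np.column_stack([regs, deriv])
    out = bold.data.copy()
    out[mask] = regress_out(bold.data[mask], regs)
    return bold.with_data(out)


def global_signal(bold: BoldSeries, parenchyma: np.ndarray) -> np.ndarray:
    """Spatial mean over the parenchyma mask at each time point."""
    parenchyma = np.asarray(parenchyma, dtype=bool)
    if parenchyma.shape != bold.spatial_shape:
        raise ValueError("parenchyma mask shape mismatch")
    if not parenchyma.any():
        raise ValueError("empty parenchyma mask")
    return bold.data[parenchyma].mean(axis=0)


def gsr_stage(bold: BoldSeries, parenchyma: np.ndarray,
              mask: np.ndarray | None = None) -> BoldSeries:
    """Regress the global parenchymal mean time course out of every voxel.

    The global signal is computed over ``parenchyma``; the regression is
    applied to ``mask`` (default: the whole volume, which leaves all-zero
    background voxels untouched).  After this stage the parenchymal mean
    time course has (numerically) zero variance.
    """
    g = global_signal(bold, parenchyma)
    scale = max(np.abs(bold.data).max(), 1.0)
    if g.std() <= 1e-12 * scale:
        # nothing left to remove (e.g. the stage already ran): identity
        return bold.with_data(bold.data.copy())
    if mask is None:
        mask = np.ones(bold.spatial_shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != bold.spatial_shape:
            raise ValueError("mask shape mismatch")
    out = bold.data.copy()
    out[mask] = regress_out(bold.data[mask], g[:, None])
    return bold.with_data(out)
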