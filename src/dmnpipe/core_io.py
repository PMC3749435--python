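"""Containers and file I/O for the preprocessing pipeline.

All volumes live on a common voxel grid; the axis convention is
spatial-first ``(x, y, z, t)``, matching the on-disk layout of 4D NIfTI.
Coordinates are 0-based voxel indices; no world-space resampling is
performed anywhere (inputs are assumed realigned and normalized upstream).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

logger = logging.getLogger("dmnpipe")

PROCEDURES = ("P1", "P2", "P3", "P4", "P5")


@dataclass
class BoldSeries:
    """A 4D BOLD time series with acquisition metadata.

    Parameters
    ----------
    data : ndarray, shape (X, Y, Z, T)
        Voxel intensities.
    voxel_size_mm : tuple of float
        Voxel edge lengths in millimetres.
    tr_s : float
        Repetition time (volume sampling interval) in seconds.
    space_tag : str
        Free-text label of the common space the series lives in.
    """

    data: np.ndarray
    voxel_size_mm: tuple
    tr_s: float
    space_tag: str = "common"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D series, got {self.data.ndim}D")
        if any(e < 1 for e in self.data.shape):
            raise ValueError(f"degenerate extents {self.data.shape}")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"invalid voxel size {self.voxel_size_mm}")
        self.tr_s = float(self.tr_s)
        if self.tr_s <= 0:
            raise ValueError(f"repetition time must be positive, got {self.tr_s}")

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def n_vols(self) -> int:
        return self.data.shape[3]

    def with_data(self, data: np.ndarray) -> "BoldSeries":
        """Return a copy carrying ``data`` with unchanged metadata."""
        return replace(self, data=data)


@dataclass
class MotionParams:
    """Six rigid-body realignment parameters per volume.

    Columns are (tx, ty, tz) in mm and (rx, ry, rz) in radians, expressed
    in absolute terms relative to the first volume, i.e. the first row is
    all zeros.  This is the usual realignment-parameter text-file dialect.
    """

    table: np.ndarray

    def __post_init__(self):
        self.table = np.asarray(self.table, dtype=float)
        if self.table.ndim != 2 or self.table.shape[1] != 6:
            raise ValueError(f"motion table must be T x 6, got {self.table.shape}")
        if not np.all(np.isfinite(self.table)):
            raise ValueError("motion table contains non-finite values")
        if not np.allclose(self.table[0], 0.0, atol=1e-12):
            raise ValueError("first motion row must be zero (relative to volume 1)")

    @property
    def n_vols(self) -> int:
        return self.table.shape[0]


@dataclass
class MaskSet:
    """Boolean volumes delimiting brain, parenchyma and ventricles.

    Invariants enforced: identical shapes, parenchyma and ventricles are
    subsets of the brain, and parenchyma is disjoint from the ventricles.
    """

    brain: np.ndarray
    parenchyma: np.ndarray
    ventricles: np.ndarray = None

    def __post_init__(self):
        self.brain = np.asarray(self.brain, dtype=bool)
        self.parenchyma = np.asarray(self.parenchyma, dtype=bool)
        if self.ventricles is None:
            self.ventricles = np.zeros_like(self.brain)
        self.ventricles = np.asarray(self.ventricles, dtype=bool)
        for name in ("parenchyma", "ventricles"):
            m = getattr(self, name)
            if m.shape != self.brain.shape:
                raise ValueError(f"{name} shape {m.shape} != brain {self.brain.shape}")
            if np.any(m & ~self.brain):
                raise ValueError(f"{name} mask is not a subset of the brain mask")
        if np.any(self.parenchyma & self.ventricles):
            raise ValueError("parenchyma and ventricle masks overlap")


@dataclass
class PipelineConfig:
    """Parameters steering the graded preprocessing chain.

    ``procedure`` selects which stages run (P1 smoothing only, through P5
    with outlier rejection and ventricle masking); the remaining fields
    parameterize individual stages.
    """

    procedure: str = "P5"
    smoothing_fwhm_mm: float = 8.0
    lowpass_f3db_hz: float = 0.1
    detrend_order: int = 3
    iqr_factor: float = 1.5
    ref_fraction: float = 0.10
    run_length_cut: int = 10
    dilation_voxels: int = 5
    z_threshold: float = 2.0
    n_components: int = 20
    seed: int = 0
    # config-exposed design choices
    motion_derivatives: bool = False
    ventricle_threshold_k: float = 2.0
    ventricle_min_size_voxels: int = 20

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.procedure not in PROCEDURES:
            raise ValueError(f"procedure must be one of {PROCEDURES}, got {self.procedure!r}")
        if self.smoothing_fwhm_mm < 0:
            raise ValueError("smoothing_fwhm_mm must be >= 0")
        if self.lowpass_f3db_hz <= 0:
            raise ValueError("lowpass_f3db_hz must be positive")
        if self.detrend_order < 0:
            raise ValueError("detrend_order must be >= 0")
        if self.iqr_factor <= 0:
            raise ValueError("iqr_factor must be positive")
        if not (0 < self.ref_fraction <= 1):
            raise ValueError("ref_fraction must be in (0, 1]")
        if self.run_length_cut < 1:
            raise ValueError("run_length_cut must be a positive integer")
        if self.dilation_voxels < 0:
            raise ValueError("dilation_voxels must be >= 0")
        if self.n_components < 1:
            raise ValueError("n_components must be a positive integer")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load a flat YAML/JSON key-value config; unknown keys are an error."""
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if doc is None:
            doc = {}
        if not isinstance(doc, dict):
            raise ValueError("config must be a flat key-value document")
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_file(self, path):
        doc = {f.name: getattr(self, f.name) for f in fields(self)}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# NIfTI I/O


def load_bold(path, tr_s: float | None = None) -> BoldSeries:
    """Read a 4D NIfTI series.

    Voxel size and TR come from the header; ``tr_s`` overrides the header
    value (some converters leave it unset).  Non-finite voxels raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"expected 4D series, got {img.ndim}D in {path}")
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"non-finite voxel values in {path}")
    zooms = img.header.get_zooms()
    header_tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    tr = float(tr_s) if tr_s is not None else header_tr
    if tr <= 0:
        raise ValueError(f"repetition time unavailable in header of {path}; pass tr_s")
    return BoldSeries(data=data, voxel_size_mm=tuple(float(z) for z in zooms[:3]), tr_s=tr)


def save_bold(bold: BoldSeries, path) -> None:
    affine = np.diag(list(bold.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(bold.data, dtype=np.float32), affine)
    img.header.set_zooms(tuple(bold.voxel_size_mm) + (bold.tr_s,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def save_bold_float64(bold: BoldSeries, path) -> None:
    """Lossless (float64) variant of :func:`save_bold` for fixtures."""
    affine = np.diag(list(bold.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(bold.data, dtype=np.float64), affine)
    img.header.set_zooms(tuple(bold.voxel_size_mm) + (bold.tr_s,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def load_mask(path, reference_shape=None) -> np.ndarray:
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"expected 3D mask, got {img.ndim}D in {path}")
    mask = np.asarray(img.get_fdata()) > 0.5
    if reference_shape is not None and mask.shape != tuple(reference_shape):
        raise ValueError(f"mask shape {mask.shape} != expected {tuple(reference_shape)}")
    return mask


def save_mask(mask: np.ndarray, voxel_size_mm, path) -> None:
    affine = np.diag(list(voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
    nib.save(img, str(path))


def load_mask_set(brain_path, parenchyma_path, ventricles_path=None,
                  reference_shape=None) -> MaskSet:
    brain = load_mask(brain_path, reference_shape)
    parenchyma = load_mask(parenchyma_path, brain.shape)
    ventricles = load_mask(ventricles_path, brain.shape) if ventricles_path else None
    return MaskSet(brain=brain, parenchyma=parenchyma, ventricles=ventricles)


# ---------------------------------------------------------------------------
# Motion-parameter text files


def load_motion(path, n_volumes: int) -> MotionParams:
    """Read a whitespace-delimited 6-column realignment-parameter file.

    The row count must equal ``n_volumes``.  If the first row is nonzero the
    whole table is shifted so displacements are relative to the first volume,
    with a warning.
    """
    try:
        table = np.loadtxt(str(path), dtype=float, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in motion file {path}: {exc}") from exc
    if table.shape[1] != 6:
        raise ValueError(f"motion file must have 6 columns, got {table.shape[1]}")
    if table.shape[0] != n_volumes:
        raise ValueError(
            f"motion file has {table.shape[0]} rows, expected {n_volumes}")
    if not np.allclose(table[0], 0.0, atol=1e-12):
        logger.warning(
            "motion file %s: first row nonzero; re-referencing to volume 1", path)
        table = table - table[0]
    return MotionParams(table=table)


def save_motion(motion: MotionParams, path) -> None:
    np.savetxt(str(path), motion.table, fmt="%.10e")


def save_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
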