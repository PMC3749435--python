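"""Realignment-outlier rejection (ROR).

Volumes contaminated by gross head movement are flagged on the residual
mean-square difference (MSD) from the temporal-mean reference volume.  The
detection is two-tier:

1. volumes whose MSD exceeds the Tukey upper fence (Q3 + 1.5 x IQR of the
   MSD trace) are *candidates*;
2. a candidate is actually rejected only if its MSD also exceeds an
   absolute reference value, set to 10% of the mean of the three
   mean-square differences obtained by displacing the reference volume by
   one voxel along each axis.  This guards against rejecting volumes in
   series that are simply very still overall.

Rejected volumes in short consecutive runs are repaired by per-voxel
linear interpolation in time between the nearest preserved volumes; runs
of at least ``run_length_cut`` (default 10) consecutive rejections are
removed from the series (and the motion table) altogether.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import BoldSeries, MotionParams, PipelineConfig, save_json

__all__ = [
    "OutlierReport",
    "residual_msd",
    "displacement_reference",
    "detect_outliers",
    "replace_or_remove",
    "ror_stage",
]


@dataclass
class OutlierReport:
    """Audit trail of the outlier-rejection stage."""

    msd_trace: np.ndarray
    reference_value: float
    fence_value: float
    candidate_idx: list
    replaced_idx: list
    removed_idx: list
    kept_time_index: dict  # output time index -> input time index

    def __post_init__(self):
        cand = set(self.candidate_idx)
        rep, rem = set(self.replaced_idx), set(self.removed_idx)
        if not (rep | rem) <= cand:
            raise ValueError("replaced/removed indices must be candidates")
        if rep & rem:
            raise ValueError("replaced and removed index sets overlap")

    def to_json(self, path) -> None:
        save_json({
            "msd_trace": np.asarray(self.msd_trace).tolist(),
            "reference_value": self.reference_value,
            "fence_value": self.fence_value,
            "candidate_idx": sorted(int(i) for i in self.candidate_idx),
            "replaced_idx": sorted(int(i) for i in self.replaced_idx),
            "removed_idx": sorted(int(i) for i in self.removed_idx),
            "kept_time_index": {int(k): int(v) for k, v in self.kept_time_index.items()},
        }, path)

    def to_table(self, path) -> None:
        """Tab-separated QC table: index, msd, candidate flag, action."""
        cand, rep, rem = map(set, (self.candidate_idx, self.replaced_idx, self.removed_idx))
        with open(path, "w") as fh:
            fh.write("index\tmsd\tcandidate\taction\n")
            for t, v in enumerate(np.asarray(self.msd_trace)):
                action = "removed" if t in rem else "replaced" if t in rep else "kept"
                fh.write(f"{t}\t{v:.6g}\t{int(t in cand)}\t{action}\n")


def residual_msd(bold: BoldSeries, reference: np.ndarray,
                 mask: np.ndarray) -> np.ndarray:
    """Per-volume mean square difference from ``reference`` over ``mask``."""
    reference = np.asarray(reference, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if reference.shape != bold.spatial_shape or mask.shape != bold.spatial_shape:
        raise ValueError("reference/mask shape mismatch")
    if not mask.any():
        raise ValueError("empty mask")
    diff = bold.data[mask] - reference[mask][:, None]
    return np.mean(diff * diff, axis=0)


def displacement_reference(reference: np.ndarray, mask: np.ndarray,
                           ref_fraction: float = 0.10) -> float:
    """Absolute rejection threshold from one-voxel shifts of the reference.

    For each axis the reference is displaced by one voxel and the mean
    square difference is computed over in-mask voxels whose shifted source
    is also in-mask; the result is ``ref_fraction`` times the mean of the
    three per-axis values.
    """
    reference = np.asarray(reference, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if reference.shape != mask.shape:
        raise ValueError("reference/mask shape mismatch")
    msds = []
    for axis in range(3):
        a = [slice(None)] * 3
        b = [slice(None)] * 3
        a[axis] = slice(1, None)
        b[axis] = slice(None, -1)
        valid = mask[tuple(a)] & mask[tuple(b)]
        if not valid.any():
            raise ValueError(f"mask has no interior voxel pairs along axis {axis}")
        d = reference[tuple(a)] - reference[tuple(b)]
        msds.append(float(np.mean(d[valid] ** 2)))
    return float(ref_fraction) * float(np.mean(msds))


def detect_outliers(msd, reference_value: float, iqr_factor: float = 1.5):
    """Two-tier outlier detection on the MSD trace.

    Returns ``(candidates, rejected)`` as sorted integer arrays.
    Candidates exceed the upper IQR fence; rejected candidates also exceed
    the absolute ``reference_value``.  Quartiles use linear interpolation
    of order statistics.
    """
    msd = np.asarray(msd, dtype=float)
    if msd.size < 4:
        raise ValueError("need at least 4 volumes to estimate quartiles")
    q1, q3 = np.percentile(msd, [25.0, 75.0])
    fence = q3 + iqr_factor * (q3 - q1)
    candidates = np.flatnonzero(msd > fence)
    rejected = candidates[msd[candidates] > reference_value]
    return candidates, rejected


def _runs(sorted_idx: np.ndarray):
    """Split a sorted index array into maximal consecutive runs."""
    runs = []
    for t in sorted_idx:
        if runs and t == runs[-1][-1] + 1:
            runs[-1].append(int(t))
        else:
            runs.append([int(t)])
    return runs


def replace_or_remove(bold: BoldSeries, motion: MotionParams, rejected,
                      run_length_cut: int = 10):
    """Repair or drop rejected volumes.

    Maximal consecutive runs of rejected indices shorter than
    ``run_length_cut`` are replaced by per-voxel linear interpolation in
    time between the nearest preserved volume on each side (a plain copy at
    the series ends); runs of length >= ``run_length_cut`` are deleted from
    the series and the motion table.

    Returns ``(bold, motion, replaced_idx, removed_idx, kept_time_index)``.
    """
    t_len = bold.n_vols
    rejected = np.unique(np.asarray(sorted(rejected), dtype=int))
    if rejected.size and (rejected[0] < 0 or rejected[-1] >= t_len):
        raise ValueError("rejected index out of range")
    if motion.n_vols != t_len:
        raise ValueError("motion rows != volumes")
    if t_len - rejected.size < 2:
        raise ValueError("fewer than 2 preserved volumes remain")

    data = bold.data.copy()
    replaced, removed = [], []
    for run in _runs(rejected):
        if len(run) >= run_length_cut:
            removed.extend(run)
            continue
        replaced.extend(run)
        left = run[0] - 1
        right = run[-1] + 1
        if left < 0 and right >= t_len:  # unreachable given >=2 survivors
            raise ValueError("run spans the whole series")
        for t in run:
            if left < 0:
                data[..., t] = bold.data[..., right]
            elif right >= t_len:
                data[..., t] = bold.data[..., left]
            else:
                w = (t - left) / (right - left)
                data[..., t] = (1.0 - w) * bold.data[..., left] \
                    + w * bold.data[..., right]

    keep = np.setdiff1d(np.arange(t_len), np.asarray(removed, dtype=int))
    kept_time_index = {int(out_t): int(in_t) for out_t, in_t in enumerate(keep)}
    out_bold = bold.with_data(data[..., keep])
    out_motion = MotionParams(table=motion.table[keep] - motion.table[keep][0])
    return out_bold, out_motion, replaced, removed, kept_time_index


def ror_stage(bold: BoldSeries, motion: MotionParams, mask: np.ndarray,
              cfg: PipelineConfig):
    """Full outlier-rejection stage: detect, then replace or remove.

    The reference volume is the temporal mean of the input series; MSD is
    computed over the supplied (brain) mask.

    Returns ``(bold, motion, OutlierReport)``.
    """
    reference = bold.data.mean(axis=3)
    msd = residual_msd(bold, reference, mask)
    ref_value = displacement_reference(reference, mask, cfg.ref_fraction)
    candidates, rejected = detect_outliers(msd, ref_value, cfg.iqr_factor)
    q1, q3 = np.percentile(msd, [25.0, 75.0])
    out_bold, out_motion, replaced, removed, kept = replace_or_remove(
        bold, motion, rejected, cfg.run_length_cut)
    report = OutlierReport(
        msd_trace=msd,
        reference_value=ref_value,
        fence_value=float(q3 + cfg.iqr_factor * (q3 - q1)),
        candidate_idx=sorted(int(i) for i in candidates),
        replaced_idx=sorted(int(i) for i in replaced),
        removed_idx=sorted(int(i) for i in removed),
        kept_time_index=kept,
    )
    return out_bold, out_motion, report
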