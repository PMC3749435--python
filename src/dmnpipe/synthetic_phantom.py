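"""Synthetic 4D BOLD phantoms with full ground truth.

The phantom emulates a 200-volume, TR = 2.8 s echo-planar acquisition at
2.5 mm isotropic resolution on a desk-scale 32 x 32 x 24 grid.  It
contains the signal structure the pipeline is built to handle:

* an ellipsoidal brain with a bright central ventricle compartment and a
  static smooth bias/texture field (coil sensitivity and anatomy);
* a planted 4-node network (PCC left/right, MPFC left/right, LP left and
  right) sharing a band-limited (0.01-0.08 Hz) time course with per-node
  coupling strengths;
* a cubic polynomial global drift (scanner baseline instability);
* a motion-coupled multiplicative artifact driven by six random-walk
  rigid-body motion traces through per-voxel weight fields (coil
  sensitivity / partial-volume modulation);
* additive spike volumes (sudden gross movement);
* aliased cardiac pulsatility confined to the ventricles; and
* white Gaussian thermal noise.

Per-voxel signal model::

    S(v,t) = B(v) * [1 + sum_n c_n m_n(v) a x(t) + g(v) d(t)
                       + <motion(t), w(v)> + p(v) sin(2 pi f_p t TR + phi)]
             + spike(v,t) + eps(v,t)

with B the static baseline (bias and texture included), x the network
time course (unit SD, amplitude ``a``), m_n node indicators, d the cubic
drift, w per-voxel motion weights, p the pulsation envelope and eps white
noise.  Everything is returned in :class:`PhantomTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core_io import (BoldSeries, MaskSet, MotionParams, save_bold_float64,
                      save_json, save_mask, save_motion)
from .dmn_eval import RoiSet

__all__ = ["PhantomTruth", "generate_phantom", "write_fixture_bundle", "PROFILES"]

NODE_NAMES = ("pcc", "mpfc", "lp_l", "lp_r")

# compartment labels in PhantomTruth.compartments
LABEL_BACKGROUND = 0
LABEL_PARENCHYMA = 1
LABEL_VENTRICLES = 2
LABEL_NODES = {"pcc": 3, "mpfc": 4, "lp_l": 5, "lp_r": 6}


@dataclass
class PhantomTruth:
    """Ground truth of a generated phantom."""

    network_timecourse: np.ndarray        # length T, unit SD
    network_amplitude: float              # fractional BOLD amplitude a
    node_coupling: dict                   # node -> coupling in [0, 1]
    motion: MotionParams
    spike_idx: list
    drift_coeffs: np.ndarray              # cubic in u = 2t/(T-1) - 1
    pulsation_freq_hz: float
    compartments: np.ndarray              # labeled volume
    noise_sd: float
    seed: int
    baseline: np.ndarray                  # B(v), static intensity field
    motion_weights: np.ndarray            # w(v), shape (X, Y, Z, 6)


# Study-condition profiles.  "control" mirrors a cooperative healthy
# subject (small motion, rarely a spike); "patient" a disorders-of-
# consciousness acquisition (large motion, frequent spikes, enlarged
# ventricles, weakened anterior coupling); "clean" is artifact-free apart
# from drift/noise; "spikey" plants exactly 5 large spikes; "noise" is
# thermal noise on the static anatomy only.
PROFILES = {
    "control": dict(),
    "clean": dict(motion_artifact=0.0, spike_rate=0.0),
    "spikey": dict(n_spikes=5, spike_mult=10.0, spike_rate=None),
    "patient": dict(motion_step_mm=0.02, motion_step_rad=2e-4,
                    motion_artifact=0.02, spike_rate=8.0,
                    spike_mult=(6.0, 12.0), ventricle_scale=1.5,
                    mpfc_coupling=0.2),
    "noise": dict(network_amplitude=0.0, drift_sd=0.0, motion_artifact=0.0,
                  spike_rate=0.0, pulsation_amp=0.0),
}

_DEFAULTS = dict(
    t_len=200,
    tr_s=2.8,
    voxel_mm=2.5,
    base_intensity=1000.0,
    ventricle_contrast=800.0,   # CSF is bright on T2* EPI
    bias_sd=0.05,               # smooth coil-sensitivity field, fractional
    texture_sd=0.10,            # shorter-scale anatomical texture, fractional
    network_amplitude=0.015,    # ~1.5% BOLD fluctuation
    mpfc_coupling=1.0,
    drift_sd=0.005,             # ~0.5% slow baseline drift
    motion_step_mm=0.0035,      # random-walk step; final displacement ~0.05 mm
    motion_step_rad=3.5e-5,
    motion_artifact=0.005,      # fractional amplitude of motion-coupled term
    spike_rate=0.2,             # Poisson mean number of spike volumes
    n_spikes=None,              # exact count overrides spike_rate
    spike_mult=10.0,            # spike field SD in units of noise_sd
    pulsation_amp=0.02,         # fractional, within ventricles
    pulsation_freq_hz=0.16,     # aliased cardiac frequency
    noise_sd=10.0,              # thermal noise (tSNR ~ 100)
    ventricle_scale=1.0,
)


def _ellipsoid(shape, center, semi):
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    return r2 <= 1.0


def _sphere(shape, center, radius):
    return _ellipsoid(shape, center, (radius,) * 3)


def _smooth_field(rng, shape, sigma, support, target_sd):
    """Gaussian-filtered white noise, scaled to ``target_sd`` over ``support``."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = f[support].std()
    if sd == 0:
        return np.zeros(shape)
    return f * (target_sd / sd)


def _bandlimited_timecourse(rng, t_len, tr_s, f_lo=0.01, f_hi=0.08):
    """Unit-SD Gaussian time course with power confined to [f_lo, f_hi] Hz."""
    spec = np.fft.rfft(rng.standard_normal(t_len))
    freqs = np.fft.rfftfreq(t_len, d=tr_s)
    spec[(freqs < f_lo) | (freqs > f_hi)] = 0.0
    x = np.fft.irfft(spec, n=t_len)
    sd = x.std()
    if sd == 0:
        raise ValueError("series too short for the requested passband")
    return x / sd


def _geometry(shape, ventricle_scale):
    """Brain, ventricle and node-ROI geometry on the voxel grid."""
    nx, ny, nz = shape
    center = ((nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0)
    brain = _ellipsoid(shape, center, (0.45 * nx, 0.45 * ny, 0.45 * nz))
    vent = _ellipsoid(
        shape,
        (center[0], center[1] - 0.03 * ny, center[2]),
        (0.11 * nx * ventricle_scale, 0.14 * ny * ventricle_scale,
         0.10 * nz * ventricle_scale)) & brain

    r = max(1.5, 0.072 * nx)  # shrinks with the grid so nodes stay disjoint
    # y axis: small y = anterior (MPFC), large y = posterior (PCC)
    rois = {
        "pcc_l": _sphere(shape, (0.44 * nx, 0.72 * ny, 0.55 * nz), r),
        "pcc_r": _sphere(shape, (0.56 * nx, 0.72 * ny, 0.55 * nz), r),
        "mpfc_l": _sphere(shape, (0.44 * nx, 0.26 * ny, 0.58 * nz), r),
        "mpfc_r": _sphere(shape, (0.56 * nx, 0.26 * ny, 0.58 * nz), r),
        "lp_l": _sphere(shape, (0.20 * nx, 0.62 * ny, 0.55 * nz), r),
        "lp_r": _sphere(shape, (0.80 * nx, 0.62 * ny, 0.55 * nz), r),
    }
    parenchyma = brain & ~vent
    for k in rois:
        rois[k] &= parenchyma
        if not rois[k].any():
            raise ValueError(f"infeasible geometry: node ROI {k} is empty")
    return brain, vent, parenchyma, rois


def generate_phantom(profile: str = "control", grid=(32, 32, 24),
                     overrides: dict | None = None, seed: int = 0):
    """Generate a phantom under one of the study-condition profiles.

    Parameters
    ----------
    profile : {"control", "patient", "clean", "spikey", "noise"}
    grid : 3 ints, each >= (16, 16, 12)
    overrides : dict, optional
        Parameter overrides applied on top of the profile (see module
        defaults); intended for controlled experiments.
    seed : int
        All randomness flows from this seed.

    Returns
    -------
    (BoldSeries, MotionParams, MaskSet, RoiSet, PhantomTruth)
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}")
    grid = tuple(int(g) for g in grid)
    if len(grid) != 3 or any(g < m for g, m in zip(grid, (16, 16, 12))):
        raise ValueError(f"grid {grid} below the minimum 16 x 16 x 12")
    params = dict(_DEFAULTS)
    params.update(PROFILES[profile])
    if overrides:
        unknown = set(overrides) - set(_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown phantom parameters: {sorted(unknown)}")
        params.update(overrides)
    t_len = int(params["t_len"])
    if t_len < 50:
        raise ValueError("t_len must be >= 50")
    tr_s = float(params["tr_s"])
    rng = np.random.default_rng(seed)

    brain, vent, parenchyma, rois = _geometry(grid, params["ventricle_scale"])

    # static baseline: compartment intensity x bias x texture
    intensity = np.zeros(grid)
    intensity[parenchyma] = params["base_intensity"]
    intensity[vent] = params["base_intensity"] + params["ventricle_contrast"]
    bias = _smooth_field(rng, grid, sigma=6.0, support=brain,
                         target_sd=params["bias_sd"])
    texture = _smooth_field(rng, grid, sigma=1.5, support=brain,
                            target_sd=params["texture_sd"])
    baseline = intensity * (1.0 + bias) * (1.0 + texture)

    # planted network
    x = _bandlimited_timecourse(rng, t_len, tr_s)
    coupling = {n: 1.0 for n in NODE_NAMES}
    coupling["mpfc"] = float(params["mpfc_coupling"])
    node_map = np.zeros(grid)
    node_masks = {
        "pcc": rois["pcc_l"] | rois["pcc_r"],
        "mpfc": rois["mpfc_l"] | rois["mpfc_r"],
        "lp_l": rois["lp_l"],
        "lp_r": rois["lp_r"],
    }
    for name, mask in node_masks.items():
        node_map[mask] = coupling[name]
    amp = float(params["network_amplitude"])

    # cubic drift, global over the brain (g(v) = 1 inside the brain)
    u = np.linspace(-1.0, 1.0, t_len)
    raw_poly = np.polynomial.Polynomial([0.0, *rng.standard_normal(3)])
    d_raw = raw_poly(u)
    sd = (d_raw - d_raw.mean()).std()
    scale = params["drift_sd"] / sd if (params["drift_sd"] > 0 and sd > 0) else 0.0
    # scale to the target SD and anchor d(u[0]) = 0 (drift-free at start)
    final_poly = raw_poly * scale - np.polynomial.Polynomial([d_raw[0] * scale])
    d = final_poly(u)
    drift_coeffs = np.zeros(4)
    drift_coeffs[: final_poly.coef.size] = final_poly.coef

    # motion: random walks, re-referenced to the first volume
    steps = rng.standard_normal((t_len - 1, 6))
    steps[:, :3] *= params["motion_step_mm"]
    steps[:, 3:] *= params["motion_step_rad"]
    motion_tab = np.vstack([np.zeros((1, 6)), np.cumsum(steps, axis=0)])
    motion = MotionParams(table=motion_tab)

    # motion-coupled artifact through per-voxel weight fields
    w = np.stack([_smooth_field(rng, grid, sigma=4.0, support=brain,
                                target_sd=1.0) for _ in range(6)], axis=-1)
    w *= brain[..., None]
    art2d = w[brain] @ motion_tab.T              # in-brain voxels x time
    art_sd = art2d.std()
    if params["motion_artifact"] > 0 and art_sd > 0:
        w *= params["motion_artifact"] / art_sd
        art2d *= params["motion_artifact"] / art_sd
    else:
        w[:] = 0.0
        art2d[:] = 0.0

    # ventricle pulsation (aliased cardiac)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    f_p = float(params["pulsation_freq_hz"])
    puls_env = np.where(vent, float(params["pulsation_amp"]), 0.0)
    t_sec = np.arange(t_len) * tr_s
    puls_tc = np.sin(2.0 * np.pi * f_p * t_sec + phi)

    # spike volumes
    if params["n_spikes"] is not None:
        n_spikes = int(params["n_spikes"])
    else:
        n_spikes = int(rng.poisson(params["spike_rate"])) if params["spike_rate"] else 0
    n_spikes = min(n_spikes, t_len // 4)
    spike_idx = sorted(int(i) for i in
                       rng.choice(t_len, size=n_spikes, replace=False))
    mult = params["spike_mult"]

    # assemble the in-brain signal as a (voxels x time) table; background
    # voxels carry thermal noise only (their baseline is zero)
    noise_sd = float(params["noise_sd"])
    sig = 1.0 + (node_map[brain][:, None] * (amp * x)[None, :]
                 + d[None, :]
                 + art2d
                 + puls_env[brain][:, None] * puls_tc[None, :])
    sig *= baseline[brain][:, None]
    for t in spike_idx:
        lo, hi = (mult, mult) if np.isscalar(mult) else mult
        m = rng.uniform(lo, hi)
        field = _smooth_field(rng, grid, sigma=2.0, support=brain,
                              target_sd=m * noise_sd)
        sig[:, t] += field[brain]
    if noise_sd > 0:
        data = rng.standard_normal(grid + (t_len,), dtype=np.float32)
        data *= noise_sd
        data = data.astype(np.float64)
    else:
        data = np.zeros(grid + (t_len,))
    data[brain] += sig

    compartments = np.zeros(grid, dtype=np.int16)
    compartments[parenchyma] = LABEL_PARENCHYMA
    compartments[vent] = LABEL_VENTRICLES
    for name, lab in LABEL_NODES.items():
        compartments[node_masks[name]] = lab

    voxel = float(params["voxel_mm"])
    bold = BoldSeries(data=data, voxel_size_mm=(voxel,) * 3, tr_s=tr_s,
                      space_tag=f"phantom-{profile}")
    masks = MaskSet(brain=brain, parenchyma=parenchyma, ventricles=vent)
    roi_set = RoiSet(pcc=node_masks["pcc"], mpfc=node_masks["mpfc"],
                     lp_l=node_masks["lp_l"], lp_r=node_masks["lp_r"],
                     pcc_l=rois["pcc_l"], pcc_r=rois["pcc_r"],
                     mpfc_l=rois["mpfc_l"], mpfc_r=rois["mpfc_r"])
    truth = PhantomTruth(
        network_timecourse=x,
        network_amplitude=amp,
        node_coupling=coupling,
        motion=motion,
        spike_idx=spike_idx,
        drift_coeffs=drift_coeffs,
        pulsation_freq_hz=f_p,
        compartments=compartments,
        noise_sd=noise_sd,
        seed=int(seed),
        baseline=baseline,
        motion_weights=w,
    )
    return bold, motion, masks, roi_set, truth


def write_fixture_bundle(outdir, profile: str = "control", grid=(32, 32, 24),
                         overrides: dict | None = None, seed: int = 0):
    """Generate a phantom and write it as a reloadable file bundle.

    Writes ``bold.nii.gz``, ``rp.txt``, mask and ROI NIfTIs, and a
    ``truth.json`` with the scalar/1-D ground truth.  Returns the dict of
    written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bold, motion, masks, rois, truth = generate_phantom(
        profile=profile, grid=grid, overrides=overrides, seed=seed)
    paths = {"bold": outdir / "bold.nii.gz", "motion": outdir / "rp.txt",
             "truth": outdir / "truth.json"}
    save_bold_float64(bold, paths["bold"])
    save_motion(motion, paths["motion"])
    vx = bold.voxel_size_mm
    for name, mask in (("brain", masks.brain), ("parenchyma", masks.parenchyma),
                       ("ventricles", masks.ventricles)):
        paths[name] = outdir / f"mask_{name}.nii.gz"
        save_mask(mask, vx, paths[name])
    for name in ("pcc", "mpfc", "lp_l", "lp_r", "pcc_l", "pcc_r",
                 "mpfc_l", "mpfc_r"):
        paths[f"roi_{name}"] = outdir / f"roi_{name}.nii.gz"
        save_mask(getattr(rois, name), vx, paths[f"roi_{name}"])
    save_json({
        "profile": profile,
        "seed": truth.seed,
        "network_timecourse": truth.network_timecourse,
        "network_amplitude": truth.network_amplitude,
        "node_coupling": truth.node_coupling,
        "spike_idx": truth.spike_idx,
        "drift_coeffs": truth.drift_coeffs,
        "pulsation_freq_hz": truth.pulsation_freq_hz,
        "noise_sd": truth.noise_sd,
        "tr_s": bold.tr_s,
        "voxel_size_mm": list(bold.voxel_size_mm),
        "grid": list(bold.spatial_shape),
    }, paths["truth"])
    return paths
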