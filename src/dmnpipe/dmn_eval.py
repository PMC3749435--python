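"""Default-mode-network detectability: SBA, spatial ICA, node metrics.

Two complementary connectivity read-outs are computed from a preprocessed
series:

* **Seed-based analysis (SBA)** — the mean time courses of the left and
  right posterior-cingulate/precuneus (PCC) seeds enter a single per-voxel
  general linear model; each regressor's t statistic is mapped to a z
  score through the exact distribution functions and the two hemispheric
  maps are combined with the voxel-wise maximum.

* **Spatial ICA** — the series is decomposed into a fixed number of
  spatially independent components (voxels as samples); the DMN component
  is selected automatically by node coverage and a goodness-of-fit
  ranking, with voxel-wise-maximum merging when the network splits into
  two hemispheric components.

Detectability metrics: per-node peak z inside dilated node ROIs, the
extra-DMN extent (percentage of parenchyma voxels above threshold outside
the dilated ROIs — a specificity measure), inter-node Pearson
correlations, and a within-subject normalized detectability score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "RoiSet",
    "DmnMetrics",
    "DmnSelection",
    "sba_map",
    "ica_components",
    "select_dmn_component",
    "node_metrics",
    "node_pair_correlations",
    "detectability_score",
]

NODE_NAMES = ("pcc", "mpfc", "lp_l", "lp_r")
PAIR_NAMES = ("lp_l-lp_r", "pcc_l-lp_l", "pcc_r-lp_r",
              "pcc_l-mpfc_l", "pcc_r-mpfc_r")
_PAIRS = {
    "lp_l-lp_r": ("lp_l", "lp_r"),
    "pcc_l-lp_l": ("pcc_l", "lp_l"),
    "pcc_r-lp_r": ("pcc_r", "lp_r"),
    "pcc_l-mpfc_l": ("pcc_l", "mpfc_l"),
    "pcc_r-mpfc_r": ("pcc_r", "mpfc_r"),
}


@dataclass
class RoiSet:
    """DMN node masks (PCC and MPFC bilateral; LP split by hemisphere).

    The hemisphere-split PCC/MPFC masks are needed for the node-pair
    correlations; the merged masks are used for peak-z evaluation.
    Evaluation masks are dilated by ``dilation_voxels`` iterations of a
    one-voxel cubic dilation, to absorb normalization imperfections.
    """

    pcc: np.ndarray
    mpfc: np.ndarray
    lp_l: np.ndarray
    lp_r: np.ndarray
    pcc_l: np.ndarray = None
    pcc_r: np.ndarray = None
    mpfc_l: np.ndarray = None
    mpfc_r: np.ndarray = None
    dilation_voxels: int = 5
    _dilated: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        for name in NODE_NAMES:
            m = np.asarray(getattr(self, name), dtype=bool)
            setattr(self, name, m)
            if not m.any():
                raise ValueError(f"node ROI {name} is empty")
        for a in range(len(NODE_NAMES)):
            for b in range(a + 1, len(NODE_NAMES)):
                if np.any(getattr(self, NODE_NAMES[a]) & getattr(self, NODE_NAMES[b])):
                    raise ValueError(
                        f"node ROIs {NODE_NAMES[a]} and {NODE_NAMES[b]} overlap")

    def dilated(self, name: str) -> np.ndarray:
        if name not in self._dilated:
            mask = getattr(self, name)
            if self.dilation_voxels > 0:
                mask = ndimage.binary_dilation(
                    mask, structure=np.ones((3, 3, 3), dtype=bool),
                    iterations=self.dilation_voxels)
            self._dilated[name] = mask
        return self._dilated[name]

    def dilated_union(self) -> np.ndarray:
        out = np.zeros_like(self.pcc)
        for name in NODE_NAMES:
            out |= self.dilated(name)
        return out


@dataclass
class DmnMetrics:
    """Per-map detectability metrics."""

    peak_z: dict                 # node -> float (NaN when flagged missing)
    extra_dmn_pct: float
    node_pair_r: dict = None     # pair -> float
    detectability: float = None
    missing: set = field(default_factory=set)


@dataclass
class DmnSelection:
    """Outcome of automated DMN-component selection.

    ``detected`` is False when no component shows supra-threshold voxels
    in at least two node regions (the "network not found" outcome); this
    is a value, not an error.
    """

    detected: bool
    map: np.ndarray = None
    component_indices: tuple = ()
    coverage: dict = None


# ---------------------------------------------------------------------------
# Seed-based analysis


def _t_to_z(tvals: np.ndarray, df: int) -> np.ndarray:
    """Map t statistics to standard-normal quantiles through the exact CDFs.

    Uses the survival function on the appropriate tail for numerical
    stability at large |t|.
    """
    tvals = np.asarray(tvals, dtype=float)
    z = np.empty_like(tvals)
    pos = tvals >= 0
    sf = stats.t.sf(np.abs(tvals), df)
    sf = np.clip(sf, 1e-300, 1.0)
    z_abs = stats.norm.isf(sf)
    z[pos] = z_abs[pos]
    z[~pos] = -z_abs[~pos]
    return z


def _glm_z(y: np.ndarray, design: np.ndarray, columns) -> list:
    """Per-voxel OLS t statistics for selected columns, mapped to z."""
    t_len, k = design.shape
    df = t_len - k
    xtx_inv = np.linalg.inv(design.T @ design)
    beta = y @ design @ xtx_inv.T                   # V x k
    resid = y - beta @ design.T
    sigma2 = np.sum(resid * resid, axis=1) / df
    out = []
    for j in columns:
        se = np.sqrt(np.maximum(sigma2 * xtx_inv[j, j], 1e-300))
        out.append(_t_to_z(beta[:, j] / se, df))
    return out


def sba_map(bold, seed_left: np.ndarray, seed_right: np.ndarray,
            parenchyma: np.ndarray, joint: bool = False,
            combine: bool = True) -> np.ndarray:
    """Seed-based connectivity z map from left/right PCC seed regressors.

    Each seed's mean time course enters a per-voxel GLM; the seed
    regressor's t statistic is converted to z through the exact
    distribution functions, and the left/right maps are combined with the
    voxel-wise maximum.  Voxels outside the parenchyma are set to 0.

    By default each seed gets its own GLM ``[intercept | seed]``.  With
    ``joint=True`` both seeds enter one model and partial t statistics
    are used; because the two PCC time courses share most of their
    variance, the joint model splits credit between the near-collinear
    regressors and can suppress both maps, so the marginal model is the
    default.  Near-collinear seeds (|r| > 0.999) always fall back to a
    single averaged regressor, with a warning.

    With ``combine=False`` the per-seed z maps are returned stacked along
    a leading axis instead of max-combined.  Note that under a pure-noise
    null each individual map has the standard-normal tail (P(z > 2) is
    about 2.3%) while the max-combined map has roughly twice that
    supra-threshold fraction; calibration checks should therefore look at
    the per-seed maps.
    """
    seed_left = np.asarray(seed_left, dtype=bool)
    seed_right = np.asarray(seed_right, dtype=bool)
    parenchyma = np.asarray(parenchyma, dtype=bool)
    if not (seed_left.any() and seed_right.any()):
        raise ValueError("empty seed mask")
    t_len = bold.n_vols
    if t_len <= 10:
        raise ValueError("need more than 10 volumes for SBA")
    s_l = bold.data[seed_left].mean(axis=0)
    s_r = bold.data[seed_right].mean(axis=0)
    if s_l.std() == 0 or s_r.std() == 0:
        raise ValueError("zero-variance seed time course")
    r = np.corrcoef(s_l, s_r)[0, 1]
    y = bold.data[parenchyma]                       # V x T
    intercept = np.ones(t_len)
    if np.abs(r) > 0.999:
        warnings.warn("seed time courses nearly collinear; "
                      "falling back to a single averaged regressor")
        zmaps = _glm_z(y, np.column_stack([intercept, (s_l + s_r) / 2.0]), [1])
    elif joint:
        zmaps = _glm_z(y, np.column_stack([intercept, s_l, s_r]), [1, 2])
    else:
        zmaps = (_glm_z(y, np.column_stack([intercept, s_l]), [1])
                 + _glm_z(y, np.column_stack([intercept, s_r]), [1]))
    if not combine:
        stack = np.zeros((len(zmaps),) + bold.spatial_shape)
        for j, z in enumerate(zmaps):
            stack[j][parenchyma] = z
        return stack
    z_in = np.max(np.column_stack(zmaps), axis=1)
    out = np.zeros(bold.spatial_shape)
    out[parenchyma] = z_in
    return out


# ---------------------------------------------------------------------------
# Spatial ICA


def ica_components(bold, brain: np.ndarray, n_components: int = 20,
                   seed: int = 0, max_iter: int = 400, tol: float = 1e-3):
    """Spatial ICA of the in-brain time series.

    The decomposition treats voxels as samples and time points as mixture
    channels, after whitening/dimensionality reduction to ``n_components``.
    Each spatial map is standardized to zero mean / unit variance over the
    brain and sign-aligned so its skewness is positive.

    Returns ``(maps, mixing)`` where ``maps`` has shape
    ``(n_components, X, Y, Z)`` (z-scaled; zero outside the brain) and
    ``mixing`` has shape ``(T, n_components)`` (component time courses).
    Non-convergence triggers a restart with an incremented seed, at most
    5 times, before raising; the last two restarts switch from the
    parallel (symmetric) FastICA update to one-unit deflation, which
    converges on data where the symmetric update oscillates.
    """
    brain = np.asarray(brain, dtype=bool)
    if brain.shape != bold.spatial_shape:
        raise ValueError("brain mask shape mismatch")
    n_vox = int(brain.sum())
    if n_components >= bold.n_vols or n_components >= n_vox:
        raise ValueError(
            f"n_components={n_components} must be below the number of "
            f"volumes ({bold.n_vols}) and in-mask voxels ({n_vox})")
    x = bold.data[brain].astype(np.float64)          # voxels x time
    x = x - x.mean(axis=1, keepdims=True)

    last_exc = None
    for attempt in range(6):
        ica = FastICA(n_components=n_components, whiten="unit-variance",
                      max_iter=max_iter, tol=tol,
                      algorithm="parallel" if attempt < 2 else "deflation",
                      random_state=int(seed) + attempt)
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                sources = ica.fit_transform(x)       # voxels x k
            except ConvergenceWarning as exc:
                last_exc = exc
                continue
        break
    else:
        raise RuntimeError(
            f"spatial ICA failed to converge after 6 attempts: {last_exc}")

    mixing = np.asarray(ica.mixing_)                  # time x k
    maps = np.zeros((n_components,) + bold.spatial_shape)
    for j in range(n_components):
        s = sources[:, j]
        sd = s.std()
        s = (s - s.mean()) / (sd if sd > 0 else 1.0)
        if stats.skew(s) < 0:
            s = -s
            mixing[:, j] = -mixing[:, j]
        maps[j][brain] = s
    return maps, mixing


def select_dmn_component(components: np.ndarray, rois: RoiSet,
                         z_threshold: float = 2.0,
                         brain: np.ndarray | None = None,
                         use_dilated: bool = False) -> DmnSelection:
    """Pick (and possibly merge) the DMN component from ICA spatial maps.

    A component is a candidate if it has supra-threshold voxels in at
    least two of the four node regions.  Candidates are ranked by
    goodness of fit: mean z inside the node-ROI union minus mean z
    outside it (within the brain).  If the two best candidates cover
    disjoint node sets — hemispheric splitting of the network — they are
    merged with the voxel-wise maximum.  An empty candidate set yields a
    non-detection result.

    By default the *undilated* node ROIs drive coverage and ranking:
    dilated masks (meant to absorb normalization error in the peak-z
    read-out) can cover a large share of a small brain, in which case
    nearly every component "covers" every node and the ranking loses all
    discrimination.  ``use_dilated=True`` restores dilated-mask selection
    for large grids where the dilation is proportionally small.
    """
    components = np.asarray(components)
    if components.ndim != 4 or components.shape[0] < 1:
        raise ValueError("components must be (n, X, Y, Z) with n >= 1")
    if brain is None:
        brain = np.any(components != 0, axis=0)
    if use_dilated:
        node_masks = {n: rois.dilated(n) & brain for n in NODE_NAMES}
        union = rois.dilated_union() & brain
    else:
        node_masks = {n: getattr(rois, n) & brain for n in NODE_NAMES}
        union = np.zeros_like(brain)
        for n in NODE_NAMES:
            union |= node_masks[n]
    outside = brain & ~union

    candidates = []
    for j in range(components.shape[0]):
        comp = components[j]
        covered = frozenset(
            n for n, m in node_masks.items()
            if m.any() and np.any(comp[m] > z_threshold))
        if len(covered) < 2:
            continue
        gof = comp[union].mean() - (comp[outside].mean() if outside.any() else 0.0)
        candidates.append((gof, j, covered))
    if not candidates:
        return DmnSelection(detected=False)
    candidates.sort(key=lambda c: -c[0])
    gof, j, covered = candidates[0]
    coverage = {j: sorted(covered)}
    merged = components[j]
    if len(candidates) > 1:
        gof2, j2, covered2 = candidates[1]
        if not (covered & covered2):  # hemispheric splitting
            merged = np.maximum(merged, components[j2])
            coverage[j2] = sorted(covered2)
            return DmnSelection(detected=True, map=merged,
                                component_indices=(j, j2), coverage=coverage)
    return DmnSelection(detected=True, map=merged.copy(),
                        component_indices=(j,), coverage=coverage)


# ---------------------------------------------------------------------------
# Metrics


def node_metrics(zmap: np.ndarray, rois: RoiSet, parenchyma: np.ndarray,
                 z_threshold: float = 2.0) -> DmnMetrics:
    """Peak z per (dilated) node ROI and extra-DMN extent.

    The extent is the percentage of parenchyma voxels above the threshold
    outside the union of dilated node ROIs.  A node whose dilated mask
    does not intersect the parenchyma is flagged missing (NaN); downstream
    group statistics impute such entries to the group median.
    """
    zmap = np.asarray(zmap, dtype=float)
    parenchyma = np.asarray(parenchyma, dtype=bool)
    if zmap.shape != parenchyma.shape:
        raise ValueError("map/parenchyma shape mismatch")
    if not parenchyma.any():
        raise ValueError("empty parenchyma mask")
    peak = {}
    missing = set()
    for name in NODE_NAMES:
        m = rois.dilated(name) & parenchyma
        if not m.any():
            peak[name] = float("nan")
            missing.add(name)
        else:
            peak[name] = float(zmap[m].max())
    outside = parenchyma & ~rois.dilated_union()
    n_extra = int(np.count_nonzero(zmap[outside] > z_threshold))
    extra_pct = 100.0 * n_extra / int(parenchyma.sum())
    return DmnMetrics(peak_z=peak, extra_dmn_pct=extra_pct, missing=missing)


def node_pair_correlations(bold, rois: RoiSet) -> dict:
    """Pearson r between regionally averaged time courses of node pairs.

    Pairs: LP_L-LP_R, PCC_L-LP_L, PCC_R-LP_R, PCC_L-MPFC_L, PCC_R-MPFC_R.
    A zero-variance region yields NaN (flagged missing downstream).
    """
    means = {}
    for name in ("pcc_l", "pcc_r", "mpfc_l", "mpfc_r", "lp_l", "lp_r"):
        mask = getattr(rois, name)
        if mask is None:
            raise ValueError(f"hemisphere-split ROI {name} not supplied")
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError(f"hemisphere-split ROI {name} is empty")
        means[name] = bold.data[mask].mean(axis=0)
    out = {}
    for pair, (a, b) in _PAIRS.items():
        sa, sb = means[a], means[b]
        if sa.std() == 0 or sb.std() == 0:
            out[pair] = float("nan")
        else:
            out[pair] = float(np.corrcoef(sa, sb)[0, 1])
    return out


def detectability_score(node_scores_by_grade: np.ndarray) -> np.ndarray:
    """Within-subject normalized detectability score per grade.

    ``node_scores_by_grade`` is a (grades x 4 nodes) table; the per-grade
    node sums are divided by the subject's maximum grade sum, so the best
    grade scores 1.0.  An all-zero table returns zeros with a warning.
    """
    tab = np.asarray(node_scores_by_grade, dtype=float)
    if tab.ndim != 2 or tab.shape[1] != 4 or tab.shape[0] < 1:
        raise ValueError("expected a (grades x 4 nodes) table")
    sums = tab.sum(axis=1)
    top = sums.max()
    if top <= 0:
        warnings.warn("all node scores zero; skipping normalization")
        return np.zeros_like(sums)
    return sums / top
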