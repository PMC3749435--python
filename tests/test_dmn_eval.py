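import numpy as np
import pytest

from dmnpipe import generate_phantom
from dmnpipe.core_io import BoldSeries
from dmnpipe.dmn_eval import (RoiSet, detectability_score, ica_components,
                              node_metrics, node_pair_correlations, sba_map,
                              select_dmn_component)


def _bold(data, tr=2.8):
    return BoldSeries(data=data, voxel_size_mm=(2.5, 2.5, 2.5), tr_s=tr)


def _box(shape, sl):
    m = np.zeros(shape, bool)
    m[sl] = True
    return m


def _toy_rois(shape=(12, 12, 8), dilation=0):
    return RoiSet(
        pcc=_box(shape, (slice(5, 7), slice(8, 10), slice(3, 5))),
        mpfc=_box(shape, (slice(5, 7), slice(1, 3), slice(3, 5))),
        lp_l=_box(shape, (slice(1, 3), slice(6, 8), slice(3, 5))),
        lp_r=_box(shape, (slice(9, 11), slice(6, 8), slice(3, 5))),
        dilation_voxels=dilation,
    )


class TestSba:
    def test_seed_voxel_is_map_maximum(self, rng):
        shape = (8, 8, 6)
        t = 80
        data = rng.normal(size=shape + (t,))
        seed_l = _box(shape, (slice(2, 4), slice(2, 4), slice(2, 4)))
        seed_r = _box(shape, (slice(5, 7), slice(2, 4), slice(2, 4)))
        target = (1, 6, 1)
        data[target] = data[seed_l].mean(axis=0)  # copies the left seed mean
        par = np.ones(shape, bool)
        z = sba_map(_bold(data), seed_l, seed_r, par)
        assert np.unravel_index(np.argmax(z), shape) == target

    def test_null_suprathreshold_fraction_near_normal_tail(self):
        from scipy.stats import norm
        bold, motion, masks, rois, truth = generate_phantom("noise", seed=21)
        per_seed = sba_map(bold, rois.pcc_l, rois.pcc_r, masks.parenchyma,
                           combine=False)
        for j in range(per_seed.shape[0]):
            frac = np.mean(per_seed[j][masks.parenchyma] > 2.0)
            assert frac == pytest.approx(norm.sf(2.0), abs=0.015)
        # the max-combined map has the analytic two-map null tail
        combined = sba_map(bold, rois.pcc_l, rois.pcc_r, masks.parenchyma)
        frac = np.mean(combined[masks.parenchyma] > 2.0)
        assert frac == pytest.approx(1 - (1 - norm.sf(2.0)) ** 2, abs=0.02)

    def test_planted_network_peaks_inside_nodes(self, clean_phantom):
        bold, motion, masks, rois, truth = clean_phantom
        z = sba_map(bold, rois.pcc_l, rois.pcc_r, masks.parenchyma)
        node_union = rois.pcc | rois.mpfc | rois.lp_l | rois.lp_r
        out_of_node = masks.parenchyma & ~node_union
        thresh = np.percentile(z[out_of_node], 99)
        for node in ("pcc", "lp_l", "lp_r"):
            assert z[getattr(rois, node)].max() > thresh

    def test_zero_variance_seed_rejected(self):
        shape = (6, 6, 4)
        data = np.zeros(shape + (40,))
        seed = _box(shape, (slice(0, 2), slice(0, 2), slice(0, 2)))
        with pytest.raises(ValueError, match="zero-variance"):
            sba_map(_bold(data), seed, seed, np.ones(shape, bool))


class TestIca:
    def _three_source_mixture(self, rng, shape=(12, 12, 8), t=80):
        sources = [
            _box(shape, (slice(1, 4), slice(1, 4), slice(2, 6))),
            _box(shape, (slice(7, 11), slice(2, 5), slice(2, 6))),
            _box(shape, (slice(4, 8), slice(7, 11), slice(2, 6))),
        ]
        tcs = rng.normal(size=(3, t))
        data = np.zeros(shape + (t,))
        for m, tc in zip(sources, tcs):
            data[m] += tc
        data += 0.05 * rng.normal(size=data.shape)
        return _bold(data), sources

    def test_recovers_known_sources(self, rng):
        bold, sources = self._three_source_mixture(rng)
        brain = np.ones(bold.spatial_shape, bool)
        maps, mixing = ica_components(bold, brain, n_components=3, seed=5)
        assert mixing.shape == (bold.n_vols, 3)
        for src in sources:
            best = max(abs(np.corrcoef(maps[j][brain],
                                       src[brain].astype(float))[0, 1])
                       for j in range(3))
            assert best >= 0.95

    def test_deterministic_given_seed(self, rng):
        bold, _ = self._three_source_mixture(rng)
        brain = np.ones(bold.spatial_shape, bool)
        maps1, mix1 = ica_components(bold, brain, n_components=3, seed=9)
        maps2, mix2 = ica_components(bold, brain, n_components=3, seed=9)
        np.testing.assert_array_equal(maps1, maps2)
        np.testing.assert_array_equal(mix1, mix2)

    def test_maps_standardized_positive_skew(self, rng):
        bold, _ = self._three_source_mixture(rng)
        brain = np.ones(bold.spatial_shape, bool)
        maps, _ = ica_components(bold, brain, n_components=3, seed=5)
        from scipy.stats import skew
        for j in range(3):
            vals = maps[j][brain]
            assert vals.mean() == pytest.approx(0.0, abs=1e-9)
            assert vals.std() == pytest.approx(1.0, rel=1e-9)
            assert skew(vals) >= 0

    def test_too_many_components_rejected(self, rng):
        bold, _ = self._three_source_mixture(rng, t=20)
        with pytest.raises(ValueError, match="n_components"):
            ica_components(bold, np.ones(bold.spatial_shape, bool),
                           n_components=30)


class TestSelection:
    def test_two_node_component_selected(self):
        rois = _toy_rois()
        comp = np.zeros((1, 12, 12, 8))
        comp[0][rois.pcc] = 3.0
        comp[0][rois.lp_l] = 3.0
        sel = select_dmn_component(comp, rois, z_threshold=2.0,
                                   brain=np.ones((12, 12, 8), bool))
        assert sel.detected and sel.component_indices == (0,)

    def test_hemispheric_split_merged_by_max(self):
        rois = _toy_rois()
        shape = (12, 12, 8)
        comps = np.zeros((2,) + shape)
        comps[0][rois.pcc] = 3.0
        comps[0][rois.lp_l] = 4.0
        comps[1][rois.lp_r] = 5.0
        comps[1][rois.mpfc] = 3.0
        sel = select_dmn_component(comps, rois, z_threshold=2.0,
                                   brain=np.ones(shape, bool))
        assert sel.detected and set(sel.component_indices) == {0, 1}
        np.testing.assert_array_equal(sel.map,
                                      np.maximum(comps[0], comps[1]))

    def test_single_node_coverage_is_nondetection(self):
        rois = _toy_rois()
        comp = np.zeros((1, 12, 12, 8))
        comp[0][rois.pcc] = 3.0
        sel = select_dmn_component(comp, rois, z_threshold=2.0,
                                   brain=np.ones((12, 12, 8), bool))
        assert not sel.detected and sel.map is None

    def test_overlapping_candidates_not_merged(self):
        rois = _toy_rois()
        shape = (12, 12, 8)
        comps = np.zeros((2,) + shape)
        for j in range(2):
            comps[j][rois.pcc] = 3.0 + j
            comps[j][rois.lp_l] = 3.0 + j
        sel = select_dmn_component(comps, rois, z_threshold=2.0,
                                   brain=np.ones(shape, bool))
        assert sel.detected and len(sel.component_indices) == 1


class TestNodeMetrics:
    def test_zero_map(self):
        rois = _toy_rois()
        par = np.ones((12, 12, 8), bool)
        m = node_metrics(np.zeros((12, 12, 8)), rois, par)
        assert all(v == 0.0 for v in m.peak_z.values())
        assert m.extra_dmn_pct == 0.0

    def test_peak_confined_to_one_node(self):
        rois = _toy_rois()
        par = np.ones((12, 12, 8), bool)
        zmap = np.zeros((12, 12, 8))
        zmap[rois.pcc] = 3.0
        m = node_metrics(zmap, rois, par)
        assert m.peak_z["pcc"] == 3.0
        assert m.peak_z["mpfc"] == 0.0 and m.peak_z["lp_l"] == 0.0
        assert m.extra_dmn_pct == 0.0

    def test_extra_dmn_percentage_arithmetic(self):
        rois = _toy_rois()
        shape = (12, 12, 8)
        par = np.ones(shape, bool)
        outside = par & ~rois.dilated_union()
        n_out = outside.sum()
        n_par = par.sum()
        k = n_par // 20  # aim at 5% of parenchyma
        zmap = np.zeros(shape)
        sel = np.argwhere(outside)[:k]
        zmap[tuple(sel.T)] = 3.0
        m = node_metrics(zmap, rois, par)
        assert m.extra_dmn_pct == pytest.approx(100.0 * k / n_par)

    def test_extent_invariant_under_monotone_transform(self, rng):
        rois = _toy_rois()
        par = np.ones((12, 12, 8), bool)
        zmap = rng.normal(size=(12, 12, 8)) * 2
        m1 = node_metrics(zmap, rois, par, z_threshold=2.0)
        m2 = node_metrics(np.exp(zmap), rois, par, z_threshold=np.exp(2.0))
        assert m1.extra_dmn_pct == m2.extra_dmn_pct

    def test_node_outside_parenchyma_flagged_missing(self):
        rois = _toy_rois()
        par = np.ones((12, 12, 8), bool)
        par[rois.mpfc] = False  # lesion swallowing the node
        m = node_metrics(np.zeros((12, 12, 8)), rois, par)
        assert "mpfc" in m.missing and np.isnan(m.peak_z["mpfc"])

    def test_dilation_grows_masks(self):
        r0 = _toy_rois(dilation=0)
        r2 = _toy_rois(dilation=2)
        assert r2.dilated("pcc").sum() > r0.dilated("pcc").sum()
        assert np.all(r2.dilated("pcc") | ~r0.dilated("pcc"))


class TestPairCorrelations:
    def _rois_with_hemi(self, shape=(10, 10, 6)):
        def box(x0):
            return _box(shape, (slice(x0, x0 + 2), slice(4, 6), slice(2, 4)))
        return RoiSet(pcc=box(4), mpfc=_box(shape, (slice(4, 6), slice(0, 2),
                                                    slice(2, 4))),
                      lp_l=box(0), lp_r=box(8),
                      pcc_l=_box(shape, (slice(4, 5), slice(4, 6), slice(2, 4))),
                      pcc_r=_box(shape, (slice(5, 6), slice(4, 6), slice(2, 4))),
                      mpfc_l=_box(shape, (slice(4, 5), slice(0, 2), slice(2, 4))),
                      mpfc_r=_box(shape, (slice(5, 6), slice(0, 2), slice(2, 4))))

    def test_identical_and_flipped_timecourses(self, rng):
        shape = (10, 10, 6)
        rois = self._rois_with_hemi(shape)
        tc = rng.normal(size=50)
        data = np.zeros(shape + (50,))
        for name in ("pcc_l", "pcc_r", "mpfc_l", "mpfc_r", "lp_l"):
            data[getattr(rois, name)] = tc
        data[rois.lp_r] = -tc
        r = node_pair_correlations(_bold(data), rois)
        assert r["pcc_l-lp_l"] == pytest.approx(1.0)
        assert r["lp_l-lp_r"] == pytest.approx(-1.0)

    def test_independent_noise_rarely_correlates(self, rng):
        t = 200
        count = 0
        n_draws = 100
        for _ in range(n_draws):
            a, b = rng.normal(size=(2, t))
            if abs(np.corrcoef(a, b)[0, 1]) < 0.2:
                count += 1
        assert count >= 95

    def test_zero_variance_region_flagged(self):
        shape = (10, 10, 6)
        rois = self._rois_with_hemi(shape)
        data = np.zeros(shape + (50,))
        r = node_pair_correlations(_bold(data), rois)
        assert all(np.isnan(v) for v in r.values())


class TestDetectability:
    def test_normalization(self):
        tab = np.array([[0.5, 0.5, 0.5, 0.5],
                        [1, 1, 1, 1],
                        [2, 2, 2, 2]])
        np.testing.assert_allclose(detectability_score(tab),
                                   [0.25, 0.5, 1.0])

    def test_single_grade(self):
        np.testing.assert_allclose(detectability_score([[1, 2, 3, 4]]), [1.0])

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning, match="all node scores zero"):
            out = detectability_score(np.zeros((3, 4)))
        np.testing.assert_array_equal(out, np.zeros(3))
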