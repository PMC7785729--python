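"""Voxelwise path: partitioning, paired t, clustering, smoothing, masks."""

import numpy as np
import pandas as pd
import pytest

from yokedbml.voxel import (InsulaVoxelBML, VolumeMask, cluster_threshold,
                            fit_bml_voxel, intersect, kmeans_subrois,
                            paired_ttest_map, smooth_gaussian, snr_erode,
                            sphere_mask)

AFF = np.diag([2.0, 2.0, 2.0, 1.0])


def _ellipsoid_mask(n, shape):
    grid = np.indices(shape).reshape(3, -1).T
    c = (np.array(shape) - 1) / 2
    d = (((grid - c) / (np.array(shape) / 2)) ** 2).sum(1)
    sel = np.argsort(d)[:n]
    m = np.zeros(shape, bool)
    m[grid[sel, 0], grid[sel, 1], grid[sel, 2]] = True
    return VolumeMask(m, AFF)


class TestKMeans:
    def test_single_cluster(self):
        mask = _ellipsoid_mask(50, (6, 6, 6))
        part = kmeans_subrois(mask, 1, seed=0)
        assert part.sizes().tolist() == [50]

    def test_two_separated_blobs(self):
        data = np.zeros((20, 6, 6), bool)
        data[:4] = True
        data[16:] = True
        mask = VolumeMask(data, AFF)
        part = kmeans_subrois(mask, 2, seed=1)
        vol = part.label_volume()
        left = vol[:4][data[:4].nonzero()] if False else vol[:4, :, :][data[:4]]
        right = vol[16:, :, :][data[16:]]
        assert len(set(left.tolist())) == 1
        assert len(set(right.tolist())) == 1
        assert set(left.tolist()) != set(right.tolist())

    def test_941_voxel_mask_11_subrois(self):
        """An insula-sized mask splits into 11 comparable sub-ROIs."""
        mask = _ellipsoid_mask(941, (20, 16, 14))
        part = kmeans_subrois(mask, 11, seed=0)
        sizes = part.sizes()
        assert len(sizes) == 11 and (sizes > 0).all()
        assert sizes.max() <= 2 * sizes.mean()

    def test_k_exceeds_voxels(self):
        mask = _ellipsoid_mask(10, (4, 4, 4))
        with pytest.raises(ValueError, match="out of range"):
            kmeans_subrois(mask, 11, seed=0)

    def test_seed_determinism(self):
        mask = _ellipsoid_mask(200, (10, 10, 6))
        a = kmeans_subrois(mask, 5, seed=3).labels
        b = kmeans_subrois(mask, 5, seed=3).labels
        assert np.array_equal(a, b)


class TestPairedT:
    def test_closed_form(self):
        t, p = paired_ttest_map(np.array([[1.0], [2.0], [3.0]]), np.zeros((3, 1)))
        assert t[0] == pytest.approx(2 * np.sqrt(3))
        from scipy.stats import t as tdist

        assert p[0] == pytest.approx(2 * tdist.sf(2 * np.sqrt(3), 2))

    def test_identical_groups_zero(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(5, 4, 4, 4))
        t, p = paired_ttest_map(m, m.copy())
        assert np.allclose(np.nan_to_num(t), 0.0)

    def test_matches_scipy(self):
        from scipy.stats import ttest_rel

        rng = np.random.default_rng(1)
        a = rng.normal(size=(12, 30))
        b = rng.normal(size=(12, 30))
        t, p = paired_ttest_map(a, b)
        ref = ttest_rel(a, b, axis=0)
        assert np.allclose(t, ref.statistic, atol=1e-10)
        assert np.allclose(p, ref.pvalue, atol=1e-10)

    def test_null_type_one_error_rate(self):
        """Across 5000 null voxels the p < 0.001 rate is about 0.001."""
        rng = np.random.default_rng(2)
        a = rng.normal(size=(61, 5000))
        b = rng.normal(size=(61, 5000))
        _, p = paired_ttest_map(a, b)
        rate = float(np.mean(p < 0.001))
        assert rate == pytest.approx(0.001, abs=0.0012)

    def test_zero_variance_voxel_nan(self):
        a = np.ones((4, 2))
        b = np.zeros((4, 2))
        with pytest.warns(UserWarning, match="zero variance"):
            t, p = paired_ttest_map(a, b)
        assert np.isnan(t).all()


class TestClusterThreshold:
    def test_no_suprathreshold_empty(self):
        tab, lab = cluster_threshold(np.ones((5, 5, 5)), np.zeros((5, 5, 5)),
                                     0.001, 13)
        assert len(tab) == 0 and lab.max() == 0

    def test_extent_filter_around_13(self):
        """A 15-voxel blob survives a 13-voxel extent; a 12-voxel blob does not."""
        p = np.ones((12, 12, 6))
        t = np.zeros((12, 12, 6))
        p[0:5, 0:3, 0] = 1e-5; t[0:5, 0:3, 0] = 4.0      # 15 voxels
        p[8:12, 8:11, 5] = 1e-5; t[8:12, 8:11, 5] = 4.0  # 12 voxels
        tab, lab = cluster_threshold(p, t, 0.001, 13)
        assert len(tab) == 1
        assert tab.iloc[0]["size"] == 15

    def test_connectivity_rule(self):
        """Two blobs touching only at a corner merge under 26- but not
        6-connectivity."""
        p = np.ones((8, 8, 8))
        t = np.zeros((8, 8, 8))
        p[0:2, 0:2, 0:2] = 1e-5; t[0:2, 0:2, 0:2] = 3.0
        p[2:4, 2:4, 2:4] = 1e-5; t[2:4, 2:4, 2:4] = 3.0
        tab6, _ = cluster_threshold(p, t, 0.001, 1, connectivity=6)
        tab26, _ = cluster_threshold(p, t, 0.001, 1, connectivity=26)
        assert len(tab6) == 2
        assert len(tab26) == 1

    def test_signs_separated(self):
        p = np.ones((6, 6, 6))
        t = np.zeros((6, 6, 6))
        p[0:3, 0, 0] = 1e-5; t[0:3, 0, 0] = 5.0
        p[3:6, 0, 0] = 1e-5; t[3:6, 0, 0] = -5.0
        tab, _ = cluster_threshold(p, t, 0.001, 1)
        assert sorted(tab.sign.tolist()) == [-1, 1]

    def test_invalid_connectivity(self):
        with pytest.raises(ValueError, match="connectivity"):
            cluster_threshold(np.ones((3, 3, 3)), np.zeros((3, 3, 3)), 0.01, 1,
                              connectivity=7)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=(10, 10, 10))
        t = rng.normal(size=(10, 10, 10))
        tab1, lab1 = cluster_threshold(p, t, 0.2, 3)
        tab2, lab2 = cluster_threshold(np.ascontiguousarray(p[::-1])[::-1], t, 0.2, 3)
        assert (lab1 > 0).sum() == (lab2 > 0).sum()


class TestSmoothing:
    def test_zero_fwhm_identity(self):
        mask = _ellipsoid_mask(100, (8, 8, 8))
        rng = np.random.default_rng(0)
        vol = rng.normal(size=(8, 8, 8))
        assert np.array_equal(smooth_gaussian(vol, 0.0, mask), vol)

    def test_impulse_fwhm(self):
        """A smoothed impulse has ~4 mm full width at half maximum."""
        mask = VolumeMask(np.ones((31, 31, 31), bool), AFF)
        vol = np.zeros((31, 31, 31))
        vol[15, 15, 15] = 1.0
        sm = smooth_gaussian(vol, 4.0, mask)
        prof = sm[:, 15, 15]
        # interpolate the half-maximum crossings
        half = prof.max() / 2
        above = np.flatnonzero(prof >= half)
        width_vox = above[-1] - above[0]
        assert abs(width_vox * 2.0 - 4.0) <= 1.0  # within half a voxel each side

    def test_constant_image_preserved(self):
        mask = _ellipsoid_mask(150, (10, 10, 10))
        out = smooth_gaussian(np.ones((10, 10, 10)), 4.0, mask)
        assert np.allclose(out[mask.data], 1.0, atol=1e-9)

    def test_negative_fwhm_raises(self):
        mask = _ellipsoid_mask(10, (4, 4, 4))
        with pytest.raises(ValueError):
            smooth_gaussian(np.zeros((4, 4, 4)), -1.0, mask)


class TestMaskUtils:
    def test_small_sphere_single_voxel(self):
        m = sphere_mask((5.0, 5.0, 5.0), 0.9, (6, 6, 6), AFF)
        assert m.n_voxels <= 1

    def test_sphere_radius_5mm(self):
        m = sphere_mask((10.0, 10.0, 10.0), 5.0, (11, 11, 11), AFF)
        xyz = m.coordinates_mm()
        assert (np.linalg.norm(xyz - 10.0, axis=1) <= 5.0 + 1e-9).all()
        assert m.n_voxels > 1

    def test_intersect_idempotent(self):
        m = _ellipsoid_mask(60, (6, 6, 6))
        assert np.array_equal(intersect(m, m).data, m.data)

    def test_intersect_grid_mismatch(self):
        a = _ellipsoid_mask(10, (4, 4, 4))
        b = VolumeMask(np.ones((5, 5, 5), bool), AFF)
        with pytest.raises(ValueError, match="grids"):
            intersect(a, b)

    def test_snr_erosion_exact(self):
        """Voxels built with SNR 16-40 are kept exactly when SNR >= 25."""
        rng = np.random.default_rng(4)
        snr_levels = np.linspace(16, 40, 64).reshape(4, 4, 4)
        noise = rng.normal(size=(4, 4, 4, 200))
        noise -= noise.mean(axis=3, keepdims=True)
        noise /= noise.std(axis=3, keepdims=True, ddof=1)
        series = snr_levels[..., None] + noise
        mask = VolumeMask(np.ones((4, 4, 4), bool), AFF)
        kept = snr_erode(mask, series, 25.0)
        assert np.array_equal(kept.data, snr_levels >= 25.0)


class TestVoxelBML:
    def _table(self, part, effect_label, n_pairs=18, seed=0, amp=0.5):
        rng = np.random.default_rng(seed)
        nv = len(part.labels)
        eff = np.where(part.labels == effect_label, amp, 0.0)
        shift = rng.normal(0, 0.2, n_pairs)
        rows = []
        for p in range(n_pairs):
            d = eff + shift[p] + rng.normal(0, 1.0, nv)
            rows += [{"pair": p, "voxel": v, "delta": d[v]} for v in range(nv)]
        return pd.DataFrame(rows)

    def test_recovers_injected_subroi(self):
        mask = _ellipsoid_mask(200, (10, 10, 4))
        part = kmeans_subrois(mask, 5, seed=1)
        tab = self._table(part, effect_label=2)
        res = fit_bml_voxel(tab, part, chains=2, draws=800, warmup=800, seed=0)
        inside = res.pplus[part.labels == 2]
        outside = res.pplus[part.labels != 2]
        assert np.median(inside) > 0.9
        assert 0.1 < np.median(outside) < 0.9
        assert res.max_rhat() <= 1.1

    def test_all_null_centered(self):
        mask = _ellipsoid_mask(120, (8, 8, 4))
        part = kmeans_subrois(mask, 4, seed=2)
        tab = self._table(part, effect_label=0, amp=0.0, seed=5)
        res = fit_bml_voxel(tab, part, chains=2, draws=300, warmup=300, seed=1)
        assert 0.25 < np.median(res.pplus) < 0.75

    def test_partition_coverage_required(self):
        mask = _ellipsoid_mask(50, (6, 6, 4))
        part = kmeans_subrois(mask, 3, seed=0)
        tab = pd.DataFrame({"pair": [0, 0], "voxel": [0, 1], "delta": [0.1, 0.2]})
        with pytest.raises(ValueError, match="cover"):
            InsulaVoxelBML(tab, part)
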