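"""Voxel-wise group statistics: masks, Welch maps, FDR, clusters, correlation."""

import numpy as np
import pytest
from scipy import stats

from tractfa import phantom, wbss
from tractfa.grids import ScalarMap, default_affine

SHAPE = (12, 12, 12)
AFF = default_affine((2, 2, 2), shape=SHAPE)


def _maps(stack):
    return [ScalarMap(s, AFF) for s in stack]


def brute_welch(a, b):
    """Scalar Welch-test oracle written independently of the vectorized path."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / se2 ** 0.5
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def brute_bh(pvals, alpha):
    """Step-up Benjamini-Hochberg rejection oracle (explicit loop)."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    k_max = 0
    for rank, i in enumerate(order, start=1):
        if pvals[i] <= alpha * rank / m:
            k_max = rank
    rejected = set(order[:k_max])
    return [i in rejected for i in range(m)]


class TestAnalysisMask:
    def test_constant_maps_full_or_empty(self):
        full = wbss.analysis_mask(_maps(np.full((3,) + SHAPE, 0.5)))
        empty = wbss.analysis_mask(_maps(np.full((3,) + SHAPE, 0.1)))
        assert full.all() and not empty.any()

    def test_tube_phantom_mask_matches_support(self, spec, cohort):
        maps = [phantom.sample_fa_map(spec, r)
                for _, r in cohort[cohort.timepoint == "baseline"].head(20).iterrows()]
        mask = wbss.analysis_mask(maps)
        support = phantom.geometry(spec).support_mask()
        dice = 2 * (mask & support).sum() / (mask.sum() + support.sum())
        assert dice > 0.9


class TestWelchMap:
    def test_identical_groups_give_null(self):
        rng = np.random.default_rng(0)
        stack = rng.random((4,) + SHAPE)
        t, p, _ = wbss.welch_map(_maps(stack), _maps(stack.copy()),
                                 np.ones(SHAPE, bool))
        assert np.abs(t.data).max() == 0.0
        assert np.all(p.data == 1.0)

    def test_hand_computed_example(self):
        """A={1,2,3,4}, B={3,4,5,6}: t ~ -2.191, df = 6."""
        a = np.array([1, 2, 3, 4.0])[:, None, None, None] * np.ones(SHAPE)
        b = np.array([3, 4, 5, 6.0])[:, None, None, None] * np.ones(SHAPE)
        t, df, p = wbss.welch_from_stacks(a, b)
        assert t[0, 0, 0] == pytest.approx(-2.1909, abs=1e-4)
        assert df[0, 0, 0] == pytest.approx(6.0, abs=1e-9)

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((5,) + SHAPE), rng.random((6,) + SHAPE)
        t1, p1, _ = wbss.welch_map(_maps(a), _maps(b), np.ones(SHAPE, bool))
        t2, p2, _ = wbss.welch_map(_maps(b), _maps(a), np.ones(SHAPE, bool))
        assert np.allclose(t1.data, -t2.data)
        assert np.allclose(p1.data, p2.data)

    def test_matches_bruteforce_at_random_voxels(self):
        rng = np.random.default_rng(2)
        a, b = rng.random((7,) + SHAPE), rng.random((5,) + SHAPE)
        t, df, p = wbss.welch_from_stacks(a, b)
        for _ in range(20):
            v = tuple(rng.integers(0, s) for s in SHAPE)
            ot, odf, op = brute_welch(list(a[(slice(None),) + v]),
                                      list(b[(slice(None),) + v]))
            assert t[v] == pytest.approx(ot, abs=1e-10)
            assert df[v] == pytest.approx(odf, abs=1e-10)
            assert p[v] == pytest.approx(op, abs=1e-10)


class TestFdr:
    def test_all_p_one_rejects_nothing(self):
        p = ScalarMap(np.ones(SHAPE), AFF, "p")
        _, rej = wbss.fdr_correct(p, np.ones(SHAPE, bool), 0.05)
        assert not rej.any()

    def test_bh_step_up_example(self):
        """p = {.01,.02,.03,.04} with m=4 at alpha=.05: all rejected."""
        data = np.ones(SHAPE)
        mask = np.zeros(SHAPE, bool)
        for i, pv in enumerate([0.01, 0.02, 0.03, 0.04]):
            data[i, 0, 0] = pv
            mask[i, 0, 0] = True
        _, rej = wbss.fdr_correct(ScalarMap(data, AFF, "p"), mask, 0.05)
        assert rej.sum() == 4
        assert brute_bh([0.01, 0.02, 0.03, 0.04], 0.05) == [True] * 4

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        data = rng.random(SHAPE)
        mask = rng.random(SHAPE) < 0.5
        _, rej = wbss.fdr_correct(ScalarMap(data, AFF, "p"), mask, 0.05)
        oracle = brute_bh(list(data[mask]), 0.05)
        assert list(rej[mask]) == oracle

    def test_single_voxel_q_equals_p(self):
        data = np.ones(SHAPE)
        data[0, 0, 0] = 0.03
        mask = np.zeros(SHAPE, bool)
        mask[0, 0, 0] = True
        q, _ = wbss.fdr_correct(ScalarMap(data, AFF, "p"), mask, 0.05)
        assert q.data[0, 0, 0] == pytest.approx(0.03)

    def test_q_monotone_in_p(self):
        rng = np.random.default_rng(4)
        data = rng.random(SHAPE)
        mask = np.ones(SHAPE, bool)
        q, _ = wbss.fdr_correct(ScalarMap(data, AFF, "p"), mask, 0.05)
        order = np.argsort(data.ravel())
        assert np.all(np.diff(q.data.ravel()[order]) >= -1e-12)


class TestClusterFilter:
    def _mask_with_component(self, n_voxels):
        m = np.zeros((20, 20, 20), dtype=bool)
        count = 0
        for i in range(20):
            for j in range(20):
                for k in range(20):
                    if count < n_voxels:
                        m[i // 4 + 5, j % 8 + 5, count % 8 + 5] = True
                        count += 1
        # simpler: fill a compact block
        m[:] = False
        flat = np.zeros(8000, dtype=bool)
        flat[:n_voxels] = True
        return flat.reshape((20, 20, 20))

    @pytest.mark.parametrize("size, kept", [(300, True), (256, True), (255, False)])
    def test_extent_threshold_256(self, size, kept):
        mask = self._mask_with_component(size)
        surviving, records = wbss.cluster_filter(mask, min_voxels=256)
        if kept:
            assert records[0].size_voxels == size
            assert surviving.sum() == size
        else:
            assert records == [] and surviving.sum() == 0

    def test_connectivity_choice_splits_touching_components(self):
        m = np.zeros((10, 10, 10), dtype=bool)
        m[2, 2, 2] = True
        m[3, 3, 3] = True        # diagonal touch: one cluster at 26-conn, two at 6-conn
        _, rec26 = wbss.cluster_filter(m, min_voxels=1, connectivity=3)
        _, rec6 = wbss.cluster_filter(m, min_voxels=1, connectivity=1)
        assert len(rec26) == 1 and len(rec6) == 2

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        m = rng.random((20, 20, 20)) < 0.3
        s1, r1 = wbss.cluster_filter(m, min_voxels=10)
        s2, r2 = wbss.cluster_filter(s1, min_voxels=10)
        assert np.array_equal(s1, s2)
        assert [c.size_voxels for c in r1] == [c.size_voxels for c in r2]

    def test_cluster_sizes_cross_checked(self, spec, cohort):
        """Reported voxel counts equal an independent labelled-voxel count."""
        from scipy import ndimage
        rng = np.random.default_rng(6)
        m = rng.random((20, 20, 20)) < 0.4
        surviving, records = wbss.cluster_filter(m, min_voxels=5)
        labels, n = ndimage.label(m, structure=np.ones((3, 3, 3)))
        sizes = sorted((labels == i).sum() for i in range(1, n + 1)
                       if (labels == i).sum() >= 5)
        assert sorted(c.size_voxels for c in records) == sizes


class TestCorrelationMap:
    def test_constant_scores_flagged_null(self):
        rng = np.random.default_rng(7)
        maps = _maps(rng.random((6,) + SHAPE))
        rep = wbss.correlation_map(maps, np.full(6, 3.0), np.ones(SHAPE, bool))
        assert np.all(rep.p_map.data == 1.0)
        assert rep.flagged_voxels == int(np.prod(SHAPE))

    def test_exact_linear_relation_gives_r_minus_one(self):
        scores = np.array([1, 2, 3, 4, 5.0])
        stack = (10 - 2 * scores)[:, None, None, None] * np.ones(SHAPE)
        r, p, _ = wbss.pearson_from_stack(stack, scores)
        assert np.allclose(r, -1.0)

    def test_matches_scipy_pearson_at_random_voxels(self):
        rng = np.random.default_rng(8)
        stack = rng.random((9,) + SHAPE)
        scores = rng.random(9)
        r, p, _ = wbss.pearson_from_stack(stack, scores)
        for _ in range(20):
            v = tuple(rng.integers(0, s) for s in SHAPE)
            orac = stats.pearsonr(stack[(slice(None),) + v], scores)
            assert r[v] == pytest.approx(orac.statistic, abs=1e-10)
            assert p[v] == pytest.approx(orac.pvalue, abs=1e-10)


class TestPeakSpheres:
    def _report_with_peak(self, peak_vox, mask=None):
        stat = np.zeros(SHAPE)
        stat[peak_vox] = 5.0
        sm = ScalarMap(stat, AFF, "t")
        mask = np.ones(SHAPE, bool) if mask is None else mask
        cl = wbss.ClusterRecord(tuple(sm.voxel_to_world(np.array(peak_vox))[0]),
                                10, 5.0, 1, 0.01)
        return wbss.StatReport(sm, sm.like(np.ones(SHAPE)), sm.like(np.ones(SHAPE)),
                               np.zeros(SHAPE, bool), np.zeros(SHAPE, bool),
                               [cl], mask)

    def test_radius_zero_is_single_voxel(self):
        rep = self._report_with_peak((6, 6, 6))
        rois = wbss.peak_spheres(rep, radius_mm=0.0)
        assert rois[0].sum() == 1

    def test_discrete_ball_count_at_5mm(self):
        """5 mm radius on a 2 mm grid: brute-force lattice count."""
        rep = self._report_with_peak((6, 6, 6))
        rois = wbss.peak_spheres(rep, radius_mm=5.0)
        count = 0
        for dx in range(-3, 4):
            for dy in range(-3, 4):
                for dz in range(-3, 4):
                    if (2 * dx) ** 2 + (2 * dy) ** 2 + (2 * dz) ** 2 <= 25:
                        count += 1
        assert rois[0].sum() == count == 81

    def test_sphere_clipped_to_mask(self):
        mask = np.zeros(SHAPE, bool)
        mask[6:, :, :] = True
        rep = self._report_with_peak((6, 6, 6), mask)
        rois = wbss.peak_spheres(rep, radius_mm=5.0)
        assert rois[0].sum() < 81
        assert not (rois[0] & ~mask).any()


class TestLongitudinal:
    def test_identical_timepoints_no_growth(self):
        rng = np.random.default_rng(9)
        base = rng.normal(0.5, 0.01, (6,) + SHAPE)
        sig = np.zeros(SHAPE)
        sig[4:8, 4:8, 4:8] = -0.2
        pat = _maps(base + sig)
        ctl = _maps(rng.normal(0.5, 0.01, (10,) + SHAPE))
        _, _, growth = wbss.longitudinal_compare(pat, [m for m in pat], ctl,
                                                 np.ones(SHAPE, bool),
                                                 min_voxels=10)
        assert (growth["growth"] == 0).all()

    def test_controls_vs_themselves_yield_no_clusters(self):
        rng = np.random.default_rng(10)
        ctl_stack = rng.normal(0.5, 0.01, (10,) + SHAPE)
        ctl = _maps(ctl_stack)
        r0, r1, growth = wbss.longitudinal_compare(ctl, ctl, ctl,
                                                   np.ones(SHAPE, bool),
                                                   min_voxels=10)
        assert len(r0.clusters) == 0 and len(r1.clusters) == 0 and len(growth) == 0
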