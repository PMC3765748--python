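import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats as sps

from painhub.connectivity import ZMap
from painhub.stats import (StatsError, cluster_report, covariate_regression_map,
                           extract_mean_z, label_clusters, paired_t_map,
                           permutation_cluster_correct, t_test_from_summary,
                           t_to_z, two_sample_t_map, z_to_t_threshold)


def _maps(arrs, shape=(1, 1, 1), affine=None, ids=None, cond=None):
    affine = np.eye(4) if affine is None else affine
    mask = np.ones(shape, bool)
    out = []
    for i, a in enumerate(arrs):
        out.append(ZMap(np.atleast_1d(np.asarray(a, float)), mask, affine,
                        subject_id=None if ids is None else ids[i],
                        condition=cond))
    return out


class TestTtoZ:
    def test_zero_maps_to_zero(self):
        for df in (1, 5, 100):
            assert t_to_z(0.0, df) == 0.0

    def test_antisymmetric(self):
        assert t_to_z(-2.0, 10) == pytest.approx(-t_to_z(2.0, 10))

    def test_large_df_limit(self):
        assert t_to_z(2.3, 10000) == pytest.approx(2.3, abs=0.05)

    def test_against_quadrature_oracle(self):
        # tail mass of t(df=10) beyond 2.0 by numeric integration
        df = 10
        pdf = lambda x: sps.t.pdf(x, df)
        tail, _ = integrate.quad(pdf, 2.0, np.inf)
        expected = sps.norm.isf(tail)
        assert t_to_z(2.0, df) == pytest.approx(expected, rel=1e-8)

    def test_monotone(self, rng):
        t = np.sort(rng.standard_normal(50) * 5)
        z = t_to_z(t, 8)
        assert np.all(np.diff(z) >= 0)

    def test_extreme_t_stays_finite(self):
        assert np.isfinite(t_to_z(500.0, 17))

    def test_threshold_roundtrip(self):
        t_thr = z_to_t_threshold(2.3, 17)
        assert t_to_z(t_thr, 17) == pytest.approx(2.3, rel=1e-9)


class TestTwoSampleTMap:
    def test_hand_computed_example(self):
        # pooled t for {1,2,3} vs {4,5,6}: diff -3, s_p = 1,
        # se = sqrt(2/3) -> t = -3.6742; cross-checked with scipy
        sm = two_sample_t_map(_maps([[1], [2], [3]]), _maps([[4], [5], [6]]))
        oracle = sps.ttest_ind([1, 2, 3], [4, 5, 6], equal_var=True)
        assert sm.t_values[0] == pytest.approx(-3.0 / np.sqrt(2 / 3), abs=1e-9)
        assert sm.t_values[0] == pytest.approx(oracle.statistic, abs=1e-12)
        assert sm.df == 4

    def test_identical_groups_give_zero(self, rng):
        arrs = [rng.standard_normal(5) for _ in range(4)]
        sm = two_sample_t_map(_maps(arrs, (5, 1, 1)), _maps(arrs, (5, 1, 1)))
        assert np.allclose(sm.t_values, 0.0)

    def test_group_swap_negates(self, rng):
        A = [rng.standard_normal(6) for _ in range(4)]
        B = [rng.standard_normal(6) for _ in range(5)]
        t1 = two_sample_t_map(_maps(A, (6, 1, 1)), _maps(B, (6, 1, 1))).t_values
        t2 = two_sample_t_map(_maps(B, (6, 1, 1)), _maps(A, (6, 1, 1))).t_values
        assert np.allclose(t1, -t2)

    def test_constant_shift_invariance(self, rng):
        A = [rng.standard_normal(6) for _ in range(3)]
        B = [rng.standard_normal(6) for _ in range(3)]
        t1 = two_sample_t_map(_maps(A, (6, 1, 1)), _maps(B, (6, 1, 1))).t_values
        t2 = two_sample_t_map(_maps([a + 5 for a in A], (6, 1, 1)),
                              _maps([b + 5 for b in B], (6, 1, 1))).t_values
        assert np.allclose(t1, t2, atol=1e-9)

    def test_mask_mismatch_rejected(self, rng):
        A = _maps([rng.standard_normal(4) for _ in range(2)], (4, 1, 1))
        B = _maps([rng.standard_normal(8) for _ in range(2)], (8, 1, 1))
        with pytest.raises(StatsError):
            two_sample_t_map(A, B)


class TestPairedTMap:
    def test_hand_computed_example(self):
        c1 = _maps([[2], [4], [6]])
        c2 = _maps([[1], [2], [3]])
        sm = paired_t_map(c1, c2)  # differences 1, 2, 3
        assert sm.t_values[0] == pytest.approx(3.4641, abs=1e-4)
        assert sm.df == 2

    def test_identical_conditions_zero(self, rng):
        arrs = [rng.standard_normal(4) for _ in range(3)]
        sm = paired_t_map(_maps(arrs, (4, 1, 1)), _maps(arrs, (4, 1, 1)))
        assert np.allclose(sm.t_values, 0.0)

    def test_zero_variance_difference_guarded(self):
        c1 = _maps([[1.0], [2.0], [3.0]])
        c2 = _maps([[2.0], [3.0], [4.0]])  # constant difference -1
        with pytest.warns(UserWarning):
            sm = paired_t_map(c2, c1)
        assert sm.t_values[0] == 0.0 and sm.z_values[0] == 0.0

    def test_subject_mismatch_rejected(self):
        c1 = _maps([[1], [2]], ids=["s1", "s2"])
        c2 = _maps([[1], [2]], ids=["s2", "s1"])
        with pytest.raises(StatsError):
            paired_t_map(c1, c2)


class TestCovariateRegression:
    def test_zero_maps_give_zero_slope(self):
        maps = _maps([[0], [0], [0], [0]])
        sm = covariate_regression_map(maps, [1, 2, 3, 4])
        assert sm.t_values[0] == 0.0

    def test_constant_covariate_rejected(self):
        with pytest.raises(StatsError):
            covariate_regression_map(_maps([[1], [2], [3]]), [2, 2, 2])

    def test_slope_recovery_simulation(self):
        # delta_z = 0.5 * delta_rating + noise(sd 0.1), n=18: the fitted
        # slope should fall in [0.4, 0.6] in >= 95% of seeded replicates
        rng = np.random.default_rng(2024)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            x = rng.uniform(0, 6, 18)
            y = 0.5 * x + rng.normal(0, 0.1, 18)
            slope = np.polyfit(x, y, 1)[0]
            maps = _maps([[v] for v in y])
            sm = covariate_regression_map(maps, x)
            # same slope sign and t as direct least squares
            assert np.sign(sm.t_values[0]) == np.sign(slope)
            hits += 0.4 <= slope <= 0.6
        assert hits / n_rep >= 0.95


def _bfs_clusters(binary, connectivity):
    """Independent flood-fill labeling used as the oracle."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    seen = np.zeros(binary.shape, bool)
    comps = []
    for start in zip(*np.nonzero(binary)):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            p = stack.pop()
            comp.append(p)
            for off in offsets:
                q = tuple(np.array(p) + off)
                if any(c < 0 or c >= s for c, s in zip(q, binary.shape)):
                    continue
                if binary[q] and not seen[q]:
                    seen[q] = True
                    stack.append(q)
        comps.append(set(comp))
    return comps


class TestLabelClusters:
    def test_subthreshold_field_has_no_clusters(self, rng):
        z = rng.standard_normal((6, 6, 6)) * 0.5
        labels, sizes = label_clusters(z, 2.3, 1)
        assert labels.max() == 0 and len(sizes) == 0

    def test_two_disjoint_blocks(self):
        z = np.zeros((12, 12, 12))
        z[1:4, 1:4, 1:4] = 4.0
        z[8:11, 8:11, 8:11] = 4.0
        labels, sizes = label_clusters(z, 2.3, 10)
        assert len(sizes) == 2 and list(sizes) == [27, 27]

    def test_min_voxel_filter(self):
        z = np.zeros((10, 10, 10))
        z[0, 0, 0:5] = 4.0       # 5-voxel component, below the floor
        z[5:8, 5:8, 5:8] = 4.0   # 27-voxel component
        labels, sizes = label_clusters(z, 2.3, 10)
        assert list(sizes) == [27]
        assert labels[0, 0, 0] == 0

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_bfs_oracle(self, connectivity, rng):
        z = rng.standard_normal((10, 10, 8)) * 2.0
        labels, sizes = label_clusters(z, 2.3, 1, connectivity)
        ours = [set(zip(*np.nonzero(labels == k))) for k in range(1, labels.max() + 1)]
        oracle = _bfs_clusters(z > 2.3, connectivity)
        assert sorted(map(len, ours)) == sorted(map(len, oracle))
        for comp in ours:
            assert comp in oracle

    def test_labels_sorted_by_size(self):
        z = np.zeros((20, 8, 8))
        z[0:2, 0:2, 0:2] = 4.0      # 8 voxels
        z[10:13, 0:3, 0:3] = 4.0    # 27 voxels
        labels, sizes = label_clusters(z, 2.3, 1)
        assert list(sizes) == [27, 8]
        assert labels[11, 1, 1] == 1 and labels[0, 0, 0] == 2


class TestClusterReport:
    def _statmap(self, zvol, affine):
        from painhub.stats import StatMap
        mask = np.ones(zvol.shape, bool)
        return StatMap(zvol[mask], zvol[mask], 10, "test", mask, affine)

    def test_mm3_arithmetic_on_4mm_grid(self):
        affine = np.diag([4.0, 4.0, 4.0, 1.0])
        z = np.zeros((8, 8, 8))
        z[2:5, 2:5, 2:5] = 4.0
        sm = self._statmap(z, affine)
        labels, _ = label_clusters(z, 2.3, 1)
        rep = cluster_report(sm, labels, affine)
        assert rep.loc[0, "cluster_mm3"] == pytest.approx(27 * 64.0)
        # the published 7360 mm^3 cluster corresponds to 115 4-mm voxels
        assert 7360 / 64.0 == 115

    def test_peak_world_coordinate(self):
        affine = np.diag([4.0, 4.0, 4.0, 1.0])
        affine[:3, 3] = [-40, -40, -20]
        z = np.zeros((12, 12, 8))
        z[10, 5, 2] = 5.0
        sm = self._statmap(z, affine)
        labels, _ = label_clusters(z, 2.3, 1)
        rep = cluster_report(sm, labels, affine)
        expected = affine @ np.array([10, 5, 2, 1.0])
        assert np.allclose(rep.loc[0, ["x", "y", "z"]].to_numpy(float), expected[:3])

    def test_zmax_tie_broken_by_lowest_linear_index(self):
        affine = np.eye(4)
        z = np.zeros((6, 6, 6))
        z[1, 1, 1] = 4.0
        z[1, 1, 2] = 4.0
        sm = self._statmap(z, affine)
        labels, _ = label_clusters(z, 2.3, 1)
        rep = cluster_report(sm, labels, affine)
        assert tuple(rep.loc[0, ["x", "y", "z"]]) == (1, 1, 1)


class TestPermutationCorrection:
    def _groups(self, rng, delta, shape=(8, 8, 6), n=8):
        mask = np.ones(shape, bool)
        bump = np.zeros(shape)
        bump[2:6, 2:6, 2:4] = delta
        A = [ZMap((rng.standard_normal(shape) * 0.5 + bump)[mask], mask, np.eye(4))
             for _ in range(n)]
        B = [ZMap((rng.standard_normal(shape) * 0.5)[mask], mask, np.eye(4))
             for _ in range(n)]
        return A, B

    def test_p_floor_when_observed_beats_all_perms(self, rng):
        A, B = self._groups(rng, 5.0)
        res = permutation_cluster_correct(A, "two_sample", maps_b=B,
                                          n_perm=99, seed=1)
        assert len(res.table) >= 1
        assert res.table["cluster_p"].min() == pytest.approx(1 / 100)

    def test_pvalues_within_bounds(self, rng):
        A, B = self._groups(rng, 1.0)
        res = permutation_cluster_correct(A, "two_sample", maps_b=B,
                                          n_perm=99, seed=2)
        if len(res.candidates):
            p = res.candidates["cluster_p"]
            assert ((p >= 1 / 100) & (p <= 1.0)).all()

    def test_paired_detects_planted_shift(self, rng):
        mask = np.ones((8, 8, 6), bool)
        bump = np.zeros((8, 8, 6)); bump[2:6, 2:6, 2:4] = 3.0
        ids = [f"s{i}" for i in range(8)]
        c1 = [ZMap((rng.standard_normal((8, 8, 6)) * 0.5 + bump)[mask], mask,
                   np.eye(4), subject_id=ids[i]) for i in range(8)]
        c2 = [ZMap((rng.standard_normal((8, 8, 6)) * 0.5)[mask], mask,
                   np.eye(4), subject_id=ids[i]) for i in range(8)]
        res = permutation_cluster_correct(c1, "paired", maps_b=c2,
                                          n_perm=199, seed=3)
        assert len(res.table) >= 1
        assert (res.clusters > 0)[2:6, 2:6, 2:4].any()

    def test_regression_needs_covariate(self, rng):
        A, _ = self._groups(rng, 0.0)
        with pytest.raises(StatsError):
            permutation_cluster_correct(A, "regression", n_perm=99, seed=0)

    def test_too_few_subjects_rejected(self, rng):
        A, B = self._groups(rng, 0.0, n=1)
        with pytest.raises(StatsError):
            permutation_cluster_correct(A, "two_sample", maps_b=B, n_perm=99,
                                        seed=0)

    def test_low_n_perm_rejected(self, rng):
        A, B = self._groups(rng, 0.0)
        with pytest.raises(StatsError):
            permutation_cluster_correct(A, "two_sample", maps_b=B, n_perm=50,
                                        seed=0)


class TestExtractMeanZ:
    def test_constant_map_over_cluster(self):
        mask = np.ones((4, 4, 4), bool)
        maps = [ZMap(np.full(64, 2.0), mask, np.eye(4), subject_id="a")]
        cluster = np.zeros((4, 4, 4), bool)
        cluster[1:3, 1:3, 1:3] = True
        out = extract_mean_z(maps, cluster)
        assert out.loc[0, "mean_z"] == 2.0

    def test_single_voxel_cluster(self, rng):
        mask = np.ones((3, 3, 3), bool)
        vals = rng.standard_normal(27)
        maps = [ZMap(vals, mask, np.eye(4))]
        cluster = np.zeros((3, 3, 3), bool)
        cluster[1, 2, 0] = True
        vol = maps[0].to_volume()
        assert extract_mean_z(maps, cluster).loc[0, "mean_z"] == vol[1, 2, 0]

    def test_empty_cluster_rejected(self):
        mask = np.ones((3, 3, 3), bool)
        maps = [ZMap(np.zeros(27), mask, np.eye(4))]
        with pytest.raises(StatsError):
            extract_mean_z(maps, np.zeros((3, 3, 3), bool))


class TestSummaryTTest:
    def test_equal_means_give_p_one(self):
        t, df, p = t_test_from_summary(5863, 1029, 18, 5863, 1198, 18)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_top_third_volumes(self):
        t, df, p = t_test_from_summary(5416, 932, 18, 4781, 783, 18)
        assert df == 34
        assert p == pytest.approx(0.033, abs=0.005)

    def test_total_volume_not_significant(self):
        _, _, p = t_test_from_summary(16977, 2868, 18, 16198, 2739, 18)
        assert p > 0.05

    def test_welch_close_to_pooled_for_similar_sds(self):
        tp, _, pp = t_test_from_summary(10, 2, 20, 9, 2.1, 20)
        tw, _, pw = t_test_from_summary(10, 2, 20, 9, 2.1, 20, pooled=False)
        assert tp == pytest.approx(tw, rel=1e-6)
        assert pp == pytest.approx(pw, rel=1e-2)

    def test_zero_variance_unequal_means_undefined(self):
        with pytest.raises(StatsError):
            t_test_from_summary(5, 0, 10, 6, 0, 10)
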