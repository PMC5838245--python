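import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seedconn.core import DataError, StatsError
from seedconn.group import (
    ClusterResult,
    GroupModelSpec,
    PermutationConfig,
    extract_cluster_values,
    label_clusters,
    paired_change_test,
    permutation_cluster_fwe,
    planned_group_comparison,
    summary_two_sample_t,
    voxelwise_group_contrast,
)


class Map:
    def __init__(self, data):
        self.data = np.asarray(data, dtype=float)


def make_table(n1, n2, rng, with_drug=True):
    n = n1 + n2
    d = {
        "subject_id": [f"sub-{i:03d}" for i in range(n)],
        "remitter": [1] * n1 + [0] * n2,
        "age": rng.normal(30, 8, n),
        "duration_mdd": rng.normal(10, 5, n),
        "hrsd17_baseline": rng.normal(21, 3, n),
    }
    if with_drug:
        d["drug"] = [("escitalopram", "sertraline", "venlafaxine")[i % 3]
                     for i in range(n)]
    return pd.DataFrame(d)


class TestVoxelwiseContrast:
    def test_matches_two_sample_t_without_covariates(self, rng):
        n1 = n2 = 12
        table = make_table(n1, n2, rng)
        maps = [Map(rng.normal(size=(4, 4, 4))) for _ in range(n1 + n2)]
        sm, shape = voxelwise_group_contrast(
            maps, table, GroupModelSpec(covariates=()))
        g1 = np.stack([m.data.ravel() for m in maps[:n1]])
        g2 = np.stack([m.data.ravel() for m in maps[n1:]])
        expected = stats.ttest_ind(g1, g2, axis=0).statistic
        assert sm.values == pytest.approx(expected, rel=1e-8)
        assert sm.df == n1 + n2 - 2

    def test_null_calibration(self, rng):
        n1 = n2 = 20
        table = make_table(n1, n2, rng)
        maps = [Map(rng.normal(size=(10, 10, 10))) for _ in range(n1 + n2)]
        sm, _ = voxelwise_group_contrast(maps, table)
        p = 2 * stats.t.sf(np.abs(sm.values), sm.df)
        assert np.mean(p < 0.05) == pytest.approx(0.05, abs=0.02)

    def test_planted_difference_peaks_in_region(self, rng):
        hits = 0
        for rep in range(20):
            r = np.random.default_rng(rep)
            table = make_table(15, 15, r)
            base = [r.normal(size=(6, 6, 6)) for _ in range(30)]
            for i in range(15):
                base[i][2:4, 2:4, 2:4] += 1.5
            sm, shape = voxelwise_group_contrast([Map(b) for b in base], table)
            peak = np.unravel_index(np.argmax(sm.values), shape)
            if all(2 <= c < 4 for c in peak):
                hits += 1
        assert hits >= 19

    def test_interaction_f_null(self, rng):
        table = make_table(18, 18, rng)
        maps = [Map(rng.normal(size=(5, 5, 5))) for _ in range(36)]
        sm, _ = voxelwise_group_contrast(
            maps, table, GroupModelSpec(drug_interaction=True))
        assert sm.kind == "F"
        assert sm.df_num == 2
        p = stats.f.sf(sm.values, sm.df_num, sm.df)
        assert np.mean(p < 0.05) == pytest.approx(0.05, abs=0.03)

    def test_rank_deficient_design_rejected(self, rng):
        table = make_table(10, 10, rng)
        table["duration_mdd"] = table["age"]
        maps = [Map(rng.normal(size=(3, 3, 3))) for _ in range(20)]
        with pytest.raises(StatsError):
            voxelwise_group_contrast(maps, table)


def flood_fill_oracle(binary, connectivity26=True):
    """Brute-force connected components by BFS."""
    binary = np.asarray(binary, dtype=bool)
    visited = np.zeros_like(binary)
    comps = []
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
               for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)
               and (connectivity26 or abs(i) + abs(j) + abs(k) == 1)]
    for idx in zip(*np.nonzero(binary)):
        if visited[idx]:
            continue
        stack, comp = [idx], []
        visited[idx] = True
        while stack:
            cur = stack.pop()
            comp.append(cur)
            for off in offsets:
                nb = tuple(c + o for c, o in zip(cur, off))
                if all(0 <= c < s for c, s in zip(nb, binary.shape)) \
                        and binary[nb] and not visited[nb]:
                    visited[nb] = True
                    stack.append(nb)
        comps.append(len(comp))
    return sorted(comps)


class TestClusterLabeling:
    @pytest.mark.parametrize("scheme", ["face", "corner"])
    def test_matches_flood_fill_oracle(self, rng, scheme):
        structure = PermutationConfig(connectivity_scheme=scheme).structure()
        for _ in range(25):
            stat = rng.normal(size=(6, 7, 5))
            labels, extents = label_clusters(stat, 0.8, structure)
            assert sorted(extents) == flood_fill_oracle(
                stat > 0.8, connectivity26=(scheme == "corner"))


def strong_effect_maps(rng, n1=12, n2=12, shape=(6, 6, 6)):
    maps = [rng.normal(size=shape) for _ in range(n1 + n2)]
    for i in range(n1):
        maps[i][1:4, 1:4, 1:4] += 4.0
    return [Map(m) for m in maps]


class TestPermutationFwe:
    def test_minimum_p_with_add_one_rule(self, rng):
        table = make_table(12, 12, rng)
        maps = strong_effect_maps(rng)
        cfg = PermutationConfig(n_permutations=199, fwe_alpha=0.05, rng_seed=0)
        _, clusters, null = permutation_cluster_fwe(maps, table,
                                                    GroupModelSpec(), cfg)
        best = min(clusters, key=lambda c: c.fwe_p)
        assert best.fwe_p == pytest.approx(1 / 200)
        assert best.retained
        assert all(1 / 200 <= c.fwe_p <= 1.0 for c in clusters)

    def test_subject_order_invariance(self, rng):
        table = make_table(12, 12, rng)
        maps = strong_effect_maps(rng)
        cfg = PermutationConfig(n_permutations=149, fwe_alpha=0.05, rng_seed=5)
        _, c1, _ = permutation_cluster_fwe(maps, table, GroupModelSpec(), cfg)
        perm = rng.permutation(len(table))
        table2 = table.iloc[perm].reset_index(drop=True)
        maps2 = [maps[i] for i in perm]
        _, c2, _ = permutation_cluster_fwe(maps2, table2, GroupModelSpec(), cfg)
        assert [(c.extent, c.fwe_p, c.peak_ijk) for c in c1] == \
               [(c.extent, c.fwe_p, c.peak_ijk) for c in c2]

    def test_no_clusters_is_empty_list(self, rng):
        table = make_table(10, 10, rng)
        maps = [Map(np.zeros((4, 4, 4))) for _ in range(20)]
        maps = [Map(rng.normal(scale=0.01, size=(4, 4, 4))) for _ in range(20)]
        cfg = PermutationConfig(n_permutations=100, rng_seed=1)
        _, clusters, _ = permutation_cluster_fwe(maps, table,
                                                 GroupModelSpec(), cfg)
        for c in clusters:
            assert not c.retained

    def test_global_null_fwe_calibration_with_covariate_effects(self):
        # Freedman-Lane must keep family-wise type-I error near alpha even
        # when covariates truly influence the maps
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(rep + 10_000)
            table = make_table(10, 10, rng)
            age = table["age"].to_numpy()
            maps = []
            for i in range(20):
                m = rng.normal(size=(6, 6, 6))
                m += 0.05 * (age[i] - age.mean())  # covariate effect, no group effect
                maps.append(Map(m))
            cfg = PermutationConfig(n_permutations=199, cluster_forming_p=0.01,
                                    fwe_alpha=0.05, rng_seed=rep)
            _, clusters, _ = permutation_cluster_fwe(maps, table,
                                                     GroupModelSpec(), cfg)
            if any(c.fwe_p <= 0.05 for c in clusters):
                hits += 1
        assert 0.02 <= hits / n_rep <= 0.09


class TestExtractClusterValues:
    def test_single_voxel_cluster(self, rng):
        maps = [Map(rng.normal(size=(3, 3, 3))) for _ in range(4)]
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 2, 0] = True
        vals = extract_cluster_values(mask, maps)
        assert vals == pytest.approx([m.data[1, 2, 0] for m in maps])

    def test_uniform_map(self):
        maps = [Map(np.full((3, 3, 3), 2.5))]
        mask = np.ones((3, 3, 3), dtype=bool)
        assert extract_cluster_values(mask, maps)[0] == pytest.approx(2.5)

    def test_matches_brute_force_mean(self, rng):
        maps = [Map(rng.normal(size=(4, 4, 4))) for _ in range(6)]
        mask = rng.random((4, 4, 4)) > 0.6
        mask[0, 0, 0] = True
        vals = extract_cluster_values(mask, maps)
        for v, m in zip(vals, maps):
            acc = [m.data[i, j, k] for i in range(4) for j in range(4)
                   for k in range(4) if mask[i, j, k]]
            assert v == pytest.approx(np.mean(acc))

    def test_missing_session_flagged_nan(self, rng):
        maps = [Map(rng.normal(size=(3, 3, 3))), None]
        mask = np.ones((3, 3, 3), dtype=bool)
        vals = extract_cluster_values(mask, maps)
        assert np.isnan(vals[1]) and np.isfinite(vals[0])


class TestPlannedComparison:
    def test_d_t_identity_without_covariate(self, rng):
        v1 = rng.normal(1.0, 1.0, 20)
        v0 = rng.normal(0.0, 1.0, 25)
        res = planned_group_comparison(np.concatenate([v1, v0]),
                                       [1] * 20 + [0] * 25)
        t, _, _ = summary_two_sample_t(v0.mean(), v0.std(ddof=1), 25,
                                       v1.mean(), v1.std(ddof=1), 20)
        assert res["t"] == pytest.approx(t, rel=1e-10)
        assert res["d"] == pytest.approx(res["t"] * np.sqrt(1 / 20 + 1 / 25))

    def test_null_behavior(self):
        ps, ds = [], []
        for rep in range(200):
            rng = np.random.default_rng(rep)
            vals = rng.normal(size=30)
            res = planned_group_comparison(vals, [1] * 15 + [0] * 15,
                                           age=rng.normal(30, 5, 30))
            ps.append(res["p"])
            ds.append(res["d"])
        assert abs(np.mean(ds)) < 0.15
        assert 0.35 < np.mean(ps) < 0.65  # uniform p has mean 0.5

    def test_planted_d_recovered(self):
        est = []
        for rep in range(200):
            rng = np.random.default_rng(500 + rep)
            v1 = rng.normal(1.2, 1.0, 38)
            v0 = rng.normal(0.0, 1.0, 31)
            res = planned_group_comparison(
                np.concatenate([v1, v0]), [1] * 38 + [0] * 31,
                age=rng.normal(30, 5, 69))
            est.append(res["d"])
        inside = np.mean([(0.7 <= d <= 1.7) for d in est])
        assert inside >= 0.9
        assert np.mean(est) == pytest.approx(1.2, abs=0.1)

    def test_small_group_rejected(self):
        with pytest.raises(StatsError):
            planned_group_comparison([1, 2, 3, 4], [1, 1, 0, 0])


class TestPairedChange:
    def test_no_change(self, rng):
        pre = rng.normal(size=10)
        res = paired_change_test(pre, pre.copy())
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_equivalent_to_one_sample_t(self, rng):
        pre = rng.normal(size=15)
        post = pre + rng.normal(0.3, 0.2, 15)
        res = paired_change_test(pre, post)
        ref = stats.ttest_1samp(post - pre, 0.0)
        assert res["t"] == pytest.approx(ref.statistic)
        assert res["p"] == pytest.approx(ref.pvalue)

    def test_planted_shift_power(self):
        hits = 0
        for rep in range(50):
            rng = np.random.default_rng(rep)
            pre = rng.normal(0.2, 0.3, 38)
            post = pre + rng.normal(0.2, 0.2, 38)
            if paired_change_test(pre, post)["p"] < 0.05:
                hits += 1
        assert hits >= 45

    def test_too_few_pairs(self):
        with pytest.raises(StatsError):
            paired_change_test([1, 2], [2, 3])


class TestSummaryT:
    def test_table_1a_age(self):
        t, df, p = summary_two_sample_t(34.98, 13.69, 38, 28.34, 7.10, 37)
        assert t == pytest.approx(-2.63, abs=0.01)
        assert df == 73

    def test_table_1a_duration(self):
        t, _, _ = summary_two_sample_t(14.61, 13.26, 38, 8.32, 6.48, 37)
        assert t == pytest.approx(-2.60, abs=0.01)

    def test_equal_means(self):
        t, _, p = summary_two_sample_t(5.0, 1.0, 10, 5.0, 1.2, 12)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_invalid_inputs(self):
        with pytest.raises(StatsError):
            summary_two_sample_t(1, 0.0, 10, 2, 1.0, 10)
        with pytest.raises(StatsError):
            summary_two_sample_t(1, 1.0, 1, 2, 1.0, 10)
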