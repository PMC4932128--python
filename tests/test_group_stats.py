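"""Group statistics: AUC, rank tests, z maps, smoothing, permutation maps,
voxel-wise correlation, cluster filtering."""

import itertools

import numpy as np
import pytest
from scipy import stats

from tauquant.group_stats import (
    BONFERRONI_ALPHA_3G_2ROI,
    abnormality_count_map,
    cluster_filter,
    kruskal_mannwhitney,
    permutation_twosample,
    roc_auc,
    roi_correlation_matrix,
    smooth_image,
    voxelwise_correlation,
    zscore_map,
)


class TestRocAuc:
    def test_perfect_separation(self):
        v = np.array([1, 2, 3, 10, 11, 12.0])
        l = np.array([0, 0, 0, 1, 1, 1])
        assert roc_auc(v, l) == 1.0

    def test_chance_level_for_independent_labels(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=4000)
        l = rng.integers(0, 2, size=4000)
        assert roc_auc(v, l) == pytest.approx(0.5, abs=0.03)

    def test_ties_match_exhaustive_pair_counting(self):
        v = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 2.0, 6.0])
        l = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        pairs = sum(
            1.0 if a > b else 0.5 if a == b else 0.0
            for a in v[l == 1]
            for b in v[l == 0]
        )
        assert roc_auc(v, l) == pytest.approx(pairs / 16)

    def test_label_inversion_complements_auc(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=30)
        l = (rng.uniform(size=30) > 0.4).astype(int)
        assert roc_auc(v, l) == pytest.approx(1.0 - roc_auc(v, 1 - l))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(4.0), np.zeros(4, int))

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        v = rng.normal(size=50)
        l = (rng.uniform(size=50) > 0.5).astype(int)
        assert roc_auc(v, l) == pytest.approx(roc_auc_score(l, v))


class TestRankTests:
    def test_identical_groups_produce_no_flags(self):
        g = {k: np.array([1.0, 2, 3, 4, 5]) for k in ("a", "b", "c")}
        res = kruskal_mannwhitney(g)
        assert not any(p["significant"] for p in res["pairwise"].values())

    def test_corrected_alpha_for_three_groups_two_rois(self):
        assert BONFERRONI_ALPHA_3G_2ROI == pytest.approx(0.05 / 6)
        assert round(BONFERRONI_ALPHA_3G_2ROI, 3) == 0.008

    def test_mannwhitney_p_matches_exhaustive_enumeration(self):
        a = np.array([1.3, 2.1, 0.7])
        b = np.array([3.4, 2.9, 4.0])
        res = kruskal_mannwhitney({"a": a, "b": b})
        p = res["pairwise"][("a", "b")]["p"]
        # enumerate all 20 assignments of the pooled ranks to group a
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)

        def ustat(idx):
            r = ranks[list(idx)].sum()
            return r - 3 * 4 / 2

        u_obs = ustat([0, 1, 2])
        u_all = [ustat(c) for c in itertools.combinations(range(6), 3)]
        extreme = np.mean(
            [min(u, 9 - u) <= min(u_obs, 9 - u_obs) for u in u_all]
        )
        assert p == pytest.approx(extreme)

    def test_clearly_separated_groups_flagged(self):
        res = kruskal_mannwhitney(
            {
                "hc": np.array([1.0, 1.02, 1.04, 1.01, 1.03, 1.02, 1.0]),
                "ad": np.array([1.3, 1.35, 1.28, 1.4, 1.32, 1.31, 1.29]),
            }
        )
        assert res["pairwise"][("hc", "ad")]["significant"]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_mannwhitney({"a": np.array([1.0]), "b": np.array([1.0, 2.0])})


class TestZScoreMaps:
    def test_patient_equal_to_control_mean_flags_nothing(self):
        mean = np.full((6, 6, 6), 1.2)
        sd = np.full((6, 6, 6), 0.1)
        _, flagged = zscore_map(mean, mean, sd)
        assert not flagged.any()

    def test_patient_two_sd_above_mean_flags_everything_at_1p96(self):
        mean = np.full((6, 6, 6), 1.2)
        sd = np.full((6, 6, 6), 0.1)
        zmap, flagged = zscore_map(mean + 2 * sd, mean, sd, z_threshold=1.96)
        assert flagged.all()
        assert np.allclose(zmap.values, 2.0)

    def test_control_like_subject_flags_upper_tail_fraction(self):
        rng = np.random.default_rng(3)
        mean = np.zeros((40, 40, 40))
        sd = np.ones((40, 40, 40))
        _, flagged = zscore_map(rng.normal(size=mean.shape), mean, sd)
        # one-sided: P(z > 1.96) = 2.4998 %
        assert flagged.mean() == pytest.approx(0.025, abs=0.002)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            zscore_map(np.zeros((3, 3, 3)), np.zeros((4, 4, 4)), np.ones((4, 4, 4)))


class TestCountMap:
    def test_all_zero_inputs(self):
        out = abnormality_count_map([np.zeros((3, 3, 3), bool)] * 4)
        assert not out.values.any()

    def test_identical_all_one_maps_count_to_n(self):
        out = abnormality_count_map([np.ones((3, 3, 3), bool)] * 5)
        assert np.all(out.values == 5)

    def test_random_maps_match_brute_force_sum(self):
        rng = np.random.default_rng(4)
        maps = [rng.uniform(size=(5, 5, 5)) > 0.5 for _ in range(7)]
        out = abnormality_count_map(maps)
        brute = np.zeros((5, 5, 5), int)
        for m in maps:
            for idx in zip(*np.nonzero(m)):
                brute[idx] += 1
        assert np.array_equal(out.values, brute)
        assert out.values.max() <= 7


class TestSmoothing:
    def test_zero_fwhm_is_identity(self):
        vol = np.random.default_rng(5).normal(size=(8, 8, 8))
        assert np.array_equal(smooth_image(vol, 0.0), vol)

    def test_total_activity_conserved_away_from_edges(self):
        vol = np.zeros((32, 32, 32))
        vol[12:20, 12:20, 12:20] = 1.0
        out = smooth_image(vol, 8.0, (2.0, 2.0, 2.0))
        assert out.sum() == pytest.approx(vol.sum(), rel=1e-6)

    def test_delta_input_yields_requested_fwhm(self):
        vol = np.zeros((41, 41, 41))
        vol[20, 20, 20] = 1.0
        fwhm_mm, vox = 8.0, 2.0
        out = smooth_image(vol, fwhm_mm, (vox,) * 3)
        profile = out[:, 20, 20]
        half = profile.max() / 2
        above = np.nonzero(profile >= half)[0]
        # linear interpolation at the half-maximum crossings
        lo, hi = above[0], above[-1]
        f = lambda a, b: (profile[a] - half) / (profile[a] - profile[b])
        width_vox = (hi + f(hi, hi + 1)) - (lo - f(lo, lo - 1))
        assert width_vox * vox == pytest.approx(fwhm_mm, rel=0.05)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth_image(np.zeros((3, 3, 3)), -1.0)


class TestPermutationMaps:
    def test_sampled_matches_exhaustive_for_3v3(self):
        rng = np.random.default_rng(6)
        a = [rng.normal(size=(4, 4, 4)) for _ in range(3)]
        b = [rng.normal(size=(4, 4, 4)) for _ in range(3)]
        res = permutation_twosample(a, b, n_permutations=10_000, seed=0)
        assert res["p"].meta["exhaustive"]
        assert res["p"].meta["n_permutations_used"] == 20
        # p-values are multiples of 1/20 and never below 1/20
        p = res["p"].values.ravel()
        assert np.all(p >= 1 / 20 - 1e-12)
        assert np.allclose(np.round(p * 20), p * 20)

    def test_huge_shift_flags_all_voxels(self):
        rng = np.random.default_rng(7)
        a = [rng.normal(size=(5, 5, 5)) for _ in range(4)]
        b = [rng.normal(size=(5, 5, 5)) + 10.0 for _ in range(4)]
        res = permutation_twosample(a, b, n_permutations=200, seed=0, fdr_q=0.05)
        assert res["mask"].values.all()

    def test_fdr_mask_subset_of_uncorrected(self):
        rng = np.random.default_rng(8)
        a = [rng.normal(size=(8, 8, 8)) for _ in range(5)]
        b = [rng.normal(size=(8, 8, 8)) + 0.8 for _ in range(5)]
        res = permutation_twosample(a, b, n_permutations=300, seed=1)
        assert not (res["mask"].values & ~(res["p"].values < 0.05)).any()

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(9)
        a = [rng.normal(size=(4, 4, 4)) for _ in range(6)]
        b = [rng.normal(size=(4, 4, 4)) for _ in range(6)]
        r1 = permutation_twosample(a, b, n_permutations=100, seed=5)
        r2 = permutation_twosample(a, b, n_permutations=100, seed=5)
        assert np.array_equal(r1["p"].values, r2["p"].values)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            permutation_twosample([np.zeros((2, 2, 2))], [np.zeros((2, 2, 2))] * 3)


class TestClusterFilter:
    def test_19_voxel_blob_removed_20_voxel_blob_survives(self):
        sig = np.zeros((12, 24, 12), bool)
        blob19 = np.argwhere(np.ones((3, 3, 3), bool))[:19]
        sig[tuple((blob19 + [2, 2, 2]).T)] = True
        blob20 = np.argwhere(np.ones((3, 3, 3), bool))[:20]
        sig[tuple((blob20 + [2, 14, 2]).T)] = True
        kept, table = cluster_filter(sig, cluster_extent=20)
        assert len(table) == 1
        assert table.loc[0, "size_voxels"] == 20
        assert kept.sum() == 20
        assert kept[2:5, 14:17, 2:5].sum() == 20

    def test_diagonal_voxels_are_26_connected(self):
        sig = np.zeros((6, 6, 6), bool)
        sig[1, 1, 1] = sig[2, 2, 2] = True
        _, table = cluster_filter(sig, cluster_extent=2)
        assert len(table) == 1 and table.loc[0, "size_voxels"] == 2


class TestVoxelwiseCorrelation:
    def test_identical_modalities_give_unit_r(self):
        rng = np.random.default_rng(10)
        maps = [rng.normal(size=(5, 5, 5)) for _ in range(6)]
        res = voxelwise_correlation(maps, [m.copy() for m in maps])
        assert np.allclose(res["r"].values, 1.0)

    def test_r_matches_direct_formula_at_random_voxels(self):
        rng = np.random.default_rng(11)
        a = [rng.normal(size=(6, 6, 6)) for _ in range(8)]
        b = [rng.normal(size=(6, 6, 6)) for _ in range(8)]
        res = voxelwise_correlation(a, b)
        av = np.stack(a)
        bv = np.stack(b)
        for _ in range(50):
            i, j, k = rng.integers(0, 6, 3)
            oracle = stats.pearsonr(av[:, i, j, k], bv[:, i, j, k])
            assert res["r"].values[i, j, k] == pytest.approx(oracle.statistic)
            assert res["p"].values[i, j, k] == pytest.approx(oracle.pvalue)

    def test_subject_mismatch_rejected(self):
        with pytest.raises(ValueError):
            voxelwise_correlation(
                [np.zeros((2, 2, 2))] * 4, [np.zeros((2, 2, 2))] * 3
            )


class TestRoiCorrelationMatrix:
    def _table(self, values, rois=("r1", "r2")):
        import pandas as pd

        rows = []
        for s, row in enumerate(values):
            for roi, v in zip(rois, row):
                rows.append({"subject_id": f"s{s}", "roi_name": roi, "value": v})
        return pd.DataFrame(rows)

    def test_self_correlation_diagonal_is_one(self):
        rng = np.random.default_rng(12)
        t = self._table(rng.normal(size=(6, 2)))
        r, _ = roi_correlation_matrix(t, t)
        assert np.allclose(np.diag(r.to_numpy(float)), 1.0)

    def test_negated_table_gives_minus_one(self):
        rng = np.random.default_rng(13)
        vals = rng.normal(size=(6, 2))
        ta = self._table(vals)
        tb = self._table(-vals)
        r, _ = roi_correlation_matrix(ta, tb)
        assert np.allclose(np.diag(r.to_numpy(float)), -1.0)

    def test_matches_numpy_corrcoef(self):
        rng = np.random.default_rng(14)
        va = rng.normal(size=(7, 2))
        vb = rng.normal(size=(7, 2))
        r, _ = roi_correlation_matrix(self._table(va), self._table(vb))
        assert r.loc["r1", "r2"] == pytest.approx(np.corrcoef(va[:, 0], vb[:, 1])[0, 1])

    def test_insufficient_overlap_rejected(self):
        ta = self._table(np.ones((2, 2)))
        with pytest.raises(ValueError):
            roi_correlation_matrix(ta, ta)
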