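import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from m6adyn import chromatin
from m6adyn.io_formats import STAGES


def enum_mwu_p(x, y):
    """Exhaustive two-sided Mann-Whitney p by enumerating rank splits."""
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(x) + len(y)
    ranks = pooled.argsort().argsort() + 1
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    allranks = np.arange(1, n + 1)
    us = np.array(
        [allranks[list(c)].sum() - n1 * (n1 + 1) / 2
         for c in itertools.combinations(range(n), n1)]
    )
    return min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))


class TestRankSum:
    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 7), (8, 8), (1, 8)])
    def test_matches_exact_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(3):
            x, y = rng.normal(size=n1), rng.normal(size=n2)
            assert chromatin.rank_sum_test(x, y) == pytest.approx(
                enum_mwu_p(x, y), abs=1e-12
            )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            chromatin.rank_sum_test([], [1.0])


class TestTargetAccessibility:
    def access(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.lognormal(3, 0.5, size=(n, 4)), columns=list(STAGES),
            index=pd.Index([f"g{i:04d}" for i in range(n)], name="gene_id"),
        )

    def test_targets_equal_to_all_genes_not_significant(self):
        a = self.access()
        out = chromatin.compare_target_accessibility(a.index, a, seed=1)
        assert (out.p_vs_all > 0.5).all()
        assert np.allclose(out.median_targets, out.median_all)

    def test_same_seed_gives_identical_random_control(self):
        a = self.access()
        t = a.index[:50]
        o1 = chromatin.compare_target_accessibility(t, a, seed=7)
        o2 = chromatin.compare_target_accessibility(t, a, seed=7)
        pd.testing.assert_frame_equal(o1, o2)

    def test_too_few_targets_skipped_with_warning(self):
        a = self.access()
        with pytest.warns(UserWarning, match="skipped"):
            assert chromatin.compare_target_accessibility(a.index[:2], a, seed=0) is None

    def test_boosted_targets_detected_in_most_seeds(self):
        hits = 0
        for seed in range(20):
            a = self.access(seed=seed)
            targets = a.index[:50]
            a.loc[targets] *= 2.0
            out = chromatin.compare_target_accessibility(targets, a, seed=seed)
            hits += (out.p_vs_all < 0.05).all()
        assert hits >= 18


class TestAccessibilityGroups:
    def test_split_sizes_10_80_10(self):
        s = pd.Series(np.arange(100, dtype=float),
                      index=[f"g{i:03d}" for i in range(100)])
        grp = chromatin.accessibility_groups(s)
        assert grp.value_counts().to_dict() == {"mid": 80, "low10": 10, "high10": 10}

    def test_planted_negative_coupling_orders_medians(self):
        rng = np.random.default_rng(0)
        n = 300
        idx = pd.Index([f"g{i:03d}" for i in range(n)], name="gene_id")
        access = pd.DataFrame({s: np.arange(n, dtype=float) for s in STAGES}, index=idx)
        m6a = pd.DataFrame(
            {s: 5.0 - 4.0 * np.arange(n) / n + rng.normal(0, 0.1, n) for s in STAGES},
            index=idx,
        )
        med, pv = chromatin.m6a_by_accessibility_group(access, m6a)
        assert (med.high10 < med.low10).all()
        assert (pv.low10_vs_high10 < 0.05).all()

    def test_independent_signals_have_comparable_medians(self):
        rng = np.random.default_rng(3)
        n = 500
        idx = pd.Index([f"g{i:03d}" for i in range(n)])
        access = pd.DataFrame(rng.lognormal(3, 0.5, (n, 4)), columns=list(STAGES), index=idx)
        m6a = pd.DataFrame(rng.lognormal(0.5, 0.3, (n, 4)), columns=list(STAGES), index=idx)
        med, pv = chromatin.m6a_by_accessibility_group(access, m6a)
        assert (pv.low10_vs_high10 > 0.001).all()


class TestModifiedVsUnmodified:
    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(1)
        idx = pd.Index([f"g{i}" for i in range(200)])
        access = pd.DataFrame(rng.lognormal(3, 0.4, (200, 4)), columns=list(STAGES), index=idx)
        flags = pd.DataFrame(
            np.tile(rng.random(200) < 0.5, (4, 1)).T, columns=list(STAGES), index=idx
        )
        out = chromatin.accessibility_of_modified_vs_unmodified(flags, access)
        assert (out.p > 0.01).all()

    def test_planted_shift_detected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            idx = pd.Index([f"g{i}" for i in range(500)])
            flags = pd.DataFrame(
                np.tile(rng.random(500) < 0.5, (4, 1)).T, columns=list(STAGES), index=idx
            )
            access = pd.DataFrame(
                rng.lognormal(3, 0.5, (500, 4)), columns=list(STAGES), index=idx
            )
            access[flags] *= 1.5
            out = chromatin.accessibility_of_modified_vs_unmodified(flags, access)
            hits += (out.p < 0.05).all()
        assert hits >= 18

    def test_all_modified_raises(self):
        idx = pd.Index(["a", "b"])
        access = pd.DataFrame(1.0, index=idx, columns=list(STAGES))
        flags = pd.DataFrame(True, index=idx, columns=list(STAGES))
        with pytest.raises(ValueError, match="empty"):
            chromatin.accessibility_of_modified_vs_unmodified(flags, access)


class TestCoDynamics:
    def levels(self, rows):
        return pd.DataFrame(
            rows, columns=list(STAGES),
            index=pd.Index([f"g{i}" for i in range(len(rows))], name="gene_id"),
        )

    def test_trivial_categories(self):
        m6a = self.levels([[2, 2, 2, 2], [2, 2, 2, 2], [1, 2, 2, 2]])
        access = self.levels([[5, 5, 5, 5], [5, 8, 8, 8], [5, 5, 5, 5]])
        out = chromatin.co_dynamics_categories(m6a, access)
        assert out.category.tolist() == [1, 2, 3]

    def test_concordant_and_discordant_signs(self):
        m6a = self.levels([[1, 2, 2, 2], [1, 2, 2, 2]])
        access = self.levels([[5, 10, 10, 10], [10, 5, 5, 5]])
        out = chromatin.co_dynamics_categories(m6a, access)
        assert out.category.tolist() == [5, 4]

    def test_category_map_is_partition(self, small_study):
        out = chromatin.co_dynamics_categories(
            small_study.truth.gene_mu, small_study.truth.access_clean
        )
        assert out.category.isin([1, 2, 3, 4, 5]).all()
        assert out.category.value_counts().sum() == len(out.category)

    def test_noiseless_planted_categories_recovered(self, small_study):
        out = chromatin.co_dynamics_categories(
            small_study.truth.gene_mu, small_study.truth.access_clean
        )
        truth = small_study.truth.gene_labels.category
        assert (out.category.loc[truth.index] == truth).all()


class TestPccBins:
    def matrices(self, n=2000, seed=0):
        rng = np.random.default_rng(seed)
        idx = pd.Index([f"g{i:04d}" for i in range(n)], name="gene_id")
        m6a = pd.DataFrame(rng.lognormal(0.7, 0.4, (n, 4)), columns=list(STAGES), index=idx)
        access = pd.DataFrame(rng.lognormal(3, 0.5, (n, 4)), columns=list(STAGES), index=idx)
        return m6a, access

    def test_bin_structure(self):
        m6a, access = self.matrices()
        binned, r = chromatin.pcc_bins(m6a, access)
        assert len(binned) == 18
        sizes = binned.n_genes
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == len(r) - 2 * int(np.floor(0.05 * len(r)))

    def test_flat_profile_when_changes_independent_of_pcc(self):
        m6a, access = self.matrices(seed=5)
        binned, _ = chromatin.pcc_bins(m6a, access)
        for t in binned.columns[:-1]:
            res = stats.linregress(np.arange(18), binned[t])
            assert res.pvalue > 0.005


class TestCategoryOverlap:
    def test_identical_windows_fully_consistent(self):
        idx = pd.Index([f"g{i}" for i in range(30)])
        lab = pd.Series([1, 2, 3, 4, 5] * 6, index=idx)
        per = pd.DataFrame({"w1": lab, "w2": lab, "w3": lab})
        out = chromatin.category_overlap(per)
        assert (out.n_all == out.n_w1).all()
        assert len(chromatin.consistent_genes(per, 3)) == 6

    def test_disjoint_windows_have_empty_intersection(self):
        idx = pd.Index(["a", "b"])
        per = pd.DataFrame({"w1": [3, 1], "w2": [1, 3], "w3": [2, 2]}, index=idx)
        out = chromatin.category_overlap(per)
        assert (out.n_all == 0).all()


class TestEcdfCompare:
    def test_identical_groups_coincide(self):
        rng = np.random.default_rng(0)
        v = pd.Series(rng.normal(size=100))
        curves, pv = chromatin.ecdf_compare({"a": v, "b": v.copy()})
        pd.testing.assert_frame_equal(curves["a"], curves["b"])
        assert pv.p.iloc[0] > 0.9

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(1)
        a = pd.Series(rng.normal(size=200))
        curves, pv = chromatin.ecdf_compare({"a": a, "b": a + 1.0})
        assert pv.p.iloc[0] < 0.05

    def test_single_member_group_is_a_step(self):
        curves, _ = chromatin.ecdf_compare(
            {"a": pd.Series([1.0]), "b": pd.Series([1.0, 2.0])}
        )
        assert curves["a"].ecdf.tolist() == [1.0]


class TestTfBinding:
    def test_coupled_tf_detected_and_uncoupled_not(self):
        rng = np.random.default_rng(0)
        n = 600
        idx = pd.Index([f"g{i:03d}" for i in range(n)], name="gene_id")
        lv = pd.DataFrame(
            {s: rng.uniform(0.5, 6.0, n) for s in STAGES}, index=idx
        )
        grp_idx = np.where(lv["D0"] < 1.5, 0, np.where(lv["D0"] > 4, 2, 1))
        binding = pd.DataFrame(
            {
                "POU5F1_D0": rng.lognormal(1, 0.3, n) * (1 + 0.8 * grp_idx),
                "NANOG_D0": rng.lognormal(1, 0.3, n),
            },
            index=idx,
        )
        out = chromatin.tf_binding_by_m6a_group(binding, lv)
        coupled = out[(out.tf == "POU5F1") & (out.pair == "low_vs_high")]
        assert (coupled.p < 0.05).all()
        uncoupled = out[out.tf == "NANOG"]
        assert (uncoupled.p > 0.001).all()

    def test_empty_group_skipped_with_warning(self):
        idx = pd.Index(["a", "b", "c"])
        lv = pd.DataFrame({s: [0.5, 0.7, 0.9] for s in STAGES}, index=idx)  # all low
        binding = pd.DataFrame({"NANOG_D0": [1.0, 2.0, 3.0]}, index=idx)
        with pytest.warns(UserWarning, match="empty m6A group"):
            out = chromatin.tf_binding_by_m6a_group(binding, lv)
        assert out.p.isna().all()
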