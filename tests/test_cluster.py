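"""Grid t-tests, cluster finding vs a flood-fill oracle, permutation and
bootstrap behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import compdrop as cd
from compdrop import ConfigurationError

from conftest import make_drop_table


def flood_fill_clusters(mask):
    """Brute-force 4-connectivity components of a boolean grid."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    clusters = []
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if mask[i, j] and not seen[i, j]:
                stack, members = [(i, j)], []
                seen[i, j] = True
                while stack:
                    a, b = stack.pop()
                    members.append((a, b))
                    for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        na, nb = a + da, b + db
                        if (
                            0 <= na < mask.shape[0]
                            and 0 <= nb < mask.shape[1]
                            and mask[na, nb]
                            and not seen[na, nb]
                        ):
                            seen[na, nb] = True
                            stack.append((na, nb))
                clusters.append(frozenset(members))
    return set(clusters)


class TestGridTtest:
    def test_null_data_t_near_zero_on_average(self):
        table = make_drop_table(n_items=400, grid_shape=(10, 10), seed=1)
        t, p_right, p_left = cd.grid_ttest(table)
        # mean of ~100 null t statistics: 3 SD band around 0
        assert abs(t.mean()) < 0.3
        assert np.allclose(p_right + p_left, 1.0)

    def test_planted_shift_detected(self):
        table = make_drop_table(n_items=200, effect=1.5, seed=2)
        _, p_right, _ = cd.grid_ttest(table)
        assert p_right[:3, :4].max() < 0.001

    def test_matches_from_scratch_formula_on_toy_groups(self):
        table = make_drop_table(n_items=6, grid_shape=(1, 1), seed=3)
        table.items["recalled_s3"] = [1, 1, 1, 0, 0, 0]
        table.drops[:, 0, 0] = [1.0, 2.0, 3.0, 0.0, 1.0, 2.0]
        t, p_right, _ = cd.grid_ttest(table)
        # pooled-variance two-sample t, computed by hand:
        # means 2 and 1, pooled var = (2+2)/4 = 1, t = 1/sqrt(1*(1/3+1/3))
        expected_t = 1.0 / np.sqrt(2.0 / 3.0)
        assert t[0, 0] == pytest.approx(expected_t)
        scipy_res = stats.ttest_ind(
            [1.0, 2.0, 3.0], [0.0, 1.0, 2.0], equal_var=True, alternative="greater"
        )
        assert t[0, 0] == pytest.approx(scipy_res.statistic)
        assert p_right[0, 0] == pytest.approx(scipy_res.pvalue)

    def test_empty_class_rejected(self):
        table = make_drop_table(n_items=10, seed=4)
        table.items["recalled_s3"] = 1
        with pytest.raises(ConfigurationError):
            cd.grid_ttest(table)


class TestKsNormalityCheck:
    def test_normal_drops_pass(self):
        table = make_drop_table(n_items=200, seed=5)
        out = cd.ks_normality_check(table)
        assert out["remembered"][1] > 0.05
        assert out["forgotten"][1] > 0.05

    def test_uniform_values_rejected_at_large_n(self):
        table = make_drop_table(n_items=400, grid_shape=(3, 5), seed=6)
        table.drops[:] = np.random.default_rng(7).uniform(0, 1, table.drops.shape)
        out = cd.ks_normality_check(table)
        assert out["remembered"][1] < 0.001

    def test_too_few_values_skipped_with_warning(self):
        table = make_drop_table(n_items=4, grid_shape=(1, 1), seed=8)
        table.items["recalled_s3"] = [1, 1, 0, 0]
        with pytest.warns(UserWarning):
            out = cd.ks_normality_check(table, min_n=10)
        assert out["remembered"] is None


class TestFindClusters:
    def test_all_above_threshold_gives_no_clusters(self):
        assert cd.find_clusters(np.ones((5, 5)), threshold=0.1) == []

    def test_diagonal_touching_squares_are_separate_clusters(self):
        p = np.ones((4, 4))
        p[1, 1] = p[2, 2] = 0.01
        clusters = cd.find_clusters(p, threshold=0.1)
        assert len(clusters) == 2
        assert all(len(c) == 1 for c in clusters)

    def test_cross_adjacency_joins(self):
        p = np.ones((3, 3))
        p[1, 1] = p[0, 1] = p[1, 0] = 0.01
        clusters = cd.find_clusters(p, threshold=0.1)
        assert len(clusters) == 1 and len(clusters[0]) == 3

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_agrees_with_flood_fill_oracle_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random((10, 10))
        clusters = cd.find_clusters(p, threshold=0.3)
        ours = {frozenset(map(tuple, c)) for c in clusters}
        assert ours == flood_fill_clusters(p < 0.3)


class TestClusterPermutation:
    def test_extreme_cluster_gets_add_one_floor_p(self):
        table = make_drop_table(n_items=200, effect=2.0, seed=9)
        result = cd.cluster_permutation(table, n_perm=500, seed=10)
        assert result.familywise_p.min() == pytest.approx(1.0 / 501.0)
        assert result.significant.any()

    def test_cluster_members_all_below_threshold_and_disjoint(self):
        table = make_drop_table(n_items=150, effect=1.0, seed=11)
        result = cd.cluster_permutation(table, n_perm=200, seed=12)
        seen = set()
        for cluster in result.clusters:
            for i, j in cluster:
                assert result.p_right[i, j] < result.threshold
                assert (i, j) not in seen
                seen.add((i, j))

    def test_familywise_p_in_unit_interval(self):
        table = make_drop_table(n_items=80, seed=13)
        result = cd.cluster_permutation(table, n_perm=150, seed=14)
        assert np.all((result.familywise_p > 0) & (result.familywise_p <= 1))

    def test_item_order_invariance(self):
        table = make_drop_table(n_items=100, effect=0.8, seed=15)
        perm = np.random.default_rng(16).permutation(100)
        shuffled = table.subset(perm)
        r1 = cd.cluster_permutation(table, n_perm=200, seed=17)
        r2 = cd.cluster_permutation(shuffled, n_perm=200, seed=17)
        assert np.allclose(r1.t_grid, r2.t_grid)
        assert np.array_equal(r1.cluster_sizes, r2.cluster_sizes)

    def test_small_n_perm_warns(self):
        table = make_drop_table(n_items=60, seed=18)
        with pytest.warns(UserWarning):
            cd.cluster_permutation(table, n_perm=50, seed=19)

    def test_stratified_variant_runs_and_controls_counts(self):
        table = make_drop_table(n_items=120, effect=1.0, seed=20)
        result = cd.cluster_permutation(table, n_perm=200, seed=21, stratify_by_subject=True)
        assert np.all((result.familywise_p > 0) & (result.familywise_p <= 1))


class TestSubjectBootstrap:
    def test_frequencies_in_unit_interval(self):
        table = make_drop_table(n_items=80, effect=1.0, seed=22)
        boot = cd.subject_bootstrap(table, n_boot=30, n_perm=100, seed=23)
        assert np.all((boot.frequency >= 0) & (boot.frequency <= 1))

    def test_strong_effect_in_cluster_frequencies_near_one(self):
        table = make_drop_table(n_items=240, effect=2.5, n_subjects=8, seed=24)
        boot = cd.subject_bootstrap(table, n_boot=30, n_perm=150, seed=25)
        assert boot.frequency[:3, :4].mean() > 0.9

    def test_null_data_frequencies_near_zero(self):
        table = make_drop_table(n_items=240, effect=0.0, n_subjects=8, seed=26)
        boot = cd.subject_bootstrap(table, n_boot=30, n_perm=150, seed=27)
        assert boot.frequency.mean() < 0.1

    def test_single_subject_rejected(self):
        table = make_drop_table(n_items=20, n_subjects=1, seed=28)
        with pytest.raises(ConfigurationError):
            cd.subject_bootstrap(table, n_boot=5, n_perm=100, seed=29)


class TestErrorRateSmoke:
    def test_null_familywise_rate_is_controlled_small_sample(self):
        # reduced-scale check; the full calibration lives in the acceptance suite
        rng = np.random.default_rng(30)
        n_rejections = 0
        n_rep = 40
        for _ in range(n_rep):
            table = make_drop_table(n_items=100, seed=int(rng.integers(2**31)))
            result = cd.cluster_permutation(table, n_perm=150, seed=int(rng.integers(2**31)))
            n_rejections += int(result.significant.any())
        # binomial(40, 0.05): P(X > 7) < 0.001
        assert n_rejections <= 7
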