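"""Mixed-design ANOVA, t-tests, cluster-corrected t-maps and controls.

The split-plot ANOVA is checked against an explicit sums-of-squares oracle
written independently in this file, and against pingouin's implementation
on a randomized unbalanced table.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from amynet.stats import (
    StatsError,
    bonferroni,
    mixed_anova,
    one_sample_t,
    paired_t,
    pib_vs_rglobal_correlation,
    subsample_control,
    two_sample_t,
    voxelwise_group_tmap,
)
from amynet.volumes import VolumeMap


def anova_oracle(Y, groups):
    """Independent split-plot sums-of-squares oracle (explicit loops)."""
    n, m = Y.shape
    labels = sorted(set(groups))
    grand = Y.mean()
    ss_total = ((Y - grand) ** 2).sum()
    subj_mean = Y.mean(axis=1)
    ss_between = m * ((subj_mean - grand) ** 2).sum()
    ss_group = 0.0
    for g in labels:
        sel = [i for i, x in enumerate(groups) if x == g]
        ss_group += m * len(sel) * (Y[sel].mean() - grand) ** 2
    ss_subj = ss_between - ss_group
    net_mean = Y.mean(axis=0)
    ss_net = n * ((net_mean - grand) ** 2).sum()
    ss_cells = 0.0
    for g in labels:
        sel = [i for i, x in enumerate(groups) if x == g]
        for j in range(m):
            ss_cells += len(sel) * (Y[sel, j].mean() - grand) ** 2
    ss_inter = ss_cells - ss_group - ss_net
    ss_err = ss_total - ss_between - ss_net - ss_inter
    k = len(labels)
    F_group = (ss_group / (k - 1)) / (ss_subj / (n - k))
    F_net = (ss_net / (m - 1)) / (ss_err / ((n - k) * (m - 1)))
    F_int = (ss_inter / ((k - 1) * (m - 1))) / (ss_err / ((n - k) * (m - 1)))
    return F_group, F_net, F_int


def _table(Y, groups):
    df = pd.DataFrame(Y, index=[f"s{i}" for i in range(len(Y))],
                      columns=[f"n{j}" for j in range(Y.shape[1])])
    return df, pd.Series(groups, index=df.index)


class TestMixedAnova:
    def test_location_invariance(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(8, 3))
        groups = ["a"] * 4 + ["b"] * 4
        r1 = mixed_anova(*_table(Y, groups))
        r2 = mixed_anova(*_table(Y + 100.0, groups))
        assert r1.F_group == pytest.approx(r2.F_group, rel=1e-9)
        assert r1.F_network == pytest.approx(r2.F_network, rel=1e-9)
        assert r1.F_interaction == pytest.approx(r2.F_interaction, rel=1e-9)

    def test_six_subject_hand_table_matches_oracle(self):
        Y = np.array([[3.0, 5.0], [4.0, 7.0], [2.0, 4.0],
                      [6.0, 6.0], [8.0, 7.0], [7.0, 8.0]])
        groups = ["pat"] * 3 + ["con"] * 3
        res = mixed_anova(*_table(Y, groups))
        Fg, Fn, Fi = anova_oracle(Y, groups)
        assert res.F_group == pytest.approx(Fg, abs=1e-10)
        assert res.F_network == pytest.approx(Fn, abs=1e-10)
        assert res.F_interaction == pytest.approx(Fi, abs=1e-10)
        assert res.df_group == (1, 4)
        assert res.df_network == (1, 4)

    @pytest.mark.parametrize("n_per_group,m,seed", [((4, 4), 4, 1), ((5, 3), 3, 2)])
    def test_matches_oracle_on_random_tables(self, n_per_group, m, seed):
        rng = np.random.default_rng(seed)
        n = sum(n_per_group)
        Y = rng.normal(size=(n, m))
        groups = ["a"] * n_per_group[0] + ["b"] * n_per_group[1]
        res = mixed_anova(*_table(Y, groups))
        Fg, Fn, Fi = anova_oracle(Y, groups)
        assert res.F_group == pytest.approx(Fg, abs=1e-8)
        assert res.F_network == pytest.approx(Fn, abs=1e-8)
        assert res.F_interaction == pytest.approx(Fi, abs=1e-8)

    def test_agrees_with_pingouin_on_unbalanced_table(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(9, 4)) + np.array([1.0, 0, 0, 0.5])
        groups = ["a"] * 5 + ["b"] * 4
        res = mixed_anova(*_table(Y, groups))
        long = pd.DataFrame({
            "value": Y.ravel(),
            "subject": np.repeat(np.arange(9), 4),
            "network": np.tile(np.arange(4), 9),
            "group": np.repeat(groups, 4),
        })
        ref = pg.mixed_anova(long, dv="value", within="network",
                             subject="subject", between="group", correction=False)
        assert res.F_group == pytest.approx(
            float(ref.loc[ref.Source == "group", "F"].iloc[0]), rel=1e-6)
        assert res.F_network == pytest.approx(
            float(ref.loc[ref.Source == "network", "F"].iloc[0]), rel=1e-6)
        assert res.F_interaction == pytest.approx(
            float(ref.loc[ref.Source == "Interaction", "F"].iloc[0]), rel=1e-6)

    def test_null_group_calibration(self):
        # with no group effect the group F-test rejects at its nominal rate
        rng = np.random.default_rng(4)
        rejections = 0
        n_sets = 400
        for _ in range(n_sets):
            Y = rng.normal(size=(8, 3)) + rng.normal(size=(8, 1))  # subject effects
            res = mixed_anova(*_table(Y, ["a"] * 4 + ["b"] * 4))
            rejections += res.p_group < 0.05
        rate = rejections / n_sets
        assert 0.02 < rate < 0.09  # binomial band around 5%

    def test_missing_cells_rejected(self):
        Y = np.full((4, 2), 1.0)
        Y[0, 0] = np.nan
        with pytest.raises(StatsError, match="listwise"):
            mixed_anova(*_table(Y, ["a", "a", "b", "b"]))


class TestTTests:
    def test_identical_samples_give_t_zero_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = two_sample_t(x, x.copy())
        assert res.statistic == pytest.approx(0.0)
        assert res.p_raw == pytest.approx(1.0)

    def test_three_vs_three_hand_dataset_pooled_formula(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([2.0, 4.0, 6.0])
        # independent oracle: pooled-variance formula
        sp2 = ((2) * x.var(ddof=1) + (2) * y.var(ddof=1)) / 4
        t_expected = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        res = two_sample_t(x, y)
        assert res.statistic == pytest.approx(t_expected, abs=1e-12)
        assert res.df == 4
        assert res.kind == "two_sample"

    def test_welch_option_differs_under_heteroscedasticity(self):
        rng = np.random.default_rng(5)
        x = rng.normal(scale=5.0, size=10)
        y = rng.normal(size=30)
        student = two_sample_t(x, y)
        welch = two_sample_t(x, y, welch=True)
        assert welch.df != student.df

    def test_paired_identical_inputs_rejected(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(StatsError):
            paired_t(x, x)

    def test_paired_matches_scipy(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=(2, 12))
        res = paired_t(x, y)
        ref = sps.ttest_rel(x, y)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_raw == pytest.approx(ref.pvalue)

    def test_one_sample_against_nonzero_mean(self):
        rng = np.random.default_rng(7)
        x = rng.normal(loc=0.3, size=20)
        res = one_sample_t(x, mu0=0.3)
        assert abs(res.statistic) < 3

    def test_bonferroni_examples_and_monotonicity(self):
        np.testing.assert_allclose(bonferroni([0.01], 7), [0.07])
        np.testing.assert_allclose(bonferroni([0.5], 7), [1.0])
        p = np.array([0.001, 0.01, 0.04])
        out = bonferroni(p, 7)
        assert (np.diff(out) >= 0).all()
        with pytest.raises(StatsError):
            bonferroni([0.1, 0.2], 1)

    def test_corrected_p_is_clipped_product(self):
        res = two_sample_t([1.0, 2, 3, 4], [1.1, 2.2, 3.1, 4.4], family_size=7)
        assert res.p_corrected == pytest.approx(min(1.0, res.p_raw * 7))


def _maps_from_array(data):
    return [VolumeMap(d) for d in data]


class TestVoxelwiseTMap:
    def test_group_swap_negates_t_map(self):
        rng = np.random.default_rng(8)
        data = rng.normal(size=(10, 8, 8, 8))
        labels = ["a"] * 5 + ["b"] * 5
        m1 = voxelwise_group_tmap(_maps_from_array(data), labels, height_p=0.01,
                                  min_extent=1)
        m2 = voxelwise_group_tmap(_maps_from_array(data), ["b"] * 5 + ["a"] * 5,
                                  height_p=0.01, min_extent=1)
        np.testing.assert_allclose(m1.t_map.values, -m2.t_map.values, atol=1e-10)

    def test_planted_blob_recovered_as_largest_cluster(self):
        rng = np.random.default_rng(9)
        data = rng.normal(size=(12, 16, 16, 16))
        blob = np.zeros((16, 16, 16))
        blob[5:10, 5:10, 5:10] = 3.0  # ~3 pooled SD group difference
        data[:6] += blob
        labels = ["pat"] * 6 + ["con"] * 6
        cm = voxelwise_group_tmap(_maps_from_array(data), labels,
                                  height_p=0.001, min_extent=10,
                                  n_permutations=200, seed=1)
        assert cm.clusters, "expected at least one cluster"
        top = cm.clusters[0]
        assert top.p_corrected < 0.05
        inside = sum(1 for v in top.voxels if blob[tuple(v)] > 0)
        assert inside / top.extent > 0.8

    def test_null_data_yields_no_large_clusters(self):
        rng = np.random.default_rng(10)
        data = rng.normal(size=(12, 14, 14, 14))
        labels = ["pat"] * 6 + ["con"] * 6
        cm = voxelwise_group_tmap(_maps_from_array(data), labels,
                                  height_p=1e-4, min_extent=100)
        assert cm.clusters == []

    def test_permutation_pvalues_calibrated_on_null(self):
        # corrected p of the largest null cluster should rarely be < 0.05
        rng = np.random.default_rng(11)
        n_sig = 0
        for i in range(20):
            data = rng.normal(size=(10, 12, 12, 12))
            cm = voxelwise_group_tmap(_maps_from_array(data), ["a"] * 5 + ["b"] * 5,
                                      height_p=0.01, min_extent=1,
                                      n_permutations=100, seed=i)
            if cm.clusters and cm.clusters[0].p_corrected < 0.05:
                n_sig += 1
        assert n_sig <= 4


class TestSubjectLevel:
    def test_pib_rglobal_perfectly_linear(self):
        x = np.arange(10.0)
        r, res = pib_vs_rglobal_correlation(x, 2.0 + 0.5 * x)
        assert r == pytest.approx(1.0)
        assert res.p_raw < 1e-10

    def test_null_correlation_usually_nonsignificant(self):
        rng = np.random.default_rng(12)
        r, res = pib_vs_rglobal_correlation(rng.normal(size=30), rng.normal(size=30))
        assert abs(r) < 0.4
        assert res.p_raw > 0.01

    def test_burden_gradient_across_patients_recovered(self):
        # heavier-burden patients get both more PiB and stronger coupling,
        # so median PiB and r_GLOBAL correlate positively across patients
        from amynet.pipeline import cohort_metrics
        from amynet.synthetic import generate_cohort, single_network_design

        design = single_network_design(16, 5, b_global_patient=0.6,
                                       pib_elevated=True, seed=19)
        df, _ = cohort_metrics(generate_cohort(design), compute_rlocal=False)
        pat = df[df.group == "patient"]
        r, _ = pib_vs_rglobal_correlation(pat["median_pib"], pat["r_global"])
        assert r > 0

    def test_zero_variance_rejected(self):
        with pytest.raises(StatsError):
            pib_vs_rglobal_correlation(np.ones(6), np.arange(6.0))


class TestSubsampleControl:
    @staticmethod
    def _metric(n_pat=20, n_con=8, effect=2.0, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "value": np.r_[rng.normal(loc=effect, size=n_pat), rng.normal(size=n_con)],
            "group": ["patient"] * n_pat + ["control"] * n_con,
        })

    def test_single_draw_reproducible(self):
        m = self._metric()
        s1 = subsample_control(m, n_draws=1, seed=5)
        s2 = subsample_control(m, n_draws=1, seed=5)
        assert s1.statistics[0] == s2.statistics[0]
        assert s1.subset_size == 8

    def test_constant_patient_metric_gives_constant_statistic(self):
        m = self._metric()
        m.loc[m.group == "patient", "value"] = 1.5
        s = subsample_control(m, n_draws=10, seed=6)
        assert np.allclose(s.statistics, s.statistics[0])

    def test_strong_effect_significant_in_nearly_all_draws(self):
        s = subsample_control(self._metric(effect=3.0, seed=7), n_draws=100, seed=8)
        assert s.fraction_significant[0.05] > 0.95

    def test_matched_groups_noop_with_notice(self):
        s = subsample_control(self._metric(n_pat=8, n_con=8, seed=9), n_draws=50)
        assert "matched" in s.note
        assert s.n_draws == 1
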