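"""Cohort statistics: rate fit, tagma grouping, PCA, permutation tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gzmorph import (assign_tagma, generate_cohort, pca_morphometrics,
                     regress_pc1_on_group, segment_addition_rate,
                     tagma_group_compare, tagma_separation)
from gzmorph.cohort_stats import OUT_OF_RANGE, TAGMA_CODES
from gzmorph.errors import (DegenerateColumnError, DegenerateFitError,
                            GroupingError)
from gzmorph.morphometry import PCA_MEASURES


class TestAssignTagma:
    @pytest.mark.parametrize("en, expected", [
        (3, "thoracic_premolt"), (6, "thoracic_premolt"),
        (7, "thoracic_postmolt"), (11, "thoracic_postmolt"),
        (12, "genital"), (13, "genital"),
        (14, "abdominal"), (17, "abdominal"),
        (2, OUT_OF_RANGE), (18, OUT_OF_RANGE),
    ])
    def test_lookup(self, en, expected):
        assert assign_tagma(en) == expected

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(en=st.integers(3, 17))
    def test_in_range_always_assigned(self, en):
        assert assign_tagma(en) in TAGMA_CODES


class TestSegmentAdditionRate:
    def test_noiseless_clock_slope_is_reciprocal_interval(self):
        t = np.arange(13) * 1.4
        df = pd.DataFrame({"stage_h": t, "en_stripes": 3 + np.arange(13)})
        fit = segment_addition_rate(df)
        assert fit.slope == pytest.approx(1 / 1.4)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.slope_se == pytest.approx(0.0, abs=1e-12)

    def test_default_cohort_slope_rounds_to_07(self):
        table = generate_cohort(n_per_timepoint=25, timepoints=range(19),
                                seed=0, measure=False)
        fit = segment_addition_rate(table)
        assert round(fit.slope, 1) == 0.7
        assert fit.n == 475

    def test_constant_counts_give_zero_slope(self):
        df = pd.DataFrame({"stage_h": [0, 1, 2, 3], "en_stripes": [5, 5, 5, 5]})
        assert segment_addition_rate(df).slope == 0.0

    def test_too_few_timepoints_rejected(self):
        df = pd.DataFrame({"stage_h": [1, 1, 2], "en_stripes": [3, 4, 5]})
        with pytest.raises(DegenerateFitError):
            segment_addition_rate(df)

    def test_cross_check_against_scipy(self):
        from scipy import stats
        rng = np.random.default_rng(4)
        t = np.repeat(np.arange(10.0), 5)
        y = 3 + 0.7 * t + rng.normal(0, 0.5, t.size)
        fit = segment_addition_rate(pd.DataFrame({"stage_h": t,
                                                  "en_stripes": y}))
        ref = stats.linregress(t, y)
        assert fit.slope == pytest.approx(ref.slope)
        assert fit.intercept == pytest.approx(ref.intercept)
        assert fit.slope_se == pytest.approx(ref.stderr)

    def test_rate_recovery_over_seeds(self):
        """Mean fitted slope over 100 cohorts within 3 SE of the true rate;
        the per-fit 95% CI covers it at least 90% of the time."""
        slopes, covered = [], 0
        for seed in range(100):
            table = generate_cohort(n_per_timepoint=25, timepoints=range(19),
                                    seed=seed, measure=False)
            fit = segment_addition_rate(table)
            slopes.append(fit.slope)
            if abs(fit.slope - 1 / 1.4) <= 1.96 * fit.slope_se:
                covered += 1
        slopes = np.asarray(slopes)
        se_mean = slopes.std(ddof=1) / math.sqrt(len(slopes))
        assert abs(slopes.mean() - 1 / 1.4) <= 3 * se_mean
        assert covered >= 90


def _iso_records(n=60, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.normal(size=(n, 8)), columns=list(PCA_MEASURES))


class TestPCA:
    def test_collinear_records_put_all_variance_on_pc1(self):
        x = np.linspace(0, 1, 30)
        data = {m: (i + 1) * x + i for i, m in enumerate(PCA_MEASURES)}
        res = pca_morphometrics(pd.DataFrame(data))
        assert res.variance_fractions[0] == pytest.approx(1.0)

    def test_isotropic_noise_spreads_variance(self):
        fracs = np.mean([pca_morphometrics(_iso_records(200, s)).variance_fractions
                         for s in range(5)], axis=0)
        assert fracs.max() < 0.25
        assert fracs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_fractions_sum_and_score_centering(self, measured_cohort):
        res = pca_morphometrics(measured_cohort)
        assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(res.scores.mean(axis=0), 0.0, atol=1e-9)
        # sign convention: dominant loading positive
        for j in range(res.loadings.shape[1]):
            col = res.loadings.iloc[:, j].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_constant_column_named_in_error(self):
        df = _iso_records(30)
        df["gz_widthA_mm"] = 1.0
        with pytest.raises(DegenerateColumnError) as exc:
            pca_morphometrics(df)
        assert "gz_widthA_mm" in str(exc.value)

    def test_too_few_records_rejected(self):
        with pytest.raises(DegenerateFitError):
            pca_morphometrics(_iso_records(8))

    def test_cross_check_against_sklearn(self, measured_cohort):
        from sklearn.decomposition import PCA
        from sklearn.preprocessing import StandardScaler
        X = measured_cohort.loc[:, list(PCA_MEASURES)].dropna().to_numpy()
        Z = StandardScaler().fit_transform(X)
        ref = PCA(n_components=8).fit(Z)
        res = pca_morphometrics(measured_cohort)
        # sklearn standardizes with ddof=0; variance fractions agree anyway
        assert np.allclose(ref.explained_variance_ratio_,
                           res.variance_fractions, atol=1e-6)
        for j in range(3):
            corr = np.corrcoef(ref.transform(Z)[:, j], res.scores[:, j])[0, 1]
            assert abs(corr) > 0.9999

    def test_default_cohort_pc1_dominates_and_orders_tagmata(self,
                                                             measured_cohort):
        in_range = measured_cohort[measured_cohort["tagma"] != OUT_OF_RANGE]
        res = pca_morphometrics(in_range)
        assert res.variance_fractions[0] > 0.5
        df = in_range.dropna(subset=list(PCA_MEASURES)).copy()
        df["pc1"] = res.scores[:, 0]
        means = df.groupby("tagma")["pc1"].mean()
        ordered = [means[t] for t in TAGMA_CODES if t in means]
        diffs = np.diff(ordered)
        assert (diffs > 0).all() or (diffs < 0).all()


class TestTagmaSeparation:
    def test_identical_groups_not_separated(self):
        base = np.random.default_rng(0).normal(size=(20, 3))
        scores = np.vstack([base, base])
        labels = ["a"] * 20 + ["b"] * 20
        stat, p = tagma_separation(scores, labels, n_permutations=199, seed=0)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p > 0.9

    def test_shuffled_labels_type_one_error(self):
        """Null permutation test rejects at <= nominal + 3 SE."""
        rng = np.random.default_rng(0)
        alpha = 0.05
        n_sims = 200
        rejections = 0
        for s in range(n_sims):
            scores = rng.normal(size=(48, 3))
            labels = np.repeat(list("abcd"), 12)
            rng.shuffle(labels)
            _, p = tagma_separation(scores, labels, n_permutations=99, seed=s)
            rejections += p <= alpha
        bound = alpha + 3 * math.sqrt(alpha * (1 - alpha) / n_sims)
        assert rejections / n_sims <= bound

    def test_tiny_group_rejected(self):
        scores = np.zeros((5, 3))
        with pytest.raises(GroupingError):
            tagma_separation(scores, ["a", "a", "a", "a", "b"],
                             n_permutations=19)

    def test_default_cohort_strongly_separated(self, measured_cohort):
        in_range = measured_cohort[measured_cohort["tagma"] != OUT_OF_RANGE]
        res = pca_morphometrics(in_range)
        labels = in_range.dropna(subset=list(PCA_MEASURES))["tagma"].to_numpy()
        stat, p = tagma_separation(res.scores, labels, n_permutations=999,
                                   seed=0)
        assert p <= 0.001


class TestRegressPC1OnGroup:
    def test_perfectly_grouped_scores(self):
        pc1 = np.repeat([0.0, 1.0, 2.0, 3.0], 10)
        labels = np.repeat(list(TAGMA_CODES), 10)
        adj, p = regress_pc1_on_group(pc1, labels)
        assert adj == pytest.approx(1.0)
        assert p < 1e-10

    def test_independent_scores_near_zero(self):
        rng = np.random.default_rng(1)
        adjs = [regress_pc1_on_group(rng.normal(size=40),
                                     np.repeat(list(TAGMA_CODES), 10))[0]
                for _ in range(20)]
        assert abs(np.mean(adjs)) < 0.1

    def test_single_level_rejected(self):
        with pytest.raises(DegenerateFitError):
            regress_pc1_on_group([1.0, 2.0, 3.0], ["genital"] * 3)

    def test_default_cohort_tagma_predicts_pc1(self, measured_cohort):
        in_range = measured_cohort[measured_cohort["tagma"] != OUT_OF_RANGE]
        res = pca_morphometrics(in_range)
        labels = in_range.dropna(subset=list(PCA_MEASURES))["tagma"].to_numpy()
        adj, p = regress_pc1_on_group(res.scores[:, 0], labels)
        assert adj > 0.5
        assert p < 0.001


class TestTagmaGroupCompare:
    def _records(self, shifts, n=12, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for tagma, shift in zip(TAGMA_CODES, shifts):
            for v in rng.normal(shift, 1.0, n):
                rows.append({"tagma": tagma, "gz_length_mm": v})
        return pd.DataFrame(rows)

    def test_identical_groups_not_significant(self):
        out = tagma_group_compare(self._records([0, 0, 0, 0]), "gz_length_mm")
        assert (out["p_adjusted"] > 0.05).all()

    def test_strongly_shifted_group_significant(self):
        out = tagma_group_compare(self._records([0, 0, 0, 50]), "gz_length_mm")
        sig = out[(out["group_a"] == "abdominal") |
                  (out["group_b"] == "abdominal")]
        assert (sig["p_adjusted"] < 1e-6).all()

    def test_default_cohort_premolt_vs_abdominal_gz_length(self,
                                                           measured_cohort):
        out = tagma_group_compare(measured_cohort, "gz_length_mm")
        row = out[(out["group_a"] == "thoracic_premolt") &
                  (out["group_b"] == "abdominal")]
        assert len(row) == 1
        assert float(row["p_adjusted"].iloc[0]) < 0.05
        assert float(row["mean_difference"].iloc[0]) > 0  # GZ shrinks

    def test_needs_two_populated_groups(self):
        df = pd.DataFrame({"tagma": ["genital"] * 5,
                           "gz_length_mm": np.arange(5.0)})
        with pytest.raises(GroupingError):
            tagma_group_compare(df, "gz_length_mm")
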