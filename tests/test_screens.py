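import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from irpipe.screens import (
    bh_fdr,
    dose_response,
    overlap_sets,
    screen_features,
    summarize_2x2,
)
from irpipe.synthetic import SimConfig, gen_proteomics, substream


class TestBHFDR:
    def test_step_up_arithmetic(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        np.testing.assert_allclose(bh_fdr([0.37]), [0.37])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_worked_example(self):
        # independent step-up by hand: p*(m/rank) then cumulative min from the right
        p = np.array([0.005, 0.04, 0.03, 0.9])
        expected = np.array([0.02, 0.05333333, 0.05333333, 0.9])
        np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-8)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.random(500)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_fdr(p), q_sm)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_permutation_equivariance_and_monotonicity(self, pvals):
        p = np.array(pvals)
        q = bh_fdr(p)
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(bh_fdr(p[perm]), q[perm])
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_bad_pvalues_error(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestScreenFeatures:
    def _null_data(self, seed, n=80, m=1304):
        rng = np.random.default_rng(seed)
        idx = [f"s{i}" for i in range(n)]
        features = pd.DataFrame(rng.normal(size=(n, m)), index=idx,
                                columns=[f"f{i}" for i in range(m)])
        response = pd.Series(rng.normal(size=n), index=idx)
        return features, response

    def test_null_calibration_mean_discoveries(self):
        total = 0
        for rep in range(20):
            features, response = self._null_data(rep)
            rows = screen_features(features, response, family="linear")
            total += int((rows["q"] < 0.05).sum())
        assert total / 20 <= 2.0

    def test_null_p_uniform(self):
        features, response = self._null_data(99, n=100, m=2000)
        rows = screen_features(features, response, family="linear")
        _, ks_p = stats.kstest(rows["p"], "uniform")
        assert ks_p > 0.01

    def test_planted_recovery_sensitivity(self):
        config = SimConfig(n_subjects=300, seed=17)
        rng = substream(17, "scores")
        idx = [f"s{i}" for i in range(300)]
        sas = pd.Series(rng.standard_normal(300), index=idx)
        mas = pd.Series(rng.standard_normal(300), index=idx)
        table, truth = gen_proteomics(config, sas, mas)
        rows = screen_features(table, sas, family="linear").set_index("feature")
        planted = truth["sas"] | truth["shared"]
        hits = set(rows.index[rows["q"] < 0.05])
        sensitivity = len(hits & planted) / len(planted)
        assert sensitivity >= 0.95

    def test_single_feature_q_equals_p(self):
        features, response = self._null_data(1, n=50, m=1)
        rows = screen_features(features, response, family="linear")
        assert rows["q"].item() == pytest.approx(rows["p"].item())

    def test_linear_matches_statsmodels_ols(self):
        import statsmodels.api as sm
        features, response = self._null_data(7, n=60, m=5)
        covar = pd.DataFrame({"age": np.random.default_rng(7).uniform(40, 90, 60)},
                             index=features.index)
        rows = screen_features(features, response, covar, family="linear").set_index("feature")
        X = sm.add_constant(pd.DataFrame({"response": response, "age": covar["age"]}))
        for f in features.columns:
            res = sm.OLS(features[f], X).fit()
            assert rows.loc[f, "beta"] == pytest.approx(res.params["response"])
            assert rows.loc[f, "p"] == pytest.approx(res.pvalues["response"])

    def test_logistic_mode(self, rng):
        n = 400
        idx = [f"s{i}" for i in range(n)]
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-1.5 * x))).astype(float)
        features = pd.DataFrame({"f_signal": x, "f_noise": rng.normal(size=n)}, index=idx)
        rows = screen_features(features, pd.Series(y, index=idx), family="logistic").set_index("feature")
        assert rows.loc["f_signal", "q"] < 0.05
        assert rows.loc["f_signal", "beta"] == pytest.approx(1.5, abs=0.5)

    def test_collinear_design_error(self):
        features, response = self._null_data(3, n=50, m=2)
        covar = pd.DataFrame({"dup": response.to_numpy()}, index=features.index)
        with pytest.raises(ValueError, match="collinear"):
            screen_features(features, response, covar, family="linear")

    def test_misaligned_error(self):
        features, response = self._null_data(4, n=20, m=2)
        with pytest.raises(ValueError, match="aligned"):
            screen_features(features, response.iloc[::-1], family="linear")


class TestOverlapSets:
    def test_disjoint(self):
        res = overlap_sets({"a"}, {"b"})
        assert res.counts == {"shared": 0, "only_a": 1, "only_b": 1}

    def test_identical(self):
        res = overlap_sets({"a", "b"}, {"a", "b"})
        assert res.only_a == frozenset() and res.only_b == frozenset()

    def test_partition_identity(self, rng):
        a = set(rng.choice(100, 30, replace=False))
        b = set(rng.choice(100, 40, replace=False))
        res = overlap_sets(a, b)
        assert len(res.shared) + len(res.only_a) == len(a)
        assert len(res.shared) + len(res.only_b) == len(b)

    def test_planted_shared_25_recovered(self):
        config = SimConfig(n_subjects=300, seed=23)
        rng = substream(23, "scores")
        idx = [f"s{i}" for i in range(300)]
        sas = pd.Series(rng.standard_normal(300), index=idx)
        mas = pd.Series(rng.standard_normal(300), index=idx)
        table, truth = gen_proteomics(config, sas, mas)
        covar = None
        sas_hits = screen_features(table, sas, covar, family="linear")
        mas_hits = screen_features(table, mas, covar, family="linear")
        sas_set = set(sas_hits.loc[sas_hits["q"] < 0.05, "feature"])
        mas_set = set(mas_hits.loc[mas_hits["q"] < 0.05, "feature"])
        res = overlap_sets(sas_set, mas_set)
        assert truth["shared"] <= res.shared
        # no spurious shared discoveries beyond the planted 25
        assert len(res.shared) == len(truth["shared"])


class TestDoseResponse:
    def test_bins_sum_to_one_and_tie_policy(self, rng):
        score = pd.Series(rng.normal(size=400))
        labels = pd.Series(rng.choice(["H-L", "L-H"], 400), index=score.index)
        res = dose_response(score, labels)
        np.testing.assert_allclose(res.table.sum(axis=1), 1.0)
        assert len(res.table) == 8

    def test_too_few_samples_error(self, rng):
        score = pd.Series(rng.normal(size=5))
        labels = pd.Series(["H-L", "L-H"] * 2 + ["H-L"], index=score.index)
        with pytest.raises(ValueError, match="n_bins"):
            dose_response(score, labels)

    def test_null_slope_calibration(self):
        covered = 0
        for rep in range(100):
            rng = np.random.default_rng(rep + 500)
            score = pd.Series(rng.normal(size=250))
            labels = pd.Series(rng.choice(["H-L", "L-H"], 250), index=score.index)
            res = dose_response(score, labels)
            covered += res.slope_ci[0] <= 0.0 <= res.slope_ci[1]
        assert covered >= 90

    def test_planted_coupling_recovered(self):
        from irpipe.synthetic import gen_expression
        config = SimConfig(n_subjects=4000, seed=30, tcf7_coupling=1.5)
        sim = gen_expression(config)
        score = sim.truth["tcf7_z"]
        labels = sim.truth["sas1_stratum"].map({"H": "H-L", "L": "L-H"})
        res = dose_response(score, labels)
        assert res.slope_ci[0] < 1.5 < res.slope_ci[1]
        # prevalence of the high label rises across octiles
        assert res.table["H-L"].iloc[-1] > res.table["H-L"].iloc[0]

    def test_constant_label_error(self, rng):
        score = pd.Series(rng.normal(size=40))
        labels = pd.Series(["H-L"] * 40, index=score.index)
        with pytest.raises(ValueError, match="constant"):
            dose_response(score, labels)


def fisher_oracle(table):
    """Exhaustive two-sided Fisher p: sum hypergeometric probs <= observed."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = stats.hypergeom.pmf(x, n, r1, c1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


class TestSummarize2x2:
    def test_influenza_challenge_counts(self):
        # 10/17 vs 2/8 asymptomatic
        res = summarize_2x2([[10, 7], [2, 6]])
        assert res.row_proportions[0] == pytest.approx(0.588, abs=5e-4)
        assert res.row_proportions[1] == pytest.approx(0.250)
        assert round(100 * res.row_proportions[0]) == 59
        assert round(100 * res.row_proportions[1]) == 25

    def test_odds_ratio_hand_arithmetic(self):
        res = summarize_2x2([[10, 7], [2, 6]])
        assert res.odds_ratio == pytest.approx(60 / 14, rel=1e-9)

    def test_symmetric_table(self):
        res = summarize_2x2([[5, 5], [5, 5]])
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.fisher_p == pytest.approx(1.0)

    def test_haldane_correction_only_with_zero_cell(self):
        res = summarize_2x2([[5, 0], [2, 6]])
        assert res.odds_ratio == pytest.approx((5.5 * 6.5) / (0.5 * 2.5))

    def test_fisher_matches_hypergeometric_enumeration(self):
        # brute-force oracle over all tables with n <= 30
        rng = np.random.default_rng(0)
        checked = 0
        for _ in range(300):
            n = int(rng.integers(2, 31))
            cells = rng.multinomial(n, [0.25] * 4)
            tab = cells.reshape(2, 2)
            if tab.sum(axis=1).min() == 0 or tab.sum(axis=0).min() == 0:
                continue
            res = summarize_2x2(tab)
            assert res.fisher_p == pytest.approx(fisher_oracle(tab), abs=1e-10), tab
            checked += 1
        assert checked > 100

    def test_invalid_tables(self):
        with pytest.raises(ValueError):
            summarize_2x2([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValueError):
            summarize_2x2([[0, 0], [0, 0]])
        with pytest.raises(ValueError):
            summarize_2x2([[1.5, 2], [3, 4]])
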