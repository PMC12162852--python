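import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from itertools import combinations
from scipy.stats import norm, rankdata

from irsyn.spectra_io import SubjectRecord
from irsyn.features import FeatureSet
from irsyn.stats import (chi_square_sex, covariate_only_auc,
                         extraction_efficiency, fit_logistic_score,
                         mann_whitney_u, qalb_positivity, roc_auc, tht_verdict)
from irsyn.synthetic_data import ThTScans, simulate_tht_scans


def brute_force_mwu(x, y):
    """Exact U (min orientation) and two-sided p by full enumeration of all
    group assignments of the pooled sample."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1, N = x.size, pooled.size
    ranks = rankdata(pooled)
    mu = n1 * (N - n1) / 2.0

    def u1(idx):
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0

    u_obs = u1(range(n1))
    us = np.array([u1(c) for c in combinations(range(N), n1)])
    p = float(np.mean(np.abs(us - mu) >= np.abs(u_obs - mu) - 1e-12))
    return min(u_obs, n1 * (N - n1) - u_obs), p


def make_records(ratios, labels, ages=None, sexes=None):
    rng = np.random.default_rng(0)
    recs = []
    for i, (r, y) in enumerate(zip(ratios, labels)):
        rec = SubjectRecord(subject_id=f"S{i}", diagnosis="PD" if y else "control",
                            age=float(ages[i]) if ages is not None
                            else float(rng.uniform(50, 90)),
                            sex=(sexes[i] if sexes is not None
                                 else ("F" if rng.random() < 0.5 else "M")))
        rec.features = FeatureSet(abs_max=np.nan, com_max=np.nan,
                                  ratio_1656_1623=float(r))
        recs.append(rec)
    return recs


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_all_identical_values_warn_and_p_one(self):
        with pytest.warns(UserWarning, match="identical"):
            res = mann_whitney_u([5.0, 5.0], [5.0, 5.0, 5.0])
        assert res.p_value == 1.0

    def test_exact_branch_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n1, n2 = rng.integers(2, 7), rng.integers(2, 7)
            vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # no ties
            x, y = vals[:n1], vals[n1:]
            u_bf, p_bf = brute_force_mwu(x, y)
            res = mann_whitney_u(x, y)
            assert res.test == "mann_whitney_u_exact"
            assert res.statistic == pytest.approx(u_bf)
            assert res.p_value == pytest.approx(p_bf, abs=1e-12)

    def test_type_one_error_near_alpha(self):
        """Random group splits of exchangeable data reject at ~5%."""
        rng = np.random.default_rng(11)
        data = rng.normal(size=40)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            perm = rng.permutation(data)
            if mann_whitney_u(perm[:20], perm[20:]).p_value < 0.05:
                rejections += 1
        assert rejections / reps == pytest.approx(0.05, abs=0.01)


class TestChiSquare:
    def test_balanced_table_is_null(self):
        res = chi_square_sex(np.array([[10, 10], [10, 10]]))
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_pearson_value(self):
        """Table (10,10 / 20,0): expected cells (15,5 / 15,5), so
        X^2 = 2*(25/15) + 2*(25/5) = 40/3."""
        res = chi_square_sex(np.array([[10, 10], [20, 0]]))
        assert res.statistic == pytest.approx(40.0 / 3.0)

    def test_doubling_counts_doubles_statistic(self):
        t = np.array([[12, 5], [7, 14]])
        s1 = chi_square_sex(t).statistic
        s2 = chi_square_sex(2 * t).statistic
        assert s2 == pytest.approx(2 * s1)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_sex(np.array([[0, 0], [5, 5]]))


class TestLogisticScore:
    def test_null_covariates_give_chance_auc(self):
        rng = np.random.default_rng(3)
        n = 1000
        labels = rng.random(n) < 0.5
        recs = make_records(rng.normal(1.1, 0.1, n), labels)
        score = fit_logistic_score(recs)
        assert not score.fallback
        assert abs(score.coefficients["ratio"]) < 2.0
        auc = roc_auc(score.scores, score.truth).auc
        assert auc == pytest.approx(0.5, abs=0.06)

    def test_perfect_separation_falls_back_to_rank_scores(self):
        ratios = np.concatenate([np.full(10, 1.0), np.full(10, 1.3)])
        labels = np.concatenate([np.ones(10), np.zeros(10)])  # low ratio = disease
        recs = make_records(ratios, labels.astype(bool))
        with pytest.warns(UserWarning, match="separation|converge"):
            score = fit_logistic_score(recs)
        assert score.fallback
        assert roc_auc(score.scores, score.truth).auc == 1.0

    def test_missing_covariates_are_excluded_and_counted(self):
        rng = np.random.default_rng(5)
        recs = make_records(rng.normal(1.1, 0.1, 30), rng.random(30) < 0.5)
        recs[0].features = None
        recs[1].features.valid = False
        score = fit_logistic_score(recs)
        assert score.n_excluded == 2
        assert score.scores.size == 28

    def test_empty_covariate_set_rejected(self):
        recs = make_records([1.0, 1.1, 1.2, 1.3], [1, 0, 1, 0])
        with pytest.raises(ValueError):
            fit_logistic_score(recs, covariates=())


class TestRocAuc:
    def test_scores_equal_to_labels_give_auc_one(self):
        truth = np.array([0, 1, 0, 1, 1])
        res = roc_auc(truth.astype(float), truth)
        assert res.auc == 1.0

    def test_independent_scores_give_chance_auc(self):
        rng = np.random.default_rng(9)
        n = 10_000
        res = roc_auc(rng.normal(size=n), rng.random(n) < 0.5)
        assert res.auc == pytest.approx(0.5, abs=0.02)

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(deadline=None, max_examples=100)
    def test_auc_equals_normalized_u_statistic(self, seed):
        """Trapezoidal AUC over the empirical ROC is the normalized
        Mann-Whitney U statistic (exact algebraic identity, ties included)."""
        rng = np.random.default_rng(seed)
        n1, n0 = rng.integers(3, 20), rng.integers(3, 20)
        # discretized scores to exercise ties
        pos = np.round(rng.normal(0.5, 1.0, n1), 1)
        neg = np.round(rng.normal(0.0, 1.0, n0), 1)
        scores = np.concatenate([pos, neg])
        truth = np.concatenate([np.ones(n1, int), np.zeros(n0, int)])
        auc = roc_auc(scores, truth).auc
        from scipy.stats import mannwhitneyu
        u1 = mannwhitneyu(pos, neg, alternative="two-sided").statistic
        assert auc == pytest.approx(u1 / (n1 * n0), abs=1e-12)

    def test_ci_brackets_auc_and_bootstrap_agrees(self):
        rng = np.random.default_rng(12)
        scores = np.concatenate([rng.normal(1, 1, 100), rng.normal(0, 1, 100)])
        truth = np.concatenate([np.ones(100, int), np.zeros(100, int)])
        dl = roc_auc(scores, truth, ci_method="delong")
        bs = roc_auc(scores, truth, ci_method="bootstrap", seed=0)
        assert dl.ci_low <= dl.auc <= dl.ci_high
        assert bs.ci_low == pytest.approx(dl.ci_low, abs=0.03)
        assert bs.ci_high == pytest.approx(dl.ci_high, abs=0.03)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestCovariateOnly:
    def test_sex_imbalance_alone_discriminates(self):
        """77:23 vs 47:53 M:F pattern with matched ages yields AUC > 0.5."""
        rng = np.random.default_rng(17)
        n = 1000
        labels = np.concatenate([np.ones(n, bool), np.zeros(n, bool)])
        sexes = (["F" if rng.random() < 0.23 else "M" for _ in range(n)]
                 + ["F" if rng.random() < 0.53 else "M" for _ in range(n)])
        ages = rng.normal(70, 9, 2 * n)
        recs = make_records(np.full(2 * n, 1.1), labels, ages=ages, sexes=sexes)
        res = covariate_only_auc(recs)
        assert res.auc > 0.55

    def test_balanced_demographics_give_chance(self):
        rng = np.random.default_rng(19)
        n = 2000
        recs = make_records(np.full(n, 1.1), rng.random(n) < 0.5,
                            ages=rng.normal(70, 9, n))
        assert covariate_only_auc(recs).auc == pytest.approx(0.5, abs=0.04)


class TestQalbAndExtraction:
    @pytest.mark.parametrize("age,q_alb,expected", [
        (60.0, 8.1, True),    # norm 8.0
        (75.0, 9.0, False),   # norm 9.0, strict >
        (30.0, 5.9, False),   # norm 6.0
    ])
    def test_qalb_positivity_rule(self, age, q_alb, expected):
        assert qalb_positivity(age, q_alb) is expected

    def test_extraction_efficiency_printed_concentrations(self):
        assert extraction_efficiency(1197.0, 161.0) == pytest.approx(86.55, abs=0.01)
        assert extraction_efficiency(1197.0, 1075.0) == pytest.approx(10.19, abs=0.01)
        assert extraction_efficiency(500.0, 500.0) == 0.0

    def test_supernatant_above_original_warns(self):
        with pytest.warns(UserWarning, match="dilution"):
            assert extraction_efficiency(100.0, 110.0) == pytest.approx(-10.0)


class TestThTVerdict:
    def test_aggregated_fixture_confirmed(self):
        shift, factor, aggregated = tht_verdict(simulate_tht_scans(True, seed=1))
        assert aggregated
        assert shift == pytest.approx(37.0, abs=3.0)
        assert factor >= 20.0

    def test_monomer_fixture_rejected(self):
        shift, factor, aggregated = tht_verdict(simulate_tht_scans(False, seed=1))
        assert not aggregated
        assert abs(shift) <= 3.0
        assert factor < 20.0

    def test_boundary_factor_exactly_20_at_450_is_confirmed(self):
        ex_wl = np.arange(410.0, 461.0)
        em_wl = np.arange(480.0, 621.0)
        ex = np.exp(-((ex_wl - 450.0) / 20.0) ** 2)
        em = np.full(em_wl.size, 20.0)
        blank = np.ones(em_wl.size)
        scans = ThTScans(ex_wl, ex, em_wl, em, blank, blank)
        _, factor, aggregated = tht_verdict(scans)
        assert factor == pytest.approx(20.0)
        assert aggregated
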