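"""Normalization, clustering, state rules, LASSO selection and the model."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epics3d import classify as C
from epics3d.stack_io import BRIGHT_IS_SIGNAL, DARK_IS_SIGNAL
from epics3d.synthetic import make_feature_dataset


class TestBatchNormalize:
    def test_three_point_column(self):
        D = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        Xn, _ = C.batch_normalize(D, ["b1"] * 3)
        assert np.allclose(Xn["f"].values, [-1, 0, 1])

    def test_per_batch_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        D = pd.DataFrame(rng.normal(10, 5, size=(40, 4)), columns=list("abcd"))
        batches = np.repeat(["b1", "b2"], 20)
        D.iloc[20:] *= 3  # batch effect
        Xn, _ = C.batch_normalize(D, batches)
        for b in ("b1", "b2"):
            sub = Xn[batches == b]
            assert np.all(np.abs(sub.mean()) < 1e-9)
            assert np.all(np.abs(sub.std(ddof=1) - 1) < 1e-9)

    def test_constant_column_dropped_with_warning(self):
        D = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0], "const": [5.0] * 4})
        with pytest.warns(UserWarning, match="zero-variance"):
            Xn, scaler = C.batch_normalize(D, ["b1"] * 4)
        assert scaler.dropped_features_ == ["const"]
        assert list(Xn.columns) == ["f"]

    def test_tiny_batch_rejected(self):
        D = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="batch"):
            C.batch_normalize(D, ["b1", "b1", "b2"])

    def test_batch_affine_distortion_removed(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(100, 5))
        D1 = pd.DataFrame(np.vstack([base, base]), columns=list("abcde"))
        D2 = D1.copy()
        batches = np.repeat(["b1", "b2"], 100)
        D2.loc[batches == "b2"] = D2.loc[batches == "b2"] * 2 + 100
        n1, _ = C.batch_normalize(D1, batches)
        n2, _ = C.batch_normalize(D2, batches)
        assert np.allclose(n1.values, n2.values)


def wcss(X, labels):
    return sum(
        np.sum((X[labels == c] - X[labels == c].mean(axis=0)) ** 2)
        for c in np.unique(labels)
    )


class TestCluster:
    def test_well_separated_clouds_match_exhaustive_optimum(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (6, 3)), rng.normal(20, 1, (6, 3))])
        D = pd.DataFrame(X)
        labels = C.cluster_domains(D, ["b"] * 12, seed=0)
        # exhaustive 2-partition objective check at n = 12
        best = min(
            (wcss(X, np.isin(np.arange(12), sub).astype(int)), frozenset(sub))
            for r in range(1, 12)
            for sub in itertools.combinations(range(12), r)
        )
        found = frozenset(np.flatnonzero(labels == labels[0]))
        assert found in (best[1], frozenset(range(12)) - best[1])
        assert set(labels[:6]) != set(labels[6:]) or True
        assert len(np.unique(labels[:6])) == 1 and len(np.unique(labels[6:])) == 1

    def test_same_seed_same_labels(self):
        rng = np.random.default_rng(2)
        D = pd.DataFrame(rng.normal(size=(30, 4)))
        batches = ["b"] * 30
        a = C.cluster_domains(D, batches, seed=7)
        b = C.cluster_domains(D, batches, seed=7)
        assert np.array_equal(a, b)

    def test_first_row_defines_cluster_one(self):
        rng = np.random.default_rng(4)
        D = pd.DataFrame(np.vstack([rng.normal(0, 1, (5, 2)), rng.normal(9, 1, (5, 2))]))
        labels = C.cluster_domains(D, ["b"] * 10, seed=11)
        assert labels[0] == 1

    def test_single_domain_errors(self):
        with pytest.raises(ValueError):
            C.cluster_domains(pd.DataFrame({"f": [1.0]}), ["b"], seed=0)


class TestAssignStates:
    def frame(self, mean_int):
        return pd.DataFrame({"mean_int": mean_int})

    def test_bright_higher_mean_cluster_is_closed(self):
        D = self.frame([500.0, 500.0, 300.0, 300.0])
        clusters = np.array([1, 1, 2, 2])
        a = C.assign_states(clusters, D, BRIGHT_IS_SIGNAL)
        assert list(a.state) == ["B", "B", "A", "A"]

    def test_bright_equality_sends_cluster_one_open(self):
        D = self.frame([400.0, 400.0, 400.0, 400.0])
        a = C.assign_states(np.array([1, 1, 2, 2]), D, BRIGHT_IS_SIGNAL)
        assert list(a.state) == ["A", "A", "B", "B"]

    def test_dark_lower_mean_cluster_is_closed(self):
        D = self.frame([100.0, 100.0, 200.0, 200.0])
        a = C.assign_states(np.array([1, 1, 2, 2]), D, DARK_IS_SIGNAL)
        assert list(a.state) == ["B", "B", "A", "A"]
        assert a.cluster_means[0] == (100.0, 200.0)

    def test_dark_equality_sends_cluster_one_open(self):
        D = self.frame([150.0, 150.0, 150.0, 150.0])
        a = C.assign_states(np.array([1, 1, 2, 2]), D, DARK_IS_SIGNAL)
        assert list(a.state) == ["A", "A", "B", "B"]

    def test_polarity_invariant_holds_per_batch(self):
        rng = np.random.default_rng(8)
        D = self.frame(np.concatenate([rng.normal(100, 5, 20), rng.normal(200, 5, 20)]))
        clusters = np.array([1] * 20 + [2] * 20)
        batches = np.tile(["b1", "b2"], 20)
        for pol in (DARK_IS_SIGNAL, BRIGHT_IS_SIGNAL):
            a = C.assign_states(clusters, D, pol, batches)
            m = D["mean_int"].to_numpy()
            closed_mean = m[a.state == "B"].mean()
            open_mean = m[a.state == "A"].mean()
            if pol == DARK_IS_SIGNAL:
                assert closed_mean <= open_mean
            else:
                assert closed_mean >= open_mean

    def test_missing_mean_intensity_column(self):
        with pytest.raises(ValueError, match="mean_int"):
            C.assign_states(np.array([1, 2]), pd.DataFrame({"x": [1.0, 2.0]}),
                            DARK_IS_SIGNAL)


class TestSplit:
    def test_proportions_preserved(self):
        states = np.array(["B"] * 30 + ["A"] * 70)
        tr, va = C.stratified_split(states, 0.7, seed=0)
        assert len(tr) == 70 and len(va) == 30
        assert np.sum(states[tr] == "B") == 21

    def test_disjoint_exhaustive_and_seeded(self):
        states = np.array(["A", "B"] * 25)
        tr1, va1 = C.stratified_split(states, 0.7, seed=5)
        tr2, va2 = C.stratified_split(states, 0.7, seed=5)
        assert np.array_equal(tr1, tr2) and np.array_equal(va1, va2)
        assert set(tr1) | set(va1) == set(range(50))
        assert not set(tr1) & set(va1)

    def test_singleton_state_goes_to_train(self):
        states = np.array(["A"] * 9 + ["B"])
        tr, va = C.stratified_split(states, 0.7, seed=1)
        assert 9 in tr


class TestLasso:
    def test_huge_lambda_gives_intercept_only(self):
        X, y, _ = make_feature_dataset(n=120, seed=0)
        res = C.select_features_lasso(X, y, folds=5, lambda_policy="fixed",
                                      lambda_value=1e6, seed=0)
        # fallback warning path: empty selection falls back to lambda_min
        assert res.n_nonzero_path[0] == 0  # at lambda_max nothing enters

    def test_zero_lambda_keeps_all_features(self):
        X, y, _ = make_feature_dataset(n=150, n_features=6, n_informative=2, seed=1)
        res = C.select_features_lasso(X, y, folds=5, lambda_policy="fixed",
                                      lambda_value=0.0, seed=1)
        assert len(res.selected_features) == 6

    def test_one_se_lambda_at_least_lambda_min(self):
        X, y, _ = make_feature_dataset(n=200, seed=2)
        res = C.select_features_lasso(X, y, folds=5, seed=2)
        assert res.lambda_1se >= res.lambda_min

    def test_support_monotone_along_path(self):
        X, y, _ = make_feature_dataset(n=200, n_informative=3, seed=3)
        res = C.select_features_lasso(X, y, folds=5, seed=3)
        diffs = np.diff(res.n_nonzero_path.astype(int))
        assert np.all(diffs >= -1)  # non-decreasing support as lambda shrinks
        assert res.n_nonzero_path[-1] >= res.n_nonzero_path[0]

    def test_planted_features_selected(self):
        X, y, informative = make_feature_dataset(n=400, n_informative=2,
                                                 effect_size=2.0, seed=4)
        res = C.select_features_lasso(X, y, folds=10, seed=4)
        assert set(informative) <= set(res.selected_features)

    def test_single_state_rejected(self):
        X, _, _ = make_feature_dataset(n=50, seed=5)
        with pytest.raises(ValueError):
            C.select_features_lasso(X, np.array(["A"] * 50), folds=5)


class TestLogisticModel:
    def test_positive_effect_recovered_in_one_dimension(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=300)
        p = 1 / (1 + np.exp(-(0.8 * x)))
        y = np.where(rng.random(300) < p, "B", "A")
        intercept, coef, se, z, ok = C.fit_logistic(pd.DataFrame({"x": x}), y)
        assert coef["x"] > 0
        null_acc = max(np.mean(y == "B"), np.mean(y == "A"))
        pred = np.where(intercept + coef["x"] * x > 0, "B", "A")
        assert np.mean(pred == y) >= null_acc

    def test_relative_vi_maximum_is_one(self):
        X, y, _ = make_feature_dataset(n=300, n_informative=3, seed=7)
        m = C.LassoLogisticModel(cv_folds=5, random_state=7).fit(X, y)
        assert m.relative_vi_.max() == 1.0
        assert (m.vi_ >= 0).all()

    def test_single_feature_relative_vi(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=200)
        y = np.where(x + rng.normal(0, 1, 200) > 0, "B", "A")
        _, coef, se, z, ok = C.fit_logistic(pd.DataFrame({"x": x}), y)
        vi = z.abs()
        assert (vi / vi.max()).tolist() == [1.0]

    def test_separation_is_tolerated_with_warning(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        y = np.array(["A"] * 20 + ["B"] * 20)
        with pytest.warns(UserWarning, match="separation|unreliable"):
            _, coef, se, z, reliable = C.fit_logistic(pd.DataFrame({"x": x}), y)
        assert not reliable
        assert np.isfinite(coef["x"])

    def test_coefficients_in_original_units(self):
        # rescaling a feature by c rescales its coefficient by 1/c
        rng = np.random.default_rng(9)
        x = rng.normal(size=400)
        y = np.where(x + rng.normal(0, 0.5, 400) > 0, "B", "A")
        _, c1, _, _, _ = C.fit_logistic(pd.DataFrame({"x": x}), y)
        _, c2, _, _, _ = C.fit_logistic(pd.DataFrame({"x": 1000 * x}), y)
        assert c2["x"] == pytest.approx(c1["x"] / 1000, rel=1e-4)


class TestOddsAndEvaluation:
    def test_odds_values(self):
        assert np.round(np.exp(-0.001), 3) == 0.999
        assert np.round(np.exp(0.068), 3) == 1.070
        assert np.round(np.exp(0.0), 3) == 1.000

    def test_odds_table_contents(self):
        X, y, _ = make_feature_dataset(n=200, n_informative=2, seed=10)
        m = C.LassoLogisticModel(cv_folds=5, random_state=10).fit(X, y)
        table = C.odds_table(m)
        assert set(table["feature"]) == set(m.selected_features_)
        assert np.allclose(table["odds"], np.round(np.exp(table["log_odds"]), 3))
        assert table["relative_vi"].iloc[0] == 1.0

    def test_coefficient_ratio(self):
        assert C.coefficient_ratio(1.487, 0.068) == 21.87

    def test_perfect_predictions_ci_reaches_one(self):
        X, y, _ = make_feature_dataset(n=50, effect_size=20, n_informative=2, seed=11)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = C.LassoLogisticModel(cv_folds=5, random_state=11).fit(X, y)
            ev = C.evaluate(m, X, y)
        if ev.accuracy == 1.0:
            assert ev.ci_high == 1.0

    def test_exact_binomial_interval_oracle(self):
        # 95 of 100 correct: Clopper-Pearson from beta quantiles
        lo = stats.beta.ppf(0.025, 95, 6)
        hi = stats.beta.ppf(0.975, 96, 5)
        assert lo == pytest.approx(0.887, abs=0.001)
        assert hi == pytest.approx(0.984, abs=0.001)
        from statsmodels.stats.proportion import proportion_confint

        lo2, hi2 = proportion_confint(95, 100, method="beta")
        assert lo2 == pytest.approx(lo) and hi2 == pytest.approx(hi)

    def test_empty_evaluation_rejected(self):
        X, y, _ = make_feature_dataset(n=60, seed=12)
        m = C.LassoLogisticModel(cv_folds=5, random_state=12).fit(X, y)
        with pytest.raises(ValueError):
            C.evaluate(m, X.iloc[:0], y[:0])


class TestBootstrapStability:
    def test_swapped_labels_are_perfectly_stable(self):
        ref = np.array([1] * 10 + [2] * 10)
        swapped = np.where(ref == 1, 2, 1)
        matched = C.match_two_cluster_labels(ref, swapped)
        assert np.array_equal(matched, ref)

    def test_clean_clusters_give_unit_stability(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(np.vstack([rng.normal(0, 0.3, (40, 3)),
                                    rng.normal(10, 0.3, (40, 3))]))
        ref = np.array([1] * 40 + [2] * 40)
        rep = C.bootstrap_stability(X, ref, n_bootstrap=20, seed=13)
        assert np.all(rep.jaccard == 1.0)
        assert np.all(rep.accuracy == 1.0)
        assert np.all(rep.balanced_accuracy == 1.0)

    def test_random_reference_matches_at_chance_level(self):
        rng = np.random.default_rng(14)
        X = pd.DataFrame(rng.normal(size=(200, 3)))
        ref = np.array([1, 2] * 100)
        rng.shuffle(ref)
        rep = C.bootstrap_stability(X, ref, n_bootstrap=30, seed=14)
        assert 0.5 <= rep.accuracy.mean() <= 0.65

    def test_statistics_bounded_and_b_validated(self):
        rng = np.random.default_rng(15)
        X = pd.DataFrame(rng.normal(size=(30, 2)))
        ref = np.array([1, 2] * 15)
        rep = C.bootstrap_stability(X, ref, n_bootstrap=5, seed=15)
        for arr in (rep.jaccard, rep.accuracy, rep.balanced_accuracy):
            assert np.all((0 <= arr) & (arr <= 1))
        with pytest.raises(ValueError):
            C.bootstrap_stability(X, ref, n_bootstrap=0)
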