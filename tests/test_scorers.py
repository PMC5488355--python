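import numpy as np
import pytest

from ensemblefs import (
    FeatureTable,
    fcbf_eliminate,
    fit_logistic,
    score_correlation,
    score_forest,
    score_logreg,
    score_median,
    ztransform,
)
from ensemblefs.dataio import EfsWarning

from _oracles import mw_exact_p_bruteforce


def make_table(cols: dict[str, np.ndarray], labels: np.ndarray) -> FeatureTable:
    return FeatureTable(tuple(cols), np.column_stack(list(cols.values())), labels)


class TestScoreMedian:
    def test_identical_distributions_score_zero(self):
        x = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        t = make_table({"f": x}, np.array([0, 0, 0, 1, 1, 1]))
        assert score_median(t).scores[0] == pytest.approx(0.0)

    def test_small_sample_exact_p_is_one_third(self):
        # class0 = {1,2}, class1 = {3,4}: exact two-sided p = 1/3 -> raw 2/3
        t = make_table({"f": np.array([1.0, 2.0, 3.0, 4.0])}, np.array([0, 0, 1, 1]))
        assert score_median(t).scores[0] == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_perfect_separation_large_sample(self):
        x = np.concatenate([np.linspace(0, 1, 20), np.linspace(10, 11, 20)])
        t = make_table({"f": x}, np.repeat([0, 1], 20))
        assert score_median(t).scores[0] > 0.99999

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            na, nb = rng.integers(2, 5, size=2)
            a = rng.standard_normal(na)
            b = rng.standard_normal(nb)
            t = make_table(
                {"f": np.concatenate([b, a])},
                np.concatenate([np.zeros(nb, int), np.ones(na, int)]),
            )
            raw = score_median(t).scores[0]
            assert 1.0 - raw == pytest.approx(mw_exact_p_bruteforce(a, b), abs=1e-12)

    def test_feature_missing_in_one_class_warns_and_scores_zero(self):
        x = np.array([np.nan, np.nan, np.nan, 1.0, 2.0, 3.0])
        t = make_table({"f": x}, np.array([1, 1, 1, 0, 0, 0]))
        with pytest.warns(EfsWarning, match="no non-missing"):
            assert score_median(t).scores[0] == 0.0


class TestFcbf:
    def test_duplicate_features_keep_exactly_one(self):
        rng = np.random.default_rng(0)
        labels = np.tile([0, 1], 20)
        x = rng.standard_normal(40) + labels
        t = make_table({"a": x, "b": x.copy()}, labels)
        kept, eliminated = fcbf_eliminate(t, 0.7, "pearson")
        assert kept == ["a"] and eliminated == frozenset({"b"})

    def test_uncorrelated_features_all_kept(self):
        rng = np.random.default_rng(1)
        labels = np.tile([0, 1], 30)
        t = make_table({f"f{i}": rng.standard_normal(60) for i in range(3)}, labels)
        kept, eliminated = fcbf_eliminate(t, 0.7, "pearson")
        assert len(kept) == 3 and not eliminated

    def test_redundant_less_class_correlated_feature_eliminated(self):
        # A strongly class-linked, B a noisy copy of A: r(A,B) high, A wins.
        rng = np.random.default_rng(2)
        labels = np.tile([0, 1], 100)
        a = labels + 0.8 * rng.standard_normal(200)
        b = a + 0.4 * rng.standard_normal(200)
        t = make_table({"B": b, "A": a}, labels)
        assert abs(np.corrcoef(a, b)[0, 1]) > 0.7
        kept, eliminated = fcbf_eliminate(t, 0.7, "pearson")
        assert kept == ["A"] and eliminated == frozenset({"B"})

    def test_kept_set_pairwise_below_threshold(self):
        rng = np.random.default_rng(3)
        labels = np.tile([0, 1], 40)
        base = rng.standard_normal(80)
        cols = {f"f{i}": 0.6 * base + rng.standard_normal(80) for i in range(6)}
        t = make_table(cols, labels)
        threshold = 0.5
        kept, _ = fcbf_eliminate(t, threshold, "pearson")
        sub = t.subset_features(kept)
        corr = np.corrcoef(sub.values.T)
        off = corr[~np.eye(len(kept), dtype=bool)]
        assert np.all(np.abs(off) <= threshold)


class TestScoreCorrelation:
    def test_feature_equal_to_class_scores_near_one(self):
        labels = np.tile([0, 1], 15)
        t = make_table({"f": labels.astype(float)}, labels)
        assert score_correlation(t, "pearson", 0.7).scores[0] > 0.999

    def test_eliminated_feature_scores_exactly_zero(self):
        rng = np.random.default_rng(4)
        labels = np.tile([0, 1], 20)
        x = rng.standard_normal(40) + labels
        t = make_table({"a": x, "b": x.copy()}, labels)
        vec = score_correlation(t, "pearson", 0.7)
        assert vec.scores[list(t.feature_names).index("b")] == 0.0

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        labels = np.tile([0, 1], 25)
        x = rng.standard_normal(50) + 0.8 * labels + 5.0
        t1 = make_table({"f": x}, labels)
        t2 = make_table({"f": np.exp(x)}, labels)
        s1 = score_correlation(t1, "spearman", 0.7).scores[0]
        s2 = score_correlation(t2, "spearman", 0.7).scores[0]
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_constant_feature_scores_zero_with_warning(self):
        labels = np.tile([0, 1], 10)
        t = make_table({"c": np.full(20, 3.0)}, labels)
        with pytest.warns(EfsWarning, match="undefined"):
            assert score_correlation(t, "pearson", 0.7).scores[0] == 0.0


class TestFitLogistic:
    def test_null_betas_are_small(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((1000, 4))
        y = rng.integers(0, 2, 1000)
        beta = fit_logistic(X, y)
        assert np.all(np.abs(beta[1:]) < 0.2)

    def test_complete_separation_falls_back_to_ridge(self):
        y = np.tile([0, 1], 20)
        X = ztransform(y.astype(float).reshape(-1, 1))
        with pytest.warns(EfsWarning, match="separation|ridge"):
            beta = fit_logistic(X, y)
        assert beta[1] > 0
        assert np.isfinite(beta).all()

    def test_duplicate_feature_betas_sum_to_single_beta(self):
        rng = np.random.default_rng(7)
        y = np.tile([0, 1], 50)
        x = y + rng.standard_normal(100)
        Xs = ztransform(x.reshape(-1, 1))
        single = fit_logistic(Xs, y)[1]
        duo = fit_logistic(np.column_stack([Xs, Xs]), y)
        assert duo[1] + duo[2] == pytest.approx(single, rel=0.05)

    def test_p_ge_n_uses_ridge(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((10, 12))
        y = np.tile([0, 1], 5)
        with pytest.warns(EfsWarning, match="ridge"):
            beta = fit_logistic(X, y)
        assert np.isfinite(beta).all() and len(beta) == 13

    def test_empty_feature_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_logistic(np.empty((5, 0)), np.array([0, 1, 0, 1, 0]))


class TestScoreLogreg:
    def test_opposite_effects_score_equally(self):
        # the negated copy has the same magnitude of effect, opposite sign:
        # importance is |beta|, so both get the same score
        rng = np.random.default_rng(9)
        labels = np.tile([0, 1], 100)
        up = labels + rng.standard_normal(200)
        t = make_table({"up": up, "down": -up}, labels)
        s = score_logreg(t).scores
        assert s[0] == pytest.approx(s[1], abs=1e-6)
        assert min(s) > 0.3

    def test_noise_features_score_near_zero(self):
        rng = np.random.default_rng(19)
        labels = np.tile([0, 1], 250)
        t = make_table({f"n{i}": rng.standard_normal(500) for i in range(3)}, labels)
        assert np.all(score_logreg(t).scores < 0.25)

    def test_constant_feature_scores_zero(self):
        rng = np.random.default_rng(10)
        labels = np.tile([0, 1], 20)
        t = make_table(
            {"c": np.full(40, 2.0), "x": labels + rng.standard_normal(40)}, labels
        )
        assert score_logreg(t).scores[0] == pytest.approx(0.0, abs=1e-8)


class TestScoreForest:
    def test_runs_one_equals_single_forest(self, informative_table):
        a = score_forest(informative_table, "rf_mdi", runs=1, seed=5, n_trees=10)
        b = score_forest(informative_table, "rf_mdi", runs=1, seed=5, n_trees=10)
        assert np.array_equal(a.scores, b.scores)

    def test_same_seed_same_vector_all_variants(self, informative_table):
        for variant in ("rf_mdi", "rf_error", "cf_error", "cf_auc"):
            a = score_forest(informative_table, variant, runs=2, seed=3, n_trees=10)
            b = score_forest(informative_table, variant, runs=2, seed=3, n_trees=10)
            assert np.array_equal(a.scores, b.scores), variant

    def test_informative_features_dominate_mdi(self, informative_table):
        scores = score_forest(informative_table, "rf_mdi", runs=3, seed=1, n_trees=30).scores
        names = informative_table.feature_names
        top3 = {names[i] for i in np.argsort(-scores)[:3]}
        assert top3 == {"inf_1", "inf_2", "inf_3"}

    def test_informative_features_dominate_permutation(self, informative_table):
        scores = score_forest(informative_table, "rf_error", runs=3, seed=2, n_trees=30).scores
        names = informative_table.feature_names
        top3 = {names[i] for i in np.argsort(-scores)[:3]}
        assert top3 == {"inf_1", "inf_2", "inf_3"}

    def test_label_permuted_data_has_near_zero_permutation_importance(self):
        rng = np.random.default_rng(12)
        labels = rng.permutation(np.tile([0, 1], 40))
        t = make_table({f"f{i}": rng.standard_normal(80) for i in range(5)}, labels)
        scores = score_forest(t, "rf_error", runs=5, seed=4, n_trees=20).scores
        assert np.all(np.abs(scores) < 0.05)

    def test_averaging_reduces_variance_across_repetitions(self, informative_table):
        # Monte-Carlo: the across-seed variance of the averaged importance
        # shrinks as the number of averaged forests grows.
        def spread(runs, seeds):
            vals = [
                score_forest(informative_table, "rf_mdi", runs=runs, seed=s, n_trees=5).scores
                for s in seeds
            ]
            return np.mean(np.var(np.array(vals), axis=0))

        seeds = range(100, 112)
        assert spread(12, seeds) < spread(2, seeds)

    def test_cf_auc_runs_and_detects_signal(self, informative_table):
        scores = score_forest(informative_table, "cf_auc", runs=2, seed=6, n_trees=20).scores
        names = informative_table.feature_names
        assert names[int(np.argmax(scores))].startswith("inf_")

    def test_unknown_variant_rejected(self, informative_table):
        with pytest.raises(ValueError, match="variant"):
            score_forest(informative_table, "rf_auc", runs=1)


class TestScaleInvariance:
    """Multiplying a feature by 10 leaves every scorer's output unchanged."""

    @pytest.fixture()
    def pair(self, informative_table):
        scaled_values = informative_table.values.copy()
        scaled_values[:, 0] *= 10.0
        scaled = FeatureTable(
            informative_table.feature_names, scaled_values, informative_table.class_labels
        )
        return informative_table, scaled

    def test_deterministic_scorers(self, pair):
        base, scaled = pair
        assert np.allclose(score_median(base).scores, score_median(scaled).scores, atol=1e-9)
        for m in ("pearson", "spearman"):
            assert np.allclose(
                score_correlation(base, m, 0.7).scores,
                score_correlation(scaled, m, 0.7).scores,
                atol=1e-9,
            )
        assert np.allclose(score_logreg(base).scores, score_logreg(scaled).scores, atol=1e-6)

    def test_forest_scorers_same_seed(self, pair):
        base, scaled = pair
        a = score_forest(base, "rf_mdi", runs=1, seed=7, n_trees=10).scores
        b = score_forest(scaled, "rf_mdi", runs=1, seed=7, n_trees=10).scores
        assert np.allclose(a, b, atol=1e-9)
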