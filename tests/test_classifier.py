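"""Per-gene classification: split, preprocessing, tuning, scoring,
importance."""

import math

import numpy as np
import pytest

from isowin.classify import (
    MODEL_TYPES,
    ModelSpec,
    SMALL_GRIDS,
    UntestableGene,
    binomial_accuracy_pvalue,
    extract_importance,
    fit_gene,
    near_zero_variance,
    preprocess_features,
    score_model,
    split_samples,
    tune_and_fit,
)
from isowin.counting import FeatureMatrix
from isowin.windowing import GenomicInterval, Window


def make_fm(X, y, gene_id="g1"):
    windows = [
        Window(gene_id, "exon", 2, j + 1, GenomicInterval("chr1", j * 10, j * 10 + 10, "+"))
        for j in range(X.shape[1])
    ]
    samples = [f"s{i:03d}" for i in range(X.shape[0])]
    return FeatureMatrix(gene_id, samples, windows, np.asarray(X, float), np.asarray(y))


def gaussian_data(rng, n_per_class=100, n_features=5, sep=4.0):
    X = np.vstack([
        rng.normal(0, 1, size=(n_per_class, n_features)),
        rng.normal(sep, 1, size=(n_per_class, n_features)),
    ])
    y = np.array(["group1"] * n_per_class + ["group2"] * n_per_class)
    return X, y


class TestSplit:
    def test_stratified_counts_round_half_up(self):
        ids = [f"s{i}" for i in range(100)]
        labels = ["A"] * 80 + ["B"] * 20
        split = split_samples(ids, labels, frac=0.8, seed=1)
        train_a = sum(1 for s in split.train_ids if int(s[1:]) < 80)
        train_b = len(split.train_ids) - train_a
        assert (train_a, train_b) == (64, 16)
        assert sorted(split.train_ids + split.test_ids) == sorted(ids)

    def test_deterministic_given_seed(self):
        ids = [f"s{i}" for i in range(50)]
        labels = ["A"] * 30 + ["B"] * 20
        s1 = split_samples(ids, labels, seed=7)
        s2 = split_samples(ids, labels, seed=7)
        assert s1.train_ids == s2.train_ids and s1.test_ids == s2.test_ids
        s3 = split_samples(ids, labels, seed=8)
        assert s3.train_ids != s1.train_ids

    def test_tiny_class_rejected(self):
        with pytest.raises(UntestableGene):
            split_samples(["a", "b", "c", "d"], ["A", "A", "A", "B"])


class TestPreprocess:
    def test_constant_column_dropped(self):
        X = np.column_stack([np.ones(50), np.arange(50, dtype=float)])
        assert near_zero_variance(X).tolist() == [False, True]

    def test_near_zero_variance_both_conditions(self):
        # 96 zeros + 4 ones: freq ratio 24 > 19 and 5% unique < 10% -> drop
        col = np.array([0.0] * 96 + [1.0] * 4)
        X = np.column_stack([col, np.arange(100, dtype=float)])
        assert near_zero_variance(X).tolist() == [False, True]

    def test_high_ratio_but_many_unique_values_kept(self):
        # freq ratio 51 > 19 but 51% unique >= 10% -> keep
        col = np.concatenate([np.full(51, 7.0), np.arange(49, dtype=float)])
        X = col[:, None]
        assert near_zero_variance(X).tolist() == [True]

    def test_zscaling_uses_training_statistics(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5, 2, size=(40, 3))
        train = np.arange(30)
        test = np.arange(30, 40)
        state, Xtr, Xte = preprocess_features(X, train, test)
        np.testing.assert_allclose(Xtr.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Xtr.std(axis=0, ddof=1), 1, atol=1e-12)
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0, ddof=1)
        np.testing.assert_allclose(Xte, (X[test] - mu) / sd, atol=1e-12)

    def test_known_value(self):
        # training column with mean 5, sd 2: a value of 7 scales to 1.0
        col = np.array([3.0, 7.0, 3.0, 7.0, 5.0])  # mean 5, sd(ddof=1)=2
        assert col.mean() == 5 and col.std(ddof=1) == 2
        X = np.column_stack([col, np.arange(5, dtype=float)])
        _, Xtr, _ = preprocess_features(X, np.arange(5), np.array([0]))
        assert Xtr[1, 0] == pytest.approx(1.0)

    def test_swapping_test_samples_leaves_state_unchanged(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 4))
        train = np.arange(40)
        s1, _, _ = preprocess_features(X, train, np.arange(40, 50))
        X2 = X.copy()
        X2[40:] = rng.normal(10, 5, size=(10, 4))
        s2, _, _ = preprocess_features(X2, train, np.arange(40, 50))
        np.testing.assert_array_equal(s1.means, s2.means)
        np.testing.assert_array_equal(s1.sds, s2.sds)
        assert s1.kept_windows == s2.kept_windows


class TestBinomialPValue:
    @pytest.mark.parametrize(
        "k,n,nir,expected",
        [
            (10, 10, 0.5, 0.5 ** 10),
            (5, 10, 0.5, sum(math.comb(10, j) for j in range(5, 11)) / 2 ** 10),
        ],
    )
    def test_exact_values(self, k, n, nir, expected):
        assert binomial_accuracy_pvalue(k, n, nir) == pytest.approx(expected, rel=1e-12)
        assert binomial_accuracy_pvalue(10, 10, 0.5) == pytest.approx(9.765625e-4)
        assert binomial_accuracy_pvalue(5, 10, 0.5) == pytest.approx(0.623046875)

    def test_matches_brute_force_enumeration(self):
        for n in range(1, 21):
            for nir in (0.3, 0.5, 0.8):
                for k in range(n + 1):
                    brute = sum(
                        math.comb(n, j) * nir ** j * (1 - nir) ** (n - j)
                        for j in range(k, n + 1)
                    )
                    assert binomial_accuracy_pvalue(k, n, nir) == pytest.approx(
                        brute, rel=1e-9, abs=1e-300
                    )

    def test_below_chance_accuracy_gives_large_p(self):
        assert binomial_accuracy_pvalue(3, 10, 0.5) > 0.5


class TestTuneFitScore:
    @pytest.mark.parametrize("model_type", MODEL_TYPES)
    def test_separable_data_perfect_accuracy(self, model_type):
        rng = np.random.default_rng(3)
        X, y = gaussian_data(rng, n_per_class=100, n_features=5, sep=4.0)
        fm = make_fm(X, y)
        spec = ModelSpec(model_type, grid=SMALL_GRIDS[model_type])
        res = fit_gene(fm, spec, seed=5)
        assert res.test_accuracy == 1.0
        assert res.p_value < 1e-6
        assert res.nir == 0.5

    def test_single_class_training_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        with pytest.raises(UntestableGene):
            tune_and_fit(X, np.array(["A"] * 20), ModelSpec("logistic"))

    def test_same_seed_identical_result(self):
        rng = np.random.default_rng(4)
        X, y = gaussian_data(rng, n_per_class=40, n_features=6, sep=1.0)
        fm = make_fm(X, y)
        spec = ModelSpec("gradient_boosting", grid=SMALL_GRIDS["gradient_boosting"])
        r1 = fit_gene(fm, spec, seed=11)
        r2 = fit_gene(fm, spec, seed=11)
        assert r1.params == r2.params
        assert r1.test_accuracy == r2.test_accuracy
        assert r1.p_value == r2.p_value
        np.testing.assert_array_equal(r1.importance, r2.importance)

    def test_shuffled_labels_accuracy_near_nir(self):
        # under label permutation mean accuracy should track the NIR
        rng = np.random.default_rng(6)
        accs, nirs = [], []
        for rep in range(30):
            X = rng.normal(size=(60, 5))
            y = np.array(["group1"] * 40 + ["group2"] * 20)
            y = rng.permutation(y)
            fm = make_fm(X, y)
            res = fit_gene(fm, ModelSpec("logistic"), seed=rep)
            accs.append(res.test_accuracy)
            nirs.append(res.nir)
        diff = np.mean(accs) - np.mean(nirs)
        se = np.std(np.array(accs) - np.array(nirs), ddof=1) / np.sqrt(len(accs))
        assert abs(diff) <= 3 * se + 0.02

    def test_pvalue_super_uniform_under_permutation(self):
        rng = np.random.default_rng(7)
        pvals = []
        for rep in range(200):
            X = rng.normal(size=(40, 4))
            y = rng.permutation(np.array(["group1"] * 24 + ["group2"] * 16))
            fm = make_fm(X, y)
            try:
                pvals.append(fit_gene(fm, ModelSpec("logistic"), seed=rep).p_value)
            except UntestableGene:
                pass
        pvals = np.array(pvals)
        for t in (0.01, 0.05, 0.1, 0.25):
            frac = np.mean(pvals <= t)
            se = math.sqrt(t * (1 - t) / len(pvals))
            assert frac <= t + 3 * se


class TestImportance:
    def test_informative_feature_ranks_top(self):
        rng = np.random.default_rng(8)
        top_hits = {"elastic_net": 0, "gradient_boosting": 0}
        n_sim = 25
        for rep in range(n_sim):
            n = 120
            y = np.array(["group1"] * 60 + ["group2"] * 60)
            X = rng.normal(size=(n, 21))
            X[:, 7] += np.where(y == "group1", 0.0, 2.5)
            for mt in top_hits:
                spec = ModelSpec(mt, grid=SMALL_GRIDS[mt][:1])
                fitted = tune_and_fit(X, y, spec, seed=rep)
                raw, scaled = extract_importance(fitted, X, y)
                if np.argmax(raw) == 7:
                    top_hits[mt] += 1
                assert scaled.max() == pytest.approx(100.0)
        for mt, hits in top_hits.items():
            assert hits >= 0.9 * n_sim, mt

    def test_elastic_net_fully_shrunk_gives_zero_importance(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(60, 5))
        y = np.array(["group1", "group2"] * 30)
        spec = ModelSpec("elastic_net", grid=[{"l1_ratio": 1.0, "C": 1e-6}])
        fitted = tune_and_fit(X, y, spec, seed=0)
        raw, scaled = extract_importance(fitted)
        assert np.all(raw == 0) and np.all(scaled == 0)

    def test_unused_feature_zero_gain_in_boosting(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(200, 10))
        y = np.where(X[:, 0] > 0, "group1", "group2")
        X[:, 5] = 0.0  # constant: can never be split on
        spec = ModelSpec("gradient_boosting", grid=SMALL_GRIDS["gradient_boosting"][:1])
        fitted = tune_and_fit(X, y, spec, seed=0)
        raw, _ = extract_importance(fitted)
        assert raw[5] == 0.0
        assert raw[0] > 0

    def test_logistic_importance_is_finite_even_when_separable(self):
        X = np.vstack([np.full((20, 2), -3.0), np.full((20, 2), 3.0)])
        X += np.random.default_rng(11).normal(0, 0.1, X.shape)
        y = np.array(["a"] * 20 + ["b"] * 20)
        fitted = tune_and_fit(X, y, ModelSpec("logistic"), seed=0)
        raw, scaled = extract_importance(fitted, X, y)
        assert np.all(np.isfinite(raw)) and np.all(np.isfinite(scaled))


class TestScoreModel:
    def test_nir_is_majority_share_of_test_set(self):
        rng = np.random.default_rng(12)
        X, y = gaussian_data(rng, n_per_class=30, sep=3.0)
        fitted = tune_and_fit(X, y, ModelSpec("logistic"), seed=0)
        Xte = rng.normal(0, 1, size=(10, 5))
        yte = np.array(["group1"] * 7 + ["group2"] * 3)
        acc, nir, p = score_model(fitted, Xte, yte)
        assert nir == 0.7
        assert 0 <= acc <= 1 and 0 < p <= 1
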