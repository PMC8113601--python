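"""Shapley attribution, aggregation, significance rule, clustering and the
interpretation statistics."""

import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radstack.attribution import (
    AttributionMatrix,
    DecisionTree,
    TreeEnsembleModel,
    aggregate_across_splits,
    cluster_contributions,
    cluster_from_meta_weight,
    dataset_contributions,
    enrichment_test,
    exact_shapley,
    overlap_representation,
    shap_values,
    significant_features,
    spearman_attr_value,
)
from radstack.core_data import AnnotationSets, DataError
from radstack.synthetic import generate_tiny_tree_model


def permutation_shapley(model, x, background):
    """Independent oracle: average marginal contribution over all feature
    orderings, with the same background-composite value function."""
    m = len(x)
    phi = np.zeros(m)
    cache = {}

    def value(S):
        key = frozenset(S)
        if key not in cache:
            comp = background.copy()
            for j in S:
                comp[:, j] = x[j]
            cache[key] = model.predict_proba(comp).mean()
        return cache[key]

    for order in permutations(range(m)):
        prefix = []
        for j in order:
            phi[j] += value(prefix + [j]) - value(prefix)
            prefix.append(j)
    return phi / math.factorial(m)


def stump(threshold=0.0, lo=0.2, hi=0.8, feature=0, n_features=2):
    tree = DecisionTree(
        feature=np.array([feature, -1, -1]),
        threshold=np.array([threshold, 0.0, 0.0]),
        left=np.array([1, 0, 0]),
        right=np.array([2, 0, 0]),
        value=np.array([0.0, lo, hi]),
        missing_left=np.array([True, True, True]),
    )
    return TreeEnsembleModel([tree], [f"x{j}" for j in range(n_features)],
                             aggregation="mean")


class TestExactShapley:
    def test_stump_with_balanced_background(self):
        model = stump()
        bg = np.array([[-1.0, 0.0], [1.0, 0.0]])
        X = pd.DataFrame([[1.0, 0.0], [-1.0, 0.0]], columns=model.feature_names)
        attr = shap_values(model, X, background=pd.DataFrame(bg, columns=model.feature_names))
        assert attr.mode == "exact"
        assert attr.prior == pytest.approx(0.5)
        np.testing.assert_allclose(attr.values.to_numpy(),
                                   [[0.3, 0.0], [-0.3, 0.0]], atol=1e-12)

    def test_constant_model_attributes_nothing(self):
        model = stump(lo=0.4, hi=0.4)
        bg = np.array([[0.0, 0.0]])
        phi = exact_shapley(model, np.array([[2.0, 5.0]]), bg)
        np.testing.assert_allclose(phi, 0.0, atol=1e-12)

    def test_symmetry_of_duplicated_features(self):
        # two trees, one splitting on each copy of the same underlying value
        t0 = stump(feature=0).trees[0]
        t1 = stump(feature=1).trees[0]
        model = TreeEnsembleModel([t0, t1], ["a", "b"], aggregation="mean")
        bg = np.array([[-1.0, -1.0], [1.0, 1.0]])
        phi = exact_shapley(model, np.array([[1.0, 1.0]]), bg)
        assert phi[0, 0] == pytest.approx(phi[0, 1], abs=1e-12)

    def test_matches_permutation_oracle_on_random_ensembles(self):
        worst = 0.0
        for seed in range(10):
            model = generate_tiny_tree_model(4, n_trees=3, depth=3, seed=seed)
            r = np.random.default_rng(1000 + seed)
            X = r.uniform(-1, 1, size=(2, 4))
            bg = r.uniform(-1, 1, size=(6, 4))
            phi = exact_shapley(model, X, bg)
            for i in range(2):
                oracle = permutation_shapley(model, X[i], bg)
                worst = max(worst, np.abs(phi[i] - oracle).max())
        assert worst < 1e-8

    def test_local_accuracy(self):
        model = generate_tiny_tree_model(5, n_trees=3, depth=3, seed=42)
        r = np.random.default_rng(7)
        X = pd.DataFrame(r.uniform(-1, 1, size=(4, 5)), columns=model.feature_names)
        bg = pd.DataFrame(r.uniform(-1, 1, size=(8, 5)), columns=model.feature_names)
        attr = shap_values(model, X, background=bg)
        p = model.predict_proba(X.to_numpy())
        np.testing.assert_allclose(attr.values.sum(axis=1), p - attr.prior,
                                   atol=1e-8)

    def test_feature_mismatch_rejected(self):
        model = stump()
        X = pd.DataFrame([[0.0]], columns=["wrong"])
        with pytest.raises(DataError, match="mismatch"):
            shap_values(model, X, background=X)


class TestAggregation:
    def _matrix(self, values, prior=0.2):
        df = pd.DataFrame(values).astype(float)
        df.index = [f"S{i}" for i in range(len(df))]
        df.columns = ["f0", "f1"]
        return AttributionMatrix(values=df, prior=prior,
                                 dataset_of={"f0": "a", "f1": "b"})

    def test_inverse_loss_weights(self):
        m1 = self._matrix([[0.2, 0.2]])       # row sum 0.4
        m2 = self._matrix([[0.4, 0.4]])       # row sum 0.8
        out = aggregate_across_splits([m1, m2], [0.2, 0.4])
        assert out.split_weights == pytest.approx([2 / 3, 1 / 3])
        # each row normalized to sum 1 then averaged -> still sums to 1
        assert out.values.loc["S0"].sum() == pytest.approx(1.0)

    def test_equal_losses_are_a_simple_mean(self):
        m1 = self._matrix([[0.3, 0.1]])
        m2 = self._matrix([[0.1, 0.3]])
        out = aggregate_across_splits([m1, m2], [0.5, 0.5])
        np.testing.assert_allclose(out.values.loc["S0"], [0.5, 0.5])

    def test_normalized_rows_sum_to_one(self):
        r = np.random.default_rng(3)
        mats = [self._matrix(r.normal(size=(4, 2)) + 0.5) for _ in range(3)]
        out = aggregate_across_splits(mats, [0.3, 0.5, 0.7])
        ok = [s for s in out.values.index if s not in out.flagged]
        np.testing.assert_allclose(out.values.loc[ok].sum(axis=1), 1.0, atol=1e-6)

    def test_near_prior_samples_flagged(self):
        m1 = self._matrix([[1e-9, -1e-9], [0.2, 0.2]])
        out = aggregate_across_splits([m1], [0.4])
        assert out.flagged == ["S0"]

    def test_nonpositive_loss_rejected(self):
        with pytest.raises(DataError):
            aggregate_across_splits([self._matrix([[0.1, 0.1]])], [0.0])


class TestSignificantFeatures:
    def test_worked_four_feature_example(self):
        s = pd.Series({"a": 0.5, "b": 0.3, "c": 0.15, "d": 0.05})
        assert significant_features(s, coverage=0.95) == ["a", "b", "c"]

    def test_full_coverage_keeps_all_nonzero(self):
        s = pd.Series({"a": 0.5, "b": 0.3, "c": 0.2, "z": 0.0})
        assert significant_features(s, coverage=1.0) == ["a", "b", "c"]

    def test_dominant_singleton(self):
        s = pd.Series({"big": 0.96, "s1": 0.02, "s2": 0.02})
        assert significant_features(s, coverage=0.95) == ["big"]

    def test_prefix_is_minimal(self, rng):
        s = pd.Series(rng.random(30), index=[f"f{i}" for i in range(30)])
        sig = significant_features(s, coverage=0.95)
        total = s.sum()
        assert s[sig].sum() >= 0.95 * total - 1e-12
        assert s[sig[:-1]].sum() < 0.95 * total

    def test_all_zero_gives_empty(self):
        assert significant_features(pd.Series({"a": 0.0})) == []


class TestDatasetContributions:
    def _attr(self, rows, features=("a1", "a2", "b1")):
        df = pd.DataFrame(rows, columns=list(features))
        df.index = [f"S{i}" for i in range(len(df))]
        return AttributionMatrix(values=df, prior=0.2,
                                 dataset_of={"a1": "a", "a2": "a", "b1": "b"})

    def test_fraction_arithmetic(self):
        prof = dataset_contributions(self._attr([[0.3, 0.0, 0.1], [0.1, 0.1, 0.1]],
                                                ("a1", "b1", "a2")))
        # careful: a1,a2 belong to 'a'; b1 to 'b'
        row = prof.fractions.loc["S0"]
        assert row["a"] + row["b"] == pytest.approx(1.0)

    def test_concentrated_and_rows_sum_to_one(self):
        prof = dataset_contributions(self._attr([[0.4, -0.2, 0.0], [0.1, 0.2, 0.3]]))
        assert prof.fractions.loc["S0", "a"] == pytest.approx(1.0)
        np.testing.assert_allclose(prof.fractions.sum(axis=1), 1.0, atol=1e-9)

    def test_permuting_features_within_dataset_invariant(self):
        a = dataset_contributions(self._attr([[0.3, 0.1, 0.2]]))
        b = dataset_contributions(self._attr([[0.1, 0.3, 0.2]]))
        pd.testing.assert_frame_equal(a.fractions, b.fractions)

    def test_all_zero_sample_flagged(self):
        prof = dataset_contributions(self._attr([[0.0, 0.0, 0.0], [0.1, 0.0, 0.1]]))
        assert prof.flagged == ["S0"]


class TestClustering:
    def test_three_blobs_recovered_and_ordered(self):
        r = np.random.default_rng(0)
        x = np.r_[r.normal(0.1, 0.02, 40), r.normal(0.5, 0.02, 40),
                  r.normal(0.9, 0.02, 40)]
        labels, k, _ = cluster_contributions(x, k_max=5, seed=0, n_refs=20)
        assert k == 3
        means = pd.Series(x).groupby(labels.to_numpy()).mean()
        assert means["Low"] < means["Medium"] < means["High"]

    def test_single_blob_gives_k1(self):
        r = np.random.default_rng(1)
        x = r.normal(0.5, 0.01, 80)
        _, k, _ = cluster_contributions(x, k_max=4, seed=0, n_refs=20)
        assert k == 1

    def test_degenerate_equal_input(self):
        labels, k, _ = cluster_contributions(np.full(30, 0.4), k_max=3, seed=0)
        assert k == 1 and set(labels) == {"Low"}

    def test_meta_weight_threshold_perfect_separation(self):
        w = np.r_[np.full(10, 0.1), np.full(10, 0.9)]
        labels = ["Low"] * 10 + ["High"] * 10
        t, acc = cluster_from_meta_weight(w, labels)
        assert acc == 1.0 and 0.1 <= t < 0.9

    def test_meta_weight_monotone_invariance(self):
        r = np.random.default_rng(2)
        w = r.random(40)
        labels = np.where(w + r.normal(0, 0.2, 40) < 0.5, "Low", "High")
        if len(set(labels)) < 2:
            pytest.skip("degenerate draw")
        _, acc1 = cluster_from_meta_weight(w, labels)
        _, acc2 = cluster_from_meta_weight(np.tanh(4 * w), labels)
        assert acc1 == pytest.approx(acc2)

    def test_independent_weights_give_majority_accuracy(self):
        r = np.random.default_rng(3)
        labels = ["Low"] * 30 + ["High"] * 70
        accs = []
        for _ in range(30):
            w = r.random(100)
            _, acc = cluster_from_meta_weight(w, labels)
            accs.append(acc)
        assert 0.68 <= np.mean(accs) <= 0.85  # majority fraction plus sweep optimism

    def test_single_class_grouping_rejected(self):
        with pytest.raises(DataError):
            cluster_from_meta_weight([0.1, 0.2], ["Low", "Low"])


class TestInterpretationStats:
    def test_spearman_examples(self):
        assert spearman_attr_value([1, 2, 3], [10, 20, 30])[0] == pytest.approx(1.0)
        assert spearman_attr_value([1, 2, 3], [30, 20, 10])[0] == pytest.approx(-1.0)
        assert spearman_attr_value([1, 2, 3], [1, 3, 2])[0] == pytest.approx(0.5)

    def test_spearman_constant_flagged_nan(self):
        rho, p = spearman_attr_value([1.0, 1.0, 1.0], [1, 2, 3])
        assert math.isnan(rho)

    def test_enrichment_null_table(self):
        ann = AnnotationSets(universe={f"g{i}" for i in range(40)},
                             sets={"s": {f"g{i}" for i in range(20)}})
        sig = {f"g{i}" for i in range(10)} | {f"g{i}" for i in range(20, 30)}
        out = enrichment_test(sig, ann)
        assert out.loc["s", "chi2"] == 0.0 and out.loc["s", "p"] == 1.0

    def test_enrichment_matches_scipy_yates(self):
        universe = {f"g{i}" for i in range(80)}
        members = {f"g{i}" for i in range(40)}
        sig = {f"g{i}" for i in range(30)} | {f"g{i}" for i in range(40, 50)}
        ann = AnnotationSets(universe=universe, sets={"s": members})
        out = enrichment_test(sig, ann)
        table = np.array([[30, 10], [10, 30]])
        chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
        assert out.loc["s", "chi2"] == pytest.approx(chi2)
        assert out.loc["s", "p"] == pytest.approx(p)

    def test_enrichment_transpose_symmetry(self):
        universe = {f"g{i}" for i in range(60)}
        s1 = {f"g{i}" for i in range(25)}
        s2 = {f"g{i}" for i in range(15, 45)}
        a = enrichment_test(s2, AnnotationSets(universe, {"x": s1}))
        b = enrichment_test(s1, AnnotationSets(universe, {"x": s2}))
        assert a.loc["x", "chi2"] == pytest.approx(b.loc["x", "chi2"])

    def test_enrichment_disjoint_set_rejected(self):
        ann = AnnotationSets(universe={"g1"}, sets={"s": {"h1"}})
        with pytest.raises(DataError):
            enrichment_test({"g1"}, ann)

    def test_representation_factor_arithmetic(self):
        universe = {f"g{i}" for i in range(20000)}
        s1 = {f"g{i}" for i in range(100)}
        s2 = {f"g{i}" for i in range(95, 295)}
        rf, p = overlap_representation(s1, s2, universe)
        assert rf == pytest.approx(5 / (100 * 200 / 20000))

    def test_expected_overlap_gives_rf_one(self):
        universe = {f"g{i}" for i in range(100)}
        s1 = {f"g{i}" for i in range(50)}
        s2 = {f"g{i}" for i in range(25, 75)}   # overlap 25 = 50*50/100
        rf, _ = overlap_representation(s1, s2, universe)
        assert rf == pytest.approx(1.0)

    def test_disjoint_sets_hypergeometric_tail(self):
        universe = {f"g{i}" for i in range(40)}
        s1 = {f"g{i}" for i in range(20)}
        s2 = {f"g{i}" for i in range(20, 40)}
        rf, p = overlap_representation(s1, s2, universe)
        assert rf == 0.0
        # exact hypergeometric probability of zero overlap is the extreme table
        expected_p = stats.fisher_exact([[0, 20], [20, 0]], "two-sided")[1]
        assert p == pytest.approx(expected_p)


class TestAttributionIO:
    def test_tsv_roundtrip(self, tmp_path):
        df = pd.DataFrame([[0.1, -0.2], [0.3, 0.0]], index=["S0", "S1"],
                          columns=["a1", "b1"])
        m = AttributionMatrix(values=df, prior=0.25,
                              dataset_of={"a1": "a", "b1": "b"})
        path = tmp_path / "attr.tsv"
        m.to_tsv(path)
        back = AttributionMatrix.from_tsv(path)
        np.testing.assert_allclose(back.values[["a1", "b1"]].to_numpy(),
                                   df.to_numpy())
        assert back.dataset_of == m.dataset_of
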