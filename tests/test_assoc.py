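import numpy as np
import pytest
from sklearn.base import BaseEstimator

from metprio import (
    AssociationSet,
    DataError,
    PairSVM,
    compute_metrics,
    cross_validate,
    make_pairs,
    rank_candidates,
    train_svm,
)
from metprio.assoc import PairDataset
from metprio.reduce import ReducedFeatures

from conftest import brute_force_auc


def features_for(ids, dim=3, seed=0):
    rng = np.random.default_rng(seed)
    vals = rng.normal(size=(len(ids), dim))
    return ReducedFeatures(list(ids), vals, dim, 0.99, np.ones(dim))


@pytest.fixture
def toy_features(toy_associations):
    mets = sorted({m for _, m in toy_associations.pairs} | {"m8", "m9"})
    return features_for(["OC", "D1", "D2"], seed=1), features_for(mets, seed=2)


class FirstFeatureScorer(BaseEstimator):
    """Stub classifier whose decision score is the first feature column."""

    def fit(self, X, y):
        return self

    def decision_function(self, X):
        return np.asarray(X, dtype=float)[:, 0]


class ConstantScorer(BaseEstimator):
    def fit(self, X, y):
        return self

    def decision_function(self, X):
        return np.zeros(np.asarray(X).shape[0])


class TestMakePairs:
    def test_counts_and_feature_layout(self, toy_associations, toy_features):
        dis, met = toy_features
        ds = make_pairs(toy_associations, dis, met, mode="SP", ratio=0.6, seed=0)
        # 5 positives, round(0.6 * 5) = 3 negatives
        assert ds.n_pairs == 8
        assert ds.y.sum() == 5
        assert ds.X.shape[1] == dis.values.shape[1] + met.values.shape[1]
        # disease half of every row is the focal disease's feature vector
        assert np.allclose(ds.X[:, :3], dis.row("OC"))

    def test_same_seed_reproduces_negative_sample(self, toy_associations, toy_features):
        dis, met = toy_features
        a = make_pairs(toy_associations, dis, met, "SP", 0.6, seed=5)
        b = make_pairs(toy_associations, dis, met, "SP", 0.6, seed=5)
        assert a.metabolite_ids == b.metabolite_ids
        assert np.array_equal(a.X, b.X)

    def test_sp_pool_excludes_dual_associated(self, toy_associations, toy_features):
        """m4 is tied to both the focal disease and D1: the set-difference
        rule keeps it out of the SP negative pool."""
        dis, met = toy_features
        assert toy_associations.sp_negative_pool() == {"m5", "m6", "m7"}
        ds = make_pairs(toy_associations, dis, met, "SP", ratio=0.6, seed=0)
        negatives = {m for m, y in zip(ds.metabolite_ids, ds.y) if y == 0}
        assert negatives <= {"m5", "m6", "m7"}
        assert "m4" not in negatives

    def test_sm_pool_and_disjointness(self, toy_associations, toy_features):
        dis, met = toy_features
        assert toy_associations.sm_negative_pool() == {"m8", "m9"}
        assert not (toy_associations.sp_negative_pool()
                    & toy_associations.sm_negative_pool())
        ds = make_pairs(toy_associations, dis, met, "SM", ratio=0.4, seed=0)
        negatives = {m for m, y in zip(ds.metabolite_ids, ds.y) if y == 0}
        assert negatives <= {"m8", "m9"}

    def test_pool_too_small_reports_size(self, toy_associations, toy_features):
        dis, met = toy_features
        with pytest.raises(DataError, match="pool has 3"):
            make_pairs(toy_associations, dis, met, "SP", ratio=2.0, seed=0)

    def test_empty_positives_errors(self, toy_features):
        dis, met = toy_features
        assoc = AssociationSet({("D1", "m5")}, "OC")
        with pytest.raises(DataError, match="no known associations"):
            make_pairs(assoc, features_for(["OC", "D1"]), met, "SP", 1.0, 0)

    def test_sm_without_pool_errors(self, toy_features):
        dis, met = toy_features
        assoc = AssociationSet({("OC", "m0"), ("D1", "m5")}, "OC")
        with pytest.raises(DataError, match="no-disease"):
            make_pairs(assoc, dis, met, "SM", 1.0, 0)


class TestSVM:
    def test_linearly_separable_accuracy(self):
        X = np.vstack([np.full((10, 2), -2.0), np.full((10, 2), 2.0)])
        X += np.random.default_rng(0).normal(0, 0.1, X.shape)
        y = np.repeat([0, 1], 10)
        ds = PairDataset(["d"] * 20, [f"m{i}" for i in range(20)], X, y, "SP", 0)
        model = train_svm(ds)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_single_class_errors(self):
        X = np.random.default_rng(0).normal(size=(8, 2))
        with pytest.raises(DataError, match="single-class"):
            PairSVM().fit(X, np.ones(8))

    def test_decision_scores_reproducible(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 4))
        y = (X[:, 0] + 0.3 * rng.normal(size=40) > 0).astype(int)
        s1 = PairSVM().fit(X, y).decision_function(X)
        s2 = PairSVM().fit(X, y).decision_function(X)
        assert np.allclose(s1, s2, atol=1e-8)


class TestCrossValidate:
    def make_ds(self, n=40, seed=0, informative=True):
        rng = np.random.default_rng(seed)
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 3))
        if informative:
            X[:, 0] = y + 0.01 * rng.normal(size=n)
        return PairDataset(["d"] * n, [f"m{i}" for i in range(n)], X, y, "SP", seed)

    def test_perfect_scores_give_unit_metrics(self):
        ds = self.make_ds()
        report = cross_validate(ds, k=5, seed=0, classifier=FirstFeatureScorer())
        assert report.pooled_auc == 1.0
        assert report.pooled_aupr == 1.0
        assert all(a == 1.0 for a in report.fold_auc)
        assert len(report.fold_auc) == 5

    def test_auc_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(7)
        y = np.array([1, 0, 1, 0, 1, 0, 1, 1, 0, 0] * 2)
        scores = rng.normal(size=20)
        auc, _ = compute_metrics(y, scores)
        assert auc == pytest.approx(brute_force_auc(y, scores), abs=1e-12)

    def test_three_point_example(self):
        """Two of the four positive-negative orderings are concordant."""
        auc, _ = compute_metrics([1, 0, 1], [0.9, 0.8, 0.3])
        assert auc == pytest.approx(0.5, abs=1e-12)

    def test_label_swap_maps_auc_to_complement(self):
        """AUC(y, s) = 1 - AUC(1-y, s), and negating the scores restores it."""
        ds = self.make_ds(seed=2)
        s = np.random.default_rng(0).normal(size=ds.n_pairs)
        a1, _ = compute_metrics(ds.y, s)
        a2, _ = compute_metrics(1 - ds.y, s)
        assert a1 == pytest.approx(1 - a2, abs=1e-12)
        a3, _ = compute_metrics(1 - ds.y, -s)
        assert a3 == pytest.approx(a1, abs=1e-12)

    def test_k_exceeding_minority_errors(self):
        ds = self.make_ds(n=10)
        with pytest.raises(DataError, match="minority"):
            cross_validate(ds, k=6, seed=0)
        with pytest.raises(DataError, match=">= 2"):
            cross_validate(ds, k=1, seed=0)

    def test_folds_partition_and_determinism(self):
        ds = self.make_ds(n=60, seed=4)
        r1 = cross_validate(ds, k=6, seed=9)
        r2 = cross_validate(ds, k=6, seed=9)
        assert r1.fold_auc == r2.fold_auc
        assert r1.pooled_auc == r2.pooled_auc


class TestRanking:
    def test_descending_order_and_flags(self):
        met = features_for([f"m{i}" for i in range(6)], dim=2, seed=5)
        dis = features_for(["OC"], dim=2, seed=6)
        model = FirstFeatureScorer()
        ranking = rank_candidates(model, dis, met, "OC", exclude={"m0"})
        scores = [s for _, s, _ in ranking]
        assert scores == sorted(scores, reverse=True)
        assert "m0" not in {m for m, _, _ in ranking}
        for _, s, predicted in ranking:
            assert predicted == (s > 0)

    def test_all_equal_scores_break_ties_lexicographically(self):
        met = features_for(["mB", "mA", "mC"], dim=2)
        dis = features_for(["OC"], dim=2)
        ranking = rank_candidates(ConstantScorer(), dis, met, "OC", exclude=set())
        assert [m for m, _, _ in ranking] == ["mA", "mB", "mC"]

    def test_excluding_everything_errors(self):
        met = features_for(["m1", "m2"], dim=2)
        dis = features_for(["OC"], dim=2)
        with pytest.raises(DataError, match="empty"):
            rank_candidates(ConstantScorer(), dis, met, "OC",
                            exclude={"m1", "m2"})
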