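import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aaanet.features import FEATURE_COLUMNS, compute_feature_table
from aaanet.network import PPINetwork
from aaanet.prioritize import (
    NEGATIVE,
    POSITIVE,
    EvalMetrics,
    LabeledDataset,
    RunConfig,
    TrainedModel,
    call_candidates,
    compare_classifiers,
    evaluate,
    repeated_runs,
    sample_negatives,
    split_train_test,
    tune_and_train,
)
from aaanet.synthetic import SyntheticConfig, generate_network


def make_dataset(n_pos, n_neg, separation=5.0, seed=0):
    """Gaussian feature clusters: positives shifted by `separation`."""
    rng = np.random.default_rng(seed)
    genes = [f"p{i}" for i in range(n_pos)] + [f"n{i}" for i in range(n_neg)]
    X = rng.normal(0, 1, size=(n_pos + n_neg, len(FEATURE_COLUMNS)))
    X[:n_pos] += separation
    feats = pd.DataFrame(X, index=pd.Index(genes, name="gene"), columns=FEATURE_COLUMNS)
    labels = pd.Series([POSITIVE] * n_pos + [NEGATIVE] * n_neg, index=feats.index)
    return LabeledDataset(feats, labels)


@pytest.fixture(scope="module")
def ring_net():
    """20-node ring, enough non-positives for sampling tests."""
    return PPINetwork.from_edges([(f"g{i}", f"g{(i + 1) % 20}") for i in range(20)])


class TestSampleNegatives:
    def test_size_and_disjointness(self, ring_net):
        pos = {"g0", "g1", "g2"}
        neg = sample_negatives(ring_net, pos, ratio=1.0, seed=7)
        assert len(neg) == 3
        assert neg <= ring_net.nodes - pos

    def test_deterministic_per_seed(self, ring_net):
        pos = {"g0", "g1", "g2"}
        assert sample_negatives(ring_net, pos, 1.0, seed=7) == sample_negatives(
            ring_net, pos, 1.0, seed=7
        )

    def test_ratio_scales_size(self, ring_net):
        assert len(sample_negatives(ring_net, {"g0", "g1"}, 2.0, seed=1)) == 4

    def test_all_positive_network_errors(self, ring_net):
        with pytest.raises(ValueError, match="cannot sample"):
            sample_negatives(ring_net, ring_net.nodes, 1.0, seed=0)


class TestSplit:
    def test_stratified_counts(self):
        ds = make_dataset(10, 10)
        train, test = split_train_test(ds, 0.7, seed=0)
        assert (len(train.positives), len(train.negatives)) == (7, 7)
        assert (len(test.positives), len(test.negatives)) == (3, 3)

    def test_partition(self):
        ds = make_dataset(8, 6)
        train, test = split_train_test(ds, 0.7, seed=3)
        assert set(train.genes) & set(test.genes) == set()
        assert set(train.genes) | set(test.genes) == set(ds.genes)

    def test_half_split(self):
        ds = make_dataset(4, 4)
        train, test = split_train_test(ds, 0.5, seed=0)
        assert (len(train.positives), len(train.negatives)) == (2, 2)
        assert (len(test.positives), len(test.negatives)) == (2, 2)

    def test_tiny_class_rejected(self):
        ds = make_dataset(1, 5)
        with pytest.raises(ValueError, match="stratify"):
            split_train_test(ds, 0.7, seed=0)


class TestTuneAndTrain:
    def test_knn_on_separable_clusters(self):
        ds = make_dataset(12, 12, separation=8.0)
        cfg = RunConfig(classifier="knn", cv_folds=4, n_reps=1)
        model = tune_and_train(ds, cfg, seed=0)
        assert model.params["k"] in cfg.grids["knn"]["k"]
        assert model.cv_accuracy == pytest.approx(1.0)

    def test_rf_with_perfectly_informative_feature(self):
        ds = make_dataset(10, 10, separation=0.0, seed=1)
        feats = ds.features.copy()
        feats["D"] = (ds.labels == POSITIVE).astype(float)  # label leak on purpose
        ds = LabeledDataset(feats, ds.labels)
        train, test = split_train_test(ds, 0.5, seed=0)
        cfg = RunConfig(classifier="rf", cv_folds=3, grids={"rf": {"mtry": [7], "ntree": [50]}})
        model = tune_and_train(train, cfg, seed=0)
        assert evaluate(model, test).accuracy == 1.0

    def test_nb_empty_grid_skips_search(self):
        ds = make_dataset(6, 6)
        model = tune_and_train(ds, RunConfig(classifier="nb"), seed=0)
        assert model.params == {}
        assert model.cv_accuracy is None

    def test_single_class_rejected(self):
        ds = make_dataset(6, 6)
        pos_only = LabeledDataset(
            ds.features[ds.labels == POSITIVE], ds.labels[ds.labels == POSITIVE]
        )
        with pytest.raises(ValueError, match="single-class"):
            tune_and_train(pos_only, RunConfig(classifier="nb"), seed=0)

    def test_cv_folds_exceeding_class_rejected(self):
        ds = make_dataset(5, 5)
        with pytest.raises(ValueError, match="cv_folds"):
            tune_and_train(ds, RunConfig(classifier="knn", cv_folds=10), seed=0)

    @pytest.mark.parametrize("clf", ["svm", "nb", "rf", "knn"])
    def test_all_classifiers_separate_clean_clusters(self, clf):
        ds = make_dataset(12, 12, separation=8.0)
        train, test = split_train_test(ds, 0.7, seed=0)
        grids = {
            "svm": {"gamma": [0.1], "cost": [1.0]},
            "rf": {"mtry": [2], "ntree": [50]},
            "knn": {"k": [3]},
            "nb": {},
        }
        cfg = RunConfig(classifier=clf, cv_folds=3, grids=grids)
        m = evaluate(tune_and_train(train, cfg, seed=0), test)
        assert m.accuracy == 1.0
        assert m.auc == 1.0


class _StubEstimator:
    """Fixed predictions/scores, for confusion-matrix arithmetic tests."""

    def __init__(self, preds, scores):
        self._p = np.asarray(preds)
        self._s = np.asarray(scores)
        self.classes_ = [0, 1]

    def predict(self, X):
        return self._p

    def predict_proba(self, X):
        return np.column_stack([1 - self._s, self._s])


def _stub_model(preds, scores):
    return TrainedModel("rf", _StubEstimator(preds, scores), {})


def _test_set(y):
    genes = [f"g{i}" for i in range(len(y))]
    feats = pd.DataFrame(
        np.zeros((len(y), len(FEATURE_COLUMNS))),
        index=pd.Index(genes, name="gene"),
        columns=FEATURE_COLUMNS,
    )
    labels = pd.Series([POSITIVE if v else NEGATIVE for v in y], index=feats.index)
    return LabeledDataset(feats, labels)


class TestEvaluate:
    def test_perfect_predictions(self):
        y = [1, 1, 0, 0]
        m = evaluate(_stub_model(y, [0.9, 0.8, 0.1, 0.2]), _test_set(y))
        assert (m.accuracy, m.precision, m.recall, m.f1, m.auc) == (1, 1, 1, 1, 1)

    def test_all_negative_zero_division_rule(self):
        y = [1, 1, 0, 0]
        with pytest.warns(UserWarning, match="no genes predicted positive"):
            m = evaluate(_stub_model([0, 0, 0, 0], [0.5] * 4), _test_set(y))
        assert (m.accuracy, m.precision, m.recall, m.f1) == (0.5, 0.0, 0.0, 0.0)

    def test_confusion_matrix_arithmetic(self):
        # 2 TP, 1 FP, 1 FN, 2 TN
        y_true = [1, 1, 1, 0, 0, 0]
        y_pred = [1, 1, 0, 1, 0, 0]
        scores = [0.9, 0.8, 0.4, 0.7, 0.2, 0.1]
        m = evaluate(_stub_model(y_pred, scores), _test_set(y_true))
        assert m.precision == pytest.approx(2 / 3)
        assert m.recall == pytest.approx(2 / 3)
        assert m.f1 == pytest.approx(2 / 3)
        assert m.accuracy == pytest.approx(4 / 6)

    def test_single_class_test_set_rejected(self):
        with pytest.raises(ValueError, match="AUC undefined"):
            evaluate(_stub_model([1, 1], [0.5, 0.5]), _test_set([1, 1]))

    def test_metrics_range_validated(self):
        with pytest.raises(ValueError, match="outside"):
            EvalMetrics(accuracy=1.2, precision=0, recall=0, f1=0, auc=0)


@pytest.fixture(scope="module")
def small_sim():
    cfg = SyntheticConfig(
        n_genes=80, module_size=16, p_in=0.6, p_out=0.04, holdout_fraction=0.25, seed=5
    )
    return generate_network(cfg)


class TestRepeatedRuns:
    def _cfg(self, **kw):
        base = dict(classifier="nb", n_reps=3, cv_folds=3, base_seed=11)
        base.update(kw)
        return RunConfig(**base)

    def test_bitwise_reproducible(self, small_sim):
        r1 = repeated_runs(small_sim.net, small_sim.labeled_positives, self._cfg())
        r2 = repeated_runs(small_sim.net, small_sim.labeled_positives, self._cfg())
        assert r1.votes.equals(r2.votes)
        assert [vars(a) for a in r1.metrics] == [vars(b) for b in r2.metrics]

    def test_votes_bounded_and_cover_non_positives(self, small_sim):
        res = repeated_runs(small_sim.net, small_sim.labeled_positives, self._cfg())
        assert set(res.votes.index) == small_sim.net.nodes - small_sim.labeled_positives
        assert ((res.votes >= 0) & (res.votes <= res.n_reps_scored)).all()

    def test_fixed_negatives_mode_runs(self, small_sim):
        res = repeated_runs(
            small_sim.net,
            small_sim.labeled_positives,
            self._cfg(resample_negatives_per_rep=False),
        )
        assert len(res.metrics) == 3

    def test_planted_module_is_learnable(self, small_sim):
        cfg = self._cfg(classifier="rf", n_reps=5, grids={"rf": {"mtry": [2], "ntree": [100]}})
        res = repeated_runs(small_sim.net, small_sim.labeled_positives, cfg)
        vf = res.votes / res.n_reps_scored
        hidden = sorted(small_sim.hidden_positives)
        background = sorted(small_sim.net.nodes - small_sim.disease_truth)
        assert res.mean_metric("accuracy") > 0.7
        assert vf[hidden].mean() > vf[background].mean()

    def test_no_positives_in_network_rejected(self, small_sim):
        with pytest.raises(ValueError, match="no positive genes"):
            repeated_runs(small_sim.net, {"ZZZ"}, self._cfg())

    def test_rep_failure_annotated(self, small_sim):
        cfg = self._cfg(cv_folds=200, classifier="knn")  # folds exceed class size
        with pytest.raises(RuntimeError, match="repetition 0"):
            repeated_runs(small_sim.net, small_sim.labeled_positives, cfg)

    def test_paired_classifier_comparison(self, small_sim):
        grids = {"svm": {"gamma": [0.1], "cost": [1.0]}, "rf": {"mtry": [2], "ntree": [50]},
                 "knn": {"k": [3]}, "nb": {}}
        results = compare_classifiers(
            small_sim.net,
            small_sim.labeled_positives,
            self._cfg(n_reps=2, grids=grids),
            classifiers=("svm", "nb", "rf", "knn"),
        )
        assert set(results) == {"svm", "nb", "rf", "knn"}
        # same rep-seeds -> identical vote index and metric count per classifier
        for res in results.values():
            assert len(res.metrics) == 2
            assert res.votes.index.equals(results["nb"].votes.index)


def _vote_table(votes, n):
    return pd.Series(votes, index=pd.Index([f"g{i}" for i in range(len(votes))], name="gene")), n


class TestCallCandidates:
    def test_majority_rule(self):
        votes, n = _vote_table([200, 0], 200)
        out = call_candidates(votes, n, "majority")
        called = dict(zip(out["gene"], out["called"]))
        assert called == {"g0": True, "g1": False}

    def test_any_vs_majority_contrast(self):
        votes, n = _vote_table([1], 200)
        assert call_candidates(votes, n, "any")["called"].all()
        assert not call_candidates(votes, n, "majority")["called"].any()

    def test_fraction_half_equals_majority_off_tie(self):
        n = 10
        for v in range(n + 1):
            votes, _ = _vote_table([v], n)
            maj = call_candidates(votes, n, "majority")["called"].iloc[0]
            frac = call_candidates(votes, n, "fraction", tau=0.5)["called"].iloc[0]
            if v != n / 2:
                assert maj == frac
            else:  # exact half: fraction(0.5) calls, majority does not
                assert frac and not maj

    def test_sorted_by_vote_fraction_then_gene(self):
        votes, n = _vote_table([5, 9, 9, 1], 10)
        out = call_candidates(votes, n, "any")
        assert list(out["gene"]) == ["g1", "g2", "g0", "g3"]

    def test_invalid_tau_rejected(self):
        votes, n = _vote_table([1], 10)
        with pytest.raises(ValueError, match="tau"):
            call_candidates(votes, n, "fraction", tau=1.5)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        votes=st.lists(st.integers(0, 20), min_size=1, max_size=30),
        n=st.just(20),
    )
    def test_rules_are_nested(self, votes, n):
        s, _ = _vote_table(votes, n)
        any_ = set(call_candidates(s, n, "any").query("called")["gene"])
        maj = set(call_candidates(s, n, "majority").query("called")["gene"])
        strict = set(call_candidates(s, n, "fraction", tau=0.9).query("called")["gene"])
        assert strict <= maj <= any_
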