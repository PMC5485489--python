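import math

import numpy as np
import pandas as pd
import pytest

from targetnet.network_io import LabeledProteome
from targetnet.prediction import (
    CLASSIFIERS,
    PredictionResult,
    confusion_metrics,
    cross_validate,
    feature_benchmark,
    naive_bayes_target_score,
    predict_candidates,
    select_negative_set,
    train_margin_classifier,
)


def labels_from(targets, pt1, pt2=()):
    return LabeledProteome(
        targets=set(targets), pending_featured=set(pt1),
        pending_unfeatured=set(pt2),
    )


def gaussian_blobs(n_per_class, delta, seed, n_features=39):
    rng = np.random.default_rng(seed)
    pos = rng.normal(delta, 1.0, size=(n_per_class, n_features))
    neg = rng.normal(0.0, 1.0, size=(n_per_class, n_features))
    cols = [f"f{j}" for j in range(n_features)]
    x_pos = pd.DataFrame(pos, columns=cols,
                         index=[f"pos{i}" for i in range(n_per_class)])
    x_neg = pd.DataFrame(neg, columns=cols,
                         index=[f"neg{i}" for i in range(n_per_class)])
    return x_pos, x_neg


class TestNaiveBayesScore:
    def test_uninformative_features_give_prior(self):
        # identical feature distribution in both classes -> posterior 0.5
        topo = pd.DataFrame(
            {"community": [1, 1, 2, 2, 1, 1, 2, 2],
             "coreness": [1, 2, 1, 2, 1, 2, 1, 2]},
            index=[f"x{i}" for i in range(8)],
        )
        labels = labels_from(["x0", "x1", "x2", "x3"], ["x4", "x5", "x6", "x7"])
        scores = naive_bayes_target_score(topo, labels)
        assert np.allclose(scores, 0.5)

    def test_separating_community_drives_posterior(self):
        ids = [f"x{i}" for i in range(40)]
        topo = pd.DataFrame(
            {"community": [1] * 20 + [2] * 20, "coreness": [1] * 40},
            index=ids,
        )
        labels = labels_from(ids[:20], ids[20:30], ids[30:])
        scores = naive_bayes_target_score(topo, labels)
        # all PT1 live in the target-free community -> posterior near 0
        assert (scores < 0.2).all()

    def test_hand_computed_posterior(self):
        # 2 communities, single coreness level; hand Bayes with add-one
        # smoothing: D = {a,b} in comm 1, PT = {c,d,e} with c in comm 1.
        # P(comm=1|D) = (2+1)/(2+2) = 3/4 ; P(comm=1|PT) = (1+1)/(3+2) = 2/5
        # coreness likelihoods cancel (single level).
        # posterior(c) = (3/4)/(3/4 + 2/5) with a 0.5 prior
        topo = pd.DataFrame(
            {"community": [1, 1, 1, 2, 2], "coreness": [1, 1, 1, 1, 1]},
            index=list("abcde"),
        )
        labels = labels_from(["a", "b"], ["c", "d"], ["e"])
        scores = naive_bayes_target_score(topo, labels)
        expected_c = (3 / 4) / (3 / 4 + 2 / 5)
        assert scores["c"] == pytest.approx(expected_c)
        # d, e in community 2: P(2|D) = 1/4, P(2|PT) = (2+1)/5
        assert scores["d"] == pytest.approx((1 / 4) / (1 / 4 + 3 / 5))

    def test_unseen_level_handled_by_smoothing(self):
        topo = pd.DataFrame(
            {"community": [1, 1, 2, 3], "coreness": [1, 1, 1, 1]},
            index=list("abcd"),
        )
        labels = labels_from(["a"], ["b", "c", "d"])
        scores = naive_bayes_target_score(topo, labels)  # no error
        assert scores.between(0, 1).all()

    def test_empty_class_rejected(self):
        topo = pd.DataFrame({"community": [1], "coreness": [1]}, index=["a"])
        with pytest.raises(ValueError):
            naive_bayes_target_score(topo, labels_from([], ["a"]))


class TestSelectNegativeSet:
    def test_paper_scale_half_selection(self):
        scores = pd.Series(
            np.linspace(0, 1, 1180), index=[f"p{i:04d}" for i in range(1180)]
        )
        sel = select_negative_set(scores, fraction=0.5)
        assert len(sel.negatives) == 590
        assert set(sel.negatives) == set(scores.nsmallest(590).index)

    def test_floor_rule(self):
        scores = {f"p{i}": i / 10 for i in range(7)}
        assert len(select_negative_set(scores, 0.5).negatives) == 3

    def test_ties_broken_lexicographically(self):
        scores = {"b": 0.1, "a": 0.1, "c": 0.1, "d": 0.9}
        sel = select_negative_set(scores, 0.5)
        assert sel.negatives == ("a", "b")

    def test_subset_invariant(self):
        rng = np.random.default_rng(3)
        for n in (5, 17, 100, 1180):
            scores = pd.Series(rng.random(n), index=[f"p{i}" for i in range(n)])
            sel = select_negative_set(scores, 0.5)
            assert len(sel.negatives) == math.floor(0.5 * n)
            assert set(sel.negatives) <= set(scores.index)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_negative_set({}, 0.5)


class TestMarginClassifier:
    def test_separable_blobs_high_training_accuracy(self):
        x_pos, x_neg = gaussian_blobs(50, 3.0, seed=0)
        model = train_margin_classifier(x_pos, x_neg, seed=0)
        x = pd.concat([x_pos, x_neg]).to_numpy()
        y = np.r_[np.ones(50), np.zeros(50)]
        assert (model.predict(x) == y).mean() >= 0.99

    def test_known_separating_line(self):
        # hand-placed 2-D points separable by x0 = 0
        x_pos = pd.DataFrame({"a": [1.0, 2.0, 1.5], "b": [0.0, 1.0, -1.0]},
                             index=["p1", "p2", "p3"])
        x_neg = pd.DataFrame({"a": [-1.0, -2.0, -1.5], "b": [0.5, -1.0, 1.0]},
                             index=["n1", "n2", "n3"])
        model = train_margin_classifier(x_pos, x_neg)
        test = pd.DataFrame({"a": [3.0, -3.0], "b": [0.0, 0.0]},
                            index=["q1", "q2"])
        assert list(model.predict(test.to_numpy())) == [1.0, 0.0]

    def test_single_class_rejected(self):
        x_pos, _ = gaussian_blobs(5, 1.0, seed=1)
        with pytest.raises(ValueError):
            train_margin_classifier(x_pos, x_pos.iloc[:0])


class TestCrossValidate:
    def test_confusion_metric_arithmetic(self):
        m = confusion_metrics(tp=8, fp=3, tn=14, fn=3)
        assert m["ppv"] == pytest.approx(8 / 11)
        assert m["npv"] == pytest.approx(14 / 17)
        assert m["accuracy"] == pytest.approx(22 / 28)

    def test_degenerate_npv_absent(self):
        assert confusion_metrics(tp=5, fp=5, tn=0, fn=0)["npv"] is None

    def test_perfect_classifier_all_metrics_one(self):
        x_pos, x_neg = gaussian_blobs(30, 5.0, seed=2)
        res = cross_validate(x_pos, x_neg, folds=5, seed=0)
        assert res.accuracy == 1.0 and res.ppv == 1.0 and res.npv == 1.0

    def test_chance_level_on_identical_distributions(self):
        accs = []
        for seed in range(20):
            x_pos, x_neg = gaussian_blobs(40, 0.0, seed=seed)
            accs.append(cross_validate(x_pos, x_neg, folds=5, seed=seed).accuracy)
        assert 0.4 <= np.mean(accs) <= 0.6

    def test_fold_assignment_is_partition(self):
        x_pos, x_neg = gaussian_blobs(25, 1.0, seed=4)
        res = cross_validate(x_pos, x_neg, folds=5, seed=1)
        ids = list(x_pos.index) + list(x_neg.index)
        assert sorted(res.fold_assignment) == sorted(ids)
        assert set(res.fold_assignment.values()) == set(range(5))

    def test_metrics_match_stored_confusion(self):
        x_pos, x_neg = gaussian_blobs(30, 1.0, seed=5)
        res = cross_validate(x_pos, x_neg, folds=5, seed=2)
        m = confusion_metrics(res.tp, res.fp, res.tn, res.fn)
        assert res.accuracy == m["accuracy"]
        assert res.ppv == m["ppv"] and res.npv == m["npv"]
        assert res.tp + res.fp + res.tn + res.fn == 60

    def test_small_class_rejected(self):
        x_pos, x_neg = gaussian_blobs(4, 1.0, seed=6)
        with pytest.raises(ValueError):
            cross_validate(x_pos, x_neg, folds=10)


class TestPredictCandidates:
    def test_training_positives_predicted_positive(self):
        x_pos, x_neg = gaussian_blobs(40, 3.0, seed=7)
        model = train_margin_classifier(x_pos, x_neg)
        assert set(predict_candidates(model, x_pos)) == set(x_pos.index)

    def test_empty_candidates(self):
        x_pos, x_neg = gaussian_blobs(10, 3.0, seed=8)
        model = train_margin_classifier(x_pos, x_neg)
        assert predict_candidates(model, x_pos.iloc[:0]) == ()

    def test_column_mismatch_rejected(self):
        x_pos, x_neg = gaussian_blobs(10, 3.0, seed=9)
        model = train_margin_classifier(x_pos, x_neg)
        bad = x_pos.rename(columns={"f0": "g0"})
        with pytest.raises(ValueError, match="columns"):
            predict_candidates(model, bad)

    def test_planted_positive_recall(self):
        # candidates carrying the positive-class signal at effect size 2
        # are recovered with high recall
        recalls = []
        for seed in range(10):
            x_pos, x_neg = gaussian_blobs(100, 2.0, seed=seed, n_features=10)
            model = train_margin_classifier(x_pos, x_neg, seed=seed)
            rng = np.random.default_rng(seed + 500)
            planted = pd.DataFrame(
                rng.normal(2.0, 1.0, size=(250, 10)),
                columns=x_pos.columns,
                index=[f"c{i}" for i in range(250)],
            )
            noise = pd.DataFrame(
                rng.normal(0.0, 1.0, size=(250, 10)),
                columns=x_pos.columns,
                index=[f"z{i}" for i in range(250)],
            )
            cands = predict_candidates(model, pd.concat([planted, noise]))
            recalls.append(
                sum(1 for c in cands if c.startswith("c")) / 250
            )
        assert np.mean(recalls) >= 0.8


class TestFeatureBenchmark:
    @staticmethod
    def planted_profile(n, delta, seed):
        rng = np.random.default_rng(seed)
        ids = [f"x{i:03d}" for i in range(n)]
        y = np.r_[np.ones(n // 2), np.zeros(n - n // 2)]
        cols = ["degree", "betweenness", "eigenvector", "avg_distance",
                "eccentricity", "clustering", "community", "coreness"]
        x = rng.normal(size=(n, len(cols)))
        for j, c in enumerate(cols):
            if c in ("eccentricity", "community", "coreness"):
                x[:, j] += delta * y
        prof = pd.DataFrame(x, index=ids, columns=cols)
        labels = labels_from(
            [i for i, t in zip(ids, y) if t == 1],
            [i for i, t in zip(ids, y) if t == 0],
        )
        return prof, labels

    def test_null_labels_near_chance(self):
        prof, labels = self.planted_profile(200, 0.0, seed=0)
        bm = feature_benchmark(prof, labels, classifiers=("svm", "logistic"),
                               folds=5, seed=0)
        assert ((bm["accuracy"] - 0.5).abs() < 0.12).all()

    def test_particular_features_beat_diluted_set(self):
        # signal only on the three target-characteristic features; adding
        # five pure-noise topological features dilutes the classifier
        wins = 0
        for seed in range(10):
            prof, labels = self.planted_profile(100, 0.6, seed=seed)
            bm = feature_benchmark(prof, labels, classifiers=("svm",),
                                   folds=5, seed=seed)
            by = bm.set_index("feature_set")["accuracy"]
            wins += by["particular"] > by["all_topological"]
        assert wins >= 8

    def test_single_cell_grid(self):
        prof, labels = self.planted_profile(60, 1.0, seed=3)
        bm = feature_benchmark(prof, labels, classifiers=("naive_bayes",),
                               feature_sets={"one": ("degree",)},
                               folds=5, seed=3)
        assert len(bm) == 1
        assert {"classifier", "feature_set", "accuracy", "ppv", "npv"} <= set(
            bm.columns
        )

    def test_grid_complete_for_all_requested_combinations(self):
        prof, labels = self.planted_profile(60, 1.0, seed=4)
        bm = feature_benchmark(
            prof, labels,
            classifiers=("naive_bayes", "svm", "logistic", "decision_tree"),
            folds=5, seed=4,
        )
        assert len(bm) == 4 * 2

    def test_unknown_classifier_rejected(self):
        prof, labels = self.planted_profile(40, 1.0, seed=5)
        with pytest.raises(ValueError, match="unknown classifier"):
            feature_benchmark(prof, labels, classifiers=("weka",), folds=2)

    def test_registry_contents(self):
        assert {"naive_bayes", "svm", "logistic", "decision_tree"} <= set(
            CLASSIFIERS
        )
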