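"""Candidate drug-target prediction.

The procedure mirrors the standard bootstrap for a positive-unlabeled
problem with no curated negative set:

1. score every featured pending protein (PT1) with a categorical naive
   Bayes over its community membership and coreness, under a fixed 50%
   target prior;
2. take the lowest-scoring half of PT1 as the *reliable negative* set
   (1,180 featured pending proteins yield floor(0.5 · 1180) = 590
   negatives);
3. train a maximum-margin linear classifier (SVM, linear kernel, C = 1)
   on the chemical-physical feature vectors of targets vs. negatives, with
   per-fold standardization;
4. evaluate by stratified 10-fold cross-validation (accuracy, PPV, NPV
   from the pooled held-out confusion matrix);
5. call every PT1 protein with a positive decision value a candidate
   target.

A benchmark harness runs a grid of classifiers × feature sets over the
topological profile (the "all topological" set vs. the three
target-characteristic features: eccentricity, community, coreness).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .network_io import LabeledProteome

__all__ = [
    "NegativeSetSelection",
    "PredictionResult",
    "naive_bayes_target_score",
    "select_negative_set",
    "train_margin_classifier",
    "cross_validate",
    "predict_candidates",
    "feature_benchmark",
    "confusion_metrics",
    "CLASSIFIERS",
]

#: Pluggable classifier registry for the benchmark harness.
CLASSIFIERS: dict[str, object] = {
    "naive_bayes": GaussianNB(),
    "svm": SVC(kernel="linear", C=1.0),
    "logistic": LogisticRegression(max_iter=2000),
    "decision_tree": DecisionTreeClassifier(random_state=0),
}

#: The two canonical feature sets over the topology profile.
TOPOLOGICAL_FEATURES = (
    "degree",
    "betweenness",
    "eigenvector",
    "avg_distance",
    "eccentricity",
    "clustering",
    "community",
    "coreness",
)
PARTICULAR_FEATURES = ("eccentricity", "community", "coreness")


def naive_bayes_target_score(
    topo_features: pd.DataFrame,
    labels: LabeledProteome,
    prior: float = 0.5,
) -> pd.Series:
    """Posterior target probability for every PT1 protein.

    Categorical naive Bayes over the discrete columns of *topo_features*
    (expected: ``community`` and ``coreness``), with add-one (Laplace)
    smoothing over the levels observed in the whole network, a fixed
    ``prior`` P(target), target likelihoods estimated from D, and
    non-target likelihoods from all pending proteins (PT1 ∪ PT2).

    Unseen feature levels are handled by the smoothing, never an error.
    """
    if not 0 < prior < 1:
        raise ValueError("prior must be in (0, 1)")
    d_ids = sorted(labels.targets & set(topo_features.index), key=str)
    pt_ids = sorted(labels.pending & set(topo_features.index), key=str)
    pt1_ids = sorted(labels.pending_featured & set(topo_features.index), key=str)
    if not d_ids or not pt_ids:
        raise ValueError("naive Bayes needs at least one target and one pending protein")
    log_odds = pd.Series(
        math.log(prior) - math.log(1 - prior), index=pd.Index(pt1_ids, name="id"),
        dtype=float,
    )
    for col in topo_features.columns:
        levels = sorted(topo_features[col].unique().tolist())
        k = len(levels)
        d_counts = topo_features.loc[d_ids, col].value_counts()
        pt_counts = topo_features.loc[pt_ids, col].value_counts()
        ll = {}
        for lev in levels:
            p_d = (d_counts.get(lev, 0) + 1) / (len(d_ids) + k)
            p_pt = (pt_counts.get(lev, 0) + 1) / (len(pt_ids) + k)
            ll[lev] = math.log(p_d) - math.log(p_pt)
        log_odds += topo_features.loc[pt1_ids, col].map(ll).astype(float)
    return 1.0 / (1.0 + np.exp(-log_odds))


@dataclass
class NegativeSetSelection:
    """Outcome of the negative-set construction step."""

    scores: pd.Series  # posterior target probability per PT1 protein
    negatives: tuple  # selected identifiers, sorted
    fraction: float = 0.5


def select_negative_set(
    scores: Mapping[Hashable, float] | pd.Series, fraction: float = 0.5
) -> NegativeSetSelection:
    """Select the floor(fraction · n) lowest-posterior proteins as negatives.

    Ties at the cut are broken by lexicographically smallest identifier.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    s = pd.Series(dict(scores)) if not isinstance(scores, pd.Series) else scores
    if len(s) == 0:
        raise ValueError("cannot select negatives from an empty score set")
    n_sel = math.floor(fraction * len(s))
    order = sorted(s.items(), key=lambda kv: (kv[1], str(kv[0])))
    negatives = tuple(sorted((k for k, _ in order[:n_sel]), key=str))
    return NegativeSetSelection(scores=s, negatives=negatives, fraction=fraction)


def _check_xy(x_pos: pd.DataFrame, x_neg: pd.DataFrame) -> None:
    if len(x_pos) == 0 or len(x_neg) == 0:
        raise ValueError("both classes must be nonempty")
    if list(x_pos.columns) != list(x_neg.columns):
        raise ValueError("positive and negative feature columns differ")


def _make_pipeline(estimator=None, seed: int = 0) -> Pipeline:
    if estimator is None:
        estimator = SVC(kernel="linear", C=1.0, random_state=seed)
    return Pipeline([("scale", StandardScaler()), ("clf", estimator)])


def train_margin_classifier(
    x_pos: pd.DataFrame, x_neg: pd.DataFrame, seed: int = 0
) -> Pipeline:
    """Fit the linear-kernel SVM (C = 1) on targets vs. negatives.

    Standardization is part of the fitted pipeline, so at prediction time
    the training-set scaling is reused (no leakage).
    """
    _check_xy(x_pos, x_neg)
    x = pd.concat([x_pos, x_neg])
    y = np.r_[np.ones(len(x_pos)), np.zeros(len(x_neg))]
    model = _make_pipeline(seed=seed)
    model.fit(x.to_numpy(), y)
    model.feature_names_ = list(x_pos.columns)
    return model


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict:
    """Accuracy, PPV = TP/(TP+FP) and NPV = TN/(TN+FN) from a confusion
    matrix; a metric with zero denominator is absent (None)."""
    total = tp + fp + tn + fn
    return {
        "accuracy": (tp + tn) / total if total else None,
        "ppv": tp / (tp + fp) if tp + fp else None,
        "npv": tn / (tn + fn) if tn + fn else None,
    }


@dataclass
class PredictionResult:
    """Pooled cross-validation outcome.

    The reported metrics are *properties computed from the stored confusion
    matrix*, so they can always be re-derived exactly.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    folds: int
    seed: int
    fold_assignment: dict = field(default_factory=dict)  # id -> fold index
    candidates: tuple = ()

    @property
    def accuracy(self):
        return confusion_metrics(self.tp, self.fp, self.tn, self.fn)["accuracy"]

    @property
    def ppv(self):
        return confusion_metrics(self.tp, self.fp, self.tn, self.fn)["ppv"]

    @property
    def npv(self):
        return confusion_metrics(self.tp, self.fp, self.tn, self.fn)["npv"]


def cross_validate(
    x_pos: pd.DataFrame,
    x_neg: pd.DataFrame,
    folds: int = 10,
    seed: int = 0,
    estimator=None,
) -> PredictionResult:
    """Stratified k-fold cross-validation with a pooled confusion matrix.

    Each fold trains a fresh standardize+classify pipeline on the training
    folds only.  Raises when either class is smaller than the fold count.
    """
    _check_xy(x_pos, x_neg)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if min(len(x_pos), len(x_neg)) < folds:
        raise ValueError(
            f"each class needs at least {folds} samples for {folds}-fold CV"
        )
    x = pd.concat([x_pos, x_neg])
    y = np.r_[np.ones(len(x_pos), dtype=int), np.zeros(len(x_neg), dtype=int)]
    ids = list(x.index)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    tp = fp = tn = fn = 0
    fold_assignment: dict = {}
    xv = x.to_numpy()
    for fold_idx, (train, test) in enumerate(skf.split(xv, y)):
        model = _make_pipeline(
            estimator=clone(estimator) if estimator is not None else None, seed=seed
        )
        model.fit(xv[train], y[train])
        pred = model.predict(xv[test])
        for i, p in zip(test, pred):
            fold_assignment[ids[i]] = fold_idx
            if y[i] == 1 and p == 1:
                tp += 1
            elif y[i] == 0 and p == 1:
                fp += 1
            elif y[i] == 0 and p == 0:
                tn += 1
            else:
                fn += 1
    return PredictionResult(
        tp=tp, fp=fp, tn=tn, fn=fn, folds=folds, seed=seed,
        fold_assignment=fold_assignment,
    )


def predict_candidates(model: Pipeline, candidates: pd.DataFrame) -> tuple:
    """Identifiers with a positive decision value, sorted.

    The candidate table must carry exactly the training feature columns.
    """
    if len(candidates) == 0:
        return ()
    expected = getattr(model, "feature_names_", None)
    if expected is not None and list(candidates.columns) != list(expected):
        raise ValueError(
            f"candidate feature columns {list(candidates.columns)} do not match "
            f"training columns {list(expected)}"
        )
    scores = model.decision_function(candidates.to_numpy())
    return tuple(sorted((i for i, s in zip(candidates.index, scores) if s > 0),
                        key=str))


def feature_benchmark(
    profiles: pd.DataFrame,
    labels: LabeledProteome,
    classifiers: Sequence[str] = ("naive_bayes", "svm", "logistic", "decision_tree"),
    feature_sets: Mapping[str, Sequence[str]] | None = None,
    folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """CV-metric grid: classifier × feature set over the topology profile.

    Positives are the targets; negatives are an equal-size seeded sample of
    pending proteins, so the chance level of accuracy is 0.5.  Community
    ids and coreness are passed as integer codes.
    """
    if feature_sets is None:
        feature_sets = {
            "all_topological": TOPOLOGICAL_FEATURES,
            "particular": PARTICULAR_FEATURES,
        }
    unknown = [c for c in classifiers if c not in CLASSIFIERS]
    if unknown:
        raise ValueError(f"unknown classifier(s): {unknown}; "
                         f"available: {sorted(CLASSIFIERS)}")
    pos_ids = sorted(labels.targets & set(profiles.index), key=str)
    pend_ids = sorted(labels.pending & set(profiles.index), key=str)
    rng = np.random.default_rng(seed)
    neg_ids = sorted(
        rng.choice(pend_ids, size=min(len(pos_ids), len(pend_ids)), replace=False),
        key=str,
    )
    rows = []
    for fs_name, cols in feature_sets.items():
        missing = [c for c in cols if c not in profiles.columns]
        if missing:
            raise ValueError(f"profile table lacks feature column(s) {missing}")
        x_pos = profiles.loc[pos_ids, list(cols)]
        x_neg = profiles.loc[neg_ids, list(cols)]
        for name in classifiers:
            res = cross_validate(
                x_pos, x_neg, folds=folds, seed=seed, estimator=CLASSIFIERS[name]
            )
            rows.append(
                {
                    "classifier": name,
                    "feature_set": fs_name,
                    "accuracy": res.accuracy,
                    "ppv": res.ppv,
                    "npv": res.npv,
                }
            )
    return pd.DataFrame(rows)
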