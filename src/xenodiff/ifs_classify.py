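"""Incremental forward selection (IFS) over an MCFS ranking.

Nested candidate sets F1 ⊂ F2 ⊂ … ⊂ FN are built by walking down the
ranking; every candidate is scored by stratified 10-fold cross-validated
random-forest classification, with MCC as the selection criterion (the
classes are heavily imbalanced, so raw accuracy would be misleading). All
candidates share one fold assignment, so differences along the curve
reflect the features and not fold noise. The optimum is the smallest
candidate attaining the maximum mean MCC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from . import metrics
from .data_io import ExpressionMatrix
from .errors import DegenerateLabelError, ParameterError
from .mcfs import FeatureRanking

import warnings


@dataclass
class CandidateSet:
    index: int  # i = number of features
    features: list  # top-i gene ids of the ranking


@dataclass
class IFSResult:
    """Per-candidate CV performance curve plus the selected optimum."""

    curve: pd.DataFrame  # columns: i, mcc, sensitivity, specificity, accuracy
    best_index: int  # i* (number of features)
    best_features: list

    def to_tsv(self, path) -> None:
        self.curve.to_csv(path, sep="\t", index=False, float_format="%.10g")


def build_candidate_sets(ranking: FeatureRanking) -> list[CandidateSet]:
    """All nested prefixes of the ranking: {f1}, {f1,f2}, …"""
    if len(ranking.gene_ids) == 0:
        raise ParameterError("empty ranking")
    return [
        CandidateSet(i, list(ranking.gene_ids[:i]))
        for i in range(1, len(ranking.gene_ids) + 1)
    ]


def stratified_folds(labels, n_folds: int = 10, seed: int = 0) -> np.ndarray:
    """Per-cell fold index with each class spread as evenly as possible.

    Each class's cells are shuffled then dealt round-robin across folds, so
    fold sizes per class differ by at most one; n_folds == n_cells gives
    leave-one-out.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n_folds < 2:
        raise ParameterError("n_folds must be >= 2")
    if n_folds > n:
        raise ParameterError(f"n_folds={n_folds} exceeds {n} cells")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    next_fold = 0  # continue dealing across classes to balance fold totals
    for c in np.unique(labels):
        idx = np.nonzero(labels == c)[0]
        if len(idx) < n_folds:
            warnings.warn(
                f"class {c!r} has {len(idx)} cells < {n_folds} folds; "
                "some folds will lack this class",
                stacklevel=2,
            )
        idx = rng.permutation(idx)
        for i in idx:
            assignment[i] = next_fold
            next_fold = (next_fold + 1) % n_folds
    return assignment


def default_classifier(n_estimators: int = 500, seed: int = 0) -> RandomForestClassifier:
    """The evaluation classifier: a random forest with sqrt(d) features per split."""
    return RandomForestClassifier(
        n_estimators=n_estimators, max_features="sqrt", random_state=seed, n_jobs=1
    )


def evaluate_candidate(
    X: np.ndarray,
    y: np.ndarray,
    feature_idx,
    clf,
    folds: np.ndarray,
    positive_class=None,
) -> pd.DataFrame:
    """Cross-validate one candidate feature set; one row per fold.

    Columns: fold, mcc, sensitivity, specificity, accuracy. Sensitivity is
    the recall of ``positive_class`` (default: the minority class).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise DegenerateLabelError("need two classes to evaluate")
    if positive_class is None:
        positive_class = classes[np.argmin(counts)]
    class_order = [positive_class] + [c for c in classes if c != positive_class]

    records = []
    for f in np.unique(folds):
        test = folds == f
        train = ~test
        if len(np.unique(y[train])) < 2:
            raise DegenerateLabelError(f"training fold {f} contains one class")
        model = clone(clf)
        model.fit(X[np.ix_(train, feature_idx)], y[train])
        pred = model.predict(X[np.ix_(test, feature_idx)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # degenerate-fold MCC -> 0 is fine
            fold_mcc = metrics.mcc_from_labels(pred, y[test], class_order)
        conf = metrics.confusion_counts(pred, y[test], class_order)
        sens, spec, acc = metrics.basic_metrics(conf, positive_index=0)
        records.append(
            {"fold": int(f), "mcc": fold_mcc, "sensitivity": sens,
             "specificity": spec, "accuracy": acc}
        )
    return pd.DataFrame.from_records(records)


def run_ifs(
    m: ExpressionMatrix,
    ranking: FeatureRanking,
    clf=None,
    n_folds: int = 10,
    seed: int = 0,
    positive_class=None,
    max_features: int | None = None,
) -> IFSResult:
    """Evaluate every candidate prefix of the ranking; pick the MCC optimum.

    Ties in mean MCC break toward fewer features (parsimony).
    ``max_features`` truncates the curve (None = full ranking).
    """
    clf = clf if clf is not None else default_classifier(seed=seed)
    folds = stratified_folds(m.labels, n_folds=n_folds, seed=seed)
    col = {g: j for j, g in enumerate(m.gene_ids)}
    candidates = build_candidate_sets(ranking)
    if max_features is not None:
        candidates = candidates[:max_features]

    rows = []
    for cand in candidates:
        idx = [col[g] for g in cand.features]
        per_fold = evaluate_candidate(
            m.values, m.labels, idx, clf, folds, positive_class=positive_class
        )
        means = per_fold[["mcc", "sensitivity", "specificity", "accuracy"]].mean()
        rows.append({"i": cand.index, **means.to_dict()})

    curve = pd.DataFrame.from_records(rows)
    best_pos = int(curve["mcc"].to_numpy().argmax())  # argmax → first/smallest i on ties
    best_i = int(curve.loc[best_pos, "i"])
    return IFSResult(curve, best_i, candidates[best_pos].features)


class IncrementalForwardSelection(BaseEstimator, ClassifierMixin):
    """Meta-estimator: IFS over a precomputed feature ranking.

    Fitting evaluates every ranking prefix by shared-fold cross-validation
    with ``estimator`` (default: 500-tree random forest), stores the curve
    in ``curve_`` and the winning prefix in ``best_features_`` /
    ``best_index_``, then refits the estimator on the full data restricted
    to the winning features, so ``predict`` is available.

    Parameters
    ----------
    ranking : sequence of column indices, strongest first.
    estimator : sklearn classifier, cloned per fold.
    n_folds : folds of the shared stratified assignment (default 10).
    max_features : truncate the curve after this many prefixes.
    random_state : seed for fold assignment and the default estimator.
    """

    def __init__(self, ranking=None, estimator=None, n_folds=10,
                 max_features=None, random_state=0):
        self.ranking = ranking
        self.estimator = estimator
        self.n_folds = n_folds
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        ranking = self.ranking if self.ranking is not None else list(range(X.shape[1]))
        gene_ids = [str(j) for j in range(X.shape[1])]
        em = ExpressionMatrix(
            X, [f"c{i}" for i in range(len(y))], gene_ids, y,
            np.zeros_like(X, dtype=bool),
        )
        fr = FeatureRanking(
            [gene_ids[j] for j in ranking],
            np.arange(len(ranking), 0, -1, dtype=float),
        )
        clf = self.estimator if self.estimator is not None \
            else default_classifier(seed=self.random_state)
        res = run_ifs(em, fr, clf=clf, n_folds=self.n_folds,
                      seed=self.random_state, max_features=self.max_features)
        self.curve_ = res.curve
        self.best_index_ = res.best_index
        self.best_features_ = [int(g) for g in res.best_features]
        self.best_score_ = float(res.curve["mcc"].max())
        self.final_estimator_ = clone(clf).fit(X[:, self.best_features_], y)
        self.classes_ = self.final_estimator_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "final_estimator_")
        X = np.asarray(X, dtype=float)
        return self.final_estimator_.predict(X[:, self.best_features_])
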