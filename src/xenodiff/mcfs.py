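"""Monte Carlo feature selection (MCFS).

MCFS ranks features by aggregating their split contributions over a large
ensemble of s*t decision trees: s random projections of m features are
drawn, and for each projection t trees are trained on independent
stratified train/test splits of the cells. A feature g accumulates relative
importance

    RI_g = sum over trees tau of  wAcc(tau)^u *
           sum over nodes of tau splitting on g of
               IG(node) * (samples in node / samples in tree)^v

where wAcc is the weighted (per-class-mean) accuracy of the tree on its
held-out cells and IG is the base-2 information gain of the split. Features
with high RI are consistently useful across many random contexts, which is
robust to the strong class imbalance typical of tumor-vs-xenograft data.

Defaults for the exponents and ensemble size follow common MCFS practice
(u = v = 1, s = 1000, t = 5, m ~ 5% of features, train fraction 0.66); all
are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .data_io import ExpressionMatrix
from .errors import DegenerateLabelError, LogicError, ParameterError


@dataclass
class MCFSParams:
    """Ensemble-size and weighting parameters of the MCFS ranking."""

    s: int = 1000
    t: int = 5
    m: int | None = None  # default: max(ceil(0.05 * d), 2)
    u: float = 1.0
    v: float = 1.0
    train_fraction: float = 0.66
    seed: int = 0

    def resolve_m(self, d: int) -> int:
        m = self.m if self.m is not None else max(int(np.ceil(0.05 * d)), 2)
        return min(m, d)

    def validate(self, d: int) -> None:
        if self.s < 1 or self.t < 1:
            raise ParameterError("s and t must be >= 1")
        m = self.m if self.m is not None else 2
        if not 1 <= m:
            raise ParameterError(f"m must be >= 1, got {m}")
        if self.m is not None and self.m > d:
            raise ParameterError(f"m={self.m} exceeds feature count d={d}")
        if not 0 < self.train_fraction < 1:
            raise ParameterError("train_fraction must be in (0, 1)")
        if not (np.isfinite(self.u) and np.isfinite(self.v)):
            raise ParameterError("u and v must be finite reals")


@dataclass
class FeatureRanking:
    """Genes ordered by descending relative importance."""

    gene_ids: list
    ri: np.ndarray  # aligned with gene_ids, descending

    def __post_init__(self):
        self.ri = np.asarray(self.ri, dtype=float)
        if len(self.gene_ids) != len(self.ri):
            raise LogicError("ranking ids and RI values differ in length")

    def top(self, k: int) -> list:
        return self.gene_ids[:k]

    def to_tsv(self, path, params: MCFSParams | None = None) -> None:
        import json

        with open(path, "w") as fh:
            if params is not None:
                fh.write("# " + json.dumps(vars(params), sort_keys=True) + "\n")
            fh.write("rank\tgene_id\tRI\n")
            for r, (g, ri) in enumerate(zip(self.gene_ids, self.ri), start=1):
                fh.write(f"{r}\t{g}\t{ri:.10g}\n")


def sample_projections(d: int, m: int, s: int, seed: int = 0) -> list[np.ndarray]:
    """Draw s independent subsets of m distinct features, uniformly."""
    if m > d:
        raise ParameterError(f"m={m} exceeds d={d}")
    rng = np.random.default_rng(seed)
    return [np.sort(rng.choice(d, size=m, replace=False)) for _ in range(s)]


def weighted_accuracy(predicted, truth) -> float:
    """Unweighted mean of per-class recalls, over classes present in truth.

    Insensitive to class imbalance: a majority-class-only predictor scores
    1/N_classes rather than the majority fraction.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if truth.size == 0:
        raise ParameterError("empty label vectors")
    if predicted.shape != truth.shape:
        raise ParameterError("predicted and truth lengths differ")
    recalls = [
        np.mean(predicted[truth == c] == c) for c in np.unique(truth)
    ]
    return float(np.mean(recalls))


def _entropy(labels) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def information_gain(parent_labels, left_labels, right_labels) -> float:
    """Base-2 Shannon information gain of a binary split."""
    parent = np.asarray(parent_labels)
    left = np.asarray(left_labels)
    right = np.asarray(right_labels)
    if len(left) + len(right) != len(parent):
        raise LogicError("children do not partition the parent")
    merged = sorted(np.concatenate([left, right]).tolist())
    if merged != sorted(parent.tolist()):
        raise LogicError("children do not partition the parent (multiset mismatch)")
    n = len(parent)
    return _entropy(parent) - (
        len(left) / n * _entropy(left) + len(right) / n * _entropy(right)
    )


def _tree_seed(seed: int, subset_idx: int, tree_idx: int) -> np.random.SeedSequence:
    # deterministic per-tree stream, independent of execution order
    return np.random.SeedSequence([seed, subset_idx, tree_idx])


def _accumulate_tree(ri, X, y, subset, params, subset_idx, tree_idx):
    """Train one projection tree and add its RI contributions in place."""
    ss = _tree_seed(params.seed, subset_idx, tree_idx)
    split_seed, tree_seed = (int(s) % (2**31 - 1) for s in ss.generate_state(2))
    idx = np.arange(len(y))
    train, test = train_test_split(
        idx, train_size=params.train_fraction, stratify=y, random_state=split_seed
    )
    clf = DecisionTreeClassifier(criterion="entropy", random_state=tree_seed)
    clf.fit(X[np.ix_(train, subset)], y[train])
    wacc = weighted_accuracy(clf.predict(X[np.ix_(test, subset)]), y[test])

    tree = clf.tree_
    n_root = tree.n_node_samples[0]
    left, right = tree.children_left, tree.children_right
    for node in range(tree.node_count):
        if left[node] == -1:  # leaf
            continue
        n_node = tree.n_node_samples[node]
        ig = tree.impurity[node] - (
            tree.n_node_samples[left[node]] / n_node * tree.impurity[left[node]]
            + tree.n_node_samples[right[node]] / n_node * tree.impurity[right[node]]
        )
        ig = max(ig, 0.0)
        g = subset[tree.feature[node]]
        ri[g] += (wacc**params.u) * ig * (n_node / n_root) ** params.v


def rank_features(m: ExpressionMatrix, params: MCFSParams | None = None) -> FeatureRanking:
    """Run the full MCFS ensemble and return the descending RI ranking.

    Ties in RI are broken by ascending original column index; features never
    drawn into any projection keep RI = 0.
    """
    params = params or MCFSParams()
    ri = ri_scores(m.values, m.labels, params)
    order = np.lexsort((np.arange(m.n_genes), -ri))
    return FeatureRanking([m.gene_ids[i] for i in order], ri[order])


def ri_scores(X, y, params: MCFSParams) -> np.ndarray:
    """Per-feature RI vector (unsorted, aligned with columns of X)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    d = X.shape[1]
    params.validate(d)
    if np.isnan(X).any():
        raise ParameterError("input contains missing values; impute first")
    if len(np.unique(y)) < 2:
        raise DegenerateLabelError("need >= 2 classes to rank features")
    m_sub = params.resolve_m(d)
    subsets = sample_projections(d, m_sub, params.s, params.seed)
    ri = np.zeros(d)
    for s_idx, subset in enumerate(subsets):
        for t_idx in range(params.t):
            _accumulate_tree(ri, X, y, subset, params, s_idx, t_idx)
    return ri


def ri_cutoff(
    m: ExpressionMatrix,
    params: MCFSParams | None = None,
    n_perm: int = 20,
    quantile: float = 0.95,
    seed: int = 0,
) -> float:
    """Permutation-based significance threshold on RI.

    Labels are permuted ``n_perm`` times, the ranking is recomputed on each
    permuted copy, and the stated quantile of the per-permutation maximum RI
    is returned; genes whose observed RI exceed it are reported significant.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    params = params or MCFSParams()
    rng = np.random.default_rng(seed)
    maxima = []
    for p_idx in range(n_perm):
        y_perm = rng.permutation(m.labels)
        perm_params = MCFSParams(**{**vars(params), "seed": params.seed + 1 + p_idx})
        maxima.append(ri_scores(m.values, y_perm, perm_params).max())
    return float(np.quantile(maxima, quantile))


class MCFSRanker(SelectorMixin, BaseEstimator):
    """Scikit-learn feature selector backed by MCFS relative importance.

    After ``fit``, ``ri_`` holds the per-column RI vector, ``ranking_`` the
    column indices in descending-RI order. ``transform`` keeps the top
    ``n_features_to_select`` columns (all columns when None, i.e. the
    selector then only reorders knowledge, not data).

    Examples
    --------
    >>> ranker = MCFSRanker(s=100, t=3, random_state=0).fit(X, y)
    >>> ranker.ranking_[:5]   # five strongest features
    """

    def __init__(
        self,
        s: int = 1000,
        t: int = 5,
        m: int | None = None,
        u: float = 1.0,
        v: float = 1.0,
        train_fraction: float = 0.66,
        n_features_to_select: int | None = None,
        random_state: int = 0,
    ):
        self.s = s
        self.t = t
        self.m = m
        self.u = u
        self.v = v
        self.train_fraction = train_fraction
        self.n_features_to_select = n_features_to_select
        self.random_state = random_state

    def _params(self) -> MCFSParams:
        return MCFSParams(
            s=self.s, t=self.t, m=self.m, u=self.u, v=self.v,
            train_fraction=self.train_fraction, seed=self.random_state,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.ri_ = ri_scores(X, y, self._params())
        self.ranking_ = np.lexsort((np.arange(X.shape[1]), -self.ri_))
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "ri_")
        k = self.n_features_to_select or self.n_features_in_
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.ranking_[:k]] = True
        return mask
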