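"""Rough-set rule learning: decision systems, discernibility, Johnson
reducts, and RIPPER rule induction with FOIL gain.

The stage turns a classifier into something a biologist can read. First the
expression matrix (restricted to the selected genes) is viewed as a rough-set
decision system; a discernibility analysis finds a single near-minimal
attribute subset (reduct) that separates every pair of cells the full gene
set separates. RIPPER then learns an ordered list of IF-THEN threshold
rules for the minority class over the reduct genes, with a condition-free
default rule for the majority class. Rule thresholds are learned on the raw
continuous values (midpoints between observed values); discernibility, which
needs discrete values, uses a supervised entropy/MDL (Fayyad-Irani)
discretization per gene.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .data_io import ExpressionMatrix
from .errors import (
    DegenerateLabelError,
    LogicError,
    ParameterError,
)

# --------------------------------------------------------------------------
# supervised discretization (entropy minimization with MDL stopping)


def _label_entropy(y: np.ndarray) -> float:
    if len(y) == 0:
        return 0.0
    _, counts = np.unique(y, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def mdl_cut_points(x: np.ndarray, y: np.ndarray) -> list[float]:
    """Fayyad-Irani recursive binary cuts with the MDL acceptance test."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]

    def recurse(lo: int, hi: int, out: list):
        n = hi - lo
        if n < 2:
            return
        seg_x, seg_y = xs[lo:hi], ys[lo:hi]
        ent = _label_entropy(seg_y)
        k = len(np.unique(seg_y))
        if k < 2:
            return
        # candidate cuts only between distinct adjacent values
        best = None
        # cumulative class counts for O(n) entropy scan
        classes, y_idx = np.unique(seg_y, return_inverse=True)
        onehot = np.zeros((n, len(classes)))
        onehot[np.arange(n), y_idx] = 1
        cum = np.cumsum(onehot, axis=0)
        total = cum[-1]
        for i in range(n - 1):
            if seg_x[i + 1] <= seg_x[i]:
                continue
            left = cum[i]
            right = total - left
            nl, nr = left.sum(), right.sum()
            pl = left[left > 0] / nl
            pr = right[right > 0] / nr
            el = float(-(pl * np.log2(pl)).sum())
            er = float(-(pr * np.log2(pr)).sum())
            w = (nl * el + nr * er) / n
            if best is None or w < best[0]:
                best = (w, i, el, er, left, right)
        if best is None:
            return
        w, i, el, er, left, right = best
        gain = ent - w
        k1 = int((left > 0).sum())
        k2 = int((right > 0).sum())
        delta = math.log2(3**k - 2) - (k * ent - k1 * el - k2 * er)
        if gain <= (math.log2(n - 1) + delta) / n:
            return
        cut = (seg_x[i] + seg_x[i + 1]) / 2.0
        out.append(float(cut))
        recurse(lo, lo + i + 1, out)
        recurse(lo + i + 1, hi, out)

    cuts: list[float] = []
    recurse(0, len(xs), cuts)
    return sorted(cuts)


def discretize_mdl(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-column MDL discretization; columns with no accepted cut become
    a single bin (they then discern nothing)."""
    X = np.asarray(X, dtype=float)
    out = np.zeros(X.shape, dtype=int)
    for j in range(X.shape[1]):
        cuts = mdl_cut_points(X[:, j], y)
        if cuts:
            out[:, j] = np.searchsorted(cuts, X[:, j], side="right")
    return out


# --------------------------------------------------------------------------
# decision systems and discernibility


@dataclass
class DecisionSystem:
    """Rough-set view (U, A ∪ {d}) of a matrix.

    ``values`` holds the attribute table used for discernibility (possibly
    discretized); ``raw_values`` keeps the continuous originals for rule
    induction. ``generalized_decision[i]`` is the frozenset of labels among
    objects indistinguishable from object i on all attributes.
    """

    values: np.ndarray
    attributes: list
    labels: np.ndarray
    raw_values: np.ndarray | None = None
    generalized_decision: list = field(default_factory=list)

    def __post_init__(self):
        if not self.generalized_decision:
            self.generalized_decision = _generalized_decision(self.values, self.labels)

    @property
    def n_objects(self) -> int:
        return self.values.shape[0]


def _generalized_decision(values: np.ndarray, labels: np.ndarray) -> list:
    groups: dict[tuple, set] = {}
    keys = [tuple(row) for row in values]
    for key, lab in zip(keys, labels):
        groups.setdefault(key, set()).add(lab)
    return [frozenset(groups[key]) for key in keys]


def build_decision_system(
    m: ExpressionMatrix, features=None, disc: str | None = "mdl"
) -> DecisionSystem:
    """Build a decision system over the given genes (default: all).

    ``disc="mdl"`` discretizes each gene with the supervised MDL method for
    the discernibility stage; ``disc=None`` keeps raw values as attributes.
    """
    if features is None:
        features = list(m.gene_ids)
    if len(features) == 0:
        raise ParameterError("empty feature set")
    if m.missing_mask.any():
        raise ParameterError("decision system requires an imputed matrix")
    col = {g: j for j, g in enumerate(m.gene_ids)}
    try:
        idx = [col[g] for g in features]
    except KeyError as e:
        raise ParameterError(f"unknown gene {e.args[0]!r}") from None
    raw = m.values[:, idx]
    if disc == "mdl":
        vals = discretize_mdl(raw, m.labels)
    elif disc is None:
        vals = raw
    else:
        raise ParameterError(f"unknown discretization {disc!r}")
    return DecisionSystem(vals, list(features), np.asarray(m.labels), raw_values=raw)


def simplify_pos(conjunctions) -> list[frozenset]:
    """Simplify a product-of-sums: drop duplicates (idempotence) and any
    sum that is a superset of another (absorption)."""
    unique = sorted(set(map(frozenset, conjunctions)), key=lambda s: (len(s), sorted(s)))
    kept: list[frozenset] = []
    for s in unique:
        if not any(k <= s for k in kept):
            kept.append(s)
    return kept


@dataclass
class DiscernibilityStructure:
    """Discernibility matrix plus its row-wise and global POS functions.

    ``entry(i, j)`` is the set of attributes separating objects i and j when
    their generalized decisions differ, else the empty set. The functions
    are returned simplified by idempotence and absorption.
    """

    system: DecisionSystem
    _eligible: np.ndarray  # bool (n, n): generalized decisions differ
    _unique_entries: list  # simplified global conjunction list

    def entry(self, i: int, j: int) -> frozenset:
        if i == j or not self._eligible[i, j]:
            return frozenset()
        diff = self.system.values[i] != self.system.values[j]
        return frozenset(
            self.system.attributes[a] for a in np.nonzero(diff)[0]
        )

    def row_function(self, i: int) -> list[frozenset]:
        """f(x): simplified POS over the non-empty entries of row i."""
        entries = [
            self.entry(i, j) for j in range(self.system.n_objects) if j != i
        ]
        return simplify_pos(e for e in entries if e)

    def global_function(self) -> list[frozenset]:
        """g(U): simplified POS over every non-empty entry of the matrix."""
        return list(self._unique_entries)


def discernibility_matrix(system: DecisionSystem) -> DiscernibilityStructure:
    """Compute the discernibility structure of a decision system.

    Entries exist only for object pairs whose generalized decisions differ
    (pairs with equal generalized decision cannot and need not be
    separated).
    """
    values = np.asarray(system.values)
    n = system.n_objects
    gd = system.generalized_decision
    gd_lut: dict[frozenset, int] = {}
    gd_ids = np.array([gd_lut.setdefault(g, len(gd_lut)) for g in gd])
    eligible = gd_ids[:, None] != gd_ids[None, :]

    # collect the distinct non-empty entries without materializing n^2 sets:
    # group objects by identical attribute rows, then compare row patterns
    patterns: dict[tuple, int] = {}
    pat_rows = []
    pat_gd = []
    for i in range(n):
        key = tuple(values[i])
        if key not in patterns:
            patterns[key] = len(pat_rows)
            pat_rows.append(values[i])
            pat_gd.append(gd[i])
    P = np.array(pat_rows)
    uniq: set[frozenset] = set()
    for a_idx in range(len(P)):
        diff = P[a_idx + 1:] != P[a_idx]
        for off, row in enumerate(diff):
            b_idx = a_idx + 1 + off
            if pat_gd[a_idx] == pat_gd[b_idx]:
                continue
            attrs = np.nonzero(row)[0]
            if len(attrs):
                uniq.add(frozenset(system.attributes[a] for a in attrs))
    return DiscernibilityStructure(system, eligible, simplify_pos(uniq))


def johnson_reduct(pos_function, attribute_order=None) -> list:
    """Greedy (Johnson) reduct from a product-of-sums discernibility function.

    Repeatedly pick the attribute occurring in the most remaining sums
    (frequency ties break by ascending position in ``attribute_order``),
    delete the sums it covers, and stop when none remain.
    """
    remaining = [frozenset(c) for c in pos_function]
    if any(len(c) == 0 for c in remaining):
        raise LogicError("empty conjunction in discernibility function")
    if attribute_order is None:
        attribute_order = sorted({a for c in remaining for a in c})
    rank = {a: i for i, a in enumerate(attribute_order)}
    reduct: list = []
    while remaining:
        counts: dict = {}
        for c in remaining:
            for a in c:
                counts[a] = counts.get(a, 0) + 1
        best = min(counts, key=lambda a: (-counts[a], rank[a]))
        reduct.append(best)
        remaining = [c for c in remaining if best not in c]
    return reduct


def reduct_discerns_all(system: DecisionSystem, reduct) -> bool:
    """Validity check: the reduct separates every object pair that the full
    attribute set separates (pairs with differing generalized decision)."""
    col = {a: j for j, a in enumerate(system.attributes)}
    ridx = [col[a] for a in reduct]
    values = system.values
    gd = system.generalized_decision
    n = system.n_objects
    for i in range(n):
        for j in range(i + 1, n):
            if gd[i] == gd[j]:
                continue
            if (values[i] != values[j]).any() and not (
                values[i, ridx] != values[j, ridx]
            ).any():
                return False
    return True


# --------------------------------------------------------------------------
# RIPPER


def foil_gain(p0: int, n0: int, p: int, n: int) -> float:
    """FOIL information gain of refining a rule: p * (log2 p/(p+n) −
    log2 p0/(p0+n0)); zero when the refinement covers no positives."""
    if p0 + n0 == 0:
        raise LogicError("rule covers nothing before refinement")
    if p == 0:
        return 0.0
    return p * (math.log2(p / (p + n)) - math.log2(p0 / (p0 + n0)))


@dataclass(frozen=True)
class Condition:
    gene: str
    op: str  # ">=" or "<="
    threshold: float

    def holds(self, value: float) -> bool:
        return value >= self.threshold if self.op == ">=" else value <= self.threshold

    def __str__(self) -> str:
        return f"{self.gene} {self.op} {self.threshold:g}"


@dataclass
class DecisionRule:
    conditions: tuple  # of Condition; distinct genes
    outcome: object
    support: int = 0
    coverage: float = 0.0
    rank: int = 0

    def matches(self, mapping) -> bool:
        for c in self.conditions:
            try:
                value = mapping[c.gene]
            except KeyError:
                raise ParameterError(f"cell lacks a value for gene {c.gene!r}") from None
            if not c.holds(value):
                return False
        return True

    def __str__(self) -> str:
        if not self.conditions:
            return f"Other conditions -> {self.outcome}"
        lhs = " AND ".join(str(c) for c in self.conditions)
        return f"IF {lhs} THEN {self.outcome}"


@dataclass
class RuleSet:
    """Ordered rules for the minority class plus a condition-free default."""

    rules: list  # DecisionRule, rank order; default excluded
    default_class: object

    def apply(self, mapping):
        for rule in self.rules:
            if rule.matches(mapping):
                return rule.outcome
        return self.default_class

    def to_json(self, path=None):
        payload = {
            "rules": [
                {
                    "rank": r.rank,
                    "conditions": [
                        {"gene": c.gene, "op": c.op, "threshold": c.threshold}
                        for c in r.conditions
                    ],
                    "outcome": str(r.outcome),
                    "support": r.support,
                    "coverage": r.coverage,
                }
                for r in self.rules
            ],
            "default_class": str(self.default_class),
        }
        if path is None:
            return json.dumps(payload, indent=2)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def to_table(self) -> str:
        lines = []
        for i, r in enumerate(self.rules, start=1):
            first = True
            for c in r.conditions:
                lead = f"Rule {i}" if first else ""
                out = str(r.outcome) if first else ""
                lines.append(f"{lead}\t{c.gene} {c.op} {c.threshold:.6f}\t{out}")
                first = False
        lines.append(f"Rule {len(self.rules) + 1}\tOther conditions\t{self.default_class}")
        return "\n".join(lines)


def apply_rules(ruleset: RuleSet, mapping):
    """Class of the first rule (rank order) whose conditions all hold, else
    the default class."""
    return ruleset.apply(mapping)


@dataclass
class RipperParams:
    grow_fraction: float = 2 / 3  # grow:prune = 2:1, stratified
    dl_budget: float = 64.0  # bits over the best description length
    k_optimize: int = 2  # global optimization passes
    max_rules: int = 50
    seed: int = 0


def _lchoose(n: int, k: int) -> float:
    if k < 0 or k > n:
        return 0.0
    return (math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)) / math.log(2)


class _RipperCore:
    """Internal RIPPER state over one (X, y, positive-class) problem."""

    def __init__(self, X, y, positive, attrs, names, params: RipperParams):
        self.X = X
        self.pos_mask = y == positive
        self.attrs = list(attrs)
        self.names = names
        self.params = params
        self.rng = np.random.default_rng(params.seed)
        # bits to name one condition: attribute + direction + threshold
        n_thr = sum(
            max(len(np.unique(X[:, a])) - 1, 1) for a in self.attrs
        )
        self.cond_bits = math.log2(max(2 * n_thr, 2))

    # --- rule/dataset geometry

    def covers(self, conditions, rows=None) -> np.ndarray:
        rows = slice(None) if rows is None else rows
        Xv = self.X[rows]
        out = np.ones(Xv.shape[0], dtype=bool)
        for c in conditions:
            col = Xv[:, c.attr]
            out &= (col >= c.threshold) if c.op == ">=" else (col <= c.threshold)
        return out

    # --- description length

    def rule_dl(self, conditions) -> float:
        k = len(conditions)
        # RIPPER halves the theoretical cost to correct attribute redundancy
        return 0.5 * (math.log2(k + 1) + k * self.cond_bits)

    def exceptions_dl(self, rules, active: np.ndarray) -> float:
        covered = np.zeros(int(active.sum()), dtype=bool)
        Xa = self.X[active]
        for conds in rules:
            m = np.ones(len(Xa), dtype=bool)
            for c in conds:
                col = Xa[:, c.attr]
                m &= (col >= c.threshold) if c.op == ">=" else (col <= c.threshold)
            covered |= m
        pos = self.pos_mask[active]
        fp = int((covered & ~pos).sum())
        fn = int((~covered & pos).sum())
        n_cov = int(covered.sum())
        n_unc = len(Xa) - n_cov
        return (
            _lchoose(n_cov, fp)
            + _lchoose(n_unc, fn)
            + math.log2(n_cov + 1)
            + math.log2(n_unc + 1)
        )

    def total_dl(self, rules, active) -> float:
        return sum(self.rule_dl(r) for r in rules) + self.exceptions_dl(rules, active)

    # --- growing and pruning

    def _split_grow_prune(self, rows: np.ndarray):
        pos_rows = rows[self.pos_mask[rows]]
        neg_rows = rows[~self.pos_mask[rows]]
        grow, prune = [], []
        for part in (pos_rows, neg_rows):
            part = self.rng.permutation(part)
            cut = int(round(self.params.grow_fraction * len(part)))
            grow.extend(part[:cut])
            prune.extend(part[cut:])
        return np.array(sorted(grow), dtype=int), np.array(sorted(prune), dtype=int)

    def _best_condition(self, rows, used_attrs, p0, n0):
        """Vectorized FOIL-gain scan over every midpoint threshold of every
        available attribute; deterministic tie-break (first best wins in
        attribute order, '<=' before '>=', lower threshold first)."""
        pos = self.pos_mask[rows]
        best_gain, best = 0.0, None
        base = math.log2(p0 / (p0 + n0))
        for a in self.attrs:
            if a in used_attrs:
                continue
            v = self.X[rows, a]
            order = np.argsort(v, kind="stable")
            sv, sp = v[order], pos[order]
            boundary = np.nonzero(sv[1:] > sv[:-1])[0]  # cut after index i
            if len(boundary) == 0:
                continue
            thr = (sv[boundary] + sv[boundary + 1]) / 2.0
            cpos = np.cumsum(sp)
            total_p = cpos[-1]
            # op <=: keep rows with v <= thr  (indices 0..i)
            p_le = cpos[boundary].astype(float)
            n_le = boundary + 1.0 - p_le
            # op >=: keep rows with v >= thr
            p_ge = total_p - p_le
            n_ge = (len(sv) - (boundary + 1.0)) - p_ge
            for op, p_arr, n_arr in (("<=", p_le, n_le), (">=", p_ge, n_ge)):
                with np.errstate(divide="ignore", invalid="ignore"):
                    gains = np.where(
                        p_arr > 0,
                        p_arr * (np.log2(p_arr / (p_arr + n_arr)) - base),
                        0.0,
                    )
                k = int(np.argmax(gains))
                if gains[k] > best_gain + 1e-12:
                    best_gain = float(gains[k])
                    best = _Cond(a, op, float(thr[k]))
        return best, best_gain

    def grow(self, rows, start=()):
        conditions = list(start)
        while True:
            cov = rows[self.covers(conditions, rows)]
            p0 = int(self.pos_mask[cov].sum())
            n0 = len(cov) - p0
            if n0 == 0 or p0 == 0:
                break
            used = {c.attr for c in conditions}
            cond, gain = self._best_condition(cov, used, p0, n0)
            if cond is None or gain <= 0:
                break
            conditions.append(cond)
        return tuple(conditions)

    def prune(self, conditions, prune_rows):
        """Drop a suffix of conditions to maximize (p−n)/(p+n) on the prune
        set; ties favor the shorter rule. Returns (conditions, value)."""
        best_val, best_len = -1.0, 0
        for klen in range(len(conditions), -1, -1):
            cov = prune_rows[self.covers(conditions[:klen], prune_rows)]
            p = int(self.pos_mask[cov].sum())
            n = len(cov) - p
            val = -1.0 if p + n == 0 else (p - n) / (p + n)
            if val >= best_val:  # >= walks toward shorter rules on ties
                best_val, best_len = val, klen
        return conditions[:best_len], best_val

    # --- main loop

    def fit(self):
        n = len(self.X)
        active = np.ones(n, dtype=bool)  # examples not yet covered
        rules: list[tuple] = []
        full = np.arange(n)
        best_dl = self.total_dl(rules, np.ones(n, dtype=bool))
        while self.pos_mask[active].any() and len(rules) < self.params.max_rules:
            rows = full[active]
            if not (~self.pos_mask[rows]).any():
                break  # only positives remain; nothing to separate
            grow_rows, prune_rows = self._split_grow_prune(rows)
            conds = self.grow(grow_rows)
            if len(prune_rows):
                conds, val = self.prune(conds, prune_rows)
            else:
                val = 1.0
            if len(conds) == 0 or val <= 0:
                break  # pruned rule no better than chance
            trial = rules + [conds]
            dl = self.total_dl(trial, np.ones(n, dtype=bool))
            if dl > best_dl + self.params.dl_budget:
                break
            best_dl = min(best_dl, dl)
            rules.append(conds)
            newly = self.covers(conds)
            active &= ~newly

        for _ in range(self.params.k_optimize):
            rules = self._optimize(rules)
        rules = self._global_prune(rules)
        return rules

    def _optimize(self, rules):
        """Per rule, consider a from-scratch replacement and a grown
        revision; keep whichever variant minimizes total description
        length."""
        n = len(self.X)
        everything = np.ones(n, dtype=bool)
        full = np.arange(n)
        out = list(rules)
        for i in range(len(out)):
            others = out[:i] + out[i + 1:]
            covered_by_others = np.zeros(n, dtype=bool)
            for conds in others:
                covered_by_others |= self.covers(conds)
            rows = full[~covered_by_others]
            if len(rows) == 0 or not self.pos_mask[rows].any():
                continue
            grow_rows, prune_rows = self._split_grow_prune(rows)
            variants = [out[i]]
            repl = self.grow(grow_rows)
            if len(prune_rows):
                repl, _ = self.prune(repl, prune_rows)
            if repl:
                variants.append(repl)
            rev = self.grow(grow_rows, start=out[i])
            if len(prune_rows):
                rev, _ = self.prune(rev, prune_rows)
            if rev:
                variants.append(rev)
            dls = [
                self.total_dl(out[:i] + [v] + out[i + 1:], everything)
                for v in variants
            ]
            out[i] = variants[int(np.argmin(dls))]
        return out

    def _global_prune(self, rules):
        """Keep the prefix of the rule list with minimal description length
        (the final global pruning); also drop any rule that no longer covers
        a positive example."""
        n = len(self.X)
        everything = np.ones(n, dtype=bool)
        dls = [
            self.total_dl(rules[:k], everything) for k in range(len(rules) + 1)
        ]
        rules = rules[: int(np.argmin(dls))]
        kept = []
        active = np.ones(n, dtype=bool)
        for conds in rules:
            cov = self.covers(conds) & active
            if (cov & self.pos_mask).any():
                kept.append(conds)
                active &= ~self.covers(conds)
        return kept


@dataclass(frozen=True)
class _Cond:
    attr: int
    op: str
    threshold: float


def ripper(
    system: DecisionSystem,
    reduct=None,
    params: RipperParams | None = None,
    positive_class=None,
) -> RuleSet:
    """Learn an ordered threshold-rule set for the minority class.

    ``system`` must carry continuous values (``raw_values`` if present,
    else ``values``); candidate attributes are restricted to ``reduct``
    (default: all attributes). The returned :class:`RuleSet` ends with an
    implicit default rule predicting the majority class, and every non-
    default rule reports its support (matching cells of its outcome class)
    and coverage (support / class size).
    """
    params = params or RipperParams()
    X = system.raw_values if system.raw_values is not None else system.values
    X = np.asarray(X, dtype=float)
    y = np.asarray(system.labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise DegenerateLabelError(
            f"RIPPER requires exactly two classes, got {len(classes)}"
        )
    if positive_class is None:
        positive_class = classes[np.argmin(counts)]
    negative_class = [c for c in classes if c != positive_class][0]

    if reduct is None:
        reduct = list(system.attributes)
    col = {a: j for j, a in enumerate(system.attributes)}
    try:
        attr_idx = [col[a] for a in reduct]
    except KeyError as e:
        raise ParameterError(f"reduct attribute {e.args[0]!r} not in system") from None

    core = _RipperCore(X, y, positive_class, attr_idx, system.attributes, params)
    raw_rules = core.fit()

    pos_total = int((y == positive_class).sum())
    rules = []
    for rank, conds in enumerate(raw_rules, start=1):
        cov = core.covers(conds)
        support = int((cov & (y == positive_class)).sum())
        rules.append(
            DecisionRule(
                conditions=tuple(
                    Condition(system.attributes[c.attr], c.op, c.threshold)
                    for c in conds
                ),
                outcome=positive_class,
                support=support,
                coverage=support / pos_total if pos_total else 0.0,
                rank=rank,
            )
        )
    return RuleSet(rules, default_class=negative_class)


def rule_network_edges(ruleset: RuleSet) -> list[tuple]:
    """Weighted gene-pair co-occurrence edges for rule-network display.

    Every unordered gene pair appearing together in a rule gets an edge
    weighted by the sum over such rules of support x coverage, normalized
    to [0, 1] by the maximum edge. Single-condition rules contribute no
    edges.
    """
    weights: dict[tuple, float] = {}
    for rule in ruleset.rules:
        genes = sorted({c.gene for c in rule.conditions})
        w = rule.support * rule.coverage
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                key = (genes[i], genes[j])
                weights[key] = weights.get(key, 0.0) + w
    if not weights:
        return []
    top = max(weights.values())
    scale = top if top > 0 else 1.0
    return [
        (g1, g2, w / scale) for (g1, g2), w in sorted(weights.items())
    ]


def write_edges_tsv(edges, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene1\tgene2\tweight\n")
        for g1, g2, w in edges:
            fh.write(f"{g1}\t{g2}\t{w:.10g}\n")


# --------------------------------------------------------------------------
# sklearn estimator


class RipperClassifier(BaseEstimator, ClassifierMixin):
    """Rough-set + RIPPER classifier producing interpretable threshold rules.

    ``fit`` (two classes only) optionally discretizes the features with the
    supervised MDL method, computes the global discernibility function and
    a Johnson reduct, then runs RIPPER on the raw continuous values
    restricted to the reduct. After fitting, ``ruleset_`` holds the ordered
    rules (minority class) plus default class and ``reduct_`` the selected
    attributes.

    Parameters
    ----------
    use_reduct : bool
        Restrict RIPPER's candidate attributes to the Johnson reduct
        computed from the MDL-discretized system (default True).
    per_object_reduct : bool
        Use the union of per-object row functions f(x) rather than the
        global function g(U) when reducting (default False = global).
    """

    def __init__(self, use_reduct=True, per_object_reduct=False,
                 grow_fraction=2 / 3, dl_budget=64.0, k_optimize=2,
                 positive_class=None, feature_names=None, random_state=0):
        self.use_reduct = use_reduct
        self.per_object_reduct = per_object_reduct
        self.grow_fraction = grow_fraction
        self.dl_budget = dl_budget
        self.k_optimize = k_optimize
        self.positive_class = positive_class
        self.feature_names = feature_names
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        names = (
            list(self.feature_names)
            if self.feature_names is not None
            else [f"f{j}" for j in range(X.shape[1])]
        )
        disc = discretize_mdl(X, y)
        system = DecisionSystem(disc, names, y, raw_values=X)
        if self.use_reduct:
            struct = discernibility_matrix(system)
            if self.per_object_reduct:
                conj = simplify_pos(
                    c for i in range(system.n_objects) for c in struct.row_function(i)
                )
            else:
                conj = struct.global_function()
            if conj:
                self.reduct_ = johnson_reduct(conj, attribute_order=names)
            else:
                warnings.warn("no discernible pairs; using all attributes")
                self.reduct_ = list(names)
        else:
            self.reduct_ = list(names)
        params = RipperParams(
            grow_fraction=self.grow_fraction,
            dl_budget=self.dl_budget,
            k_optimize=self.k_optimize,
            seed=self.random_state,
        )
        self.ruleset_ = ripper(
            system, reduct=self.reduct_, params=params,
            positive_class=self.positive_class,
        )
        self.classes_ = np.unique(y)
        self.feature_names_ = names
        return self

    def predict(self, X):
        check_is_fitted(self, "ruleset_")
        X = np.asarray(X, dtype=float)
        col = {g: j for j, g in enumerate(self.feature_names_)}
        out = []
        for row in X:
            mapping = {g: row[j] for g, j in col.items()}
            out.append(self.ruleset_.apply(mapping))
        return np.asarray(out)


# --------------------------------------------------------------------------
# published reference rule set


def published_pdx_rules() -> RuleSet:
    """The published seven-rule classifier separating original human breast
    tumor cells from PDX cells: six threshold rules for the human class and
    a condition-free default assigning everything else to PDX."""
    human, pdx = "Human tumor", "PDX tumor"
    raw = [
        [("KRT19", ">=", 1.939224), ("KRT5", "<=", 0.148786), ("CDH3", "<=", 0.868794)],
        [("EMP1", ">=", 4.237572), ("CAV2", "<=", 1.610886)],
        [("TP53", "<=", 0.291193), ("CXCR4", ">=", 4.367387), ("TGFBR2", "<=", 1.868461)],
        [("CXCR4", "<=", -2.474571), ("CD44", ">=", 0.086944),
         ("PTEN", ">=", 0.143515), ("VIM", "<=", 0.647694)],
        [("PARP2", ">=", 3.111536)],
        [("PLCB4", ">=", 3.744729), ("AKT1", "<=", -0.070679)],
    ]
    rules = [
        DecisionRule(
            conditions=tuple(Condition(g, op, t) for g, op, t in conds),
            outcome=human,
            rank=i,
        )
        for i, conds in enumerate(raw, start=1)
    ]
    return RuleSet(rules, default_class=pdx)
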