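import itertools
import math

import numpy as np
import pytest

from xenodiff import SyntheticSpec, generate
from xenodiff.errors import DegenerateLabelError, LogicError, ParameterError
from xenodiff.rough_rules import (
    DecisionSystem,
    RipperClassifier,
    RipperParams,
    apply_rules,
    build_decision_system,
    discernibility_matrix,
    discretize_mdl,
    foil_gain,
    johnson_reduct,
    published_pdx_rules,
    reduct_discerns_all,
    ripper,
    rule_network_edges,
    simplify_pos,
)

from conftest import make_matrix


# --------------------------------------------------------------------------
# decision systems and generalized decision


def brute_force_generalized_decision(values, labels):
    out = []
    for i, row in enumerate(values):
        ds = {
            labels[j]
            for j, other in enumerate(values)
            if tuple(other) == tuple(row)
        }
        out.append(frozenset(ds))
    return out


class TestDecisionSystem:
    def test_identical_rows_share_union_of_labels(self):
        s = DecisionSystem(
            np.array([[0, 1], [0, 1]]), ["a1", "a2"], np.array(["A", "B"])
        )
        assert s.generalized_decision == [frozenset("AB"), frozenset("AB")]

    def test_distinct_rows_keep_own_label(self):
        s = DecisionSystem(
            np.array([[0, 1], [1, 1], [2, 0]]), ["a1", "a2"],
            np.array(["A", "B", "A"]),
        )
        assert s.generalized_decision == [
            frozenset("A"), frozenset("B"), frozenset("A")
        ]

    def test_matches_brute_force_grouping(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            vals = rng.integers(0, 2, size=(6, 3))
            labs = rng.choice(list("AB"), size=6)
            s = DecisionSystem(vals, ["a", "b", "c"], labs)
            assert s.generalized_decision == brute_force_generalized_decision(
                vals, labs
            )

    def test_build_requires_features_and_imputed(self, tiny_matrix):
        with pytest.raises(ParameterError):
            build_decision_system(tiny_matrix, features=[])
        s = build_decision_system(tiny_matrix, disc="mdl")
        assert s.raw_values.shape == tiny_matrix.values.shape


# --------------------------------------------------------------------------
# discernibility and reducts


class TestDiscernibility:
    def test_same_decision_pairs_are_empty(self):
        s = DecisionSystem(
            np.array([[0, 0], [1, 1]]), ["a1", "a2"], np.array(["A", "A"])
        )
        d = discernibility_matrix(s)
        assert d.entry(0, 1) == frozenset()

    def test_single_differing_attribute(self):
        s = DecisionSystem(
            np.array([[0, 0], [1, 0]]), ["a1", "a2"], np.array(["A", "B"])
        )
        d = discernibility_matrix(s)
        assert d.entry(0, 1) == frozenset({"a1"})
        assert d.global_function() == [frozenset({"a1"})]

    def test_absorption_removes_supersets(self):
        conj = [{"a1", "a3", "a5"}, {"a1", "a2"}, {"a1", "a2", "a4"}]
        out = simplify_pos(conj)
        assert frozenset({"a1", "a2", "a4"}) not in out
        assert set(out) == {frozenset({"a1", "a2"}), frozenset({"a1", "a3", "a5"})}

    def test_idempotence_removes_duplicates(self):
        out = simplify_pos([{"a1"}, {"a1"}, {"a2", "a1"}])
        assert out == [frozenset({"a1"})]

    def test_row_function_simplified(self):
        vals = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 1, 1]])
        labs = np.array(["A", "B", "B", "B"])
        s = DecisionSystem(vals, ["a1", "a2", "a3"], labs)
        d = discernibility_matrix(s)
        # row 0 entries: {a1}, {a1,a2}, {a1,a2,a3} -> absorption keeps {a1}
        assert d.row_function(0) == [frozenset({"a1"})]


def brute_force_min_reduct(system):
    attrs = system.attributes
    for k in range(1, len(attrs) + 1):
        for combo in itertools.combinations(attrs, k):
            if reduct_discerns_all(system, combo):
                return list(combo)
    return list(attrs)


def random_system(rng, max_objects=10, max_attrs=6):
    n = int(rng.integers(2, max_objects + 1))
    p = int(rng.integers(1, max_attrs + 1))
    vals = rng.integers(0, 3, size=(n, p))
    labs = rng.choice(list("AB"), size=n)
    return DecisionSystem(vals, [f"a{j}" for j in range(p)], labs)


class TestJohnsonReduct:
    def test_forced_single_attribute(self):
        # brute force over subsets confirms {a2} is the unique minimal hit
        g = [{"a1", "a2"}, {"a2", "a3"}, {"a2"}]
        assert johnson_reduct(g) == ["a2"]

    def test_singleton_conjunctions_force_both(self):
        assert sorted(johnson_reduct([{"a1"}, {"a2"}])) == ["a1", "a2"]

    def test_frequency_tie_breaks_by_order(self):
        assert johnson_reduct([{"a1", "a2"}]) == ["a1"]

    def test_empty_conjunction_rejected(self):
        with pytest.raises(LogicError):
            johnson_reduct([{"a1"}, set()])

    def test_validity_and_greedy_bound_on_random_systems(self):
        # the reduct must discern everything the full attribute set
        # discerns, and greedy set cover is within (1 + ln m) of optimal
        rng = np.random.default_rng(7)
        for _ in range(60):
            s = random_system(rng)
            d = discernibility_matrix(s)
            g = d.global_function()
            if not g:
                continue
            reduct = johnson_reduct(g, attribute_order=s.attributes)
            assert reduct_discerns_all(s, reduct)
            minimal = brute_force_min_reduct(s)
            assert len(reduct) <= len(minimal) * (1 + math.log(len(g)))


# --------------------------------------------------------------------------
# FOIL gain and RIPPER


class TestFoilGain:
    def test_direct_formula_value(self):
        expect = 6 * (math.log2(6 / 7) - math.log2(0.5))
        assert foil_gain(10, 10, 6, 1) == pytest.approx(expect, abs=1e-9)
        assert expect == pytest.approx(4.666, abs=1e-3)

    def test_covering_nothing_is_zero(self):
        assert foil_gain(10, 10, 0, 0) == 0.0

    def test_pure_negative_exclusion_is_positive(self):
        assert foil_gain(10, 10, 10, 4) > 0

    def test_empty_base_rejected(self):
        with pytest.raises(LogicError):
            foil_gain(0, 0, 0, 0)


def continuous_system(X, y, names=None):
    names = names or [f"g{j + 1}" for j in range(X.shape[1])]
    return DecisionSystem(
        discretize_mdl(X, y), names, np.asarray(y), raw_values=np.asarray(X, float)
    )


class TestRipper:
    def test_perfectly_separated_single_gene(self):
        rng = np.random.default_rng(0)
        y = np.array(["human"] * 30 + ["pdx"] * 90)
        X = rng.normal(0, 0.5, size=(120, 3))
        X[:30, 0] += 5.0
        rs = ripper(continuous_system(X, y), params=RipperParams(seed=0))
        assert rs.default_class == "pdx"
        assert len(rs.rules) == 1
        rule = rs.rules[0]
        assert rule.outcome == "human" and len(rule.conditions) == 1
        assert rule.conditions[0].gene == "g1"
        pred = [rs.apply({f"g{j + 1}": X[i, j] for j in range(3)}) for i in range(120)]
        assert (np.array(pred) == y).all()

    def test_threshold_recovery_with_label_noise(self):
        # planted rule g1 >= 2.0 -> minority class, 5% label noise
        rng = np.random.default_rng(3)
        n = 800
        y = np.array(["pdx"] * 600 + ["human"] * 200)
        X = rng.normal(2, 1, size=(n, 5))
        X[:, 0] = np.where(
            y == "human",
            2.05 + rng.exponential(1, n),
            1.95 - rng.exponential(1, n),
        )
        flip = rng.random(n) < 0.05
        y = np.where(flip, np.where(y == "human", "pdx", "human"), y)
        rs = ripper(continuous_system(X, y), params=RipperParams(seed=0))
        g1_rules = [
            c for r in rs.rules for c in r.conditions if c.gene == "g1" and c.op == ">="
        ]
        assert g1_rules, "no rule on the planted gene"
        assert 1.8 <= g1_rules[0].threshold <= 2.2

    def test_pure_noise_learns_nothing(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(400, 4))
        y = rng.choice(["human", "pdx"], size=400, p=[0.3, 0.7])
        rs = ripper(continuous_system(X, y), params=RipperParams(seed=1))
        assert rs.rules == []
        assert rs.default_class == "pdx"

    def test_every_rule_has_support(self):
        rng = np.random.default_rng(8)
        y = np.array(["human"] * 60 + ["pdx"] * 140)
        X = rng.normal(0, 1, size=(200, 4))
        X[:60, 0] += 2.5
        X[:30, 1] -= 2.5
        rs = ripper(continuous_system(X, y), params=RipperParams(seed=2))
        assert all(r.support >= 1 for r in rs.rules)
        assert all(0 < r.coverage <= 1 for r in rs.rules)
        assert [r.rank for r in rs.rules] == list(range(1, len(rs.rules) + 1))

    def test_reduct_restricts_attributes(self):
        rng = np.random.default_rng(9)
        y = np.array(["human"] * 50 + ["pdx"] * 100)
        X = rng.normal(0, 1, size=(150, 4))
        X[:50, 2] += 4.0
        rs = ripper(continuous_system(X, y), reduct=["g3"], params=RipperParams(seed=0))
        assert {c.gene for r in rs.rules for c in r.conditions} <= {"g3"}

    def test_single_class_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(DegenerateLabelError):
            ripper(continuous_system(X, np.array(["a"] * 5)))


class TestApplyPublishedRules:
    """The published seven-rule classifier applied to constructed cells."""

    GENES = ["KRT19", "KRT5", "CDH3", "EMP1", "CAV2", "TP53", "CXCR4",
             "TGFBR2", "CD44", "PTEN", "VIM", "PARP2", "PLCB4", "AKT1"]

    def base_cell(self):
        # satisfies none of the six human-tumor rules: every ">=" condition
        # unmet and the "<=" only conditions broken where needed
        cell = {g: 0.0 for g in self.GENES}
        cell["CXCR4"] = 0.0  # between -2.474571 and 4.367387
        cell["TP53"] = 1.0  # breaks rule 3's TP53 <= 0.291193
        return cell

    def test_default_rule_for_unmatched_cell(self):
        rs = published_pdx_rules()
        assert apply_rules(rs, self.base_cell()) == "PDX tumor"

    def test_high_parp2_triggers_rule_5(self):
        rs = published_pdx_rules()
        cell = self.base_cell()
        cell["PARP2"] = 3.5
        assert apply_rules(rs, cell) == "Human tumor"

    def test_keratin_rule_1(self):
        rs = published_pdx_rules()
        cell = self.base_cell()
        cell.update(KRT19=2.0, KRT5=0.1, CDH3=0.5)
        assert apply_rules(rs, cell) == "Human tumor"

    def test_each_rule_fires_alone(self):
        rs = published_pdx_rules()
        for rule in rs.rules:
            cell = self.base_cell()
            for c in rule.conditions:
                margin = 0.5 if c.op == ">=" else -0.5
                cell[c.gene] = c.threshold + margin
            assert apply_rules(rs, cell) == "Human tumor", str(rule)

    def test_missing_gene_value_rejected(self):
        rs = published_pdx_rules()
        cell = self.base_cell()
        del cell["PARP2"]
        cell["KRT19"] = 5.0  # forces evaluation past rule 1 into rule 5
        cell["KRT5"] = 5.0
        with pytest.raises(ParameterError):
            apply_rules(rs, cell)


class TestRuleNetwork:
    def test_published_rule1_contributes_keratin_edges(self):
        rs = published_pdx_rules()
        for r in rs.rules:  # weights need support; assign uniform support
            r.support, r.coverage = 10, 0.1
        edges = {(a, b) for a, b, _ in rule_network_edges(rs)}
        assert {("CDH3", "KRT19"), ("CDH3", "KRT5"), ("KRT19", "KRT5")} <= edges

    def test_single_condition_rules_give_no_edges(self):
        from xenodiff.rough_rules import Condition, DecisionRule, RuleSet

        rs = RuleSet(
            [DecisionRule((Condition("g1", ">=", 1.0),), "A", support=3,
                          coverage=0.5, rank=1)],
            default_class="B",
        )
        assert rule_network_edges(rs) == []

    def test_shared_pair_weights_add_and_normalize(self):
        from xenodiff.rough_rules import Condition, DecisionRule, RuleSet

        mk = lambda sup, cov, rank: DecisionRule(
            (Condition("g1", ">=", 1.0), Condition("g2", "<=", 2.0)),
            "A", support=sup, coverage=cov, rank=rank,
        )
        rs = RuleSet([mk(4, 0.5, 1), mk(2, 0.25, 2)], default_class="B")
        edges = rule_network_edges(rs)
        assert edges == [("g1", "g2", 1.0)]  # 4*0.5 + 2*0.25, self-normalized

        solo = RuleSet([mk(4, 0.5, 1)], default_class="B")
        assert rule_network_edges(solo) == [("g1", "g2", 1.0)]


class TestRipperClassifier:
    def test_sklearn_api_and_accuracy(self):
        from sklearn.base import clone

        rng = np.random.default_rng(1)
        y = np.array(["human"] * 50 + ["pdx"] * 150)
        X = rng.normal(0, 1, size=(200, 4))
        X[:50, 1] += 4.0
        clf = clone(RipperClassifier(random_state=0))
        clf.fit(X, y)
        assert (clf.predict(X) == y).mean() >= 0.95
        assert clf.ruleset_.default_class == "pdx"
        assert set(clf.get_params()) >= {"use_reduct", "dl_budget", "random_state"}

    def test_per_object_reduct_variant_runs(self):
        rng = np.random.default_rng(2)
        y = np.array(["human"] * 40 + ["pdx"] * 80)
        X = rng.normal(0, 1, size=(120, 3))
        X[:40, 0] += 4.0
        clf = RipperClassifier(per_object_reduct=True, random_state=0).fit(X, y)
        assert "f0" in clf.reduct_


def test_planted_rule_recovered_from_synthetic_generator():
    from xenodiff import PlantedRule

    rule = PlantedRule(conditions=((0, ">=", 2.0),), target_class="human", fraction=1.0)
    spec = SyntheticSpec(
        n_cells=400, n_genes=6, class_counts={"human": 100, "pdx": 300},
        informative_genes=0, rule_genes=(rule,), seed=13,
    )
    m, _ = generate(spec)
    rs = ripper(continuous_system(m.values, m.labels, names=m.gene_ids),
                params=RipperParams(seed=0))
    g1 = [c for r in rs.rules for c in r.conditions if c.gene == "g1"]
    assert g1 and g1[0].op == ">=" and 1.8 <= g1[0].threshold <= 2.2
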