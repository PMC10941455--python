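"""Rule extraction, MCC scoring, association and redundancy pruning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from embryosig.rules import (
    Condition,
    ConfusionCounts,
    Rule,
    binary_phi,
    build_rule_graph,
    category_composition,
    confusion,
    extract_rules,
    fire_vector,
    isolated_rules,
    mcc,
    rule_association,
    rule_fire,
    select_rules,
    simplify_conditions,
    write_dot,
    write_graphml,
)

from conftest import make_cohort, make_record


class TestMCC:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            (ConfusionCounts(tp=5, fp=0, tn=5, fn=0), 1.0),      # perfect
            (ConfusionCounts(tp=0, fp=5, tn=0, fn=5), -1.0),     # inverted
            (ConfusionCounts(tp=3, fp=1, tn=4, fn=2), 10 / np.sqrt(600)),
            (ConfusionCounts(tp=5, fp=5, tn=0, fn=0), 0.0),      # zero marginal
        ],
    )
    def test_known_tables(self, counts, expected):
        assert mcc(counts) == pytest.approx(expected, abs=1e-12)

    def test_phi_oracle_equivalence(self):
        """MCC of a confusion table equals the Pearson correlation of the
        underlying binary prediction/label vectors."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(2, 40))
            pred = rng.integers(0, 2, n)
            true = rng.integers(0, 2, n)
            counts = ConfusionCounts(
                tp=int(np.sum((pred == 1) & (true == 1))),
                fp=int(np.sum((pred == 1) & (true == 0))),
                tn=int(np.sum((pred == 0) & (true == 0))),
                fn=int(np.sum((pred == 0) & (true == 1))),
            )
            if pred.std() == 0 or true.std() == 0:
                assert mcc(counts) == 0.0
            else:
                phi = np.corrcoef(pred, true)[0, 1]
                assert mcc(counts) == pytest.approx(phi, abs=1e-12)


@settings(max_examples=200, derandomize=True)
@given(
    tp=st.integers(0, 50), fp=st.integers(0, 50),
    tn=st.integers(0, 50), fn=st.integers(0, 50),
)
def test_mcc_symmetries(tp, fp, tn, fn):
    """MCC is bounded, invariant to swapping the positive/negative class,
    and flips sign when the prediction is negated."""
    c = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    v = mcc(c)
    assert -1.0 <= v <= 1.0
    swapped = ConfusionCounts(tp=tn, fp=fn, tn=tp, fn=fp)
    assert mcc(swapped) == pytest.approx(v, abs=1e-12)
    negated = ConfusionCounts(tp=fp, fp=tp, tn=fn, fn=tn)
    assert mcc(negated) == pytest.approx(-v, abs=1e-12)


class TestRuleBasics:
    def test_empty_rule_invalid(self):
        with pytest.raises(ValueError):
            Rule((), "BL")

    def test_simplification_tightest_interval(self):
        conds = (
            Condition("t4", "<=", 40.0),
            Condition("t4", "<=", 38.0),
            Condition("t4", ">", 30.0),
            Condition("imcs", ">", 6.0),
        )
        simplified = simplify_conditions(conds)
        t4 = {(c.op, c.threshold) for c in simplified if c.feature == "t4"}
        assert t4 == {(">", 30.0), ("<=", 38.0)}

    def test_contradictory_interval_rejected(self):
        with pytest.raises(ValueError, match="empty interval"):
            Rule((Condition("t4", "<=", 30.0), Condition("t4", ">", 35.0)), "BL")

    def test_fire_and_missing_policy(self):
        rule = Rule((Condition("t4", "<=", 40.0), Condition("imcs", ">", 6.0)), "BL")
        assert rule_fire(rule, {"t4": 38.0, "imcs": 7.0})
        assert not rule_fire(rule, {"t4": 41.0, "imcs": 7.0})
        assert not rule_fire(rule, {"t4": float("nan"), "imcs": 7.0})

    def test_json_round_trip(self):
        rule = Rule((Condition("t4", "<=", 40.0),), "BL", support=10,
                    confusion=ConfusionCounts(5, 5, 10, 2), mcc=0.3)
        back = Rule.from_dict(rule.to_dict())
        assert back.key() == rule.key()
        assert back.mcc == rule.mcc


class TestConfusion:
    def _table(self, labels):
        return make_cohort(
            [make_record(embryo_id=f"E{i}", label=l) for i, l in enumerate(labels)]
        )

    def test_always_true_rule_saturates(self):
        table = self._table(["BL", "BL", "nBL", "nBL", "nBL"])
        rule = Rule((Condition("t4", "<=", 1e9),), "BL")
        conf = confusion(rule, table)
        assert (conf.tp, conf.fp, conf.tn, conf.fn) == (2, 3, 0, 0)

    def test_perfect_rule(self):
        table = self._table(["BL", "BL", "nBL"])
        table.df.loc[2, "imcs"] = 4.0
        rule = Rule((Condition("imcs", ">", 6.0),), "BL")
        conf = confusion(rule, table)
        assert (conf.tp, conf.fp, conf.tn, conf.fn) == (2, 0, 1, 0)
        assert mcc(conf) == 1.0

    def test_four_row_enumeration(self):
        table = self._table(["BL", "nBL", "BL", "nBL"])
        table.df["imcs"] = [8.0, 8.0, 5.0, 5.0]  # fires on rows 0, 1
        rule = Rule((Condition("imcs", ">", 6.0),), "BL")
        conf = confusion(rule, table)
        assert (conf.tp, conf.fp, conf.tn, conf.fn) == (1, 1, 1, 1)

    def test_counts_sum_to_n(self, planted_cohort):
        table, truth = planted_cohort
        rule = truth.planted_rules[0][0]
        conf = confusion(rule, table)
        assert conf.n == len(table)

    def test_empty_table_errors(self):
        table = self._table(["BL", "nBL"]).subset(np.array([], dtype=int))
        rule = Rule((Condition("imcs", ">", 6.0),), "BL")
        with pytest.raises(ValueError):
            confusion(rule, table)


class TestAssociation:
    def test_self_association_is_one(self, planted_cohort):
        table, truth = planted_cohort
        rule = truth.planted_rules[0][0]
        assert rule_association(rule, rule, table) == pytest.approx(1.0)

    def test_complement_is_minus_one(self, planted_cohort):
        table, _ = planted_cohort
        a = Rule((Condition("imcs", ">", 6.0),), "BL")
        b = Rule((Condition("imcs", "<=", 6.0),), "nBL")
        assert rule_association(a, b, table) == pytest.approx(-1.0)

    def test_orthogonal_firing_vectors(self):
        assert binary_phi(np.array([1, 1, 0, 0]), np.array([1, 0, 1, 0])) == 0.0

    def test_symmetry(self, planted_cohort):
        table, _ = planted_cohort
        a = Rule((Condition("imcs", ">", 6.5),), "BL")
        b = Rule((Condition("t4", "<=", 39.0),), "BL")
        assert rule_association(a, b, table) == rule_association(b, a, table)


class TestExtraction:
    def _toy_table(self):
        vals = [1.0, 2.0, 9.0, 10.0]
        labels = ["nBL", "nBL", "BL", "BL"]
        return make_cohort(
            [make_record(embryo_id=f"E{i}", label=l, imcs=v)
             for i, (v, l) in enumerate(zip(vals, labels))]
        )

    def test_midpoint_split_on_toy(self):
        """Depth-1 CART on {1,2,9,10} with labels --++ splits at the
        midpoint 5.5 and yields a positive rule imcs > 5.5."""
        table = self._toy_table()
        rules = extract_rules(table, feature_set=["imcs"], n_trees=1, max_depth=1,
                              min_support_frac=0.0, bootstrap=False, seed=0)
        pos = [r for r in rules if r.predicted_class == "BL"]
        assert len(pos) == 1
        (cond,) = pos[0].conditions
        assert cond.op == ">"
        assert cond.threshold == pytest.approx(5.5)
        assert pos[0].mcc == pytest.approx(1.0)

    def test_deduplication(self):
        table = self._toy_table()
        rules = extract_rules(table, feature_set=["imcs"], n_trees=20, max_depth=1,
                              min_support_frac=0.0, bootstrap=False, seed=0)
        keys = [r.key() for r in rules]
        assert len(keys) == len(set(keys))
        assert len(rules) == 2  # one positive + one negative leaf path

    def test_full_support_filter_kills_everything(self):
        table = self._toy_table()
        rules = extract_rules(table, feature_set=["imcs"], n_trees=5, max_depth=2,
                              min_support_frac=1.0, seed=0)
        assert rules == []

    def test_single_class_errors(self):
        table = make_cohort([make_record(embryo_id=f"E{i}", label="BL")
                             for i in range(4)])
        with pytest.raises(ValueError):
            extract_rules(table, n_trees=1)

    def test_supports_and_mcc_bounds(self, planted_cohort):
        table, _ = planted_cohort
        rules = extract_rules(table, n_trees=10, seed=3)
        n = len(table)
        for r in rules:
            assert r.support >= int(np.ceil(0.05 * n))
            assert -1.0 <= r.mcc <= 1.0


class TestSelection:
    def test_identical_rules_collapse(self, planted_cohort):
        table, _ = planted_cohort
        a = Rule((Condition("imcs", ">", 6.5),), "BL")
        b = Rule((Condition("imcs", ">", 6.5),), "BL")
        from embryosig.rules import score_rule

        score_rule(a, table)
        score_rule(b, table)
        selected, _ = select_rules([a, b], table)
        assert len(selected) == 1

    def test_negative_mcc_dropped(self, planted_cohort):
        table, _ = planted_cohort
        bad = Rule((Condition("imcs", "<=", 6.5),), "BL")  # anti-predictive
        from embryosig.rules import score_rule

        score_rule(bad, table)
        assert bad.mcc < 0
        selected, _ = select_rules([bad], table)
        assert selected == []

    def test_input_order_invariance(self, planted_cohort):
        table, _ = planted_cohort
        rules = extract_rules(table, n_trees=8, seed=1)
        s1, _ = select_rules(list(rules), table)
        s2, _ = select_rules(list(reversed(rules)), table)
        assert [r.key() for r in s1] == [r.key() for r in s2]

    def test_planted_rules_survive_near_duplicates(self):
        """Two independent true rules plus noisy near-duplicates: both true
        rules survive and the survivor graph is (almost) edge-free."""
        from embryosig.rules import score_rule
        from embryosig.simulate import SimulationConfig, generate_cohort

        for seed in range(5):
            cfg = SimulationConfig(
                n_patients=40, n_embryos=300, seed=seed,
                planted_rules=(
                    (Rule((Condition("imcs", ">", 6.5),), "BL"), 3.0),
                    (Rule((Condition("total_fsh", "<=", 2250.0),), "BL"), 3.0),
                ),
            )
            table, truth = generate_cohort(cfg)
            true_a = Rule((Condition("imcs", ">", 6.5),), "BL")
            true_b = Rule((Condition("total_fsh", "<=", 2250.0),), "BL")
            near_dups = [
                Rule((Condition("imcs", ">", 6.5), Condition("age", "<=", 60.0)), "BL"),
                Rule((Condition("imcs", ">", 6.51),), "BL"),
                Rule((Condition("total_fsh", "<=", 2250.5),), "BL"),
                Rule((Condition("total_fsh", "<=", 2249.0),), "BL"),
                Rule((Condition("imcs", ">", 6.49),), "BL"),
            ]
            pool = [true_a, true_b] + near_dups
            for r in pool:
                score_rule(r, table)
            selected, graph = select_rules(pool, table)
            keys = {r.conditions[0].feature for r in selected}
            assert {"imcs", "total_fsh"} <= keys
            assert graph.number_of_edges() <= 1

    def test_survivor_invariants(self, planted_cohort):
        table, _ = planted_cohort
        rules = extract_rules(table, n_trees=10, seed=2)
        selected, graph = select_rules(rules, table)
        for r in selected:
            assert r.mcc > 0.0
        assert graph.number_of_nodes() == len(selected)
        assert all(d["weight"] > 0.8 for _, _, d in graph.edges(data=True))
        iso = isolated_rules(graph)
        assert all(graph.degree(i) == 0 for i in iso)


def test_category_composition():
    rules = [
        Rule((Condition("imcs", ">", 6.0), Condition("age", "<=", 35.0)), "BL"),
        Rule((Condition("osi", ">", 5.0), Condition("imcs", ">", 7.0)), "BL"),
    ]
    comp = category_composition(rules)
    assert comp == {"woman": 1, "cos": 1, "embryo": 1}


def test_graph_exports(tmp_path, planted_cohort):
    table, _ = planted_cohort
    rules = extract_rules(table, n_trees=5, seed=0)
    _, graph = select_rules(rules, table)
    write_graphml(graph, tmp_path / "g.graphml")
    write_dot(graph, tmp_path / "g.dot")
    import networkx as nx

    back = nx.read_graphml(tmp_path / "g.graphml")
    assert back.number_of_nodes() == graph.number_of_nodes()
    assert (tmp_path / "g.dot").read_text().startswith("graph rules")
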