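"""Rule encoding, signature search and frozen evaluation."""

import numpy as np
import pandas as pd
import pytest

from embryosig.classifiers import FAST_ROSTER, ClassifierRoster
from embryosig.crossval import CVSpec, auc_score
from embryosig.rules import Condition, Rule, score_rule
from embryosig.signature import (
    Signature,
    encode_rules,
    evaluate_on_cohort,
    order_rules,
    search_signature,
)
from embryosig.simulate import SimulationConfig, default_planted_rules, generate_cohort

from conftest import make_cohort, make_record

SPEC = CVSpec(n_folds=5, n_repeats=2, seed=0)
ROSTER = ClassifierRoster(("logistic_regression",), seed=0)


def _scored(rule, table):
    return score_rule(rule, table)


class TestEncoding:
    def test_direct_evaluation(self):
        table = make_cohort(
            [make_record(embryo_id="E1", imcs=8.0),
             make_record(embryo_id="E2", imcs=8.0)]
        )
        r_fires = Rule((Condition("imcs", ">", 6.0),), "BL")
        r_never = Rule((Condition("imcs", ">", 9.0),), "BL")
        X = encode_rules([r_fires, r_never], table)
        assert X.tolist() == [[1.0, 0.0], [1.0, 0.0]]

    def test_duplicate_rule_duplicate_column(self, planted_cohort):
        table, _ = planted_cohort
        r = Rule((Condition("imcs", ">", 6.5),), "BL")
        X = encode_rules([r, r], table)
        assert np.array_equal(X[:, 0], X[:, 1])

    def test_purity(self, planted_cohort):
        table, _ = planted_cohort
        r = Rule((Condition("t4", "<=", 39.0),), "BL")
        assert np.array_equal(encode_rules([r], table), encode_rules([r], table))

    def test_empty_rule_list_errors(self, planted_cohort):
        table, _ = planted_cohort
        with pytest.raises(ValueError):
            encode_rules([], table)


class TestSearch:
    def test_perfect_rule_gives_k1_auc1(self, noiseless_single_rule_cohort):
        table, truth = noiseless_single_rule_cohort
        rule = _scored(truth.planted_rules[0][0], table)
        sig, report = search_signature([rule], table, roster=ROSTER, spec=SPEC)
        assert sig.chosen_k == 1
        assert report.curve["auc_mean"].iloc[0] == pytest.approx(1.0)

    def test_curve_length_equals_rule_count(self, planted_cohort):
        table, truth = planted_cohort
        rules = [_scored(r, table) for r, _ in truth.planted_rules]
        sig, report = search_signature(rules, table, roster=ROSTER, spec=SPEC)
        assert list(report.curve["k"]) == [1, 2, 3]
        assert 1 <= sig.chosen_k <= 3

    def test_mcc_ordering(self, planted_cohort):
        table, truth = planted_cohort
        rules = [_scored(r, table) for r, _ in truth.planted_rules]
        ordered = order_rules(rules)
        mccs = [r.mcc for r in ordered]
        assert mccs == sorted(mccs, reverse=True)

    def test_planted_recovery_close_to_bayes(self):
        """True rules + noise rules: the search keeps a small signature
        whose CV AUC is within 0.05 of the generator's Bayes AUC."""
        ok = 0
        for seed in range(3):
            cfg = SimulationConfig(
                n_patients=100, n_embryos=1000,
                planted_rules=default_planted_rules(), label_noise=0.1, seed=seed,
            )
            table, truth = generate_cohort(cfg)
            true_rules = [_scored(r, table) for r, _ in truth.planted_rules]
            rng = np.random.default_rng(seed)
            noise_rules = [
                _scored(
                    Rule((Condition("bmi", ">", float(rng.uniform(19, 30))),), "BL"),
                    table,
                )
                for _ in range(10)
            ]
            sig, report = search_signature(
                true_rules + noise_rules, table,
                roster=ClassifierRoster(FAST_ROSTER, seed=seed),
                spec=CVSpec(n_folds=10, n_repeats=2, seed=seed),
            )
            bayes = truth.bayes_auc(table.labels)
            if sig.chosen_k <= 6 and report.curve["auc_mean"].max() >= bayes - 0.05:
                ok += 1
        assert ok >= 2

    def test_composition_counts_distinct_features(self, planted_cohort):
        table, truth = planted_cohort
        rules = [_scored(r, table) for r, _ in truth.planted_rules]
        sig, _ = search_signature(rules, table, roster=ROSTER, spec=SPEC)
        assert sum(sig.composition.values()) == len(
            set().union(*(r.features for r in sig.rules))
        )


class TestEvaluation:
    def _signature(self, table, rules):
        scored = [_scored(r, table) for r in rules]
        from embryosig.rules import category_composition

        return Signature(
            rules=scored, chosen_k=len(scored), classifier="logistic_regression",
            composition=category_composition(scored),
        )

    def test_memorization_limit(self, noiseless_single_rule_cohort):
        table, truth = noiseless_single_rule_cohort
        sig = self._signature(table, [truth.planted_rules[0][0]])
        report = evaluate_on_cohort(sig, table, table, roster=ROSTER)
        assert report.max_auc == pytest.approx(1.0)
        assert report.max_accuracy == pytest.approx(1.0)

    def test_reported_max_bounds_members(self, planted_cohort):
        table, truth = planted_cohort
        sig = self._signature(table, [r for r, _ in truth.planted_rules])
        report = evaluate_on_cohort(
            sig, table, table, roster=ClassifierRoster(FAST_ROSTER)
        )
        assert (report.per_classifier["auc"] <= report.max_auc + 1e-12).all()
        assert (report.per_classifier["accuracy"] <= report.max_accuracy + 1e-12).all()

    def test_label_permutation_null(self):
        """Permuted validation labels: max-roster AUC hovers near chance."""
        cfg = SimulationConfig(n_patients=80, n_embryos=500,
                               planted_rules=default_planted_rules(), seed=3)
        table, truth = generate_cohort(cfg)
        sig = self._signature(table, [r for r, _ in truth.planted_rules])
        rng = np.random.default_rng(0)
        aucs = []
        for _ in range(10):
            permuted = rng.permutation(table.labels)
            report = evaluate_on_cohort(
                sig, table, table, validation_labels=permuted,
                roster=ClassifierRoster(FAST_ROSTER),
            )
            aucs.append(report.max_auc)
        assert 0.40 <= float(np.mean(aucs)) <= 0.60

    def test_no_leakage_of_validation_labels(self, planted_cohort):
        """Mutating validation labels must not change predicted scores,
        only the metrics computed from them."""
        table, truth = planted_cohort
        sig = self._signature(table, [r for r, _ in truth.planted_rules])
        r1 = evaluate_on_cohort(sig, table, table, roster=ROSTER)
        flipped = 1.0 - table.labels
        r2 = evaluate_on_cohort(sig, table, table, validation_labels=flipped,
                                roster=ROSTER)
        # scores unchanged => AUC exactly mirrors: auc(flipped) = 1 - auc
        assert r2.max_auc == pytest.approx(1.0 - r1.per_classifier["auc"].iloc[0])

    def test_single_rule_logreg_matches_indicator_auc(self, planted_cohort):
        """With one rule and a monotone classifier the AUC equals the raw
        rule-indicator AUC computed by pair concordance."""
        table, truth = planted_cohort
        rule = truth.planted_rules[0][0]
        sig = self._signature(table, [rule])
        report = evaluate_on_cohort(sig, table, table, roster=ROSTER)
        indicator = encode_rules([sig.rules[0]], table)[:, 0]
        assert report.max_auc == pytest.approx(
            auc_score(table.labels, indicator), abs=1e-12
        )

    def test_empty_validation_errors(self, planted_cohort):
        table, truth = planted_cohort
        sig = self._signature(table, [truth.planted_rules[0][0]])
        empty = table.subset(np.array([], dtype=int))
        with pytest.raises(ValueError):
            evaluate_on_cohort(sig, table, empty, roster=ROSTER)
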