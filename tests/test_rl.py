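import itertools

import numpy as np
import pytest

from trlfm.io import GoodRuleCriteria
from trlfm.rl import (
    ABSTAIN,
    Beam,
    Rule,
    certainty_factor,
    fisher_exact_p,
    initial_rules,
    is_good,
    learn_rules,
    predict,
    rule_statistics,
    specialize,
)
from trlfm.synth import WORKED_EXAMPLE_RULE, worked_example_dataset

from .conftest import make_discrete_dataset, random_discrete_dataset
from .oracles import brute_rule_stats, enumerate_rule_space, hypergeom_tail


class TestCertaintyFactor:
    def test_laplace_at_zero_coverage_is_uninformative(self):
        assert certainty_factor(0, 0, "laplace", n_classes=2) == 0.5

    def test_precision_on_reference_counts(self):
        assert certainty_factor(56, 4, "precision") == pytest.approx(56 / 60)

    def test_laplace_on_reference_counts(self):
        assert certainty_factor(56, 4, "laplace", n_classes=2) == pytest.approx(57 / 62)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            certainty_factor(-1, 0)


class TestFisherExact:
    def test_empty_coverage_gives_one(self):
        assert fisher_exact_p(0, 0, 3, 5) == 1.0

    def test_two_by_two_diagonal_table(self):
        assert fisher_exact_p(2, 0, 0, 2) == pytest.approx(1 / 6)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_for_small_tables(self, seed):
        rng = np.random.default_rng(seed)
        while True:
            cells = rng.multinomial(int(rng.integers(1, 13)), [0.25] * 4)
            if cells.sum() <= 12:
                break
        a, b, c, d = (int(x) for x in cells)
        assert fisher_exact_p(a, b, c, d) == pytest.approx(hypergeom_tail(a, b, c, d))


class TestRuleStatistics:
    def test_reference_rule_counts_on_worked_dataset(self):
        ds = worked_example_dataset()
        rule = rule_statistics(Rule(conjuncts=WORKED_EXAMPLE_RULE, consequent="Case"), ds)
        assert (rule.tp, rule.fp, rule.coverage) == (56, 4, 60)

    def test_rule_matching_nothing(self):
        ds = make_discrete_dataset([(0, "Case"), (0, "Control")], columns=["v1"])
        rule = rule_statistics(Rule(conjuncts=(("v1", 1),), consequent="Case"), ds)
        assert (rule.tp, rule.fp, rule.coverage) == (0, 0, 0)

    @pytest.mark.parametrize("seed", range(8))
    def test_counts_match_per_instance_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        ds = random_discrete_dataset(rng)
        var = ds.variable_names[int(rng.integers(len(ds.variable_names)))]
        conjuncts = ((var, int(rng.integers(2))),)
        rule = rule_statistics(Rule(conjuncts=conjuncts, consequent="Case"), ds)
        assert (rule.tp, rule.fp) == brute_rule_stats(conjuncts, "Case", ds)
        assert rule.tp + rule.fp == rule.coverage

    def test_unknown_variable_rejected(self):
        ds = make_discrete_dataset([(0, "Case"), (1, "Control")], columns=["v1"])
        with pytest.raises(KeyError):
            rule_statistics(Rule(conjuncts=(("nope", 0),), consequent="Case"), ds)


class TestInitialRules:
    def test_two_rules_per_marker_value(self):
        ds = make_discrete_dataset([(0, "Case"), (1, "Control")], columns=["v1"])
        rules = initial_rules(ds)
        assert len(rules) == 4  # 1 var x 2 intervals x 2 classes
        per_value = {}
        for r in rules:
            per_value.setdefault(r.conjuncts[0], set()).add(r.consequent)
        assert all(v == {"Case", "Control"} for v in per_value.values())

    def test_count_formula(self):
        rows = [(0, 1, 0, "Case"), (1, 0, 1, "Control"),
                (0, 0, 0, "Case"), (1, 1, 1, "Control")]
        ds = make_discrete_dataset(rows)
        assert len(initial_rules(ds)) == 3 * 2 * 2


class TestSpecialize:
    @pytest.fixture
    def toy(self):
        return make_discrete_dataset(
            [(0, 0, 0, "Case"), (1, 1, 0, "Control"), (0, 1, 1, "Case"),
             (1, 0, 1, "Control")]
        )

    def test_specialization_count(self, toy):
        rule = rule_statistics(Rule(conjuncts=(("v1", 0),), consequent="Case"), toy)
        children = specialize(rule, toy)
        assert len(children) == 4  # 2 free binary variables x 2 intervals

    def test_rule_at_conjunct_cap_yields_nothing(self, toy):
        crit = GoodRuleCriteria(max_conjuncts=1)
        rule = rule_statistics(Rule(conjuncts=(("v1", 0),), consequent="Case"), toy)
        assert specialize(rule, toy, crit) == []

    def test_coverage_never_increases(self, toy):
        for parent in initial_rules(toy):
            for child in specialize(parent, toy):
                assert child.coverage <= parent.coverage


class TestIsGood:
    def test_perfect_rule_accepted(self):
        ds = make_discrete_dataset([(0, "Case")] * 5 + [(1, "Control")] * 5,
                                   columns=["v1"])
        rule = rule_statistics(Rule(conjuncts=(("v1", 0),), consequent="Case"), ds)
        assert is_good(rule, GoodRuleCriteria(min_cf=0.7), ds)

    def test_zero_coverage_rejected(self):
        ds = make_discrete_dataset([(0, "Case"), (0, "Control")], columns=["v1"])
        rule = rule_statistics(Rule(conjuncts=(("v1", 1),), consequent="Case"), ds)
        assert not is_good(rule, GoodRuleCriteria(min_coverage=1), ds)

    def test_cf_exactly_at_threshold_accepted(self):
        ds = make_discrete_dataset([(0, "Case")] * 10 + [(1, "Control")] * 2,
                                   columns=["v1"])
        rule = rule_statistics(Rule(conjuncts=(("v1", 0),), consequent="Case"), ds)
        crit = GoodRuleCriteria(min_cf=rule.cf, min_coverage=1)
        assert is_good(rule, crit, ds)


def oracle_model(dataset, criteria):
    """Exhaustive-search reference: enumerate the whole rule space, keep
    good rules, admit in beam-key order with inductive strengthening."""
    scored = []
    for conjuncts, cls in enumerate_rule_space(dataset, criteria.max_conjuncts):
        tp, fp = brute_rule_stats(conjuncts, cls, dataset)
        cf = certainty_factor(tp, fp, criteria.cf_function,
                              n_classes=len(dataset.class_domain))
        scored.append(Rule(conjuncts=conjuncts, consequent=cls, tp=tp, fp=fp, cf=cf))
    scored.sort(key=Rule.sort_key)
    accepted, covered = [], set()
    y = dataset.labels_array()
    for rule in scored:
        negatives = int((y != rule.consequent).sum())
        if rule.cf < criteria.min_cf or rule.coverage < criteria.min_coverage:
            continue
        if negatives and rule.fp / negatives > criteria.max_fp_rate:
            continue
        new = {
            i for i, sid in enumerate(dataset.sample_ids)
            if y[i] == rule.consequent
            and all(dataset.values.loc[sid][v] == iv for v, iv in rule.conjuncts)
        }
        if criteria.inductive_strengthening > 0 and \
                len(new - covered) < criteria.inductive_strengthening:
            continue
        accepted.append((rule.conjuncts, rule.consequent, rule.tp, rule.fp))
        covered |= new
    return accepted


class TestLearnRules:
    @pytest.mark.parametrize("strengthening", [0, 1])
    @pytest.mark.parametrize("seed", range(6))
    def test_unbounded_beam_equals_exhaustive_search(self, seed, strengthening):
        """With the beam wider than the rule space, beam search returns
        exactly the exhaustive-search rule set passing the criteria."""
        rng = np.random.default_rng(seed)
        ds = random_discrete_dataset(rng, n_vars=3, n_samples=8)
        criteria = GoodRuleCriteria(
            min_cf=0.6, min_coverage=2, max_fp_rate=0.5, max_conjuncts=3,
            inductive_strengthening=strengthening, beam_width=10_000,
        )
        model = learn_rules(ds, criteria)
        got = [(r.conjuncts, r.consequent, r.tp, r.fp) for r in model.rules]
        want = [(tuple(sorted(c)), cls, tp, fp)
                for c, cls, tp, fp in oracle_model(ds, criteria)]
        got_norm = [(tuple(sorted(c)), cls, tp, fp) for c, cls, tp, fp in got]
        assert got_norm == want

    def test_best_rule_matches_exhaustive_best(self):
        rng = np.random.default_rng(10)
        ds = random_discrete_dataset(rng, n_vars=2, n_samples=6)
        criteria = GoodRuleCriteria(min_cf=0.0, min_coverage=1, max_fp_rate=1.0,
                                    max_conjuncts=2, inductive_strengthening=0,
                                    beam_width=10_000)
        model = learn_rules(ds, criteria)
        oracle = oracle_model(ds, criteria)
        assert (tuple(sorted(model.rules[0].conjuncts)), model.rules[0].consequent) \
            == (tuple(sorted(oracle[0][0])), oracle[0][1])

    def test_impossible_coverage_gives_empty_model(self):
        ds = make_discrete_dataset([(0, "Case"), (1, "Control")], columns=["v1"])
        model = learn_rules(ds, GoodRuleCriteria(min_coverage=10))
        assert model.rules == ()

    def test_perfect_predictor_yields_clean_single_conjunct_rule(self):
        rows = [(0, "Case")] * 5 + [(1, "Control")] * 5
        ds = make_discrete_dataset(rows, columns=["marker"])
        model = learn_rules(ds, GoodRuleCriteria(min_cf=0.8, min_coverage=4))
        assert any(r.conjuncts == (("marker", 0),) and r.fp == 0 for r in model.rules)

    def test_xor_interaction_found_despite_useless_parents(self):
        """A two-variable interaction whose single-conjunct parents are
        uninformative is still reached by the search."""
        rows = [(0, 0, "Case"), (1, 1, "Case"), (0, 1, "Control"), (1, 0, "Control")] * 3
        ds = make_discrete_dataset(rows)
        model = learn_rules(ds, GoodRuleCriteria(min_cf=0.8, min_coverage=3,
                                                 max_fp_rate=0.0, max_conjuncts=2))
        antecedents = {frozenset(r.conjuncts) for r in model.rules}
        assert frozenset({("v1", 0), ("v2", 0)}) in antecedents

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        ds = random_discrete_dataset(rng, n_vars=3, n_samples=8)
        crit = GoodRuleCriteria(min_cf=0.5, min_coverage=1, max_fp_rate=1.0)
        assert learn_rules(ds, crit, seed=1) == learn_rules(ds, crit, seed=1)

    def test_all_model_rules_pass_criteria_and_fit_beam(self):
        rng = np.random.default_rng(8)
        ds = random_discrete_dataset(rng, n_vars=3, n_samples=8)
        crit = GoodRuleCriteria(min_cf=0.6, min_coverage=2, max_fp_rate=0.5,
                                beam_width=5)
        model = learn_rules(ds, crit)
        assert len(model.rules) <= crit.beam_width
        for r in model.rules:
            assert is_good(r, crit, ds)
            assert r.tp + r.fp == r.coverage


class TestBeam:
    def test_capacity_and_ordering(self):
        beam = Beam(2)
        r1 = Rule(conjuncts=(("a", 0),), consequent="x", tp=5, fp=0, cf=0.9)
        r2 = Rule(conjuncts=(("b", 0),), consequent="x", tp=4, fp=1, cf=0.7)
        r3 = Rule(conjuncts=(("c", 0),), consequent="x", tp=6, fp=0, cf=0.95)
        assert beam.add(r1) and beam.add(r2) and beam.add(r3)
        contents = list(beam)
        assert len(contents) == 2
        assert contents == [r3, r1]  # worst (r2) evicted, cf-descending order

    def test_duplicates_suppressed(self):
        beam = Beam(5)
        r = Rule(conjuncts=(("a", 0), ("b", 1)), consequent="x", cf=0.5)
        r_reordered = Rule(conjuncts=(("b", 1), ("a", 0)), consequent="x", cf=0.5)
        assert beam.add(r)
        assert not beam.add(r_reordered)

    def test_conjuncts_on_same_variable_rejected(self):
        with pytest.raises(ValueError):
            Rule(conjuncts=(("a", 0), ("a", 1)), consequent="x")


class TestPredict:
    @pytest.fixture
    def model(self):
        ds = make_discrete_dataset(
            [(0, 0, "Case")] * 5 + [(1, 1, "Control")] * 5)
        return learn_rules(ds, GoodRuleCriteria(min_cf=0.7, min_coverage=3))

    def test_no_matching_rule_abstains_with_neutral_score(self, model):
        cls, score = predict(model, {"v1": 9, "v2": 9})
        assert cls == ABSTAIN and score == 0.0

    def test_single_matching_rule(self):
        from trlfm.rl import RuleModel

        rule = Rule(conjuncts=(("v1", 0),), consequent="Case", tp=9, fp=0, cf=0.9)
        model = RuleModel(rules=(rule,), criteria=GoodRuleCriteria(),
                          class_domain=("Case", "Control"))
        cls, score = predict(model, {"v1": 0})
        assert cls == "Case" and score == pytest.approx(0.9)

    def test_weighted_vote_arithmetic(self):
        from trlfm.rl import RuleModel

        rules = (
            Rule(conjuncts=(("a", 0),), consequent="Case", tp=8, fp=0, cf=0.8),
            Rule(conjuncts=(("b", 0),), consequent="Case", tp=7, fp=0, cf=0.7),
            Rule(conjuncts=(("c", 0),), consequent="Control", tp=9, fp=0, cf=0.9),
        )
        model = RuleModel(rules=rules, criteria=GoodRuleCriteria(),
                          class_domain=("Case", "Control"))
        cls, score = predict(model, {"a": 0, "b": 0, "c": 0})
        assert cls == "Case"
        assert score == pytest.approx(0.8 + 0.7 - 0.9)
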